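"""Orchestration: run the chemical profile, bioactivity scan and phylogeny
stages over a panel and write machine-readable outputs plus a MANIFEST.

Outputs (all plain text, deterministic under fixed config + seed):

* ``chemical_profile.csv``  — one row per sequence, all physicochemical columns
* ``bioactivity_scan.csv``  — one row per sequence, Table-style scan columns
* ``similarity_combined.csv`` / ``similarity_<class>.csv`` — percent-identity
  matrices (full square, header row/column of labels)
* ``pdistance_*.csv``       — matching p-distance matrices
* ``tree_combined.nwk`` / ``tree_<class>.nwk`` — rooted NJ trees with
  bootstrap supports as internal labels
* ``MANIFEST.json``         — config hash, seed, per-file sha256, versions

Stage functions are pure in (panel, config); the file layer is separate so
re-running one stage reproduces the full-run artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, bioactivity, physchem, phylo, seqio
from .align import Alignment, progressive_align
from .bioactivity import PropensityParams
from .seqio import CLASS_ORDER, Panel, ProteinSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All run settings; defaults are the analysis' standard constants
    (window 7, threshold 0.225, minimum stretch 12, 1000 bootstrap
    replicates, 90% support confirmation, rat outgroup)."""

    fasta: str | None = None
    metadata: str | None = None
    alignment: str | None = None          # pre-computed gapped FASTA bypass
    outdir: str = "results/run"
    hydrophobic_set: str = "".join(sorted(physchem.HYDROPHOBIC_SET))
    basic_set: str = "".join(sorted(physchem.BASIC_SET))
    antiox_set: str = "".join(sorted(bioactivity.ANTIOXIDANT_SET))
    window: int = 7
    threshold: float = 0.225
    min_stretch: int = 12
    n_reps: int = 1000
    seed: int = 0
    outgroup: str | None = None           # None -> auto-detect a rat-like label
    support_confirm: float = 90.0
    precision: int = 2
    phylogeny: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        PropensityParams(self.window, self.threshold, self.min_stretch)

    @property
    def scan_params(self) -> PropensityParams:
        return PropensityParams(self.window, self.threshold, self.min_stretch)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_panel(config: RunConfig) -> dict[str, dict[str, ProteinSequence]]:
    if config.fasta is None:
        raise ValueError("config.fasta is required to load a panel")
    records = seqio.read_fasta(config.fasta, metadata=config.metadata)
    return seqio.build_panel(records)


def _iter_panel(panel: Panel):
    for species in panel:
        classes = panel[species]
        ordered = [c for c in CLASS_ORDER if c in classes]
        ordered += [c for c in classes if c not in CLASS_ORDER]
        for cls in ordered:
            yield species, cls, classes[cls]


def run_profile(panel: Panel, config: RunConfig | None = None) -> pd.DataFrame:
    """Chemical table: one row per panel sequence (full precision)."""
    config = config or RunConfig()
    if not panel:
        raise ValueError("empty panel")
    rows = []
    hset = frozenset(config.hydrophobic_set)
    bset = frozenset(config.basic_set)
    for species, cls, seq in _iter_panel(panel):
        prof = physchem.physchem_profile(seq)
        rows.append(
            dict(
                species=species, casein_class=cls, length=prof.length,
                mw_kda=round(prof.mw / 1000.0, 3),
                hydrophobicity_pct=physchem.hydrophobicity_index(seq, hset),
                basic_pct=physchem.basic_fraction(seq, bset),
                neg_count=prof.neg_count, pos_count=prof.pos_count,
                aliphatic_index=prof.aliphatic_index,
                instability_index=prof.instability_index,
            )
        )
    return pd.DataFrame(rows)


def run_scan(panel: Panel, config: RunConfig | None = None) -> pd.DataFrame:
    """Bioactivity table mirroring the biological-parameters layout."""
    config = config or RunConfig()
    if not panel:
        raise ValueError("empty panel")
    params = config.scan_params
    aset = frozenset(config.antiox_set)
    rows = []
    for species, cls, seq in _iter_panel(panel):
        scan = bioactivity.scan_sequence(seq, params)
        rows.append(
            dict(
                species=species, casein_class=cls,
                hydrophobicity_pct=physchem.hydrophobicity_index(seq),
                basic_pct=physchem.basic_fraction(seq),
                n_stretches=len(scan.stretches),
                stretch_intervals=bioactivity.format_intervals(scan.stretches),
                avg_antimicrobial_index=scan.average_index,
                antioxidant_index=bioactivity.antioxidant_index(seq, aset),
            )
        )
    return pd.DataFrame(rows)


def _resolve_outgroup(labels: list[str], config: RunConfig) -> str:
    if config.outgroup is not None:
        if config.outgroup not in labels:
            raise ValueError(f"outgroup {config.outgroup!r} not in panel: {labels}")
        return config.outgroup
    for label in labels:
        if "rat" in label.lower():
            return label
    raise ValueError("no outgroup given and no rat-like label found")


@dataclass
class PhylogenyResult:
    alignment: Alignment
    similarity: phylo.DistanceMatrix
    p_distance: phylo.DistanceMatrix
    tree: phylo.Clade                      # rooted, with bootstrap supports
    confirmed: list[frozenset] = field(default_factory=list)


def _analyse_alignment(aln: Alignment, outgroup: str, config: RunConfig,
                       seed: int) -> PhylogenyResult:
    sim = phylo.similarity_matrix(aln)
    pdist = sim.to_p_distance()
    tree = phylo.bootstrap_supports(aln, n_reps=config.n_reps, seed=seed)
    rooted = phylo.root_on_outgroup(tree, outgroup)
    confirmed = phylo.confirmed_edges(rooted, config.support_confirm)
    return PhylogenyResult(aln, sim, pdist, rooted, confirmed)


def run_phylogeny(
    panel: Panel, config: RunConfig | None = None,
    imported_alignment: Alignment | None = None,
) -> dict[str, PhylogenyResult]:
    """Combined (concatenated) and per-class phylogenies.

    Returns a mapping with key ``"combined"`` plus one key per casein class.
    An imported alignment (gapped FASTA) replaces the built-in aligner for
    the combined analysis only.
    """
    config = config or RunConfig()
    combined = seqio.concat_by_species(panel)
    labels = list(combined)
    outgroup = _resolve_outgroup(labels, config)

    results: dict[str, PhylogenyResult] = {}
    if imported_alignment is not None:
        aln = imported_alignment
    else:
        aln = _align_family([combined[sp] for sp in labels], labels)
    results["combined"] = _analyse_alignment(aln, outgroup, config, config.seed)

    for k, cls in enumerate(CLASS_ORDER):
        seqs, labs = [], []
        for sp in labels:
            if cls not in panel[sp]:
                raise seqio.ValidationError(f"species {sp!r} missing class {cls!r}")
            seqs.append(panel[sp][cls])
            labs.append(sp)
        aln_c = _align_family(seqs, labs)
        results[cls] = _analyse_alignment(aln_c, outgroup, config, config.seed + k + 1)
    return results


def _align_family(seqs: list[ProteinSequence], labels: list[str]) -> Alignment:
    if len({len(s) for s in seqs}) == 1:
        # indel-free family: progressive alignment would be gap-free anyway
        from .align import stack_alignment
        aln = stack_alignment(seqs)
    else:
        aln = progressive_align(seqs)
    return Alignment(ids=tuple(labels),
                     rows=dict(zip(labels, (aln.rows[i] for i in aln.ids))))


# ---------------------------------------------------------------------------
# File layer
# ---------------------------------------------------------------------------


def write_matrix_csv(dm: phylo.DistanceMatrix, path: Path, precision: int) -> None:
    df = pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels))
    df.round(precision).to_csv(path, index_label="organism")


#: Printed decimals per column, matching conventional report precision.
_TABLE_DECIMALS = {
    "mw_kda": 3, "avg_antimicrobial_index": 3,
    "hydrophobicity_pct": 1, "basic_pct": 1, "antioxidant_index": 1,
    "aliphatic_index": 2, "instability_index": 2,
}


def _fmt_table(df: pd.DataFrame, precision: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(_TABLE_DECIMALS.get(col, precision))
    return out


def run_all(config: RunConfig, panel: Panel | None = None) -> dict:
    """Execute profile -> scan -> phylogeny, write all artifacts + MANIFEST.

    Returns the MANIFEST dict. Stage failures abort with a stage-tagged
    error; already-written outputs are retained and the MANIFEST marks the
    run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "complete": False,
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    written: dict[str, str] = manifest["outputs"]

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    try:
        if panel is None:
            panel = load_panel(config)

        logger.info("stage profile: %d sequences", sum(len(v) for v in panel.values()))
        profile = run_profile(panel, config)
        emit("chemical_profile.csv",
             lambda p: _fmt_table(profile, config.precision).to_csv(p, index=False))

        logger.info("stage scan")
        scan = run_scan(panel, config)
        emit("bioactivity_scan.csv",
             lambda p: _fmt_table(scan, config.precision).to_csv(p, index=False))

        if config.phylogeny:
            logger.info("stage phylogeny: %d bootstrap replicates", config.n_reps)
            imported = None
            if config.alignment:
                imported = Alignment.read_fasta(config.alignment)
            trees = run_phylogeny(panel, config, imported_alignment=imported)
            for key, res in trees.items():
                tag = key.replace("alpha-", "alpha")
                emit(f"similarity_{tag}.csv",
                     lambda p, r=res: write_matrix_csv(r.similarity, p, config.precision))
                emit(f"pdistance_{tag}.csv",
                     lambda p, r=res: write_matrix_csv(r.p_distance, p, 4))
                emit(f"tree_{tag}.nwk",
                     lambda p, r=res: p.write_text(r.tree.to_newick() + "\n"))
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise after MANIFEST
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["complete"] = True
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return manifest
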