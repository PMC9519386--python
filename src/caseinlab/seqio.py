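"""Protein panel I/O: FASTA read/write, panel registry, per-species concatenation.

A *panel* is the central container of this package: a mapping
``species -> casein class -> ProteinSequence`` covering (ideally) all four
casein classes (alpha-S1, alpha-S2, beta, kappa) for each species. Panels are
stored on disk as plain multi-record FASTA with headers ``>{species}|{class}``;
arbitrary FASTA is also loadable, with metadata supplied through a sidecar CSV
(``id,species,class``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

#: The 20 canonical amino acids (one-letter codes).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Canonical casein class labels in the fixed concatenation order.
CLASS_ORDER = ("alpha-S1", "alpha-S2", "beta", "kappa")
CLASS_LABELS = CLASS_ORDER + ("other",)


class FormatError(ValueError):
    """Malformed input file (empty FASTA, bad syntax)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain constraint."""


@dataclass(frozen=True)
class ProteinSequence:
    """One panel member: a protein chain tagged with species and casein class.

    ``residues`` must use only the 20 canonical one-letter codes; ambiguity
    codes (B, J, O, U, X, Z) and ``*`` are rejected at construction unless the
    terminal stop has been stripped beforehand (see :func:`read_fasta`'s
    ``strip_terminal_stop``).
    """

    id: str
    residues: str
    species: str = "other"
    casein_class: str = "other"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in _ALPHABET_SET:
                raise ValidationError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        if self.casein_class not in CLASS_LABELS:
            raise ValidationError(
                f"record {self.id!r}: unknown casein class {self.casein_class!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def label(self) -> str:
        if self.species != "other" or self.casein_class != "other":
            return f"{self.species}|{self.casein_class}"
        return self.id


Panel = Mapping[str, Mapping[str, ProteinSequence]]


def read_fasta(
    path: str | Path,
    metadata: str | Path | None = None,
    strip_terminal_stop: bool = False,
) -> list[ProteinSequence]:
    """Read a protein FASTA file into validated :class:`ProteinSequence` records.

    Headers of the form ``species|class`` (with ``class`` one of the canonical
    casein labels) are parsed into the ``species`` / ``casein_class`` fields;
    any other header becomes the record id with species/class ``other``.
    A sidecar CSV (columns ``id,species,class``) may supply metadata for
    arbitrary headers. ``strip_terminal_stop`` removes a single trailing ``*``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    meta: dict[str, tuple[str, str]] = {}
    if metadata is not None:
        meta = _read_sidecar(metadata)

    out: list[ProteinSequence] = []
    for rec in records:
        residues = str(rec.seq).upper()
        if strip_terminal_stop and residues.endswith("*"):
            residues = residues[:-1]
        header = rec.description.strip() or rec.id
        species, cls = "other", "other"
        rec_id = rec.id
        m = re.fullmatch(r"([^|]+)\|([^|]+)", header)
        if m and m.group(2) in CLASS_LABELS:
            species, cls = m.group(1), m.group(2)
            rec_id = header
        elif rec.id in meta:
            species, cls = meta[rec.id]
        out.append(
            ProteinSequence(id=rec_id, residues=residues, species=species, casein_class=cls)
        )
    return out


def _read_sidecar(path: str | Path) -> dict[str, tuple[str, str]]:
    meta: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "species", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: sidecar must have columns id,species,class")
        for row in reader:
            cls = row["class"]
            if cls not in CLASS_LABELS:
                raise ValidationError(f"{path}: unknown class {cls!r} for id {row['id']!r}")
            meta[row["id"]] = (row["species"], cls)
    return meta


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write records as FASTA, 60 residues per line, header ``>{species}|{class}``
    (or ``>{id}`` for untagged records)."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record list")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.label}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def build_panel(records: Iterable[ProteinSequence]) -> dict[str, dict[str, ProteinSequence]]:
    """Arrange records into the species -> class -> sequence mapping."""
    panel: dict[str, dict[str, ProteinSequence]] = {}
    for rec in records:
        slot = panel.setdefault(rec.species, {})
        if rec.casein_class in slot:
            raise ValidationError(
                f"duplicate entry for species {rec.species!r} class {rec.casein_class!r}"
            )
        slot[rec.casein_class] = rec
    return panel


def concat_by_species(panel: Panel) -> dict[str, ProteinSequence]:
    """Concatenate each species' four caseins in the fixed class order.

    The order alpha-S1 -> alpha-S2 -> beta -> kappa is a stable convention;
    it does not affect any distance but makes concatenated outputs
    reproducible byte-for-byte.
    """
    out: dict[str, ProteinSequence] = {}
    for species, classes in panel.items():
        parts = []
        for cls in CLASS_ORDER:
            if cls not in classes:
                raise ValidationError(f"species {species!r} is missing class {cls!r}")
            parts.append(classes[cls].residues)
        out[species] = ProteinSequence(
            id=f"{species}|combined", residues="".join(parts), species=species
        )
    return out


# ---------------------------------------------------------------------------
# Panel registry: the 24-entry species x class accession table (precursor
# sequences, lengths in residues, average molecular weights in kDa).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistryRow:
    casein_class: str
    species: str          # scientific name
    common_name: str
    accession: str
    expected_length: int  # residues (precursor incl. signal peptide)
    expected_mw: float    # kDa


_REGISTRY_ROWS: tuple[tuple[str, str, str, str, int, float], ...] = (
    ("alpha-S1", "Camelus dromedarius", "Arabian camel", "NP_001290495.1", 222, 25.843),
    ("alpha-S1", "Ovis aries", "Sheep", "ACJ46472.1", 214, 24.315),
    ("alpha-S1", "Capra hircus", "Goat", "ALJ30147.1", 213, 24.130),
    ("alpha-S1", "Bos taurus", "Cattle", "1308122A", 214, 24.435),
    ("alpha-S1", "Bubalus bubalis", "Water buffalo", "APQ30583.1", 214, 24.312),
    ("alpha-S1", "Rattus norvegicus", "Rat", "NP_620229.2", 284, 31.801),
    ("alpha-S2", "Camelus dromedarius", "Arabian camel", "NP_001290490.1", 193, 22.964),
    ("alpha-S2", "Ovis aries", "Sheep", "NP_001009363.1", 223, 26.331),
    ("alpha-S2", "Capra hircus", "Goat", "CAB94236.1", 223, 26.341),
    ("alpha-S2", "Bos taurus", "Cattle", "NP_776953.1", 222, 26.120),
    ("alpha-S2", "Bubalus bubalis", "Water buffalo", "ADW77639.1", 222, 26.223),
    ("alpha-S2", "Rattus norvegicus", "Rat", "NP_001099211.1", 179, 20.231),
    ("beta", "Camelus dromedarius", "Arabian camel", "NP_001290492.1", 232, 26.217),
    ("beta", "Ovis aries", "Sheep", "QST88854.1", 222, 24.946),
    ("beta", "Capra hircus", "Goat", "AAK97639.1", 223, 24.992),
    ("beta", "Bos taurus", "Cattle", "AAB29137.1", 224, 25.098),
    ("beta", "Bubalus bubalis", "Water buffalo", "NP_001277808.1", 224, 25.101),
    ("beta", "Rattus norvegicus", "Rat", "NP_058816.2", 231, 25.345),
    ("kappa", "Camelus dromedarius", "Arabian camel", "KAB1281948.1", 219, 24.717),
    ("kappa", "Ovis aries", "Sheep", "AAP69943.1", 162, 17.989),
    ("kappa", "Capra hircus", "Goat", "AAM12026.1", 162, 17.896),
    ("kappa", "Bos taurus", "Cattle", "NP_776719.1", 190, 21.269),
    ("kappa", "Bubalus bubalis", "Water buffalo", "NP_001277901.1", 190, 21.397),
    ("kappa", "Rattus norvegicus", "Rat", "NP_113750.1", 178, 19.548),
)


@dataclass(frozen=True)
class PanelRegistry:
    """The fixed 24-accession species x casein-class panel (6 species x 4 classes,
    rat included as the phylogenetic outgroup)."""

    rows: tuple[RegistryRow, ...] = field(
        default_factory=lambda: tuple(RegistryRow(*r) for r in _REGISTRY_ROWS)
    )

    def __len__(self) -> int:
        return len(self.rows)

    def lookup(self, species: str, casein_class: str) -> RegistryRow:
        for row in self.rows:
            if row.casein_class == casein_class and species in (row.species, row.common_name):
                return row
        raise KeyError(f"no registry row for {species!r} / {casein_class!r}")

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            if row.species not in seen:
                seen.append(row.species)
        return seen

    @property
    def accessions(self) -> list[str]:
        return [row.accession for row in self.rows]


def load_panel_registry() -> PanelRegistry:
    """Return the immutable 24-row panel registry."""
    return PanelRegistry()


def load_accession_panel(path: str | Path) -> dict[str, dict[str, ProteinSequence]]:
    """Load the real accession panel from a local FASTA produced by
    :func:`fetch_accession_panel`, validated against the registry (accession
    per header, lengths must match the registry exactly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: accession panel FASTA not present; run "
            "caseinlab.seqio.fetch_accession_panel() once with network access"
        )
    registry = load_panel_registry()
    by_acc = {row.accession: row for row in registry.rows}
    panel: dict[str, dict[str, ProteinSequence]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        if acc not in by_acc:
            continue
        row = by_acc[acc]
        seq = ProteinSequence(
            id=acc, residues=str(rec.seq).upper(),
            species=row.species, casein_class=row.casein_class,
        )
        if len(seq) != row.expected_length:
            raise ValidationError(
                f"{acc}: length {len(seq)} != registry length {row.expected_length}"
            )
        panel.setdefault(row.species, {})[row.casein_class] = seq
    missing = [a for a in by_acc if a not in {s.id for c in panel.values() for s in c.values()}]
    if missing:
        raise ValidationError(f"{path}: missing accessions {missing}")
    return panel


def fetch_accession_panel(path: str | Path, email: str = "caseinlab@example.org") -> None:
    """One-time NCBI fetch of the 24 registry accessions into a local FASTA.

    Optional convenience only — nothing in the core pipeline or test suite
    depends on network access.
    """
    from Bio import Entrez

    Entrez.email = email
    registry = load_panel_registry()
    with Entrez.efetch(
        db="protein", id=",".join(registry.accessions), rettype="fasta", retmode="text"
    ) as handle, open(path, "w") as out:
        out.write(handle.read())
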