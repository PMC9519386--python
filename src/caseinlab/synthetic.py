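"""Synthetic protein panels with controlled composition, planted
antimicrobial-like segments and known phylogenetic structure.

The generator emulates a milk-casein-style study panel without any external
data: per casein class it samples a root sequence from a target residue
composition, evolves it along a divergence tree (site-independent
substitutions, uniform over the 19 alternative residues, no indels — so the
resulting families are alignment-free), and optionally overwrites chosen
segments with low-propensity residue multisets to create ground-truth
bactericidal stretches.

Randomness contract: every generator is a pure function of its inputs and an
integer seed. Independent child streams are derived with
``numpy.random.SeedSequence(seed).spawn`` in a fixed, documented order, so no
draw can be reordered by refactoring or parallelism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phylo import Clade, parse_newick
from .seqio import ALPHABET, ProteinSequence

_RES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
_RES_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Default residue groups used by the composition helpers.
HYDROPHOBIC = "GAVLIPFMW"
BASIC = "RKH"
OTHER = "CDENQSTY"


@dataclass(frozen=True)
class CompositionTarget:
    """Target mole fractions over the 20 residues (non-negative, sum to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.fractions) != set(ALPHABET):
            raise ValueError("composition must have exactly the 20 canonical residues")
        vals = list(self.fractions.values())
        if any(v < 0 for v in vals):
            raise ValueError("composition fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1 (got {sum(vals)!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[aa] for aa in ALPHABET], dtype=float)

    @classmethod
    def uniform(cls) -> "CompositionTarget":
        return cls({aa: 1.0 / 20.0 for aa in ALPHABET})

    @classmethod
    def from_group_fractions(
        cls, hydrophobic: float, basic: float
    ) -> "CompositionTarget":
        """Composition with the given hydrophobic and basic mole fractions,
        spread uniformly within each group (remainder on the other residues)."""
        rest = 1.0 - hydrophobic - basic
        if rest < 0:
            raise ValueError("hydrophobic + basic fractions exceed 1")
        frac = {aa: hydrophobic / len(HYDROPHOBIC) for aa in HYDROPHOBIC}
        frac |= {aa: basic / len(BASIC) for aa in BASIC}
        frac |= {aa: rest / len(OTHER) for aa in OTHER}
        return cls(frac)


#: Class-typical compositions: alpha-S2-like is basic-rich/low-hydrophobic,
#: beta-like is the most hydrophobic with the least basic content, alpha-S1
#: and kappa are intermediate.
CASEIN_LIKE_COMPOSITIONS: dict[str, CompositionTarget] = {
    "alpha-S1": CompositionTarget.from_group_fractions(0.44, 0.115),
    "alpha-S2": CompositionTarget.from_group_fractions(0.32, 0.16),
    "beta": CompositionTarget.from_group_fractions(0.515, 0.095),
    "kappa": CompositionTarget.from_group_fractions(0.44, 0.105),
}


def sample_sequence(
    composition: CompositionTarget, length: int, seed: int | np.random.SeedSequence
) -> str:
    """Draw ``length`` residues i.i.d. from the composition (deterministic per seed)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(20, size=length, p=composition.as_array())
    return _RES[idx].tobytes().decode()


def plant_stretch(
    seq: str | ProteinSequence,
    residues: str | Sequence[str],
    start: int,
    length: int,
    seed: int | np.random.SeedSequence = 0,
) -> str:
    """Overwrite positions ``[start, start+length)`` with a random arrangement
    of the given residue multiset; the multiset (hence the segment's PV
    statistics) is exactly controlled, only the order is randomised."""
    s = seq.residues if isinstance(seq, ProteinSequence) else seq
    residues = "".join(residues)
    if length != len(residues):
        raise ValueError("length must equal the residue multiset size")
    if start < 0 or start + length > len(s):
        raise ValueError("planted stretch exceeds sequence bounds")
    if length == 0:
        return s
    rng = np.random.default_rng(seed)
    arranged = "".join(rng.permutation(list(residues)))
    return s[:start] + arranged + s[start + length :]


def evolve_on_tree(
    root: str | ProteinSequence, tree: Clade | str, seed: int
) -> dict[str, str]:
    """Evolve a root sequence along a tree; returns leaf-label -> sequence.

    Along a branch of length ``b`` (expected substitutions/site) each site
    substitutes independently with probability ``1 - exp(-b)``; the
    replacement is uniform over the other 19 residues. Child RNG streams are
    spawned in pre-order, one per edge.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    s = root.residues if isinstance(root, ProteinSequence) else root
    seq0 = np.array([_RES_INDEX[aa] for aa in s], dtype=np.int64)

    edges = [n for n in tree.walk() if n is not tree]
    for node in edges:
        if node.length is None:
            raise ValueError("every non-root node needs a branch length")
        if node.length < 0:
            raise ValueError("branch lengths must be >= 0")
    streams = iter(np.random.SeedSequence(seed).spawn(len(edges)))

    leaves: dict[str, str] = {}

    def descend(node: Clade, seq: np.ndarray) -> None:
        for child in node.children:
            rng = np.random.default_rng(next(streams))
            p_sub = 1.0 - math.exp(-child.length)
            mutated = seq.copy()
            hit = rng.random(seq.size) < p_sub
            n_hit = int(hit.sum())
            if n_hit:
                # uniform over the 19 alternatives via a 1..19 offset mod 20
                offset = rng.integers(1, 20, size=n_hit)
                mutated[hit] = (mutated[hit] + offset) % 20
            if child.is_leaf:
                if child.name is None:
                    raise ValueError("every leaf needs a label")
                leaves[child.name] = _RES[mutated].tobytes().decode()
            else:
                descend(child, mutated)

    descend(tree, seq0)
    return leaves


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic species x casein-class panel.

    ``divergence_tree`` (Newick or :class:`Clade`; leaves = species labels,
    branch lengths in expected substitutions/site) fixes the true phylogeny
    shared by all classes. ``planted_stretches`` maps a class label to a list
    of ``(residue multiset, start, length)`` segments overwritten in every
    species' sequence of that class after evolution.
    """

    species_labels: tuple[str, ...]
    class_labels: tuple[str, ...] = ("alpha-S1", "alpha-S2", "beta", "kappa")
    length_range: tuple[int, int] = (160, 290)
    compositions: Mapping[str, CompositionTarget] = field(
        default_factory=lambda: dict(CASEIN_LIKE_COMPOSITIONS)
    )
    divergence_tree: str | Clade = ""
    planted_stretches: Mapping[str, tuple[tuple[str, int, int], ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= 10000):
            raise ValueError("length_range must satisfy 1 <= lo <= hi <= 10000")
        tree = self.tree()
        if set(tree.leaf_names()) != set(self.species_labels):
            raise ValueError("divergence_tree leaves must equal species_labels")
        for cls in self.class_labels:
            if cls not in self.compositions:
                raise ValueError(f"no composition for class {cls!r}")
        if self.planted_stretches:
            for cls, specs in self.planted_stretches.items():
                for residues, start, length in specs:
                    if len(residues) != length:
                        raise ValueError("stretch multiset size must equal its length")
                    if start + length > lo:
                        raise ValueError(
                            "planted stretch must fit within the minimum length"
                        )

    def tree(self) -> Clade:
        t = self.divergence_tree
        return parse_newick(t) if isinstance(t, str) else t


def make_panel(spec: PanelSpec) -> dict[str, dict[str, ProteinSequence]]:
    """Generate one sequence per (species, class).

    Per class (in ``class_labels`` order): spawn a child seed, sample the
    class root length and sequence, evolve it on the divergence tree, then
    apply any planted stretches. Identical spec => identical panel.
    """
    root_ss = np.random.SeedSequence(spec.seed)
    class_streams = root_ss.spawn(len(spec.class_labels))
    panel: dict[str, dict[str, ProteinSequence]] = {sp: {} for sp in spec.species_labels}
    tree = spec.tree()
    for cls, ss in zip(spec.class_labels, class_streams):
        len_ss, root_ss_c, evo_ss, plant_ss = ss.spawn(4)
        lo, hi = spec.length_range
        length = int(np.random.default_rng(len_ss).integers(lo, hi + 1))
        root = sample_sequence(spec.compositions[cls], length, root_ss_c)
        leaves = evolve_on_tree(root, tree, _entropy_int(evo_ss))
        plant_streams = iter(plant_ss.spawn(len(spec.species_labels) * 8))
        for sp in spec.species_labels:
            seq = leaves[sp]
            for residues, start, slen in (spec.planted_stretches or {}).get(cls, ()):
                seq = plant_stretch(seq, residues, start, slen, next(plant_streams))
            panel[sp][cls] = ProteinSequence(
                id=f"{sp}|{cls}", residues=seq, species=sp, casein_class=cls
            )
    return panel


def _entropy_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def panel_ground_truth_rows(spec: PanelSpec) -> list[dict]:
    """Ground-truth table rows (species, class, stretch bounds, true tree)."""
    newick = spec.tree().to_newick()
    rows = []
    for sp in spec.species_labels:
        for cls in spec.class_labels:
            stretches = (spec.planted_stretches or {}).get(cls, ())
            if stretches:
                for residues, start, length in stretches:
                    rows.append(
                        dict(species=sp, casein_class=cls, stretch_start=start,
                             stretch_end=start + length, tree_newick=newick)
                    )
            else:
                rows.append(
                    dict(species=sp, casein_class=cls, stretch_start=-1,
                         stretch_end=-1, tree_newick=newick)
                )
    return rows
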