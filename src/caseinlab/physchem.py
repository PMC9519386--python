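"""Protein chemical parameters: composition, molecular weight, hydrophobicity
index, basic-residue percentage, charged-residue counts, aliphatic index and
instability index.

Conventions
-----------
* All percentages are mole percents of the whole chain (0-100).
* Molecular weight uses average (not monoisotopic) residue masses plus one
  water; this matches the values conventionally reported for protein
  precursors by sequence-analysis servers.
* The instability index is the Guruprasad dipeptide-weight sum,
  ``(10/L) * sum_i DIWV(x_i, x_{i+1})``; values above 40 conventionally flag a
  protein as unstable in vitro.
* The aliphatic index is ``X(A) + 2.9 X(V) + 3.9 (X(I) + X(L))`` on mole
  percents — a proxy for thermostability contributed by aliphatic side chains.
* All values are kept at full precision internally; printed precision (1-2
  decimals) is applied only when tables are serialised.

The residue mass table and the 400-entry dipeptide instability weight table
are the published standard tables as shipped with Biopython
(``Bio.Data.IUPACData`` / ``Bio.SeqUtils.ProtParamData``); alternative tables
can be passed explicitly to every function that uses one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Data.IUPACData import protein_weights as _AA_WEIGHTS
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV

from .seqio import ALPHABET, ProteinSequence

WATER_MASS = 18.015  # Da, released per peptide bond

#: Average residue masses (free amino-acid mass minus one water), Da.
RESIDUE_MASSES: dict[str, float] = {aa: _AA_WEIGHTS[aa] - 18.0153 for aa in ALPHABET}

#: Hydrophobic residues: Gly, Ala, Val, Leu, Ile, Pro, Phe, Met, Trp.
HYDROPHOBIC_SET = frozenset("GAVLIPFMW")
#: Basic residues in the chemical sense: Arg, Lys, His.
BASIC_SET = frozenset("RKH")
#: Positively charged at neutral pH as counted here: Arg + Lys (His excluded).
POSITIVE_SET = frozenset("RK")
#: Negatively charged: Asp + Glu.
NEGATIVE_SET = frozenset("DE")


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric scale (masses, propensities, ...)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(ALPHABET):
            raise ValueError(f"scale {self.name!r} must cover exactly the 20 residues")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class DipeptideScale:
    """Ordered-pair weights, e.g. the 400 dipeptide instability weights."""

    name: str
    values: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if len(self.values) != 400:
            raise ValueError(f"dipeptide scale {self.name!r} must have 400 entries")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.values[pair]


#: The Guruprasad dipeptide instability weights as a DipeptideScale.
INSTABILITY_WEIGHTS = DipeptideScale(
    "guruprasad-diwv",
    {(a, b): _DIWV[a][b] for a in ALPHABET for b in ALPHABET},
)


def _residues(seq: ProteinSequence | str) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else seq


def composition(seq: ProteinSequence | str) -> dict[str, float]:
    """Mole-percent composition over all 20 residues (absent residues -> 0)."""
    s = _residues(seq)
    n = len(s)
    return {aa: 100.0 * s.count(aa) / n for aa in ALPHABET}


def molecular_weight(seq: ProteinSequence | str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    s = _residues(seq)
    return sum(RESIDUE_MASSES[aa] for aa in s) + WATER_MASS


def molecular_weight_kda(seq: ProteinSequence | str) -> float:
    """Molecular weight in kDa rounded to 3 decimals (registry convention)."""
    return round(molecular_weight(seq) / 1000.0, 3)


def _set_fraction(seq: ProteinSequence | str, members: frozenset[str] | set[str]) -> float:
    s = _residues(seq)
    if not members:
        raise ValueError("residue set must be non-empty")
    if not set(members) <= set(ALPHABET):
        raise ValueError(f"residue set {members!r} outside the 20-letter alphabet")
    return 100.0 * sum(s.count(aa) for aa in members) / len(s)


def hydrophobicity_index(
    seq: ProteinSequence | str, hydrophobic_set: frozenset[str] = HYDROPHOBIC_SET
) -> float:
    """Percentage of hydrophobic residues (default set G,A,V,L,I,P,F,M,W)."""
    return _set_fraction(seq, hydrophobic_set)


def basic_fraction(seq: ProteinSequence | str, basic_set: frozenset[str] = BASIC_SET) -> float:
    """Percentage of basic residues (default set R,K,H)."""
    return _set_fraction(seq, basic_set)


def charged_counts(seq: ProteinSequence | str) -> tuple[int, int]:
    """(negative, positive) residue counts: (#D + #E, #R + #K)."""
    s = _residues(seq)
    neg = sum(s.count(aa) for aa in NEGATIVE_SET)
    pos = sum(s.count(aa) for aa in POSITIVE_SET)
    return neg, pos


def aliphatic_index(seq: ProteinSequence | str) -> float:
    comp = composition(seq)
    return comp["A"] + 2.9 * comp["V"] + 3.9 * (comp["I"] + comp["L"])


def instability_index(
    seq: ProteinSequence | str, diwv: DipeptideScale = INSTABILITY_WEIGHTS
) -> float:
    s = _residues(seq)
    if len(s) < 2:
        raise ValueError("instability index requires at least 2 residues")
    total = sum(diwv[(s[i], s[i + 1])] for i in range(len(s) - 1))
    return 10.0 * total / len(s)


@dataclass(frozen=True)
class PhyschemProfile:
    """All computed chemical indices for one sequence."""

    length: int
    mw: float                 # Da
    hydrophobicity_pct: float
    basic_pct: float
    neg_count: int
    pos_count: int
    aliphatic_index: float
    instability_index: float
    composition: Mapping[str, float]


def physchem_profile(seq: ProteinSequence | str) -> PhyschemProfile:
    """Compute the full chemical profile with the default residue sets."""
    s = _residues(seq)
    neg, pos = charged_counts(s)
    return PhyschemProfile(
        length=len(s),
        mw=molecular_weight(s),
        hydrophobicity_pct=hydrophobicity_index(s),
        basic_pct=basic_fraction(s),
        neg_count=neg,
        pos_count=pos,
        aliphatic_index=aliphatic_index(s),
        instability_index=instability_index(s),
        composition=composition(s),
    )
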