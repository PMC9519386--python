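"""Antimicrobial-region scanning and the antioxidant activity index.

The scan follows the propensity-scale approach used for antimicrobial-region
prediction in whole proteins: each residue carries a bactericidal propensity
value (PV) derived from IC50 data — *lower* PV means the residue is more
favoured in antimicrobial peptides (Arg, Lys, Cys, Trp lowest; Asp, Glu
highest). The per-residue PVs are smoothed with a centred sliding window, and
*bactericidal stretches* are maximal runs of window-averaged values strictly
below a propensity threshold that reach a minimum length.

Defaults are the scanner's standard settings: window 7, threshold 0.225,
minimum stretch length 12.

The antioxidant activity index is the mole percentage of the hydrophobic
residues most associated with radical scavenging (default Trp, Met, Ile,
Leu, Pro); an alternative set substituting Tyr for Trp is also in use in the
literature and can be passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physchem import ResidueScale, _set_fraction
from .seqio import ProteinSequence

#: Bactericidal propensity values (PV) per residue; lower = more antimicrobial.
PV_VALUES: dict[str, float] = {
    "R": 0.106, "K": 0.111, "C": 0.165, "W": 0.172, "Y": 0.185,
    "I": 0.198, "V": 0.200, "H": 0.202, "N": 0.240, "T": 0.242,
    "F": 0.246, "L": 0.246, "Q": 0.248, "G": 0.265, "M": 0.265,
    "S": 0.281, "A": 0.307, "P": 0.327, "E": 0.449, "D": 0.479,
}

#: Antioxidant residue set (Trp, Met, Ile, Leu, Pro).
ANTIOXIDANT_SET = frozenset("WMILP")
#: Literature variant with Tyr in place of Trp.
ANTIOXIDANT_SET_TYR = frozenset("YMILP")


def pv_scale() -> ResidueScale:
    """The bactericidal propensity scale as a :class:`ResidueScale`."""
    return ResidueScale("bactericidal-propensity", dict(PV_VALUES))


@dataclass(frozen=True)
class PropensityParams:
    """Scanner settings: window (odd, residues), propensity threshold and
    minimum stretch length (residues)."""

    window: int = 7
    threshold: float = 0.225
    min_stretch: int = 12
    edge_mode: str = "shrink"  # "shrink": truncated windows at termini; "skip": no edge calls

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_stretch < 1:
            raise ValueError("min_stretch must be >= 1")
        if self.edge_mode not in ("shrink", "skip"):
            raise ValueError("edge_mode must be 'shrink' or 'skip'")


@dataclass(frozen=True)
class PropensityScan:
    """Scan result: raw per-residue PVs, windowed profile, called stretches
    (0-based half-open intervals) and the whole-sequence average index."""

    per_residue_pv: tuple[float, ...]
    profile: tuple[float, ...]
    stretches: tuple[tuple[int, int], ...]
    average_index: float
    params: PropensityParams = field(default_factory=PropensityParams)


def propensity_profile(
    seq: ProteinSequence | str, params: PropensityParams | None = None
) -> PropensityScan:
    """Per-residue PVs and the window-averaged profile (stretches not called).

    ``profile[i]`` is the mean PV over the window of ``params.window``
    positions centred at ``i``; at the termini the window shrinks to its
    in-bounds part so the profile has the same length as the sequence.
    """
    params = params or PropensityParams()
    s = seq.residues if isinstance(seq, ProteinSequence) else seq
    pv = np.array([PV_VALUES[aa] for aa in s], dtype=float)
    n = pv.size
    half = params.window // 2
    csum = np.concatenate(([0.0], np.cumsum(pv)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    profile = (csum[hi] - csum[lo]) / (hi - lo)
    return PropensityScan(
        per_residue_pv=tuple(pv.tolist()),
        profile=tuple(profile.tolist()),
        stretches=(),
        average_index=float(pv.mean()),
        params=params,
    )


def bactericidal_stretches(
    scan: PropensityScan, params: PropensityParams | None = None
) -> tuple[tuple[int, int], ...]:
    """Maximal runs of profile values strictly below the threshold, kept iff
    they reach ``min_stretch`` positions; sorted by start, pairwise disjoint.

    In ``edge_mode="skip"`` the truncated-window positions at the termini
    (the first and last ``window // 2``) never qualify.
    """
    params = params or scan.params
    profile = np.asarray(scan.profile)
    below = profile < params.threshold
    if params.edge_mode == "skip":
        half = params.window // 2
        if half:
            below[:half] = False
            below[-half:] = False
    out: list[tuple[int, int]] = []
    start: int | None = None
    for i, flag in enumerate(np.append(below, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= params.min_stretch:
                out.append((start, i))
            start = None
    return tuple(out)


def scan_sequence(
    seq: ProteinSequence | str, params: PropensityParams | None = None
) -> PropensityScan:
    """Full scan: profile plus called bactericidal stretches."""
    params = params or PropensityParams()
    scan = propensity_profile(seq, params)
    stretches = bactericidal_stretches(scan, params)
    return PropensityScan(
        per_residue_pv=scan.per_residue_pv,
        profile=scan.profile,
        stretches=stretches,
        average_index=scan.average_index,
        params=params,
    )


def average_antimicrobial_index(seq: ProteinSequence | str) -> float:
    """Arithmetic mean of the raw per-residue PVs over the whole sequence.

    Uses raw PVs, not the windowed profile: with shrinking edge windows the
    two means differ only in how the few terminal residues are weighted.
    """
    s = seq.residues if isinstance(seq, ProteinSequence) else seq
    return float(np.mean([PV_VALUES[aa] for aa in s]))


def antioxidant_index(
    seq: ProteinSequence | str, antiox_set: frozenset[str] = ANTIOXIDANT_SET
) -> float:
    """Mole percentage of antioxidant-associated residues (default W,M,I,L,P)."""
    return _set_fraction(seq, antiox_set)


def format_intervals(stretches: tuple[tuple[int, int], ...]) -> str:
    """Serialise intervals as ``start-end`` (0-based half-open), ';'-joined."""
    return ";".join(f"{a}-{b}" for a, b in stretches)
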