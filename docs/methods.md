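# Methods

## Panel model

The unit of analysis is a *panel*: one protein sequence per (species, casein
class) over the four casein classes α-S1, α-S2, β and κ. Sequences are the
full deposited precursor chains (signal peptide included) — the shipped
24-accession registry lists precursor lengths and molecular weights, and all
indices are computed on the same chains for consistency. Only the 20
canonical residues are accepted; ambiguity codes are rejected at parse time
rather than silently dropped, because every downstream index assumes
canonical residues (a permissive flag strips a single terminal `*`).
Per-species concatenation uses the fixed class order α-S1 → α-S2 → β → κ;
the order is irrelevant to distances but keeps outputs byte-reproducible.

## Physicochemical indices

All percentages are mole percents; values are held at full precision and
rounded only when tables are serialised (1 decimal for percentages, 2 for
aliphatic/instability, 3 for kDa and the average antimicrobial index).

* **Molecular weight**: sum of average residue masses plus one water
  (18.015 Da). Average (not monoisotopic) masses are used — this is what the
  registry's kDa values correspond to. The mass and dipeptide-weight tables
  are the published standard tables shipped with Biopython; both can be
  replaced by an explicit argument.
* **Hydrophobicity index**: % of {G,A,V,L,I,P,F,M,W}. Whether glycine
  belongs in the hydrophobic set is debatable; the default follows the set
  as commonly enumerated for caseins and is a parameter.
* **Basic %**: % of {R,K,H}. Histidine is basic in the chemical sense, so it
  is counted here, while the **charged-residue counts** use the stricter
  charge-at-neutral-pH definitions: negative = #D + #E, positive = #R + #K
  (His excluded). Both sets are parameters.
* **Aliphatic index**: X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)); range 0 (no
  aliphatic side chains) to 390 (poly-Ile/Leu).
* **Instability index**: (10/L)·Σ DIWV over the L−1 adjacent pairs, with the
  Guruprasad 400-entry dipeptide weight table; > 40 conventionally predicts
  in-vitro instability. This is the only order-sensitive index — the tests
  assert both its order sensitivity and the permutation invariance of every
  composition-based index.

## Antimicrobial scanning

Each residue carries a bactericidal propensity value (PV) from an
IC₅₀-derived scale (Arg 0.106 … Asp 0.479; lower = more antimicrobial). The
profile at position *i* is the mean PV over a centred window (default 7); at
the termini the window shrinks to its in-bounds part so the profile keeps
length L (`edge_mode="skip"` instead refuses to call the first/last
window//2 positions). A *bactericidal stretch* is a maximal run of profile
values strictly below the threshold (default 0.225; ties fall outside) of
length ≥ `min_stretch` (default 12, the scanning tool's conventional minimum
reported-domain length — the analysis names only the window and threshold,
so the minimum length is a first-class parameter). Intervals are 0-based
half-open everywhere; human-readable reports may print 1-based closed forms,
labelled as such.

The *average antimicrobial index* is the mean of the **raw** per-residue
PVs, not of the windowed profile: with shrinking edge windows the two differ
only in the weighting of the few terminal residues, and the raw mean is the
natural whole-chain summary.

Note a geometric subtlety: window averaging *narrows* a low-PV segment
embedded in a high-PV background — with window 7, a planted 12-mer of Arg in
poly-Asp yields a below-threshold run of only 10 positions, which the
default minimum length rejects. Planted-segment recovery is therefore
guaranteed only for segments of length ≥ `min_stretch + window − 1`; the
synthetic recovery experiments use exactly that margin. Conversely, when the
background sits near the threshold the called run can widen by up to
window − 1 positions per side.

The antioxidant activity index is the mole % of {W,M,I,L,P}; a literature
variant substitutes Tyr for Trp ({Y,M,I,L,P}) and is provided as a named
alternative set.

## Alignment and phylogeny

Pairwise global alignment uses BLOSUM62 with affine gaps (open 10, extend
0.5, matrix units) via Biopython's `PairwiseAligner`; among co-optimal
alignments the first in the aligner's deterministic enumeration is taken.
Multiple alignment is classic progressive alignment: guide tree by UPGMA on
pairwise-alignment p-distances, then profile–profile Gotoh alignment with
sum-of-pairs column scores and the same affine penalties ("once a gap,
always a gap"). A pre-computed alignment can be supplied anywhere instead;
equal-length (indel-free) families are stacked directly, since alignment of
same-length sequences without indels is the identity. At extreme divergence
(≈60% differences) global alignment of compositionally similar proteins is
intrinsically ambiguous and the aligner may introduce spurious gap pairs;
this does not affect the pipeline's indel-free synthetic panels.

Distances are uncorrected p-distances with **pairwise deletion** (columns
gapped in either row of a pair are ignored); percent similarity is
100·(1−p). A pair with zero comparable columns raises a named error.
Complete-deletion is not the default because near-identical pairs — the
quantities of interest — are insensitive to it, while pairwise deletion is
robust to a single ragged row.

Neighbor joining follows the canonical algorithm: Q-criterion pair
selection, branch lengths ℓᵢ = d/2 + (rᵢ−rⱼ)/(2(m−2)), agglomeration to a
final trifurcation. Determinism rules are fixed: Q ties break to the lowest
current index pair, and a negative branch length is clamped to zero with the
deficit moved to its sister so the pair sum d is preserved. On any additive
matrix the tree reproduces all pairwise path lengths exactly (tested to
1e−9); the implementation is cross-checked against scikit-bio's NJ on noisy
additive matrices.

Rooting places the root at the midpoint of the outgroup's pendant edge;
re-rooting on the same outgroup is a no-op, and rooting never changes the
unrooted split set. Bootstrap resamples alignment columns with replacement
(default 1000 replicates), rebuilds p-distance + NJ per replicate, and
annotates each internal edge of the reference tree with the percentage of
replicates containing the same bipartition; edges above 90% are flagged
"confirmed". Replicates with undefined distances are dropped, logged, and
excluded from the denominator. Internally the bootstrap uses a canonical
(sorted) row order so that supports are invariant to input label order
despite index-based NJ tie-breaking. Replicate column streams are spawned
from `numpy.random.SeedSequence(seed)` in replicate order.

## Synthetic panels

The generator emulates the features of a casein study panel that the
pipeline actually consumes:

* **Composition control** — i.i.d. residue draws from a 20-vector of mole
  fractions. Class-typical defaults mirror the casein contrast (hydrophobic
  fraction: α-S1 0.44, α-S2 0.32, β 0.515, κ 0.44; basic fraction: 0.115,
  0.16, 0.095, 0.105), spread uniformly within each residue group. Lengths
  are drawn per class from 160–290 residues.
* **Divergence** — a root per class evolved along a given tree; per branch
  of length b (expected substitutions/site) each site substitutes with
  probability 1 − e^(−b), uniformly over the 19 alternatives. No rate
  heterogeneity and no indels: the simplest model that exercises the
  distance/NJ stages, and indel-freedom makes synthetic families
  alignment-free. The default study tree has two cherries at depth 0.02
  under internal branches of 0.06–0.10, a camel-analogue at 0.35 and a
  rat-like outgroup at 0.90.
* **Planted ground truth** — segments overwritten with a fixed low-PV
  residue multiset in random arrangement, so segment PV statistics are
  exactly controlled while order varies.

Every generator is a pure function of (spec, seed); child streams are
spawned from a single `SeedSequence` in documented order (classes in listed
order; per class: length, root, evolution, planting), so identical specs
give identical panels.

What passing on synthetic panels does **not** show: real caseins have
indels, non-i.i.d. composition (proline/glutamine clustering, phosphoserine
motifs), and among-site rate variation; p-distances on deep real divergences
are underestimates. Synthetic recovery therefore validates the machinery,
not the biological calibration.

## Degenerate inputs and numerical choices

Empty FASTA → format error; non-canonical residue → validation error naming
record and position; instability index requires L ≥ 2; NJ requires ≥ 3 taxa
and a symmetric matrix; bootstrap requires ≥ 4 rows. Branch lengths are
written with 6 decimals and Newick round-trips preserve topology, lengths
and supports. Matrix symmetry is enforced to 1e−12.

## Known limitations

* The accession-backed reproduction (registry lengths/weights against the
  actual deposited sequences, published per-species index values, the real
  combined topology) requires a one-time networked fetch of the 24
  accessions; the shipped registry carries the expected values but not the
  sequences themselves.
* No model-corrected distances (Poisson/JTT), no ML/Bayesian inference, no
  rate heterogeneity in simulation.
* Percent-identity values depend on the aligner behind them; the built-in
  progressive aligner is one reasonable choice, and an imported alignment is
  accepted wherever alignments are consumed.
* Phosphorylation (central to casein chemistry) is outside scope: masses and
  indices are computed on unmodified chains.
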