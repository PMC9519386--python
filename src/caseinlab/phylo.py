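"""Distance matrices, neighbor-joining trees, outgroup rooting and bootstrap.

Distances are uncorrected p-distances with pairwise deletion: for each pair of
rows, gapped columns in either row are ignored and p is the fraction of
differing comparable columns. Percent similarity is ``100 * (1 - p)``.

Trees are built with canonical neighbor joining (Q-criterion pair selection,
standard branch-length formulas). Determinism rules: ties on Q are broken by
the lowest pair of current indices; a negative branch length is clamped to 0
and the deficit moved to its sister branch so the pair's length sum is kept.
Bootstrap support for an internal edge is the percentage of column-resampled
replicates whose NJ tree contains the same bipartition; edges above a support
threshold (default 90) are flagged "confirmed".
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .align import GAP, Alignment

logger = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """A pair of rows shares no comparable (mutually ungapped) columns."""


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Square labelled matrix in either 'similarity' (%) or 'p-distance' mode."""

    labels: tuple[str, ...]
    values: np.ndarray
    mode: str  # "similarity" | "p-distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        diag = 100.0 if self.mode == "similarity" else 0.0
        if self.mode not in ("similarity", "p-distance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not np.allclose(np.diag(v), diag):
            raise ValueError(f"diagonal must be {diag} in {self.mode} mode")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_p_distance(self) -> "DistanceMatrix":
        if self.mode == "p-distance":
            return self
        return DistanceMatrix(self.labels, 1.0 - self.values / 100.0, "p-distance")

    def to_similarity(self) -> "DistanceMatrix":
        if self.mode == "similarity":
            return self
        return DistanceMatrix(self.labels, 100.0 * (1.0 - self.values), "similarity")


def _pair_stats(mat: np.ndarray, gap_byte: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (comparable, identical) column counts for a byte matrix."""
    n = mat.shape[0]
    nongap = mat != gap_byte
    comparable = np.zeros((n, n), dtype=np.int64)
    ident = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            c = int(both.sum())
            comparable[i, j] = comparable[j, i] = c
            k = int(((mat[i] == mat[j]) & both).sum())
            ident[i, j] = ident[j, i] = k
    return comparable, ident


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix of an alignment."""
    if len(aln) < 2:
        raise ValueError("need at least 2 rows")
    mat = aln.matrix()
    comparable, ident = _pair_stats(mat, ord(GAP))
    n = len(aln.ids)
    zero_pairs = [(aln.ids[i], aln.ids[j]) for i in range(n) for j in range(i + 1, n)
                  if comparable[i, j] == 0]
    if zero_pairs:
        raise UndefinedDistanceError(
            f"no comparable columns for pair(s): {zero_pairs}"
        )
    with np.errstate(invalid="ignore"):
        p = 1.0 - ident / np.maximum(comparable, 1)
    np.fill_diagonal(p, 0.0)
    return DistanceMatrix(tuple(aln.ids), p, "p-distance")


def similarity_matrix(aln: Alignment) -> DistanceMatrix:
    """Percent-identity matrix (identities over mutually ungapped columns)."""
    return p_distance_matrix(aln).to_similarity()


# ---------------------------------------------------------------------------
# Trees and Newick
# ---------------------------------------------------------------------------


@dataclass
class Clade:
    """A tree node; ``length`` and ``support`` describe the edge to its parent."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def copy(self) -> "Clade":
        return copy.deepcopy(self)

    # -- Newick -------------------------------------------------------------

    def to_newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            token = self.name or ""
        else:
            inner = ",".join(c._newick_node() for c in self.children)
            label = "" if self.support is None else _fmt_support(self.support)
            token = f"({inner}){label}"
        if self.length is not None:
            token += f":{self.length:.6f}"
        return token


def _fmt_support(x: float) -> str:
    return f"{x:g}"


def parse_newick(text: str) -> Clade:
    """Parse a Newick string; numeric internal labels are read as supports."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_clade() -> Clade:
        nonlocal pos
        node = Clade()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in Newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^,():;]*", s[pos:])
        label = m.group(0)
        pos += len(label)
        label = label.strip()
        if label:
            if node.children and re.fullmatch(r"[0-9.eE+-]+", label):
                node.support = float(label)
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[^,():;]*", s[pos:])
            node.length = float(m.group(0))
            pos += len(m.group(0))
        return node

    root = parse_clade()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick at offset {pos}")
    return root


def bipartitions(tree: Clade) -> set[frozenset]:
    """Non-trivial unrooted splits, each canonicalised as the side that does
    NOT contain the lexicographically smallest leaf name."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: set[frozenset] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> Clade:
    """Neighbor-joining tree from a p-distance matrix (unrooted: the returned
    root is the final trifurcation and carries no edge of its own)."""
    dm = dist.to_p_distance()
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among ties (row-major argmin is exactly that)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return Clade(children=[a, b, c])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def root_on_outgroup(tree: Clade, label: str) -> Clade:
    """Root at the midpoint of the outgroup's pendant edge.

    The returned tree has a bifurcating root whose children are the outgroup
    leaf and the remainder of the tree; all other relationships (unrooted
    splits) are unchanged. Re-rooting on the same outgroup is idempotent.
    """
    tree = tree.copy()
    leaves = {lf.name: lf for lf in tree.leaves()}
    if label not in leaves:
        raise ValueError(f"outgroup {label!r} is not a leaf of the tree")
    if len(tree.children) == 2 and any(
        c.is_leaf and c.name == label for c in tree.children
    ):
        return tree

    parent_of: dict[int, Clade] = {}
    for node in tree.walk():
        for c in node.children:
            parent_of[id(c)] = node
    out_leaf = leaves[label]
    pend = out_leaf.length if out_leaf.length is not None else 0.0

    # Reverse the path from the outgroup's parent up to the old root; each
    # flipped edge keeps its (length, support), which annotate the same
    # unrooted split as before.
    path = [out_leaf]
    while id(path[-1]) in parent_of:
        path.append(parent_of[id(path[-1])])
    carried_len, carried_sup = pend / 2.0, out_leaf.support
    out_leaf.length = pend / 2.0
    new_root = Clade(children=[out_leaf])
    prev = new_root
    for k in range(1, len(path)):
        node = path[k]
        below = path[k - 1]
        node.children = [c for c in node.children if c is not below]
        next_len, next_sup = node.length, node.support
        node.length, node.support = carried_len, carried_sup
        prev.children.append(node)
        prev = node
        carried_len, carried_sup = next_len, next_sup
    # The old root ends the chain; if it was left with a single child, splice it out.
    _suppress_unifurcations(new_root)
    return new_root


def _suppress_unifurcations(tree: Clade) -> None:
    for node in list(tree.walk()):
        for idx, child in enumerate(list(node.children)):
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                if grand.support is None:
                    grand.support = child.support
                node.children[idx] = grand
                child = grand


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_supports(
    aln: Alignment, n_reps: int = 1000, seed: int = 0
) -> Clade:
    """NJ tree of the alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each replicate's
    column-index stream comes from an independent child of
    ``numpy.random.SeedSequence(seed)`` (spawned in replicate order), so the
    result is reproducible and replicates could be computed in any order.
    Replicates in which some pair loses all comparable columns are dropped
    (with a logged warning) and excluded from the denominator.
    """
    if len(aln) < 4:
        raise ValueError("bootstrap needs an alignment with at least 4 rows")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    # canonical (sorted) label order: NJ tie-breaking is index-based, so a
    # fixed internal order makes supports invariant to input row order
    order = sorted(aln.ids)
    aln = Alignment(ids=tuple(order), rows={k: aln.rows[k] for k in order})
    ref_dm = p_distance_matrix(aln)
    ref = nj_tree(ref_dm)

    mat = aln.matrix()
    gap = ord(GAP)
    n_cols = mat.shape[1]
    counts: dict[frozenset, int] = {}
    targets = bipartitions(ref)
    for split in targets:
        counts[split] = 0
    children = np.random.SeedSequence(seed).spawn(n_reps)
    valid = 0
    dropped = 0
    labels = tuple(aln.ids)
    for child in children:
        rng = np.random.default_rng(child)
        cols = rng.integers(0, n_cols, n_cols)
        sub = mat[:, cols]
        comparable, ident = _pair_stats(sub, gap)
        off = ~np.eye(len(labels), dtype=bool)
        if np.any(comparable[off] == 0):
            dropped += 1
            continue
        p = 1.0 - ident / np.maximum(comparable, 1)
        np.fill_diagonal(p, 0.0)
        rep_tree = nj_tree(DistanceMatrix(labels, p, "p-distance"))
        rep_splits = bipartitions(rep_tree)
        for split in targets & rep_splits:
            counts[split] += 1
        valid += 1
    if dropped:
        logger.warning("dropped %d/%d bootstrap replicates with undefined distances",
                       dropped, n_reps)
    if valid == 0:
        raise UndefinedDistanceError("all bootstrap replicates had undefined distances")

    all_leaves = frozenset(ref.leaf_names())
    refname = min(all_leaves)
    for node in ref.walk():
        if node is ref or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if refname in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / valid
    return ref


def confirmed_edges(tree: Clade, threshold: float = 90.0) -> list[frozenset]:
    """Splits whose bootstrap support strictly exceeds ``threshold`` percent."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out = []
    for node in tree.walk():
        if node is tree or node.is_leaf or node.support is None:
            continue
        if node.support > threshold:
            side = frozenset(node.leaf_names())
            if ref in side:
                side = all_leaves - side
            out.append(side)
    return out
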