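"""Distance-based 16S phylogenetics: pairwise distances, neighbor joining,
bootstrap support.

Distances come in three models: ``p`` (raw mismatch fraction over
pairwise-complete sites), ``jc`` (Jukes-Cantor, -3/4 ln(1 - 4p/3)) and
``tn93_pooled`` (Tamura-Nei 1993 with base frequencies pooled over all
sequences and per-pair transition/transversion proportions; an explicit
stand-in for composite-likelihood distances, to which it is close but not
identical).  Trees are built with the canonical neighbor-joining
agglomeration (Q-criterion), deterministic tie-breaking by lowest node-index
pair and negative branch lengths clamped to zero.  Bootstrap support
resamples alignment columns with replacement and reports, for every internal
bipartition of the full-data tree, the percentage of replicate trees that
contain it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_DNA = set("ACGT")
_ALLOWED = set("ACGT-N")
_PURINES = {"A", "G"}


class DistanceUndefinedError(ValueError):
    """A pairwise distance cannot be computed (saturation or no shared sites)."""


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A, C, G, T, -, N}."""

    names: list[str]
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        lengths = {len(self.seqs[n]) for n in self.names}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for n in self.names:
            bad = set(self.seqs[n]) - _ALLOWED
            if bad:
                raise ValueError(f"{n}: illegal characters {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[self.names[0]]) if self.names else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        seqs = {
            n: "".join(self.seqs[n][c] for c in cols) for n in self.names
        }
        return Alignment(names=list(self.names), seqs=seqs)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    from Bio import SeqIO

    names, seqs = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise ValueError(f"no sequences in {path}")
    return Alignment(names=names, seqs=seqs)


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])


def _pair_sites(s1: str, s2: str) -> list[tuple[str, str]]:
    return [(a, b) for a, b in zip(s1, s2) if a in _DNA and b in _DNA]


def compute_distances(aln: Alignment, model: str = "jc") -> DistanceMatrix:
    """Pairwise distances under the chosen model.

    Columns holding a gap or N in either member of a pair are dropped for
    that pair (pairwise-complete sites).
    """
    if aln.n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    if model not in {"p", "jc", "tn93_pooled"}:
        raise ValueError(f"unknown model {model!r}")

    freqs = None
    if model == "tn93_pooled":
        counts = {b: 0 for b in "ACGT"}
        for n in aln.names:
            for ch in aln.seqs[n]:
                if ch in _DNA:
                    counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            raise DistanceUndefinedError("alignment has no A/C/G/T sites")
        freqs = {b: counts[b] / total for b in "ACGT"}

    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.names[i], aln.names[j]
            sites = _pair_sites(aln.seqs[a], aln.seqs[b])
            if not sites:
                raise DistanceUndefinedError(f"no shared sites for ({a}, {b})")
            if model == "tn93_pooled":
                dist = _tn93(sites, freqs, pair=(a, b))
            else:
                p = sum(x != y for x, y in sites) / len(sites)
                if model == "p":
                    dist = p
                else:
                    if p >= 0.75:
                        raise DistanceUndefinedError(
                            f"jc distance undefined for ({a}, {b}): p={p:.3f} >= 3/4"
                        )
                    dist = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(names=list(aln.names), matrix=d)


def _tn93(sites, freqs, pair) -> float:
    n = len(sites)
    p1 = sum(1 for x, y in sites if x != y and {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in sites if x != y and {x, y} == {"C", "T"}) / n
    q = sum(
        1 for x, y in sites if x != y and (x in _PURINES) != (y in _PURINES)
    ) / n
    gA, gC, gG, gT = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gR, gY = gA + gG, gC + gT
    if min(gA * gG, gC * gT, gR * gY) == 0:
        raise DistanceUndefinedError("degenerate base frequencies for tn93")
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR)
    w2 = 1 - p2 / k2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise DistanceUndefinedError(f"tn93 distance undefined for {pair}")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """Tree node; the root of an unrooted NJ tree is a trifurcation."""

    name: str | None = None
    length: float = 0.0  # branch to parent; meaningless at the root
    children: list["Node"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    def to_newick(self, with_support: bool = False) -> str:
        return self._newick(with_support, root=True) + ";"

    def _newick(self, with_support: bool, root: bool = False) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        if root:
            return f"({inner}){label}"
        return f"({inner}){label}:{self.length:.6g}"


def tree_bipartitions(root: Node) -> set[frozenset[str]]:
    """Nontrivial bipartitions of an unrooted tree, canonicalized as the
    side not containing the alphabetically first taxon."""
    all_leaves = root.leaf_names()
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()

    def visit(node: Node) -> None:
        for c in node.children:
            side = c.leaf_names()
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side if ref not in side else all_leaves - side)
            visit(c)

    visit(root)
    return out


def tree_distance_matrix(root: Node) -> DistanceMatrix:
    """Additive (path-length) distances between all leaf pairs."""
    names = sorted(root.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    d = np.zeros((n, n))

    def below(node: Node) -> dict[str, float]:
        """leaf -> distance from node; fills cross-pair distances."""
        if node.is_leaf:
            return {node.name: 0.0}
        per_child = []
        for c in node.children:
            sub = {k: v + c.length for k, v in below(c).items()}
            per_child.append(sub)
        merged: dict[str, float] = {}
        for ci, sub in enumerate(per_child):
            for other in per_child[ci + 1:]:
                for a, da in sub.items():
                    for b, db in other.items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
            merged.update(sub)
        return merged

    below(root)
    return DistanceMatrix(names=names, matrix=d)


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Canonical neighbor joining.

    At each step the pair minimizing the Q-criterion is joined; ties are
    broken by the lexicographically lowest (i, j) node-index pair, so the
    output is deterministic.  Negative branch lengths are clamped to 0.
    Returns the unrooted tree as a trifurcating root (bifurcating for 2 or
    3 input taxa joined at the root).
    """
    if not np.allclose(dm.matrix, dm.matrix.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    nodes: list[Node] = [Node(name=nm) for nm in dm.names]
    active = list(range(n))
    d = {
        (i, j): float(dm.matrix[i, j])
        for i in range(n) for j in range(n) if i != j
    }
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                qq = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (qq, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = dist(i, j)
        bi = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        child_i, child_j = node_of[i], node_of[j]
        child_i.length = max(0.0, bi)
        child_j.length = max(0.0, bj)
        new = Node(children=[child_i, child_j])
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dij) / 2
            d[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = new

    # join the final three (or the originally three) nodes at the root
    x, y, z = active
    dxy, dxz, dyz = dist(x, y), dist(x, z), dist(y, z)
    bx = (dxy + dxz - dyz) / 2
    by = (dxy + dyz - dxz) / 2
    bz = (dxz + dyz - dxy) / 2
    for k, bl in zip((x, y, z), (bx, by, bz)):
        node_of[k].length = max(0.0, bl)
    return Node(children=[node_of[x], node_of[y], node_of[z]])


def bootstrap_support(
    aln: Alignment,
    model: str = "jc",
    replicates: int = 500,
    seed: int = 0,
) -> Node:
    """NJ tree on the full alignment with bootstrap support per branch.

    Columns are resampled with replacement ``replicates`` times; support of
    an internal branch is the percentage of replicate trees containing its
    bipartition.  Same seed, same output.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if aln.n_sites < 4:
        raise ValueError("alignment must have >= 4 columns")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(compute_distances(aln, model))
    target = tree_bipartitions(full)
    counts = {bp: 0 for bp in target}
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        try:
            tree = neighbor_joining(compute_distances(rep, model))
        except DistanceUndefinedError:
            continue  # saturated replicate contributes no support
        reps = tree_bipartitions(tree)
        for bp in target:
            if bp in reps:
                counts[bp] += 1

    all_leaves = full.leaf_names()
    ref = min(all_leaves)

    def annotate(node: Node) -> None:
        for c in node.children:
            if not c.is_leaf:
                side = c.leaf_names()
                if 2 <= len(side) <= len(all_leaves) - 2:
                    bp = side if ref not in side else all_leaves - side
                    c.support = 100.0 * counts[bp] / replicates
            annotate(c)

    annotate(full)
    return full
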