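"""Kimura 2-parameter distances, neighbour-joining trees, bootstrap.

The NJ path (Saitou-Nei agglomeration on K2 or Hudson-FST distances)
is the implemented tree surface; negative branch-length estimates are
clamped to zero with the deficit transferred to the sister branch, and
pair selection ties are broken lexicographically so output is
deterministic. Newick is the single interchange format, with bootstrap
supports stored as internal node labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignio import LocusAlignment, NUCLEOTIDES
from .differentiation import hudson_fst

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ValueError):
    """Distance formula undefined: too many differences (log of <= 0)."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    method: str = "K2"
    #: per-pair transition / transversion proportions (K2 only)
    P: np.ndarray | None = None
    Q: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, length)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(
            f"{c._newick()}:{length:.6g}" for c, length in self.children
        )
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"


def kimura2p_distance(seq_a: str, seq_b: str) -> float:
    """K2 distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    P and Q are transition and transversion mismatch proportions over
    sites where both sequences carry an unambiguous base.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    valid = transitions = transversions = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in NUCLEOTIDES or y not in NUCLEOTIDES:
            continue
        valid += 1
        if x != y:
            if frozenset((x, y)) in TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if valid == 0:
        raise ValueError("no jointly valid sites")
    p = transitions / valid
    q = transversions / valid
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K2 distance undefined (saturated divergence)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2_distance_matrix(aln: LocusAlignment) -> DistanceMatrix:
    n = aln.n
    labels = [r.sample_id for r in aln.records]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kimura2p_distance(
                aln.records[i].sequence, aln.records[j].sequence
            )
    return DistanceMatrix(labels, d, "K2")


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    When two clusters remain they are joined through the root; with
    three, the root branch lengths solve the three-point equations.
    Negative branch lengths are clamped to 0 and the deficit moved to
    the sister branch.
    """
    if len(dist.labels) < 3:
        raise ValueError("neighbour joining needs >= 3 labels")
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(lab) for lab in dist.labels
    }
    # canonical name of a cluster = smallest leaf label inside it
    active = sorted(dist.labels)
    d = {
        (a, b): float(dist.matrix[dist.labels.index(a), dist.labels.index(b)])
        for a in dist.labels
        for b in dist.labels
    }
    while len(active) > 3:
        k = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (k - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = d[(a, b)] / 2.0 + (r[a] - r[b]) / (2.0 * (k - 2))
        lb = d[(a, b)] - la
        la, lb = _clamp_pair(la, lb)
        new_name = min(a, b)
        merged = TreeNode(None, [(nodes[a], la), (nodes[b], lb)])
        dnew = {}
        for c in active:
            if c in (a, b):
                continue
            dnew[c] = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2.0
        active = [c for c in active if c not in (a, b)]
        for c in active:
            d[(new_name, c)] = d[(c, new_name)] = max(dnew[c], 0.0)
        active.append(new_name)
        active.sort()
        nodes[new_name] = merged

    if len(active) == 3:
        a, b, c = active
        la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2.0
        lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2.0
        lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2.0
        root = TreeNode(None, [
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ])
    else:
        a, b = active
        root = TreeNode(None, [
            (nodes[a], d[(a, b)] / 2.0),
            (nodes[b], d[(a, b)] / 2.0),
        ])
    return root


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of the leaf set, canonicalised to the side
    not containing the alphabetically first leaf."""
    all_leaves = sorted(tree.leaves())
    anchor = all_leaves[0]
    total = set(all_leaves)
    out: set[frozenset] = set()

    def walk(node: TreeNode) -> set[str]:
        if not node.children:
            return {node.name}
        below = set()
        for child, _ in node.children:
            below |= walk(child)
        if 1 < len(below) < len(total) - 1:
            side = total - below if anchor in below else below
            out.add(frozenset(side))
        return below

    walk(tree)
    return out


def bootstrap_support(
    aln: LocusAlignment,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> TreeNode:
    """NJ tree on K2 distances with column-bootstrap supports (0-100)."""
    from .simdata import _as_rng

    if aln.n < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    rng = _as_rng(seed)
    tree = neighbor_joining(k2_distance_matrix(aln))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    L = aln.length
    mat = aln.matrix()
    labels = [r.sample_id for r in aln.records]
    done = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        try:
            seqs = ["".join(row) for row in sub]
            n = len(seqs)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = kimura2p_distance(seqs[i], seqs[j])
            rep = neighbor_joining(DistanceMatrix(labels, d, "K2"))
        except SaturationError:
            continue
        done += 1
        rep_bps = bipartitions(rep)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    def annotate(node: TreeNode, total: set[str], anchor: str):
        for child, _ in node.children:
            below = set(child.leaves())
            if 1 < len(below) < len(total) - 1:
                side = total - below if anchor in below else below
                key = frozenset(side)
                if key in counts and done:
                    child.support = 100.0 * counts[key] / done
            annotate(child, total, anchor)

    leaves = sorted(tree.leaves())
    annotate(tree, set(leaves), leaves[0])
    return tree


def fst_nj_tree(pops: dict[str, LocusAlignment]) -> TreeNode:
    """NJ tree on the pairwise Hudson-FST matrix between populations.

    Negative FST estimates are floored at 0; an undefined pair (both
    samples monomorphic and identical) is an error naming the pair.
    """
    labels = sorted(pops)
    if len(labels) < 3:
        raise ValueError("need >= 3 populations")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fst, _, _ = hudson_fst(pops[labels[i]], pops[labels[j]])
            if fst is None:
                raise ValueError(
                    f"FST undefined for pair ({labels[i]}, {labels[j]})"
                )
            d[i, j] = d[j, i] = max(fst, 0.0)
    return neighbor_joining(DistanceMatrix(labels, d, "FST"))
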