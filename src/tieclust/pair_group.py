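"""Classical pair-group UPGMA with a complete log of tied minima.

At every agglomeration step the pair of clusters at the minimal working
distance is merged and the distance from the new cluster to every other one
is the size-weighted arithmetic mean (the Lance–Williams update for average
linkage), which equals the mean over all element pairs.  Working distances
are re-rounded to the matrix's decimal precision after every update (the
same limited resolution that makes input distances collide), so ties at any
depth of the dendrogram are judged at the resolution of the data.  When two
or more pairs attain the minimum the result is not unique; this engine picks
one deterministically and records every such tie in a :class:`TieRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .proximity import ProximityMatrix

__all__ = [
    "Leaf",
    "Clade",
    "Dendrogram",
    "TieRecord",
    "upgma",
    "has_ties",
    "cophenetic",
    "to_newick",
    "canonical_form",
    "fmt_height",
]


def fmt_height(h: float, p: int | None) -> str:
    """Fixed-decimal height at precision p, trailing zeros stripped ("1.50" -> "1.5")."""
    if p is None:
        return repr(float(h))
    s = f"{h:.{p}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


class Leaf:
    """A single item; height 0 by definition."""

    __slots__ = ("label", "canon")
    height = 0.0
    children: tuple = ()

    def __init__(self, label: str):
        self.label = str(label)
        self.canon = self.label

    def __repr__(self) -> str:
        return f"Leaf({self.label!r})"


class Clade:
    """Internal node: >=2 children merged at ``height``.

    ``canon`` is a canonical string (children sorted lexicographically,
    height printed at the working precision): two nodes have equal ``canon``
    iff they have the same topology and the same merge heights.  ``band``
    holds the [min, max] tied-distance interval for multidendrogram nodes
    and is excluded from ``canon`` so binary multidendrograms compare equal
    to pair-group dendrograms.
    """

    __slots__ = ("children", "height", "canon", "band")

    def __init__(self, children, height: float, p: int | None, band=None):
        self.children = tuple(children)
        if len(self.children) < 2:
            raise ValueError("a clade needs at least 2 children")
        self.height = float(height)
        self.band = band
        self.canon = (
            "(" + ",".join(sorted(c.canon for c in self.children)) + "):"
            + fmt_height(self.height, p)
        )

    def __repr__(self) -> str:
        return f"Clade({self.canon})"


def _leaf_labels(node) -> list[str]:
    if isinstance(node, Leaf):
        return [node.label]
    out: list[str] = []
    for c in node.children:
        out.extend(_leaf_labels(c))
    return out


def cluster_key(node) -> tuple[str, ...]:
    """A cluster named by its sorted leaf labels (used in tie records)."""
    return tuple(sorted(_leaf_labels(node)))


@dataclass(frozen=True)
class Dendrogram:
    """Binary rooted ultrametric tree over ``leaves`` (input order kept)."""

    root: object
    leaves: tuple[str, ...]
    precision_p: int | None = None

    @property
    def n(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class TieRecord:
    """What happened at one agglomeration step.

    ``tied_pairs`` lists every unordered cluster pair attaining the minimal
    working distance ``d_min`` (clusters named by their sorted leaf labels);
    the step is a genuine tie iff there are at least two of them.
    """

    step_index: int
    d_min: float
    tied_pairs: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    chosen_pair: tuple[tuple[str, ...], tuple[str, ...]]

    @property
    def is_tie(self) -> bool:
        return len(self.tied_pairs) >= 2


def _check_clusterable(m: ProximityMatrix) -> None:
    if m.kind != "distance":
        raise ValueError(
            "clustering requires a distance matrix; convert similarities "
            "with similarity_to_distance first"
        )
    if m.n < 2:
        raise ValueError("need at least 2 items")


def fraction_matrix(m: ProximityMatrix) -> list[list[Fraction]]:
    """Working distances as exact rationals.

    Finite-decimal inputs become exact p-decimal fractions; unrounded inputs
    keep their exact binary-float value.  Exact arithmetic is what makes tie
    detection and merge commutation order-independent — float noise at an
    exact rounding half (e.g. a mean of 0.65 at one decimal) would otherwise
    make the outcome depend on the merge order.
    """
    p = m.precision_p
    if p is None:
        return [[Fraction(v) for v in row] for row in m.values.tolist()]
    scale = 10 ** p
    return [
        [Fraction(int(math.floor(abs(v) * scale + 0.5)), scale) for v in row]
        for row in m.values.tolist()
    ]


def round_frac(x: Fraction, p: int | None) -> Fraction:
    """Exact half-away-from-zero rounding of a non-negative rational."""
    if p is None:
        return x
    scale = 10 ** p
    return Fraction(math.floor(x * scale + Fraction(1, 2)), scale)


def working_view(U, p: int | None, reround: bool):
    """The distances actually compared: rounded to p when re-rounding is on."""
    if reround and p is not None:
        return [[round_frac(v, p) for v in row] for row in U]
    return U


def min_tied_pairs(U, p: int | None, reround: bool):
    """Minimal working distance and every (i, j) pair attaining it, i < j."""
    R = working_view(U, p, reround)
    k = len(R)
    d_min = None
    for i in range(k):
        for j in range(i + 1, k):
            if d_min is None or R[i][j] < d_min:
                d_min = R[i][j]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k) if R[i][j] == d_min]
    return d_min, pairs


def merge_pair(nodes, sizes, U, i, j, height, p):
    """Merge clusters i and j; the new cluster is appended after the survivors."""
    keep = [k for k in range(len(nodes)) if k not in (i, j)]
    si, sj = sizes[i], sizes[j]
    new_row = [(si * U[i][k] + sj * U[j][k]) / (si + sj) for k in keep]
    U2 = [[U[a][b] for b in keep] for a in keep]
    for row, v in zip(U2, new_row):
        row.append(v)
    U2.append(new_row + [Fraction(0)])
    nodes2 = [nodes[t] for t in keep] + [Clade((nodes[i], nodes[j]), height, p)]
    sizes2 = [sizes[t] for t in keep] + [si + sj]
    return nodes2, sizes2, U2


def upgma(
    m: ProximityMatrix,
    tie_rule: str = "first_index",
    reround: bool = True,
) -> tuple[Dendrogram, list[TieRecord]]:
    """Pair-group UPGMA returning one binary dendrogram plus the full tie log.

    ``tie_rule`` breaks ties deterministically by lexicographic cluster index
    (clusters are indexed in creation order, merged clusters last):
    ``first_index`` merges the smallest tied pair — what most off-the-shelf
    clustering software silently does — and ``last_index`` the largest.
    """
    _check_clusterable(m)
    if tie_rule not in ("first_index", "last_index"):
        raise ValueError(f"tie_rule must be first_index|last_index, got {tie_rule!r}")
    p = m.precision_p
    nodes: list = [Leaf(lab) for lab in m.labels]
    sizes = [1] * m.n
    U = fraction_matrix(m)
    records: list[TieRecord] = []
    for step in range(1, m.n):
        d_min, pairs = min_tied_pairs(U, p, reround)
        i, j = pairs[0] if tie_rule == "first_index" else pairs[-1]
        records.append(
            TieRecord(
                step_index=step,
                d_min=float(d_min),
                tied_pairs=tuple(
                    tuple(sorted((cluster_key(nodes[a]), cluster_key(nodes[b]))))
                    for a, b in pairs
                ),
                chosen_pair=tuple(
                    sorted((cluster_key(nodes[i]), cluster_key(nodes[j])))
                ),
            )
        )
        nodes, sizes, U = merge_pair(nodes, sizes, U, i, j, d_min, p)
    return Dendrogram(nodes[0], tuple(m.labels), p), records


def has_ties(records: list[TieRecord]) -> bool:
    """True iff any step had two or more pairs at the minimal distance."""
    if not records:
        raise ValueError("empty tie log")
    return any(r.is_tie for r in records)


def cophenetic(t: Dendrogram) -> ProximityMatrix:
    """Matrix of lowest-common-ancestor heights between all leaf pairs."""
    idx = {lab: k for k, lab in enumerate(t.leaves)}
    M = np.zeros((t.n, t.n))

    def fill(node) -> list[str]:
        if isinstance(node, Leaf):
            return [node.label]
        groups = [fill(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        M[idx[a], idx[b]] = M[idx[b], idx[a]] = node.height
        return [lab for g in groups for lab in g]

    fill(t.root)
    return ProximityMatrix(list(t.leaves), M, "distance", t.precision_p)


_NEWICK_UNSAFE = set("()[]{}:;,'\" \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t, dialect: str = "raw_heights") -> str:
    """Serialize a dendrogram (or multidendrogram) to newick.

    ``raw_heights``: branch length = parent height - child height, so node
    depth from the leaves equals the merge distance.  ``ultrametric_halved``:
    every length divided by 2, so the root-to-tip path equals height/2 (the
    convention when a dendrogram height is read as a path distance); one
    extra decimal digit is printed to keep halved lengths exact.
    """
    if dialect not in ("raw_heights", "ultrametric_halved"):
        raise ValueError(f"unknown dialect {dialect!r}")
    halved = dialect == "ultrametric_halved"
    p = t.precision_p
    if p is not None and halved:
        p = p + 1

    def emit(node, parent_h: float) -> str:
        length = parent_h - node.height
        if halved:
            length /= 2.0
        blen = fmt_height(length, p)
        if isinstance(node, Leaf):
            return f"{_quote(node.label)}:{blen}"
        kids = sorted(node.children, key=lambda c: c.canon)
        inner = ",".join(emit(c, node.height) for c in kids)
        return f"({inner}):{blen}"

    root = t.root
    if isinstance(root, Leaf):
        return f"{_quote(root.label)};"
    kids = sorted(root.children, key=lambda c: c.canon)
    inner = ",".join(emit(c, root.height) for c in kids)
    return f"({inner});"


def canonical_form(t) -> str:
    """Deterministic string identifying topology + merge heights.

    Children are sorted lexicographically and heights printed at the working
    precision, so two dendrograms get the same string iff they are the same
    clustering ("structurally different" trees get different strings).
    """
    return t.root.canon
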