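"""Variable-group UPGMA: the unique multidendrogram with tie bands.

Instead of arbitrarily picking one of the tied pairs, every set of clusters
connected through pairs at the minimal distance is merged simultaneously into
one (possibly non-binary) node.  The result is unique — invariant under any
relabeling of the input — at the price of polytomies.  Each node carries a
tie band ``[band_min, band_max]``: the minimal (merge) distance and the
maximal pairwise distance among the clusters fused at that node, showing how
heterogeneous the tie actually is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Hashable, Iterable

from .pair_group import (
    Clade,
    Leaf,
    _check_clusterable,
    fmt_height,
    fraction_matrix,
    min_tied_pairs,
    to_newick,
)
from .proximity import ProximityMatrix

__all__ = [
    "Multidendrogram",
    "tie_closure",
    "multidendrogram",
    "to_multidendro_json",
    "from_multidendro_json",
]


@dataclass(frozen=True)
class Multidendrogram:
    """n-ary rooted tree; internal nodes carry a height and a tie band."""

    root: object
    leaves: tuple[str, ...]
    precision_p: int | None = None

    @property
    def n(self) -> int:
        return len(self.leaves)


def tie_closure(tied_pairs: Iterable[tuple[Hashable, Hashable]]) -> list[set]:
    """Partition the clusters involved in tied pairs into merge groups.

    Groups are the connected components of the graph whose edges are the
    tied pairs: if B ties with A and with C, all three merge together even
    though (A, C) itself may not attain the minimum.
    """
    parent: dict = {}

    def find(x):
        while parent[x] is not x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in tied_pairs:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra is not rb:
            parent[ra] = rb
    comps: dict = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def multidendrogram(m: ProximityMatrix, reround: bool = True) -> Multidendrogram:
    """Build the unique variable-group multidendrogram of a distance matrix.

    At each iteration all pairs at the (rounded) minimal working distance are
    found, their transitive closure forms the merge groups, and every group
    is merged in the same step.  A group node sits at the minimal distance;
    its band maximum is the largest *unrounded* pairwise working distance
    among the merged clusters (clamped to the height when rounding makes it
    marginally smaller; a 2-cluster group has a degenerate band).  The
    distance from a new group to anything else is the size-weighted mean —
    exactly the mean over all element pairs, as in pair-group UPGMA.
    """
    _check_clusterable(m)
    p = m.precision_p
    nodes: list = [Leaf(lab) for lab in m.labels]
    sizes = [1] * m.n
    U = fraction_matrix(m)
    while len(nodes) > 1:
        d_min, pairs = min_tied_pairs(U, p, reround)
        h = float(d_min)
        merge_groups = sorted(sorted(g) for g in tie_closure(pairs))
        merged = {i for g in merge_groups for i in g}
        # singletons ride along unchanged; groups become one weighted block
        blocks = [[i] for i in range(len(nodes)) if i not in merged]
        new_nodes = [nodes[b[0]] for b in blocks]
        for g in merge_groups:
            band_hi = max(
                (float(U[i][j]) for i, j in combinations(g, 2)), default=h
            )
            band = (h, h) if len(g) == 2 else (h, max(h, band_hi))
            new_nodes.append(Clade([nodes[i] for i in g], d_min, p, band=band))
            blocks.append(g)
        # weighted aggregation: U'[a,b] = sum_{i in a, j in b} s_i s_j U[i][j] / (S_a S_b)
        S = [sum(sizes[i] for i in blk) for blk in blocks]
        k = len(blocks)
        U2 = [[Fraction(0)] * k for _ in range(k)]
        for a in range(k):
            for b in range(a + 1, k):
                tot = sum(
                    sizes[i] * sizes[j] * U[i][j] for i in blocks[a] for j in blocks[b]
                )
                U2[a][b] = U2[b][a] = tot / (S[a] * S[b])
        nodes, sizes, U = new_nodes, S, U2
    return Multidendrogram(nodes[0], tuple(m.labels), p)


def _node_to_obj(node, p):
    if isinstance(node, Leaf):
        return {"label": node.label}
    band = node.band or (node.height, node.height)
    rnd = (lambda x: float(fmt_height(x, p)))
    return {
        "children": [_node_to_obj(c, p) for c in node.children],
        "height": rnd(node.height),
        "band_min": rnd(band[0]),
        "band_max": rnd(band[1]),
    }


def to_multidendro_json(t: Multidendrogram, newick_polytomy_path=None) -> str:
    """Serialize a multidendrogram (heights and bands) to nested JSON.

    Newick cannot carry tie bands; if ``newick_polytomy_path`` is given, a
    lossy newick with polytomies at the band minimum is written there too.
    """
    obj = {
        "leaves": list(t.leaves),
        "precision_p": t.precision_p,
        "root": _node_to_obj(t.root, t.precision_p),
    }
    if newick_polytomy_path is not None:
        Path(newick_polytomy_path).write_text(to_newick(t) + "\n")
    return json.dumps(obj, indent=2)


def _node_from_obj(obj, p):
    if "label" in obj:
        return Leaf(obj["label"])
    children = [_node_from_obj(c, p) for c in obj["children"]]
    return Clade(
        children, obj["height"], p, band=(obj["band_min"], obj["band_max"])
    )


def from_multidendro_json(text: str) -> Multidendrogram:
    """Inverse of :func:`to_multidendro_json`."""
    obj = json.loads(text)
    p = obj["precision_p"]
    return Multidendrogram(_node_from_obj(obj["root"], p), tuple(obj["leaves"]), p)
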