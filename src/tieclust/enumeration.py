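"""Exhaustive enumeration of all binary UPGMA dendrograms under tied distances.

Whenever several cluster pairs attain the minimal working distance, each
choice branches the agglomeration.  Naively recursing over every choice
re-explores the same partial clustering factorially often (two disjoint tied
merges commute), so the optimized search treats partial clusterings as
states of a DAG: a state is the multiset of partial subtrees built so far
(topology + heights), identical states are expanded once, and the number of
structurally distinct binary dendrograms is exactly the number of distinct
terminal states reached.  A no-deduplication brute force over small inputs
serves as the validation oracle.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .pair_group import (
    Leaf,
    _check_clusterable,
    fraction_matrix,
    merge_pair,
    min_tied_pairs,
)
from .proximity import ProximityMatrix

__all__ = [
    "EnumerationResult",
    "count_binary_dendrograms",
    "brute_force_enumerate",
    "canonical_state",
]

DEFAULT_MAX_TREES = 10_000_000
_BRUTE_FORCE_GUARD = 8


@dataclass(frozen=True)
class EnumerationResult:
    """Outcome of the dendrogram count.

    ``count`` is exact when ``truncated`` is False, otherwise a lower bound
    (the search stopped at ``max_trees`` distinct trees).  ``trees`` holds the
    canonical forms when requested; ``states_visited`` counts the distinct
    partial clusterings expanded.
    """

    count: int
    truncated: bool
    states_visited: int
    max_trees: int | None
    trees: frozenset[str] | None = None


def _topology_only(canon: str) -> str:
    # drop every ":height" annotation, keeping parenthesis structure + labels
    out, i = [], 0
    while i < len(canon):
        ch = canon[i]
        if ch == ":":
            i += 1
            while i < len(canon) and canon[i] not in ",()":
                i += 1
            continue
        out.append(ch)
        i += 1
    return "".join(out)


def canonical_state(nodes) -> str:
    """Deterministic key of a partial clustering: sorted subtree canonical forms.

    Equal keys mean identical forests (same subtrees with the same heights),
    hence identical sets of possible completions — the property that makes
    state deduplication sound.
    """
    return "|".join(sorted(node.canon for node in nodes))


def _digest(text: str) -> bytes:
    # 128-bit digest: collision probability negligible at 10^7 states
    return hashlib.blake2b(text.encode(), digest_size=16).digest()


def _branches(nodes, sizes, U, p, reround):
    d_min, pairs = min_tied_pairs(U, p, reround)
    for i, j in pairs:
        yield merge_pair(nodes, sizes, U, i, j, d_min, p)


def count_binary_dendrograms(
    m: ProximityMatrix,
    max_trees: int | None = DEFAULT_MAX_TREES,
    keep_trees: bool = False,
    reround: bool = True,
    by_topology: bool = False,
) -> EnumerationResult:
    """Count (and optionally collect) every distinct binary dendrogram.

    Depth-first search over tie choices with memoization on
    :func:`canonical_state`; the reachable-state graph is a DAG whose
    terminal states are exactly the distinct dendrograms.  With a finite
    ``max_trees`` the search stops once that many distinct trees are found
    and reports a lower bound (``truncated=True``).  ``by_topology=True``
    identifies trees by shape only, ignoring merge heights.
    """
    _check_clusterable(m)
    if max_trees is not None and max_trees < 1:
        raise ValueError("max_trees must be >= 1")
    p = m.precision_p
    start = ([Leaf(lab) for lab in m.labels], [1] * m.n, fraction_matrix(m))
    visited = {_digest(canonical_state(start[0]))}
    tree_keys: set = set()
    trees: set[str] | None = set() if keep_trees else None
    stack = [start]
    states_visited = 0
    truncated = False
    while stack:
        nodes, sizes, U = stack.pop()
        states_visited += 1
        if len(nodes) == 1:
            canon = _topology_only(nodes[0].canon) if by_topology else nodes[0].canon
            key = _digest(canon)
            if key not in tree_keys:
                tree_keys.add(key)
                if trees is not None:
                    trees.add(nodes[0].canon)
            if max_trees is not None and len(tree_keys) >= max_trees and stack:
                truncated = True
                break
            continue
        for child in _branches(nodes, sizes, U, p, reround):
            key = _digest(canonical_state(child[0]))
            if key not in visited:
                visited.add(key)
                stack.append(child)
    return EnumerationResult(
        count=len(tree_keys),
        truncated=truncated,
        states_visited=states_visited,
        max_trees=max_trees,
        trees=frozenset(trees) if trees is not None else None,
    )


def brute_force_enumerate(m: ProximityMatrix, reround: bool = True) -> frozenset[str]:
    """Oracle: exhaustive recursion over every tie choice, no state deduplication.

    Final trees are deduplicated by canonical form only.  Guarded to n <= 8 —
    the path count grows factorially without memoization.
    """
    _check_clusterable(m)
    if m.n > _BRUTE_FORCE_GUARD:
        raise ValueError(f"brute force is guarded to n <= {_BRUTE_FORCE_GUARD}")
    p = m.precision_p
    found: set[str] = set()

    def recurse(nodes, sizes, U):
        if len(nodes) == 1:
            found.add(nodes[0].canon)
            return
        for child in _branches(nodes, sizes, U, p, reround):
            recurse(*child)

    recurse([Leaf(lab) for lab in m.labels], [1] * m.n, fraction_matrix(m))
    return frozenset(found)
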