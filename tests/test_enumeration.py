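"""Counting all binary dendrograms: oracle equivalence and structural checks."""

import numpy as np
import pytest

from tieclust import (
    ProximityMatrix,
    TieDesign,
    brute_force_enumerate,
    canonical_form,
    canonical_state,
    count_binary_dendrograms,
    planted_tie_matrix,
    upgma,
)
from tieclust.pair_group import Leaf, merge_pair
from tieclust.synthetic import random_grid_matrix


def test_chain_has_two_dendrograms(chain):
    res = count_binary_dendrograms(chain, keep_trees=True)
    assert res.count == 2 and not res.truncated
    assert res.trees == frozenset({"((A,B):1,C):1.5", "((B,C):1,A):1.5"})
    assert res.trees == brute_force_enumerate(chain)


def test_equilateral_triple_has_three(equilateral):
    res = count_binary_dendrograms(equilateral)
    assert res.count == 3
    assert len(brute_force_enumerate(equilateral)) == 3


def test_tie_free_matrix_has_one(tie_free):
    res = count_binary_dendrograms(tie_free, keep_trees=True)
    assert res.count == 1
    assert res.trees == frozenset({canonical_form(upgma(tie_free)[0])})


@pytest.mark.parametrize("k, expected", [(1, 3), (2, 9), (3, 27)])
def test_block_multiplicativity_equilateral_triples(k, expected):
    m, claimed = planted_tie_matrix(TieDesign((("equilateral", 3),) * k))
    assert claimed == expected
    assert count_binary_dendrograms(m).count == expected


def test_equilateral_quadruple_counts_all_topologies():
    # 4 items all at the same distance: every rooted binary shape occurs,
    # (2n-3)!! = 15, all at equal heights
    m, claimed = planted_tie_matrix(TieDesign((("equilateral", 4),)))
    assert claimed == 15
    res = count_binary_dendrograms(m)
    assert res.count == 15
    assert len(brute_force_enumerate(m)) == 15


@pytest.mark.parametrize("seed", range(60))
def test_oracle_equivalence_on_random_tied_matrices(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    m = random_grid_matrix(n, grid_step=0.2, value_range=(0.2, 1.2), seed=seed)
    res = count_binary_dendrograms(m, keep_trees=True)
    oracle = brute_force_enumerate(m)
    assert res.count == len(oracle)
    assert res.trees == oracle


@pytest.mark.parametrize("seed", range(25))
def test_pair_group_tree_is_always_enumerated(seed):
    m = random_grid_matrix(6, grid_step=0.25, value_range=(0.25, 1.5), seed=500 + seed)
    trees = count_binary_dendrograms(m, keep_trees=True).trees
    for rule in ("first_index", "last_index"):
        assert canonical_form(upgma(m, tie_rule=rule)[0]) in trees


def test_cap_gives_lower_bound_and_truncation_flag(equilateral):
    capped = count_binary_dendrograms(equilateral, max_trees=1)
    assert capped.truncated and capped.count == 1
    full = count_binary_dendrograms(equilateral, max_trees=3)
    assert not full.truncated and full.count == 3
    with pytest.raises(ValueError):
        count_binary_dendrograms(equilateral, max_trees=0)


def test_by_topology_collapses_height_variants():
    # two clusters at different heights but identical shape
    v = np.array(
        [
            [0.0, 1.0, 6.0, 6.0],
            [1.0, 0.0, 6.0, 6.0],
            [6.0, 6.0, 0.0, 2.0],
            [6.0, 6.0, 2.0, 0.0],
        ]
    )
    m = ProximityMatrix(list("ABCD"), v, "distance", 0)
    assert count_binary_dendrograms(m).count == 1
    assert count_binary_dendrograms(m, by_topology=True).count == 1
    chain3, _ = planted_tie_matrix(TieDesign((("chain", 3),)))
    # the two chain resolutions differ in topology as well as heights
    assert count_binary_dendrograms(chain3, by_topology=True).count == 2


def test_commuting_merges_reach_the_same_state():
    labels = list("ABCD")
    v = np.full((4, 4), 8.0)
    v[0, 1] = v[1, 0] = 1.0
    v[2, 3] = v[3, 2] = 1.0
    np.fill_diagonal(v, 0.0)
    nodes = [Leaf(l) for l in labels]
    sizes = [1, 1, 1, 1]
    ab_first = merge_pair(*merge_pair(nodes, sizes, v.copy(), 0, 1, 1.0, 0), 0, 1, 1.0, 0)
    cd_first = merge_pair(*merge_pair(nodes, sizes, v.copy(), 2, 3, 1.0, 0), 0, 1, 1.0, 0)
    assert canonical_state(ab_first[0]) == canonical_state(cd_first[0])
    # initial state key is just the sorted leaves
    assert canonical_state(nodes) == "A|B|C|D"
    # differing only in one merge height -> different keys
    h1 = merge_pair(nodes, sizes, v.copy(), 0, 1, 1.0, 0)
    h2 = merge_pair(nodes, sizes, v.copy(), 0, 1, 2.0, 0)
    assert canonical_state(h1[0]) != canonical_state(h2[0])


def test_brute_force_guard():
    m = random_grid_matrix(9, grid_step=0.5, value_range=(0.5, 2.0), seed=0)
    with pytest.raises(ValueError, match="n <= 8"):
        brute_force_enumerate(m)
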