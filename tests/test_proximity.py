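"""Proximity matrices: parsing, precision, rounding, transforms."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tieclust import (
    AsymmetryError,
    MatrixParseError,
    ProximityMatrix,
    ZeroSimilarityError,
    infer_precision,
    read_proximity_matrix,
    round_to_precision,
    similarity_to_distance,
    write_proximity_matrix,
)
from tieclust.proximity import round_half_away
from tieclust.synthetic import random_grid_matrix


@pytest.mark.parametrize(
    "tokens, expected",
    [
        (["1.0459", "1.1112"], 4),
        (["1", "2", "3"], 0),
        (["0.5", "0.125"], 3),
        (["0.50"], 2),  # trailing zeros are printed precision
    ],
)
def test_infer_precision(tokens, expected):
    assert infer_precision(tokens) == expected


def test_round_to_precision_half_away_and_idempotent():
    m = ProximityMatrix(
        ["a", "b"], np.array([[0.0, 1.04586], [1.04586, 0.0]]), "distance"
    )
    r = round_to_precision(m, 4)
    assert r.values[0, 1] == 1.0459
    assert r.precision_p == 4
    again = round_to_precision(r, 4)
    assert np.array_equal(again.values, r.values)
    # half away from zero, not half even
    assert round_half_away(0.25, 1) == 0.3
    assert round_half_away(-0.25, 1) == -0.3


@settings(derandomize=True, max_examples=200)
@given(
    x=st.floats(min_value=0, max_value=100, allow_nan=False),
    y=st.floats(min_value=0, max_value=100, allow_nan=False),
    p=st.integers(min_value=0, max_value=6),
)
def test_rounding_is_monotone(x, y, p):
    lo, hi = sorted((x, y))
    assert round_half_away(lo, p) <= round_half_away(hi, p)


def test_similarity_to_distance_closed_forms():
    s = ProximityMatrix(
        ["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]), "similarity", 1
    )
    one = similarity_to_distance(s, "one_minus")
    assert one.kind == "distance" and one.values[0, 1] == 0.5
    neg = similarity_to_distance(s, "neg_log")
    assert neg.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)
    assert neg.precision_p is None
    ident = ProximityMatrix(["a", "b"], np.ones((2, 2)), "similarity")
    assert similarity_to_distance(ident, "one_minus").values[0, 1] == 0.0
    assert similarity_to_distance(ident, "neg_log").values[0, 1] == 0.0


def test_one_minus_is_involutive_on_similarities():
    s = ProximityMatrix(
        ["a", "b", "c"],
        np.array([[1.0, 0.25, 0.75], [0.25, 1.0, 0.5], [0.75, 0.5, 1.0]]),
        "similarity",
        2,
    )
    d = similarity_to_distance(s, "one_minus")
    assert d.values[~np.eye(3, dtype=bool)].max() <= 1.0
    back = ProximityMatrix(s.labels, 1.0 - d.values + np.eye(3) * 0, "similarity")
    # 1 - (1 - s) returns the original values exactly at the stored precision
    np.fill_diagonal(back.values, 1.0)
    assert np.allclose(back.values, s.values, atol=0)


def test_neg_log_zero_similarity_errors_unless_capped():
    s = ProximityMatrix(
        ["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]), "similarity", 1
    )
    with pytest.raises(ZeroSimilarityError, match="'a' and 'b'"):
        similarity_to_distance(s, "neg_log")
    capped = similarity_to_distance(s, "neg_log", neg_log_cap=9.9)
    assert capped.values[0, 1] == 9.9


LOWER_TRIANGULAR = """3
A
B 0.3012
C 0.4120 0.1200
"""


def test_read_phylip_lower_infers_precision():
    m = read_proximity_matrix(io.StringIO(LOWER_TRIANGULAR), "phylip_lower", "distance")
    assert m.labels == ["A", "B", "C"]
    assert m.precision_p == 4
    assert m.values[0, 1] == 0.3012 and m.values[2, 1] == 0.12


def test_asymmetric_input_is_an_error_not_averaged():
    text = ",A,B\nA,0.00,0.30\nB,0.31,0.00\n"
    with pytest.raises(AsymmetryError):
        read_proximity_matrix(io.StringIO(text), "csv", "distance")


@pytest.mark.parametrize("bad", [",A,B\nA,0,x\nB,x,0\n", ",A,B\nA,0,1\n"])
def test_malformed_matrix_raises_parse_error(bad):
    with pytest.raises(MatrixParseError):
        read_proximity_matrix(io.StringIO(bad), "csv", "distance")


@pytest.mark.parametrize("fmt", ["csv", "tsv", "phylip_square", "phylip_lower"])
@pytest.mark.parametrize("seed", [1, 2])
def test_matrix_round_trip(fmt, seed):
    m = random_grid_matrix(7, grid_step=0.05, value_range=(0.05, 2.0), seed=seed)
    buf = io.StringIO()
    write_proximity_matrix(m, buf, format=fmt)
    back = read_proximity_matrix(io.StringIO(buf.getvalue()), fmt, "distance")
    assert back.labels == m.labels
    assert back.precision_p == m.precision_p
    assert np.array_equal(back.values, m.values)


def test_matrix_invariant_violations_rejected():
    with pytest.raises(AsymmetryError):
        ProximityMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "distance")
    with pytest.raises(ValueError, match="representable"):
        ProximityMatrix(
            ["a", "b"], np.array([[0.0, 1.2345], [1.2345, 0.0]]), "distance", 2
        )
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        ProximityMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]), "similarity")
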