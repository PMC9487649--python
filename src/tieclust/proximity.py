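"""Labeled proximity matrices: I/O, precision handling, similarity/distance transforms.

A :class:`ProximityMatrix` is a symmetric labeled matrix of either similarities
(off-diagonal values in [0, 1], unit diagonal) or distances (non-negative,
zero diagonal).  Each matrix carries ``precision_p``: the number of decimal
digits the values are stated at, or ``None`` for unrounded values.  Finite
decimal precision is what makes tied distances common in practice, so the
precision is a first-class attribute that the clustering engines consult.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AsymmetryError, MatrixParseError, ZeroSimilarityError

__all__ = [
    "ProximityMatrix",
    "infer_precision",
    "round_half_away",
    "round_to_precision",
    "similarity_to_distance",
    "read_proximity_matrix",
    "write_proximity_matrix",
]


def round_half_away(x, p: int):
    """Round to ``p`` decimals, halves away from zero (3.5 -> 4, -3.5 -> -4).

    This is the decimal rounding convention most software applies when
    printing values to a fixed number of digits, and it is monotone and
    idempotent, which the clustering engines rely on.
    """
    x = np.asarray(x, dtype=float)
    f = 10.0 ** p
    out = np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f
    return out if out.ndim else float(out)


@dataclass
class ProximityMatrix:
    """Symmetric labeled similarity or distance matrix with decimal precision.

    Parameters
    ----------
    labels : ordered unique names of the items.
    values : (n, n) symmetric float array.
    kind : ``"similarity"`` or ``"distance"``.
    precision_p : number of decimal digits the values are stated at, or
        ``None`` for unrounded values.
    """

    labels: list[str]
    values: np.ndarray
    kind: str
    precision_p: int | None = None

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixParseError("duplicate labels in proximity matrix")
        if self.values.shape != (n, n):
            raise MatrixParseError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"kind must be similarity|distance, got {self.kind!r}")
        if not np.array_equal(self.values, self.values.T):
            raise AsymmetryError("matrix is not symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if self.kind == "similarity":
            if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
                raise ValueError("similarity values must lie in [0, 1]")
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
                raise ValueError("similarity diagonal must be 1")
        else:
            if off.size and off.min() < -1e-12:
                raise ValueError("distances must be non-negative")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
                raise ValueError("distance diagonal must be 0")
        if self.precision_p is not None:
            p = int(self.precision_p)
            if p < 0:
                raise ValueError("precision_p must be >= 0")
            if not np.array_equal(self.values, round_half_away(self.values, p)):
                raise ValueError(
                    f"values are not representable at {p} decimal digits; "
                    "round_to_precision first"
                )
            self.precision_p = p

    @property
    def n(self) -> int:
        return len(self.labels)

    def copy(self) -> "ProximityMatrix":
        return replace(self, labels=list(self.labels), values=self.values.copy())

    def permuted(self, order: Sequence[int]) -> "ProximityMatrix":
        """Return the matrix with rows/columns reordered by ``order``."""
        idx = np.asarray(order)
        return ProximityMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.kind,
            self.precision_p,
        )


def infer_precision(tokens: Iterable[str]) -> int:
    """Maximum number of digits printed after the decimal point across tokens.

    ``{"1.0459", "1.1112"} -> 4``; integers give 0.  Trailing zeros count:
    the printed text, not the numeric value, defines the stated resolution.
    """
    best = None
    for tok in tokens:
        try:
            exp = Decimal(str(tok).strip()).as_tuple().exponent
        except InvalidOperation as e:  # pragma: no cover - guarded by parsers
            raise MatrixParseError(f"non-numeric token {tok!r}") from e
        digits = max(0, -exp) if isinstance(exp, int) else 0
        best = digits if best is None else max(best, digits)
    if best is None:
        raise ValueError("infer_precision needs at least one value")
    return best


def round_to_precision(m: ProximityMatrix, p: int) -> ProximityMatrix:
    """Round every value half-away-from-zero to ``p`` decimals."""
    if p < 0:
        raise ValueError("precision must be >= 0")
    vals = round_half_away(m.values, p)
    vals = (vals + vals.T) / 2.0  # rounding a symmetric matrix stays symmetric
    return ProximityMatrix(list(m.labels), vals, m.kind, p)


def similarity_to_distance(
    m: ProximityMatrix,
    transform: str = "one_minus",
    neg_log_cap: float | str = "error",
) -> ProximityMatrix:
    """Convert a similarity matrix to distances.

    ``one_minus``: d = 1 - s (keeps the decimal precision).
    ``neg_log``:   d = -ln(s); s = 0 raises :class:`ZeroSimilarityError`
    unless a finite ``neg_log_cap`` is supplied, in which case that cap is
    used.  The -log transform produces irrational values, so the result is
    marked unrounded.
    """
    if m.kind != "similarity":
        raise ValueError("similarity_to_distance requires a similarity matrix")
    s = m.values
    if transform == "one_minus":
        d = 1.0 - s
        p = m.precision_p
        if p is not None:
            d = round_half_away(d, p)
        np.fill_diagonal(d, 0.0)
        return ProximityMatrix(list(m.labels), d, "distance", p)
    if transform == "neg_log":
        zero = (s <= 0) & ~np.eye(m.n, dtype=bool)
        if zero.any():
            if neg_log_cap == "error":
                i, j = map(int, np.argwhere(zero)[0])
                raise ZeroSimilarityError(
                    f"similarity 0 between {m.labels[i]!r} and {m.labels[j]!r}: "
                    "-log is undefined (pass a finite neg_log_cap to cap it)"
                )
            cap = float(neg_log_cap)
            if cap <= 0:
                raise ValueError("neg_log_cap must be positive")
        with np.errstate(divide="ignore"):
            d = -np.log(s)
        if zero.any():
            d[zero] = cap
        np.fill_diagonal(d, 0.0)
        return ProximityMatrix(list(m.labels), d, "distance", None)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# text formats: CSV/TSV with header row+column, PHYLIP square / lower-triangular
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "tsv", "phylip_square", "phylip_lower")


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = Path(source)
    if path.exists():
        return path.read_text()
    text = str(source)
    if "\n" in text or "," in text:
        return text
    raise MatrixParseError(f"no such file: {source}")


def read_proximity_matrix(source, format: str = "csv", kind: str = "distance") -> ProximityMatrix:
    """Parse a proximity matrix from text.

    The decimal precision is inferred from the printed tokens.  Asymmetry
    beyond one unit in the last printed digit is an error — inconsistent
    matrices are rejected, never silently averaged.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    text = _as_text(source)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
        labels = [str(x) for x in df.index]
        if list(map(str, df.columns)) != labels:
            raise MatrixParseError("row and column labels differ or matrix is not square")
        tokens = df.to_numpy()
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        try:
            n = int(lines[0].split()[0])
        except (ValueError, IndexError) as e:
            raise MatrixParseError("PHYLIP matrix must start with the item count") from e
        rows = [ln.split() for ln in lines[1 : n + 1]]
        if len(rows) != n:
            raise MatrixParseError(f"expected {n} rows, found {len(rows)}")
        labels = [r[0] for r in rows]
        if format == "phylip_square":
            tokens = np.array([r[1:] for r in rows], dtype=object)
            if any(len(r) != n + 1 for r in rows):
                raise MatrixParseError("square PHYLIP rows must have n values each")
        else:
            tokens = np.full((n, n), "0", dtype=object)
            for i, r in enumerate(rows):
                if len(r) != i + 1:
                    raise MatrixParseError(
                        f"lower-triangular row {i + 1} ({r[0]!r}) has {len(r) - 1} "
                        f"values, expected {i}"
                    )
                for j, tok in enumerate(r[1:]):
                    tokens[i, j] = tokens[j, i] = tok

    if len(set(labels)) != len(labels):
        raise MatrixParseError("duplicate labels")
    flat = [str(t) for t in tokens.ravel()]
    try:
        values = np.array([[float(t) for t in row] for row in tokens], dtype=float)
    except (TypeError, ValueError) as e:
        raise MatrixParseError(f"non-numeric cell in matrix: {e}") from e
    p = infer_precision(flat)
    if p > 12:  # full-float repr: treat as unrounded, not a decimal precision
        p = None
    ulp = 10.0 ** (-(p if p is not None else 15))
    asym = np.abs(values - values.T)
    if asym.max() > 0.51 * ulp:
        i, j = map(int, np.unravel_index(int(asym.argmax()), asym.shape))
        raise AsymmetryError(
            f"asymmetric entries ({labels[i]}, {labels[j]}): "
            f"{values[i, j]} vs {values[j, i]}"
        )
    values = np.triu(values) + np.triu(values, 1).T
    if p is not None:
        values = round_half_away(values, p)
    return ProximityMatrix(labels, values, kind, p)


def write_proximity_matrix(m: ProximityMatrix, dest, format: str = "csv") -> None:
    """Write a matrix in one of the supported text formats.

    Values are printed at ``precision_p`` decimals (``repr`` when unrounded),
    so a read-back infers the same precision and identical values.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")

    def fmt(v: float) -> str:
        return repr(float(v)) if m.precision_p is None else f"{v:.{m.precision_p}f}"

    buf = io.StringIO()
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        buf.write(sep.join([""] + m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            buf.write(sep.join([lab] + [fmt(v) for v in m.values[i]]) + "\n")
    elif format == "phylip_square":
        buf.write(f"{m.n}\n")
        for i, lab in enumerate(m.labels):
            buf.write(" ".join([lab] + [fmt(v) for v in m.values[i]]) + "\n")
    else:
        buf.write(f"{m.n}\n")
        for i, lab in enumerate(m.labels):
            buf.write(" ".join([lab] + [fmt(v) for v in m.values[i, :i]]) + "\n")
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
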