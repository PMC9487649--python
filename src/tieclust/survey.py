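"""Survey statistics: tie prevalence, binomial CI, extrapolation, count bins.

Given per-source tie results (does the source's matrix admit more than one
binary dendrogram, and how many), this module computes the fraction of
sources affected with a binomial confidence interval, extrapolates the
fraction to a larger population, and bins the dendrogram counts into
log-decade classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .enumeration import DEFAULT_MAX_TREES, count_binary_dendrograms
from .proximity import (
    read_proximity_matrix,
    round_to_precision,
    similarity_to_distance,
)

__all__ = [
    "SurveyRecord",
    "SurveySummary",
    "Bin",
    "BIN_EDGES",
    "summarize",
    "bin_counts",
    "run_survey",
]

_CI_METHODS = {"wald": "normal", "wilson": "wilson", "clopper_pearson": "beta"}

# log-decade classes for the number of alternative binary dendrograms;
# a count above the last edge falls in the open top bin (">10000")
BIN_EDGES = ((2, 10), (11, 100), (101, 1000), (1001, 10000))


def _iround(x: float) -> int:
    """round half up — the convention for printed integer percentages"""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SurveyRecord:
    """Tie outcome for one source matrix."""

    source_id: str
    has_tie: bool
    dendrogram_count: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.has_tie != (self.dendrogram_count >= 2):
            raise ValueError(
                f"{self.source_id!r}: has_tie must hold iff dendrogram_count >= 2"
            )


@dataclass(frozen=True)
class Bin:
    label: str
    low: int
    high: int | None  # None = open top bin
    count: int
    percent: int  # of tied records, rounded to an integer


@dataclass(frozen=True)
class SurveySummary:
    """Prevalence of ties with CI and (optional) population extrapolation.

    ``proportion`` and the CI bounds are fractions in [0, 1]; the ``*_pct``
    properties give the integer-rounded percentages as they would be printed.
    Extrapolations are ``round(fraction x population_N)``.
    """

    n_tied: int
    n_analyzed: int
    confidence: float
    method: str
    proportion: float
    ci_low: float
    ci_high: float
    population_N: int | None = None
    extrapolated: int | None = None
    extrapolated_low: int | None = None
    extrapolated_high: int | None = None
    histogram: tuple[Bin, ...] | None = None

    @property
    def proportion_pct(self) -> int:
        return _iround(100 * self.proportion)

    @property
    def ci_low_pct(self) -> int:
        return _iround(100 * self.ci_low)

    @property
    def ci_high_pct(self) -> int:
        return _iround(100 * self.ci_high)


def summarize(
    n_tied: int,
    n_analyzed: int,
    confidence: float = 0.95,
    population_N: int | None = None,
    method: str = "wald",
    histogram: tuple[Bin, ...] | None = None,
) -> SurveySummary:
    """Tie prevalence with a binomial CI and population extrapolation.

    The default interval is the Wald (normal approximation)
    p-hat +/- z*sqrt(p-hat(1-p-hat)/n), clipped to [0, 1]; ``wilson`` and
    ``clopper_pearson`` are available as alternatives.
    """
    if not (0 <= n_tied <= n_analyzed) or n_analyzed < 1:
        raise ValueError(f"invalid counts: n_tied={n_tied}, n_analyzed={n_analyzed}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if method not in _CI_METHODS:
        raise ValueError(f"method must be one of {sorted(_CI_METHODS)}")
    p_hat = n_tied / n_analyzed
    lo, hi = proportion_confint(
        n_tied, n_analyzed, alpha=1 - confidence, method=_CI_METHODS[method]
    )
    lo = min(max(float(lo), 0.0), 1.0)
    hi = min(max(float(hi), 0.0), 1.0)
    extr = extr_lo = extr_hi = None
    if population_N is not None:
        extr = _iround(p_hat * population_N)
        extr_lo = _iround(lo * population_N)
        extr_hi = _iround(hi * population_N)
    return SurveySummary(
        n_tied=n_tied,
        n_analyzed=n_analyzed,
        confidence=confidence,
        method=method,
        proportion=p_hat,
        ci_low=lo,
        ci_high=hi,
        population_N=population_N,
        extrapolated=extr,
        extrapolated_low=extr_lo,
        extrapolated_high=extr_hi,
        histogram=histogram,
    )


def bin_counts(records: Iterable) -> tuple[Bin, ...]:
    """Histogram of dendrogram counts over the tied records.

    Bins: [2-10], [11-100], [101-1000], [1001-10000], [>10000]; percentages
    are of the tied total, rounded to integers.  Accepts
    :class:`SurveyRecord` objects or raw integer counts (all must be >= 2:
    only tied sources have a count distribution).
    """
    counts = [
        r.dendrogram_count if isinstance(r, SurveyRecord) else int(r) for r in records
    ]
    if any(c < 2 for c in counts):
        raise ValueError("bin_counts expects tied records only (counts >= 2)")
    total = len(counts)
    bins = []
    for low, high in BIN_EDGES:
        k = sum(low <= c <= high for c in counts)
        bins.append(
            Bin(f"{low}-{high}", low, high, k, _iround(100 * k / total) if total else 0)
        )
    top_low = BIN_EDGES[-1][1] + 1
    k = sum(c >= top_low for c in counts)
    bins.append(
        Bin(f">{BIN_EDGES[-1][1]}", top_low, None, k,
            _iround(100 * k / total) if total else 0)
    )
    return tuple(bins)


def run_survey(
    manifest,
    confidence: float = 0.95,
    population_N: int | None = None,
    max_trees: int | None = DEFAULT_MAX_TREES,
    ci_method: str = "wald",
) -> tuple[list[SurveyRecord], list[tuple[str, str]], SurveySummary]:
    """Run the tie survey over a manifest of proximity matrices.

    ``manifest`` is a CSV with columns ``id, path, kind, transform,
    precision`` (paths relative to the manifest's directory; ``transform`` in
    none|one_minus|neg_log; ``precision`` "auto" or an integer).  Each entry
    is read, converted to a distance matrix if needed, rounded, and its
    binary dendrograms counted.  Failures are recorded per entry, never
    fatal; returns ``(records, failures, summary)``.
    """
    mpath = Path(manifest)
    df = pd.read_csv(mpath, dtype=str)
    if df.empty:
        raise ValueError("empty survey manifest")
    records: list[SurveyRecord] = []
    failures: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        sid = str(row["id"])
        try:
            path = mpath.parent / str(row["path"])
            kind = str(row.get("kind", "distance"))
            fmt = "tsv" if path.suffix == ".tsv" else "csv"
            m = read_proximity_matrix(path, format=fmt, kind=kind)
            transform = str(row.get("transform", "none") or "none")
            if m.kind == "similarity":
                if transform == "none":
                    transform = "one_minus"
                m = similarity_to_distance(m, transform=transform)
            elif transform != "none":
                raise ValueError(f"transform {transform!r} on a distance matrix")
            prec = str(row.get("precision", "auto") or "auto")
            if prec != "auto":
                m = round_to_precision(m, int(prec))
            elif m.precision_p is None:
                raise ValueError("precision 'auto' on an unrounded matrix")
            res = count_binary_dendrograms(m, max_trees=max_trees)
            records.append(
                SurveyRecord(sid, res.count >= 2, res.count, res.truncated)
            )
        except Exception as e:  # noqa: BLE001 - error isolation per entry
            failures.append((sid, f"{type(e).__name__}: {e}"))
    if not records:
        raise ValueError("no manifest entry could be analyzed")
    tied = [r for r in records if r.has_tie]
    hist = bin_counts(tied) if tied else None
    summary = summarize(
        len(tied),
        len(records),
        confidence=confidence,
        population_N=population_N,
        method=ci_method,
        histogram=hist,
    )
    return records, failures, summary
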