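"""Validity and efficiency diagnostics for conformal regressors.

Validity is the empirical fraction of prediction intervals containing the
true value; a valid predictor matches the nominal confidence.  Efficiency
is interval tightness, summarized by the median prediction interval width
(MPI).  Point-prediction quality is reported as Q^2 (squared Pearson
correlation between observed and predicted) and RMSEP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDataError, LengthMismatchError


@dataclass
class EvalReport:
    coverage: float
    mpi: float
    q2: float
    rmsep: float
    n: int
    confidence: float
    infinite_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "mpi": self.mpi,
            "q2": self.q2,
            "rmsep": self.rmsep,
            "n": self.n,
            "confidence": self.confidence,
            "infinite_fraction": self.infinite_fraction,
        }


def coverage(intervals: Sequence, truths: Sequence[float]) -> float:
    """Fraction of closed intervals [lower, upper] containing the truth.

    Infinite intervals count as covering.
    """
    if len(intervals) != len(truths):
        raise LengthMismatchError(
            f"{len(intervals)} intervals vs {len(truths)} truths"
        )
    if not intervals:
        raise LengthMismatchError("empty input")
    hits = sum(
        1 for iv, y in zip(intervals, truths) if iv.lower <= y <= iv.upper
    )
    return hits / len(intervals)


def median_interval_width(intervals: Sequence) -> float:
    """Median width over finite intervals (infinite ones are excluded;
    report their fraction separately via :func:`infinite_fraction`)."""
    widths = [iv.width for iv in intervals if math.isfinite(iv.width)]
    if not widths:
        return math.inf
    return float(np.median(widths))


def infinite_fraction(intervals: Sequence) -> float:
    """Fraction of intervals with unbounded width."""
    if not intervals:
        return 0.0
    return sum(1 for iv in intervals if not math.isfinite(iv.width)) / len(
        intervals
    )


def q2(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise DegenerateDataError("need two equal-length series of n >= 2")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise DegenerateDataError("constant series has undefined correlation")
    r = np.corrcoef(y, y_hat)[0, 1]
    return float(r * r)


def rmsep(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean squared error of prediction."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise LengthMismatchError("need equal-length non-empty series")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def evaluate_predictions(intervals: Sequence, truths: Sequence[float],
                         confidence: float) -> EvalReport:
    """Bundle coverage, MPI, Q^2 and RMSEP for one confidence level."""
    mids = [iv.midpoint for iv in intervals]
    return EvalReport(
        coverage=coverage(intervals, truths),
        mpi=median_interval_width(intervals),
        q2=q2(truths, mids),
        rmsep=rmsep(truths, mids),
        n=len(intervals),
        confidence=confidence,
        infinite_fraction=infinite_fraction(intervals),
    )


def efficiency_table(predict_fn, variants: Sequence[str],
                     confidences: Sequence[float]):
    """MPI matrix with nonconformity variants as rows and confidence
    levels as columns; a parallel coverage matrix audits validity.

    ``predict_fn(variant, confidence)`` must return a list of intervals;
    per-cell coverage additionally needs ``predict_fn`` to attach truths —
    instead we accept interval lists only and callers audit coverage via
    :func:`coverage` themselves; see :func:`efficiency_report` for the
    bundled version used by the CLI.
    """
    import pandas as pd

    if any(not (0 < c < 1) for c in confidences):
        raise ValueError("confidences must lie in (0, 1)")
    data = {}
    for variant in variants:
        row = []
        for conf in confidences:
            row.append(median_interval_width(predict_fn(variant, conf)))
        data[variant] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[f"{c:g}" for c in confidences]
    )


def efficiency_report(predict_fn, truths: Sequence[float],
                      variants: Sequence[str],
                      confidences: Sequence[float]):
    """Like :func:`efficiency_table` but returns (mpi, coverage) frames."""
    import pandas as pd

    mpi_data, cov_data = {}, {}
    for variant in variants:
        mpi_row, cov_row = [], []
        for conf in confidences:
            intervals = predict_fn(variant, conf)
            mpi_row.append(median_interval_width(intervals))
            cov_row.append(coverage(intervals, truths))
        mpi_data[variant] = mpi_row
        cov_data[variant] = cov_row
    cols = [f"{c:g}" for c in confidences]
    return (
        pd.DataFrame.from_dict(mpi_data, orient="index", columns=cols),
        pd.DataFrame.from_dict(cov_data, orient="index", columns=cols),
    )


def calibration_curve(predict_at, truths: Sequence[float],
                      grid: Iterable[float]) -> list[tuple[float, float]]:
    """Empirical coverage per nominal confidence level.

    ``predict_at(confidence)`` returns the interval list for the test set.
    """
    out = []
    for conf in grid:
        if not (0 < conf < 1):
            raise ValueError("confidence grid must lie in (0, 1)")
        out.append((conf, coverage(predict_at(conf), truths)))
    return out
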