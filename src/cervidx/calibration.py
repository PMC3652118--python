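"""Confidence-interval calibration of membership functions.

The published system set the plateaus of its morphometric membership
functions from per-condition feature statistics: the two-sided, sigma-known
normal confidence interval of each condition's mean represents 100%
membership of that condition's set.  This module reproduces that procedure
and converts a list of labeled intervals into a trapezoidal variable
definition.

The published table rounds the normal quantile to 2.58 for the 99% level,
but its printed bounds are only recovered with the exact quantile
``Phi^-1(0.995) = 2.5758...``; the exact quantile is used here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .fuzzy import ConfigurationError, FuzzySet, FuzzyVariable, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSummary",
    "IntervalEstimate",
    "confidence_interval",
    "intervals_to_membership",
    "summaries_from_csv",
    "variable_to_config",
]


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of one condition's feature sample."""

    label: str
    n: int
    mean: float
    variance: float      # population variance (sigma known)
    confidence: float = 0.99

    def validate(self) -> None:
        if self.n < 1:
            raise InputError(f"{self.label}: sample size must be >= 1, got {self.n}")
        if self.variance < 0:
            raise InputError(f"{self.label}: variance must be >= 0, got {self.variance}")
        if not 0.0 < self.confidence < 1.0:
            raise InputError(
                f"{self.label}: confidence must be in (0, 1), got {self.confidence}"
            )


@dataclass(frozen=True)
class IntervalEstimate:
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise InputError(f"interval lower bound {self.lo} exceeds upper {self.hi}")

    @property
    def width(self) -> float:
        return self.hi - self.lo


def confidence_interval(summary: SampleSummary) -> IntervalEstimate:
    """Two-sided sigma-known CI of the mean: mean -/+ z * sqrt(variance/n)."""
    summary.validate()
    z = norm.ppf(0.5 + summary.confidence / 2.0)
    half = z * (summary.variance / summary.n) ** 0.5
    return IntervalEstimate(summary.mean - half, summary.mean + half)


def intervals_to_membership(
    labeled: Sequence[tuple[str, IntervalEstimate]],
    universe: tuple[float, float],
    name: str = "calibrated",
) -> FuzzyVariable:
    """Convert ordered labeled intervals into trapezoidal sets.

    Each set's plateau is its confidence interval; shoulders extend linearly
    to the adjacent interval's near edge, and the outermost shoulders extend
    to the universe bounds.  Overlapping plateaus are truncated at the
    midpoint of their overlap, with a warning.
    """
    if not labeled:
        raise InputError("no calibration intervals supplied")
    lo_u, hi_u = float(universe[0]), float(universe[1])
    intervals = [iv for _, iv in labeled]
    for i, iv in enumerate(intervals):
        if iv.lo < lo_u or iv.hi > hi_u:
            raise ConfigurationError(
                f"interval {labeled[i][0]!r} {iv} outside universe {universe}"
            )
    centers = [0.5 * (iv.lo + iv.hi) for iv in intervals]
    if any(c2 < c1 for c1, c2 in zip(centers, centers[1:])):
        raise InputError("calibration intervals must be ordered by mean")

    plateaus = [[iv.lo, iv.hi] for iv in intervals]
    for i in range(len(plateaus) - 1):
        if plateaus[i][1] > plateaus[i + 1][0]:
            mid = 0.5 * (plateaus[i][1] + plateaus[i + 1][0])
            logger.warning(
                "calibration: plateaus of %r and %r overlap; truncated at %g",
                labeled[i][0], labeled[i + 1][0], mid,
            )
            plateaus[i][1] = mid
            plateaus[i + 1][0] = mid

    sets = []
    for i, (label, _) in enumerate(labeled):
        b, c = plateaus[i]
        a = lo_u if i == 0 else plateaus[i - 1][1]
        d = hi_u if i == len(labeled) - 1 else plateaus[i + 1][0]
        a, d = min(a, b), max(d, c)
        sets.append(FuzzySet(label, "trapezoid", (a, b, c, d)))
    return FuzzyVariable(name=name, universe=(lo_u, hi_u), sets=tuple(sets))


def summaries_from_csv(path) -> list[SampleSummary]:
    """Read calibration input rows (label, n, mean, variance[, confidence])."""
    df = pd.read_csv(path)
    required = {"label", "n", "mean", "variance"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"calibration CSV lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleSummary(
                label=str(row["label"]),
                n=int(row["n"]),
                mean=float(row["mean"]),
                variance=float(row["variance"]),
                confidence=float(row.get("confidence", 0.99)),
            )
        )
    return out


def variable_to_config(variable: FuzzyVariable) -> dict:
    """Emit a variable-config fragment usable inside a model definition."""
    return {
        "name": variable.name,
        "universe": list(variable.universe),
        "sets": [
            {"label": s.label, "shape": s.shape, "params": list(s.params)}
            for s in variable.sets
        ],
    }
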