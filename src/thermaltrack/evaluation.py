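"""Survey evaluation: probability of detection, precision rate, RMSE, MAE,
and false-positive composition.

The atoms of every formula are per-survey counts: K_obs collared animals
known present on site, K_detected of them found by the method (true
positives, matched one-to-one, so K_detected <= K_obs), and K_false
signatures falsely identified or unidentifiable.  Then

    P_d = K_detected / K_obs                 (probability of detection)
    PR  = K_detected / (K_obs + K_false)     (precision rate)

and across a series of surveys i = 1..n,

    RMSE = sqrt( sum_i (K_obs,i - K_detected,i)^2 / n )
    MAE  = (1/n) sum_i |K_obs,i - K_detected,i| .

Report percentages round half away from zero to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SurveyCounts",
    "FalsePositiveBreakdown",
    "MethodSeries",
    "round_half_up",
    "probability_of_detection",
    "precision_rate",
    "rmse",
    "mae",
    "pooled_probability_of_detection",
    "fp_composition",
    "survey_report",
]

FP_CLASSES = ("kangaroo", "car", "human", "other")


def round_half_up(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SurveyCounts:
    """Per-survey detection counts for one method."""

    survey_id: str
    k_obs: int
    k_detected: int
    k_false: int | None = None

    def __post_init__(self) -> None:
        if self.k_obs < 0 or self.k_detected < 0:
            raise ValueError("counts must be non-negative")
        if self.k_false is not None and self.k_false < 0:
            raise ValueError("counts must be non-negative")
        if self.k_detected > self.k_obs:
            raise ValueError(
                f"{self.survey_id}: K_detected ({self.k_detected}) exceeds "
                f"K_obs ({self.k_obs}); matching is one-to-one against collared animals"
            )


@dataclass(frozen=True)
class FalsePositiveBreakdown:
    """Counts of objects falsely identified as the target species."""

    kangaroo: int = 0
    car: int = 0
    human: int = 0
    other: int = 0

    def __post_init__(self) -> None:
        if min(self.kangaroo, self.car, self.human, self.other) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.kangaroo + self.car + self.human + self.other


@dataclass(frozen=True)
class MethodSeries:
    """Ordered per-survey (K_obs, K_detected) pairs for one method."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("series needs at least one survey")

    @classmethod
    def from_counts(cls, counts: Sequence[SurveyCounts]) -> "MethodSeries":
        return cls(tuple((c.k_obs, c.k_detected) for c in counts))

    @property
    def n(self) -> int:
        return len(self.pairs)


def probability_of_detection(c: SurveyCounts) -> float:
    """P_d as a percentage: 100 * K_detected / K_obs."""
    if c.k_obs == 0:
        raise ValueError(f"{c.survey_id}: P_d undefined with K_obs = 0")
    return 100.0 * c.k_detected / c.k_obs


def precision_rate(k_detected: int, k_obs: int, k_false: int) -> float:
    """PR as a percentage: 100 * K_detected / (K_obs + K_false)."""
    if k_obs + k_false <= 0:
        raise ValueError("PR undefined with K_obs + K_false = 0")
    return 100.0 * k_detected / (k_obs + k_false)


def rmse(series: MethodSeries) -> float:
    """Root mean square of per-survey count errors K_obs,i - K_detected,i."""
    sq = [(ko - kd) ** 2 for ko, kd in series.pairs]
    return math.sqrt(sum(sq) / series.n)


def mae(series: MethodSeries) -> float:
    """Mean absolute per-survey count error."""
    return sum(abs(ko - kd) for ko, kd in series.pairs) / series.n


def pooled_probability_of_detection(counts: Sequence[SurveyCounts]) -> float:
    """Pooled P_d: 100 * sum(K_detected) / sum(K_obs) over surveys."""
    if not counts:
        raise ValueError("no surveys")
    total_obs = sum(c.k_obs for c in counts)
    if total_obs == 0:
        raise ValueError("pooled P_d undefined with total K_obs = 0")
    return 100.0 * sum(c.k_detected for c in counts) / total_obs


def fp_composition(b: FalsePositiveBreakdown) -> dict[str, int]:
    """Percentage of misidentified objects per class, rounded to integers.

    The denominator is the sum of the class counts.
    """
    if b.total == 0:
        raise ValueError("no false positives to compose")
    return {
        cls: round_half_up(100.0 * getattr(b, cls) / b.total) for cls in FP_CLASSES
    }


def survey_report(
    counts_by_method: Mapping[str, Sequence[SurveyCounts]],
) -> pd.DataFrame:
    """Per-survey and pooled detection/precision table across methods.

    One row per (survey, method) plus a pooled row per method; percentage
    columns are integer-rounded, precision rate blank where K_false is
    unknown.
    """
    rows = []
    for method, counts in counts_by_method.items():
        for c in counts:
            pr = (
                round_half_up(precision_rate(c.k_detected, c.k_obs, c.k_false))
                if c.k_false is not None
                else None
            )
            rows.append(
                {
                    "survey_id": c.survey_id,
                    "method": method,
                    "k_obs": c.k_obs,
                    "k_detected": c.k_detected,
                    "k_false": c.k_false,
                    "pd_pct": round_half_up(probability_of_detection(c)),
                    "pr_pct": pr,
                }
            )
        if counts:
            total_obs = sum(c.k_obs for c in counts)
            total_det = sum(c.k_detected for c in counts)
            falses = [c.k_false for c in counts]
            total_false = sum(f for f in falses if f is not None) if any(
                f is not None for f in falses
            ) else None
            pooled_pr = (
                round_half_up(precision_rate(total_det, total_obs, total_false))
                if total_false is not None and all(f is not None for f in falses)
                else None
            )
            rows.append(
                {
                    "survey_id": "pooled",
                    "method": method,
                    "k_obs": total_obs,
                    "k_detected": total_det,
                    "k_false": total_false,
                    "pd_pct": round_half_up(
                        pooled_probability_of_detection(list(counts))
                    ),
                    "pr_pct": pooled_pr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["survey_id", "method", "k_obs", "k_detected", "k_false", "pd_pct", "pr_pct"],
    )
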