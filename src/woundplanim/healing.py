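"""Healing-trajectory statistics and method-comparison reports.

The weekly contraction statistic is

    CO_i = 100 * (S0 - S_i) / S0

where S0 is the baseline wound area and S_i the area at week i; positive
values mean shrinkage, negative values growth (e.g. transient enlargement
after debridement).  Early contraction predicts healing, and four threshold
rules from the chronic-wound literature are implemented verbatim:

* ``weekly_10_15`` — a mean weekly reduction of 10-15% predicts healing
  (>= 10% passes);
* ``two_week_25`` — >= 25% reduction within two weeks;
* ``two_to_four_week_20_40`` — 20-40% reduction within two to four weeks;
* ``four_week_40`` — clinical reassessment is indicated unless the area
  fell by at least 40% within four weeks.

Threshold boundaries are inclusive: reaching the lower bound of a quoted
range counts as predicted-to-heal (the conservative-to-heal reading of
ranges stated without open/closed qualification).

Method comparison mirrors the standard planimetric-agreement analysis:
signed percent differences of each estimator against a chosen reference,
per-method signed mean errors, and pairwise Pearson correlations of the
area vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IncompleteDataError,
    InsufficientSeriesError,
    InvalidBaselineError,
    InvalidParameterError,
    InvalidReferenceError,
    UndefinedCorrelationError,
)

__all__ = [
    "HealingSeries",
    "ComparisonReport",
    "contraction_percentage",
    "build_series",
    "classify_healing",
    "percent_difference",
    "mean_error",
    "pearson_r",
    "compare_methods",
]

RULES = ("weekly_10_15", "two_week_25", "two_to_four_week_20_40", "four_week_40")


def contraction_percentage(S0: float, Si: float) -> float:
    """Percentage contraction 100 * (S0 - Si) / S0 of the wound area."""
    if S0 <= 0:
        raise InvalidBaselineError(f"baseline area S0 must be > 0; got {S0}")
    if Si < 0:
        raise InvalidParameterError(f"area Si must be >= 0; got {Si}")
    return 100.0 * (S0 - Si) / S0


@dataclass(frozen=True)
class HealingSeries:
    """Time-ordered wound areas with per-week contraction and normalization.

    ``coi[i]`` is the contraction percentage of week ``week_index[i]``
    relative to baseline; ``normalized`` is areas / S0, so the algebraic
    identity ``normalized[i] == 1 - coi[i]/100`` holds exactly.
    """

    week_index: tuple[int, ...]
    areas: tuple[float, ...]
    coi: tuple[float, ...]
    normalized: tuple[float, ...]

    def coi_at_week(self, week: int) -> float:
        try:
            return self.coi[self.week_index.index(week)]
        except ValueError:
            raise InsufficientSeriesError(
                f"series has no reading for week {week}"
            ) from None

    @property
    def last_week(self) -> int:
        return self.week_index[-1]


def build_series(
    areas: Sequence[float], weeks: Sequence[int] | None = None
) -> HealingSeries:
    """Assemble a :class:`HealingSeries` from time-ordered areas (cm^2).

    ``weeks`` defaults to 0, 1, 2, ...; it must be strictly increasing and
    start at 0 (the baseline reading).
    """
    areas = tuple(float(a) for a in areas)
    if len(areas) < 2:
        raise InsufficientSeriesError("a healing series needs at least 2 readings")
    if weeks is None:
        weeks = tuple(range(len(areas)))
    else:
        weeks = tuple(int(w) for w in weeks)
        if len(weeks) != len(areas):
            raise InvalidParameterError("weeks and areas must have equal length")
        if weeks[0] != 0 or any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise InvalidParameterError("weeks must start at 0 and strictly increase")
    S0 = areas[0]
    if S0 <= 0:
        raise InvalidBaselineError("baseline area must be > 0")
    if any(a < 0 for a in areas):
        raise InvalidParameterError("areas must be >= 0")
    coi = tuple(contraction_percentage(S0, a) for a in areas)
    normalized = tuple(a / S0 for a in areas)
    return HealingSeries(week_index=weeks, areas=areas, coi=coi, normalized=normalized)


def _mean_weekly_contraction(series: HealingSeries) -> float:
    """Mean of the week-over-week percentage contractions.

    Each step uses the preceding reading as its own baseline:
    100 * (S_{i-1} - S_i) / S_{i-1}, averaged over consecutive readings.
    """
    vals = []
    for (w0, a0), (w1, a1) in zip(
        zip(series.week_index, series.areas), zip(series.week_index[1:], series.areas[1:])
    ):
        if a0 <= 0:
            vals.append(0.0 if a1 == 0 else -np.inf)
        else:
            vals.append(100.0 * (a0 - a1) / a0 / (w1 - w0))
    return float(np.mean(vals))


def classify_healing(series: HealingSeries, rule: str) -> tuple[str, str]:
    """Classify a healing trajectory against one of the four threshold rules.

    Returns ``(verdict, rationale)`` with verdict in ``predicted_to_heal``,
    ``reassess`` or ``indeterminate``.  ``indeterminate`` arises only for the
    two-to-four-week rule when the threshold has not been met but the series
    ends before week 4, so the window is still open.

    Raises
    ------
    InsufficientSeriesError
        If the series does not reach the rule's horizon (naming it).
    """
    if rule == "weekly_10_15":
        rate = _mean_weekly_contraction(series)
        if rate >= 10.0:
            return (
                "predicted_to_heal",
                f"mean weekly contraction {rate:.1f}% >= 10% predicts healing",
            )
        return ("reassess", f"mean weekly contraction {rate:.1f}% < 10%")

    if rule == "two_week_25":
        if series.last_week < 2:
            raise InsufficientSeriesError(
                "rule two_week_25 needs a week-2 reading"
            )
        c2 = series.coi_at_week(2)
        if c2 >= 25.0:
            return (
                "predicted_to_heal",
                f"contraction {c2:.1f}% at week 2 >= 25% predicts healing",
            )
        return ("reassess", f"contraction {c2:.1f}% at week 2 < 25%")

    if rule == "two_to_four_week_20_40":
        if series.last_week < 2:
            raise InsufficientSeriesError(
                "rule two_to_four_week_20_40 needs at least a week-2 reading"
            )
        window = [w for w in series.week_index if 2 <= w <= 4]
        best = max(series.coi_at_week(w) for w in window)
        if best >= 20.0:
            return (
                "predicted_to_heal",
                f"contraction reached {best:.1f}% within weeks 2-4 (>= 20%)",
            )
        if series.last_week >= 4:
            return (
                "reassess",
                f"contraction peaked at {best:.1f}% (< 20%) through week 4",
            )
        return (
            "indeterminate",
            f"only {best:.1f}% so far and the 2-4 week window is still open",
        )

    if rule == "four_week_40":
        if series.last_week < 4:
            raise InsufficientSeriesError("rule four_week_40 needs a week-4 reading")
        c4 = series.coi_at_week(4)
        if c4 >= 40.0:
            return (
                "predicted_to_heal",
                f"contraction {c4:.1f}% at week 4 >= 40% predicts healing",
            )
        return (
            "reassess",
            f"contraction {c4:.1f}% at week 4 is not more than 40%: "
            "clinical reassessment indicated",
        )

    raise InvalidParameterError(f"unknown rule {rule!r}; choose one of {RULES}")


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference 100 * (value - reference) / reference."""
    if reference <= 0:
        raise InvalidReferenceError(f"reference must be > 0; got {reference}")
    return 100.0 * (value - reference) / reference


def mean_error(errors: Sequence[float]) -> float:
    """Arithmetic mean of signed percentage errors."""
    errors = list(errors)
    if not errors:
        raise InvalidParameterError("mean_error needs a non-empty list")
    return float(np.mean(errors))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two area vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("pearson_r needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ComparisonReport:
    """Agreement of several measurement methods against a reference method.

    ``per_wound_errors`` is a wound x method table of signed percent
    differences relative to the reference; ``mean_errors`` are its signed
    column means; ``correlations`` holds pairwise Pearson r between the
    methods' area vectors (None when fewer than 3 complete wounds exist).
    """

    reference_label: str
    per_wound_areas: pd.DataFrame
    per_wound_errors: pd.DataFrame
    mean_errors: pd.Series
    correlations: pd.DataFrame | None = None
    mean_abs_errors: pd.Series = field(default=None)

    def to_csv(self, path) -> None:
        """Write the long-format per-wound table (wound, method, area, error)."""
        long = (
            self.per_wound_areas.stack()
            .rename("area_cm2")
            .to_frame()
            .join(self.per_wound_errors.stack().rename("pct_diff_vs_reference"))
            .reset_index()
        )
        long.columns = ["wound_id", "method", "area_cm2", "pct_diff_vs_reference"]
        long.to_csv(path, index=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_error_pct": self.mean_errors,
                "mean_abs_error_pct": self.mean_abs_errors,
                "n": self.per_wound_errors.notna().sum(),
            }
        )


def compare_methods(
    measurements: Mapping[str, Mapping[str, float]], reference_label: str
) -> ComparisonReport:
    """Build a :class:`ComparisonReport` from per-wound method->area maps.

    ``measurements`` maps wound id -> {method label -> area cm^2}.  Every
    wound must carry the reference method's area; other methods may be
    missing for individual wounds (their entries stay NaN and are excluded
    from that method's mean).
    """
    for wound, methods in measurements.items():
        if reference_label not in methods:
            raise IncompleteDataError(
                f"wound {wound!r} is missing the reference method "
                f"{reference_label!r}"
            )
    areas = pd.DataFrame.from_dict(measurements, orient="index").astype(float)
    ref = areas[reference_label]
    if (ref <= 0).any():
        bad = ref.index[ref <= 0].tolist()
        raise InvalidReferenceError(f"non-positive reference areas for wounds {bad}")
    errors = areas.sub(ref, axis=0).div(ref, axis=0) * 100.0

    complete = areas.dropna()
    correlations = None
    if complete.shape[0] >= 3:
        varying = complete.loc[:, complete.nunique() > 1]
        if varying.shape[1] >= 2:
            correlations = varying.corr(method="pearson")

    return ComparisonReport(
        reference_label=reference_label,
        per_wound_areas=areas,
        per_wound_errors=errors,
        mean_errors=errors.mean(),
        correlations=correlations,
        mean_abs_errors=errors.abs().mean(),
    )
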