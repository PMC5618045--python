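"""Reagent shelf-life analysis from replicate S-index measurements.

A reagent set is considered *stable* at a storage time point as long as the
difference in mean S-index between stains made from 0% HbS blood and stains
made from blood at or above the assay's limit of detection remains
statistically significant (two-sided p < 0.05).  The *limit of stability*
(LOS) is the last stable storage day strictly before the earliest failing
time point.

The significance test is Welch's two-sample t-test (unequal variances); a
permutation test serves as an independent cross-check in the test suite.
No multiple-testing correction is applied across time points: stability is
a per-time-point criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

DEFAULT_ALPHA = 0.05


@dataclass
class StabilitySeries:
    """Replicate S-index measurements over storage time.

    ``records`` is tidy with columns ``day, group, replicate, s_index``;
    group is ``"zero"`` (0% HbS) or ``"lod"`` (at-LOD HbS level).
    """

    records: pd.DataFrame
    formulation: str = "MS"
    storage: str = "dry"

    def __post_init__(self) -> None:
        required = {"day", "group", "s_index"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"series missing columns: {sorted(missing)}")
        bad_groups = set(self.records["group"]) - {"zero", "lod"}
        if bad_groups:
            raise ValidationError(f"unknown groups: {sorted(bad_groups)}")
        days = self.records["day"].unique()
        if np.any(days < 0):
            raise ValidationError("storage days must be non-negative")
        if not np.all(np.diff(days) > 0):
            raise ValidationError("time points must be sorted and unique")
        sizes = self.records.groupby(["day", "group"]).size()
        if (sizes < 2).any():
            raise ValidationError("need at least 2 replicates per group per time point")
        if set(sizes.index.get_level_values("group")) != {"zero", "lod"}:
            raise ValidationError("both groups required at every time point")

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.records["day"].unique())


@dataclass(frozen=True)
class StabilityResult:
    """Per-time-point p-values, stability flags, and the limit of stability."""

    p_values: dict[float, float]
    stable_flags: dict[float, bool]
    limit_of_stability_days: float
    censored: bool  # True when every time point was stable: LOS is a lower bound
    alpha: float = DEFAULT_ALPHA

    @property
    def reported(self) -> str:
        qualifier = ">= " if self.censored else ""
        return f"{qualifier}{self.limit_of_stability_days:g} days"


def stability_test(
    zero_group: Sequence[float], lod_group: Sequence[float]
) -> float:
    """Two-sided p-value for a difference in mean S-index (Welch's t-test).

    If both groups have zero variance, p is 1 when the means are equal
    (no evidence of difference, by convention) and 0 otherwise.
    """
    a = np.asarray(zero_group, dtype=np.float64)
    b = np.asarray(lod_group, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 replicates")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("groups must be finite")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def limit_of_stability(
    series: StabilitySeries, alpha: float = DEFAULT_ALPHA
) -> StabilityResult:
    """Locate the limit of stability of a reagent storage series.

    LOS is the last time point with p < alpha strictly before the earliest
    time point with p >= alpha.  If the first time point already fails, LOS
    is 0; if every time point is significant, LOS equals the last observed
    day and the result is flagged as censored (a lower bound).
    """
    p_values: dict[float, float] = {}
    for day in series.days:
        sub = series.records[series.records["day"] == day]
        p_values[float(day)] = stability_test(
            sub.loc[sub["group"] == "zero", "s_index"],
            sub.loc[sub["group"] == "lod", "s_index"],
        )
    flags = {day: p < alpha for day, p in p_values.items()}

    failing = [day for day, ok in flags.items() if not ok]
    if not failing:
        los = float(series.days[-1])
        censored = True
    else:
        first_fail = min(failing)
        stable_before = [day for day, ok in flags.items() if ok and day < first_fail]
        los = max(stable_before) if stable_before else 0.0
        censored = False
    return StabilityResult(
        p_values=p_values,
        stable_flags=flags,
        limit_of_stability_days=los,
        censored=censored,
        alpha=alpha,
    )


@dataclass(frozen=True)
class ShelfLifeRatio:
    """Ratio of two limits of stability, with its reporting convention."""

    ratio: float
    rounded: int
    reported: str


def shelf_life_ratio(
    los_a_days: float, los_b_days: float, a_is_lower_bound: bool = False
) -> ShelfLifeRatio:
    """Shelf-life ratio LOS_a / LOS_b.

    Reported rounded to the nearest integer; a ``~`` qualifier marks the
    value as approximate when the numerator is only a lower bound or the
    ratio is not an exact integer (e.g. 24/5 = 4.8 -> "~5").
    """
    if los_b_days <= 0:
        raise DegenerateInputError("denominator limit of stability must be > 0")
    if los_a_days <= 0:
        raise DegenerateInputError("numerator limit of stability must be > 0")
    ratio = los_a_days / los_b_days
    rounded = int(round(ratio))
    approx = a_is_lower_bound or abs(ratio - rounded) > 1e-12
    return ShelfLifeRatio(
        ratio=ratio,
        rounded=rounded,
        reported=f"~{rounded}" if approx else f"{rounded}",
    )
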