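"""Subgroup decomposition: stratified rates, gap statistics, multiple-response tables.

Classification rates are decomposable over any partition of the population:
the overall deprived headcount is the group-size-weighted mean of group
headcounts.  Gap statistics follow the survey's reporting convention for
male/female comparisons: the point differential a - b plus the percent
difference 100*(a - b)/a with the first-listed (female) group's rate as the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import DEFAULT_HOPEFULNESS_CUTOFF, recode_hopefulness
from .index import WellbeingProfiles

__all__ = [
    "stratified_rates",
    "gap",
    "GapStatistic",
    "multiple_response_table",
    "hopefulness_shift",
    "HopefulnessShift",
]


def stratified_rates(
    profiles: WellbeingProfiles,
    stratifier: str,
    covariates: pd.DataFrame | None = None,
    missing_label: str | None = None,
) -> pd.DataFrame:
    """Per-group maintained/deprived percentages, overall and per domain.

    ``stratifier`` names a covariate column (taken from ``covariates`` or
    from the profiles' own covariate table).  Respondents with a missing
    stratifier are excluded from the denominators unless ``missing_label``
    is given, in which case they are reported as their own group under that
    label.  Returns a tidy DataFrame with one row per group x measure,
    where measure is ``overall`` or a domain name, and columns ``n``,
    ``maintained_pct``, ``deprived_pct``.
    """
    cov = covariates if covariates is not None else profiles.covariates
    if cov is None or stratifier not in cov.columns:
        raise KeyError(f"unknown stratifier {stratifier!r}")
    groups = cov[stratifier].astype("object").copy()
    if missing_label is not None:
        groups = groups.where(groups.notna(), missing_label)
    keep = groups.notna()
    if not keep.any():
        raise ValueError(f"stratifier {stratifier!r} has no non-missing groups")

    maintained = profiles.maintained
    z = profiles.domain_sufficiency
    rows = []
    for gname, idx in groups[keep].groupby(groups[keep]).groups.items():
        n = len(idx)
        m_pct = float(maintained.loc[idx].mean()) * 100.0
        rows.append(
            {
                "group": gname,
                "measure": "overall",
                "n": n,
                "maintained_pct": m_pct,
                "deprived_pct": 100.0 - m_pct,
            }
        )
        for dom in z.columns:
            dm = float(z.loc[idx, dom].mean()) * 100.0
            rows.append(
                {
                    "group": gname,
                    "measure": dom,
                    "n": n,
                    "maintained_pct": dm,
                    "deprived_pct": 100.0 - dm,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GapStatistic:
    """Point differential and percent difference between two group rates.

    ``percent_difference`` uses ``group_a`` (first-listed, female in the
    study's tables) as the denominator and is None when that rate is zero.
    A positive differential indicates greater vulnerability of group a when
    the rates measure deprivation.
    """

    group_a_rate: float
    group_b_rate: float
    point_differential: float
    percent_difference: float | None


def gap(rate_a: float, rate_b: float) -> GapStatistic:
    """Gap between two percentage rates: points a - b, percent 100*(a-b)/a."""
    for r in (rate_a, rate_b):
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"rate {r} outside [0, 100]")
    points = rate_a - rate_b
    pct = None if rate_a == 0 else 100.0 * points / rate_a
    return GapStatistic(
        group_a_rate=rate_a,
        group_b_rate=rate_b,
        point_differential=points,
        percent_difference=pct,
    )


def multiple_response_table(
    conditions: pd.DataFrame, group_mask=None
) -> pd.Series:
    """Share (%) of a group answering yes to each binary condition column.

    Multiple-response semantics: each respondent can satisfy several
    conditions, so no normalisation across conditions is applied and the
    values can total more than 100.
    """
    conditions = pd.DataFrame(conditions)
    if group_mask is None:
        group_mask = pd.Series(True, index=conditions.index)
    group_mask = pd.Series(group_mask, index=conditions.index).astype(bool)
    if not group_mask.any():
        raise ValueError("the group is empty")
    sub = conditions.loc[group_mask]
    vals = sub.to_numpy(dtype=float)
    if not np.isin(vals[~np.isnan(vals)], (0.0, 1.0)).all():
        raise TypeError("condition columns must be binary")
    return sub.mean() * 100.0


@dataclass(frozen=True)
class HopefulnessShift:
    """Shares (%) of respondents above the hopefulness cutoff in two waves."""

    share_pre_pct: float
    share_during_pct: float
    change_points: float  # pre minus during, in percentage points


def hopefulness_shift(
    pre, during, cutoff: int = DEFAULT_HOPEFULNESS_CUTOFF
) -> HopefulnessShift:
    """Percentage-point fall in the "highly positive" share between paired waves.

    Both waves are dichotomised at the same cutoff on the 1-8 scale; the
    change is share_pre - share_during in points (positive = a fall during
    the pandemic period).
    """
    pre = np.atleast_1d(np.asarray(pre))
    during = np.atleast_1d(np.asarray(during))
    if pre.shape != during.shape:
        raise ValueError(
            f"waves must be paired per respondent: {pre.shape} vs {during.shape}"
        )
    pre_bin = recode_hopefulness(pre, cutoff=cutoff)
    dur_bin = recode_hopefulness(during, cutoff=cutoff)
    share_pre = float(np.nanmean(pre_bin)) * 100.0
    share_during = float(np.nanmean(dur_bin)) * 100.0
    return HopefulnessShift(
        share_pre_pct=share_pre,
        share_during_pct=share_during,
        change_points=share_pre - share_during,
    )
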