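"""Dual-cutoff counting core: domain sufficiency, composite index, AF aggregates.

The measurement follows the Alkire-Foster counting methodology with a
"two-thirds" convention at both cutoffs.  Within a domain holding ``m``
binary achievement indicators, a respondent is sufficient iff their raw
score reaches ``ceil(2m/3)`` (for the Ecology domain's 9 variables that is
6 of 9).  Summing the D domain sufficiency indicators gives the composite
Wellbeing Index W in 0..D; a respondent has "maintained overall wellbeing"
iff W reaches the cross-domain cutoff k = ceil(2D/3) (4 of 6 in the default
configuration).  Population aggregates are the deprivation headcount H, the
intensity A (mean deprivation count among the deprived, reported both in
domain units and as a share of D), and the adjusted headcount M0 = H x A.

The general API carries per-domain weights (normalised to sum to D) and an
arbitrary cross-domain cutoff; equal weights with k = ceil(2D/3) reproduce
the unweighted counting rule exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import IndicatorMatrix

__all__ = [
    "domain_threshold",
    "score_domain",
    "classify_overall",
    "build_profiles",
    "summarize",
    "driver_table",
    "WellbeingProfiles",
    "IndexSummary",
]


def domain_threshold(m: int) -> int:
    """Two-thirds sufficiency threshold: smallest integer t with t >= 2m/3.

    ``domain_threshold(9) == 6`` and ``domain_threshold(6) == 4`` — the same
    rule fixes both the within-domain cutoffs and the cross-domain counting
    cutoff.
    """
    if not float(m).is_integer() or m < 1:
        raise ValueError(f"variable count must be a positive integer, got {m!r}")
    return math.ceil(2 * int(m) / 3)


def _as_binary(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if not np.isin(arr[~np.isnan(arr)], (0.0, 1.0)).all():
        raise TypeError(f"{name} must contain only 0/1 entries")
    return arr


def score_domain(indicators) -> tuple:
    """Raw domain score and sufficiency for one domain's indicator block.

    For a length-m binary vector returns ``(raw, sufficiency)`` with
    ``raw = sum(indicators)`` and ``sufficiency = 1`` iff
    ``raw >= domain_threshold(m)``.  A 2-D (n x m) array returns the two
    length-n integer arrays.
    """
    arr = _as_binary(indicators, "indicators")
    if np.isnan(arr).any():
        raise TypeError("indicators contain missing values; recode with as_zero first")
    one_dim = arr.ndim == 1
    arr = np.atleast_2d(arr)
    m = arr.shape[1]
    t = domain_threshold(m)
    raw = arr.sum(axis=1).astype(int)
    suff = (raw >= t).astype(int)
    if one_dim:
        return int(raw[0]), int(suff[0])
    return raw, suff


def _normalise_weights(weights, domains: Sequence[str]) -> np.ndarray:
    d = len(domains)
    if weights is None:
        return np.ones(d)
    if isinstance(weights, Mapping):
        w = np.array([float(weights[name]) for name in domains])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (d,):
            raise ValueError(f"expected {d} weights, got shape {w.shape}")
    if (w <= 0).any():
        raise ValueError("domain weights must be positive")
    return w * d / w.sum()  # normalise to sum to D so k keeps domain units


def classify_overall(domain_sufficiency, k: int | None = None, weights=None):
    """Composite index W, maintained flag and deprivation count c.

    ``W = sum_d w_d z_d`` (weights normalised to sum to D; all-equal by
    default so W is a plain count), ``maintained = 1`` iff ``W >= k`` with
    ``k = ceil(2D/3)`` when not given, and ``c = D - W``.

    A length-D vector returns a dict with keys ``W``, ``maintained``, ``c``;
    an (n x D) array or DataFrame returns a DataFrame with those columns.
    """
    if isinstance(domain_sufficiency, pd.DataFrame):
        index = domain_sufficiency.index
        arr = _as_binary(domain_sufficiency.to_numpy(), "domain sufficiency")
        ncol = len(domain_sufficiency.columns)
        names = list(domain_sufficiency.columns)
    else:
        arr = _as_binary(domain_sufficiency, "domain sufficiency")
        index = None
        names = None
        ncol = np.atleast_2d(arr).shape[1]
    if np.isnan(arr).any():
        raise TypeError("domain sufficiency contains missing values")
    one_dim = arr.ndim == 1
    arr = np.atleast_2d(arr)
    d = arr.shape[1]
    if k is None:
        k = domain_threshold(d)
    if not 1 <= k <= d:
        raise ValueError(f"cross-domain cutoff k={k} out of range 1..{d}")
    w = _normalise_weights(weights, names if names is not None else range(d))
    W = arr @ w
    if weights is None:
        W = W.astype(int)
    maintained = (W >= k).astype(int)
    c = d - W
    if one_dim:
        return {"W": W[0].item(), "maintained": int(maintained[0]), "c": c[0].item()}
    out = pd.DataFrame({"W": W, "maintained": maintained, "c": c})
    if index is not None:
        out.index = index
    return out


@dataclass
class WellbeingProfiles:
    """Per-respondent domain scores, sufficiency, composite index and class.

    ``domain_scores`` and ``domain_sufficiency`` are respondents x domains
    DataFrames; ``summary`` holds the W / maintained / c columns from
    :func:`classify_overall`.
    """

    domain_scores: pd.DataFrame
    domain_sufficiency: pd.DataFrame
    summary: pd.DataFrame
    k: int
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n(self) -> int:
        return len(self.summary)

    @property
    def domains(self) -> list[str]:
        return list(self.domain_sufficiency.columns)

    @property
    def maintained(self) -> pd.Series:
        return self.summary["maintained"]

    @property
    def deprived_mask(self) -> pd.Series:
        return self.summary["maintained"] == 0

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-respondent table for CSV serialization."""
        scores = self.domain_scores.add_prefix("score:")
        suff = self.domain_sufficiency.add_prefix("sufficient:")
        parts = [scores, suff, self.summary]
        if not self.covariates.empty:
            parts.append(self.covariates)
        return pd.concat(parts, axis=1)


def build_profiles(
    matrix: IndicatorMatrix, k: int | None = None, weights=None
) -> WellbeingProfiles:
    """Score every domain of an indicator matrix and classify each respondent.

    Missing indicators must have been resolved by the recode stage
    (``as_zero`` policy); remaining NaNs raise.
    """
    scores: dict[str, np.ndarray] = {}
    suff: dict[str, np.ndarray] = {}
    for name, cols in matrix.domains.items():
        raw, z = score_domain(matrix.data[cols].to_numpy())
        scores[name] = raw
        suff[name] = z
    domain_scores = pd.DataFrame(scores, index=matrix.data.index)
    domain_sufficiency = pd.DataFrame(suff, index=matrix.data.index)
    if weights is None and matrix.weights:
        w = np.array([matrix.weights[n] for n in domain_sufficiency.columns])
        weights = None if np.allclose(w, w[0]) else w
    summary = classify_overall(domain_sufficiency, k=k, weights=weights)
    if k is None:
        k = domain_threshold(len(matrix.domains))
    return WellbeingProfiles(
        domain_scores=domain_scores,
        domain_sufficiency=domain_sufficiency,
        summary=summary,
        k=k,
        covariates=matrix.covariates,
    )


@dataclass
class IndexSummary:
    """Population-level AF aggregates.

    ``intensity_domains`` (A_raw) is the mean deprivation count among the
    deprived, in domain units (the quantity printed as 3.6 in the study
    configuration); ``intensity_share`` is A = A_raw / D and
    ``adjusted_headcount`` is M0 = H x A on the share scale.  Censored
    per-domain deprivation is the share deprived in the domain *among the
    overall-deprived*; the uncensored version divides by everyone.
    """

    n_total: int
    n_maintained: int
    n_deprived: int
    headcount_deprived: float
    intensity_domains: float | None
    intensity_share: float | None
    adjusted_headcount: float | None
    censored_domain_deprivation: dict[str, float]
    uncensored_domain_deprivation: dict[str, float]
    k: int
    n_domains: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_total": self.n_total,
            "n_maintained": self.n_maintained,
            "n_deprived": self.n_deprived,
            "headcount_deprived": self.headcount_deprived,
            "intensity_domains": self.intensity_domains,
            "intensity_share": self.intensity_share,
            "adjusted_headcount": self.adjusted_headcount,
            "censored_domain_deprivation": dict(self.censored_domain_deprivation),
            "uncensored_domain_deprivation": dict(self.uncensored_domain_deprivation),
            "k": self.k,
            "n_domains": self.n_domains,
        }


def _sufficiency_frame(profiles) -> tuple[pd.DataFrame, int]:
    """Accept WellbeingProfiles or a plain 0/1 domain-sufficiency DataFrame."""
    if isinstance(profiles, WellbeingProfiles):
        return profiles.domain_sufficiency, profiles.k
    z = pd.DataFrame(profiles)
    _as_binary(z.to_numpy(), "domain sufficiency")
    return z, domain_threshold(len(z.columns))


def summarize(profiles, k: int | None = None, weights=None) -> IndexSummary:
    """Headcount, intensity and adjusted headcount for a profile population.

    ``profiles`` is a :class:`WellbeingProfiles` or a respondents x domains
    0/1 sufficiency table.  With nobody deprived the intensity (and M0) are
    undefined and reported as None.
    """
    z, default_k = _sufficiency_frame(profiles)
    if len(z) == 0:
        raise ValueError("cannot summarise an empty population")
    if k is None:
        k = default_k
    cls = classify_overall(z, k=k, weights=weights)
    d = len(z.columns)
    n_total = len(z)
    n_maintained = int(cls["maintained"].sum())
    n_deprived = n_total - n_maintained
    h = n_deprived / n_total
    deprived = cls["maintained"] == 0
    if n_deprived:
        a_raw = float(cls.loc[deprived, "c"].mean())
        a = a_raw / d
        m0 = h * a
        censored = {
            name: float((z.loc[deprived, name] == 0).mean()) for name in z.columns
        }
    else:
        a_raw = a = m0 = None
        censored = {name: 0.0 for name in z.columns}
    uncensored = {name: float((z[name] == 0).mean()) for name in z.columns}
    return IndexSummary(
        n_total=n_total,
        n_maintained=n_maintained,
        n_deprived=n_deprived,
        headcount_deprived=h,
        intensity_domains=a_raw,
        intensity_share=a,
        adjusted_headcount=m0,
        censored_domain_deprivation=censored,
        uncensored_domain_deprivation=uncensored,
        k=k,
        n_domains=d,
    )


def driver_table(profiles, group: str = "deprived", k: int | None = None) -> pd.DataFrame:
    """Per-domain deprivation shares within the deprived or maintained group.

    Returns a DataFrame indexed by domain with a ``share_pct`` column, in
    descending order of expressed dissatisfaction.  Shares are
    multiple-response percentages: each respondent can be deprived in
    several domains, so the column can total more than 100.
    """
    if group not in ("deprived", "maintained"):
        raise ValueError(f"group must be 'deprived' or 'maintained', got {group!r}")
    z, default_k = _sufficiency_frame(profiles)
    if k is None:
        k = default_k
    cls = classify_overall(z, k=k)
    mask = (cls["maintained"] == 0) if group == "deprived" else (cls["maintained"] == 1)
    if not mask.any():
        raise ValueError(f"the {group} group is empty")
    shares = (z.loc[mask] == 0).mean() * 100.0
    out = pd.DataFrame({"share_pct": shares})
    out["n_group"] = int(mask.sum())
    return out.sort_values("share_pct", ascending=False, kind="stable")
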