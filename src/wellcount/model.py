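"""Binary-outcome model of wellbeing maintenance.

Fits maintained-vs-not by maximum-likelihood logistic regression on the
survey covariates (income group, hopefulness, age group, gender), with
categorical terms expanded against declared reference levels.  Reported
per-term quantities follow the conventional regression-table layout:
coefficient B, standard error, single-df Wald statistic (B/SE)^2 (with an
aggregate chi-square row for multi-level categorical terms), p-value, odds
ratio Exp(B) and its 95% CI exp(B +/- 1.96 SE).  Model-level quantities are
the Nagelkerke pseudo-R^2 and the classification accuracy at probability
cutoff 0.5.

The likelihood maximisation is delegated to statsmodels; everything
reported on top of it is computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "TermSpec",
    "RegressionResult",
    "SeparationError",
    "fit_maintenance_model",
    "nagelkerke_r2",
    "classification_rate",
    "Z_95",
]

#: two-sided 95% normal quantile used for the odds-ratio CIs
Z_95 = 1.959963984540054


class SeparationError(RuntimeError):
    """Raised when the outcome is perfectly separated by the design."""


@dataclass(frozen=True)
class TermSpec:
    """One model term: a numeric covariate or a categorical with a reference.

    ``kind='categorical'`` expands the column into indicator contrasts
    against ``reference`` (default: the first observed level); ``kind in
    ('numeric', 'ordinal')`` enters the column as a single numeric slope.
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric", "ordinal"):
            raise ValueError(f"unknown term kind {self.kind!r} for {self.name!r}")


@dataclass
class RegressionResult:
    """Per-term table plus model-level fit statistics."""

    table: pd.DataFrame  # index: term label; columns: B, SE, Wald, df, p, OR, CI_low, CI_high
    nagelkerke: float | None
    accuracy_pct: float
    n: int
    loglik: float
    loglik_null: float
    converged: bool
    fitted_probabilities: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "nagelkerke_r2": self.nagelkerke,
            "accuracy_pct": self.accuracy_pct,
            "converged": self.converged,
            "terms": self.table.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
        }


def _design_matrix(
    data: pd.DataFrame, terms: Sequence[TermSpec]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    cols: dict[str, pd.Series] = {}
    groups: dict[str, list[str]] = {}
    for t in terms:
        if t.name not in data.columns:
            raise KeyError(f"term {t.name!r} not in the covariate table")
        series = data[t.name]
        if t.kind in ("numeric", "ordinal"):
            cols[t.name] = pd.to_numeric(series, errors="raise").astype(float)
            groups[t.name] = [t.name]
        else:
            levels = list(t.levels) if t.levels else list(pd.unique(series.dropna()))
            ref = t.reference if t.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} not among levels of {t.name!r}"
                )
            contrast_levels = [lv for lv in levels if lv != ref]
            labels = []
            for lv in contrast_levels:
                label = f"{t.name}[{lv}]"
                cols[label] = (series == lv).astype(float)
                labels.append(label)
            groups[t.name] = labels
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "Constant", 1.0)
    return X, groups


def fit_maintenance_model(
    data: pd.DataFrame,
    outcome: str = "maintained",
    terms: Sequence[TermSpec] = (),
    cutoff: float = 0.5,
) -> RegressionResult:
    """Maximum-likelihood logistic fit of a binary maintenance outcome.

    Rows with a missing outcome or missing term value are dropped (the n
    actually used is reported).  Perfect separation raises an explicit
    :class:`SeparationError` rather than returning a silently divergent fit;
    an all-constant outcome raises ``ValueError``.
    """
    if not terms:
        raise ValueError("at least one model term is required")
    X, groups = _design_matrix(data, terms)
    y = pd.to_numeric(data[outcome], errors="raise")
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep].astype(float), X[keep]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError("outcome is constant; the model is not identifiable")
    n, p = X.shape
    if n < p:
        raise ValueError(f"n={n} rows cannot identify {p} parameters")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                "perfect separation: some covariate pattern determines the "
                "outcome exactly; coefficients diverge"
            ) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (perfect separation or a "
                "collinear design); the maximum-likelihood fit does not exist"
            ) from exc
    params = fit.params
    if np.abs(params).max() > 30:
        raise SeparationError(
            "perfect (or quasi-perfect) separation: coefficient estimates "
            "diverge; the maximum-likelihood fit does not exist"
        )

    se = fit.bse
    wald = (params / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    rows = {}
    for i, label in enumerate(X.columns):
        b = float(params.iloc[i])
        s = float(se.iloc[i])
        rows[label] = {
            "B": b,
            "SE": s,
            "Wald": float(wald.iloc[i]),
            "df": 1,
            "p": float(pvals[i]),
            "OR": float(np.exp(b)),
            "CI_low": float(np.exp(b - Z_95 * s)),
            "CI_high": float(np.exp(b + Z_95 * s)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")

    # aggregate Wald chi-square rows for multi-level categorical terms,
    # matching the df > 1 layout of SPSS-style regression tables
    agg_rows = {}
    for term, labels in groups.items():
        if len(labels) <= 1:
            continue
        R = np.zeros((len(labels), len(X.columns)))
        for r, lab in enumerate(labels):
            R[r, list(X.columns).index(lab)] = 1.0
        wt = fit.wald_test(R, scalar=True)
        agg_rows[term] = {
            "B": np.nan,
            "SE": np.nan,
            "Wald": float(wt.statistic),
            "df": len(labels),
            "p": float(wt.pvalue),
            "OR": np.nan,
            "CI_low": np.nan,
            "CI_high": np.nan,
        }
    if agg_rows:
        table = pd.concat([table, pd.DataFrame.from_dict(agg_rows, orient="index")])

    probs = pd.Series(fit.predict(X), index=X.index)
    ll1 = float(fit.llf)
    ll0 = float(fit.llnull)
    return RegressionResult(
        table=table,
        nagelkerke=nagelkerke_r2(ll0, ll1, n),
        accuracy_pct=classification_rate(probs, y, cutoff=cutoff),
        n=n,
        loglik=ll1,
        loglik_null=ll0,
        converged=bool(fit.mle_retvals.get("converged", True)),
        fitted_probabilities=probs,
    )


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float | None:
    """Nagelkerke pseudo-R^2: Cox-Snell rescaled to a [0, 1] range.

    ``[1 - exp(2(ll0 - ll1)/n)] / [1 - exp(2*ll0/n)]``.  Undefined (None)
    when the null model already has likelihood 1 (ll0 = 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_model < loglik_null - 1e-9:
        raise ValueError("model log-likelihood cannot be below the null's")
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom == 0.0:
        return None
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    return float(cox_snell / denom)


def classification_rate(probabilities, outcome, cutoff: float = 0.5) -> float:
    """Percentage of cases whose (p >= cutoff) prediction matches the outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcome must align")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= cutoff).astype(float)
    return float((pred == y).mean()) * 100.0
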