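"""Codebook-driven recoding of raw survey answers into binary sufficiency indicators.

A codebook declares, for every survey question that enters the wellbeing
calculus, which domain it belongs to and how its raw answer is mapped to an
achievement indicator in {0, 1, missing}.  It also declares the demographic
covariates (gender, age band, region, weekly income, hopefulness) that the
decomposition and regression stages consume.  The recoded product is an
:class:`IndicatorMatrix`: a respondents x variables binary table grouped by
domain, with the covariate table aligned row-for-row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CodebookError",
    "RecodeError",
    "VariableRule",
    "DomainSpec",
    "CovariateSpec",
    "Codebook",
    "IndicatorMatrix",
    "load_codebook",
    "recode",
    "recode_hopefulness",
    "regroup_income",
    "IncomeGroup",
    "HOPEFULNESS_SCALE",
    "DEFAULT_HOPEFULNESS_CUTOFF",
    "INCOME_BOUNDARY",
]

RULE_KINDS = ("category_set", "threshold_ge", "threshold_le", "binary_passthrough")
MISSING_POLICIES = ("as_zero", "as_missing")
COVARIATE_TYPES = ("categorical", "ordinal", "numeric")

#: the hopefulness item is asked on an ordinal 1..8 scale
#: (1 = not positive/hopeful, 8 = very positive/hopeful)
HOPEFULNESS_SCALE = (1, 8)
#: "highly positive" means the top quarter of the 8-point scale by default
DEFAULT_HOPEFULNESS_CUTOFF = 7
#: weekly income is split at $600/week, boundary inclusive in the LOW group
INCOME_BOUNDARY = 600.0


class CodebookError(ValueError):
    """Raised when a codebook violates its schema."""


class RecodeError(ValueError):
    """Raised when raw survey values cannot be recoded under the codebook."""


# ---------------------------------------------------------------------------
# Schema types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableRule:
    """Recode rule turning one raw survey column into a {0, 1, missing} indicator.

    Parameters
    ----------
    column:
        Name of the raw survey column.
    rule_kind:
        One of ``category_set`` (achievement iff the answer is in
        ``achieving``), ``threshold_ge`` / ``threshold_le`` (numeric or
        ordinal cutoff), or ``binary_passthrough`` (already 0/1).
    achieving:
        Achieving category labels (``category_set`` only).
    labels:
        Full declared label set; when given, an answer outside it (and not a
        missing code) is an error rather than silently non-achieving.
    cutoff:
        Numeric cutoff for the threshold rules.
    missing_codes:
        Raw values treated as missing before the rule is applied.  NaN/empty
        answers are always treated as missing.
    missing_policy:
        ``as_zero`` scores missing answers as non-achievement (every
        respondent classifiable); ``as_missing`` propagates NaN.
    """

    column: str
    rule_kind: str
    achieving: tuple[str, ...] = ()
    labels: tuple[str, ...] = ()
    cutoff: float | None = None
    missing_codes: tuple[str, ...] = ()
    missing_policy: str = "as_zero"

    def __post_init__(self) -> None:
        if self.rule_kind not in RULE_KINDS:
            raise CodebookError(
                f"unknown rule_kind {self.rule_kind!r} for column {self.column!r}; "
                f"expected one of {RULE_KINDS}"
            )
        if self.missing_policy not in MISSING_POLICIES:
            raise CodebookError(
                f"unknown missing_policy {self.missing_policy!r} for column {self.column!r}"
            )
        if self.rule_kind == "category_set" and not self.achieving:
            raise CodebookError(f"category_set rule for {self.column!r} needs 'achieving'")
        if self.rule_kind in ("threshold_ge", "threshold_le") and self.cutoff is None:
            raise CodebookError(f"threshold rule for {self.column!r} needs 'cutoff'")
        if self.labels and not set(self.achieving) <= set(self.labels):
            raise CodebookError(
                f"achieving categories of {self.column!r} not all in declared labels"
            )

    def apply(self, values: pd.Series) -> pd.Series:
        """Apply the rule to a raw column; returns a float series in {0, 1, NaN}."""
        values = values.copy()
        missing = values.isna()
        if self.missing_codes:
            missing |= values.astype("string").isin([str(c) for c in self.missing_codes])

        if self.rule_kind == "category_set":
            as_str = values.astype("string")
            out = as_str.isin(self.achieving).astype(float)
            if self.labels:
                known = as_str.isin(self.labels) | missing
                if not known.all():
                    bad = values.index[~known][0]
                    raise RecodeError(
                        f"column {self.column!r}, row {bad}: value "
                        f"{values.loc[bad]!r} outside declared label set"
                    )
        elif self.rule_kind in ("threshold_ge", "threshold_le"):
            numeric = pd.to_numeric(values.where(~missing), errors="coerce")
            bad_mask = numeric.isna() & ~missing
            if bad_mask.any():
                bad = values.index[bad_mask][0]
                raise RecodeError(
                    f"column {self.column!r}, row {bad}: value {values.loc[bad]!r} "
                    "is not numeric/ordinal"
                )
            if self.rule_kind == "threshold_ge":
                out = (numeric >= self.cutoff).astype(float)
            else:
                out = (numeric <= self.cutoff).astype(float)
        else:  # binary_passthrough
            numeric = pd.to_numeric(values.where(~missing), errors="coerce")
            ok = numeric.isin([0, 1]) | missing
            if not ok.all():
                bad = values.index[~ok][0]
                raise RecodeError(
                    f"column {self.column!r}, row {bad}: value {values.loc[bad]!r} "
                    "is not binary"
                )
            out = numeric.astype(float)

        out = out.astype(float)
        if self.missing_policy == "as_zero":
            out[missing] = 0.0
        else:
            out[missing] = np.nan
        return out

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"column": self.column, "rule_kind": self.rule_kind,
                             "missing_policy": self.missing_policy}
        if self.achieving:
            d["achieving"] = list(self.achieving)
        if self.labels:
            d["labels"] = list(self.labels)
        if self.cutoff is not None:
            d["cutoff"] = self.cutoff
        if self.missing_codes:
            d["missing_codes"] = list(self.missing_codes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "VariableRule":
        return cls(
            column=d["column"],
            rule_kind=d.get("rule_kind", d.get("kind", "")),
            achieving=tuple(d.get("achieving", ())),
            labels=tuple(d.get("labels", ())),
            cutoff=d.get("cutoff"),
            missing_codes=tuple(d.get("missing_codes", ())),
            missing_policy=d.get("missing_policy", "as_zero"),
        )


@dataclass(frozen=True)
class DomainSpec:
    """A wellbeing domain: an ordered set of variables and a positive weight."""

    name: str
    variables: tuple[VariableRule, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.variables:
            raise CodebookError(f"domain {self.name!r} has no variables")
        if not self.weight > 0:
            raise CodebookError(f"domain {self.name!r} has non-positive weight")

    @property
    def m(self) -> int:
        """Number of variables in the domain."""
        return len(self.variables)

    @property
    def columns(self) -> list[str]:
        return [v.column for v in self.variables]


@dataclass(frozen=True)
class CovariateSpec:
    """A demographic covariate carried alongside the indicators."""

    name: str
    type: str = "categorical"
    categories: tuple[str, ...] = ()
    missing_codes: tuple[str, ...] = ()
    no_income_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in COVARIATE_TYPES:
            raise CodebookError(f"covariate {self.name!r}: unknown type {self.type!r}")

    def clean(self, values: pd.Series) -> pd.Series:
        missing = values.isna()
        if self.missing_codes:
            missing |= values.astype("string").isin([str(c) for c in self.missing_codes])
        if self.type == "numeric":
            raw = values.astype("string")
            no_income = raw.isin([str(c) for c in self.no_income_codes]) & ~missing
            numeric = pd.to_numeric(values.where(~(missing | no_income)), errors="coerce")
            numeric[no_income] = 0.0
            return numeric
        out = values.astype("object").where(~missing, np.nan)
        if self.categories:
            as_str = values.astype("string")
            known = as_str.isin(self.categories) | missing
            if not known.all():
                bad = values.index[~known][0]
                raise RecodeError(
                    f"covariate {self.name!r}, row {bad}: value "
                    f"{values.loc[bad]!r} outside declared categories"
                )
        return out

    def no_income_mask(self, values: pd.Series) -> pd.Series:
        if self.type != "numeric" or not self.no_income_codes:
            return pd.Series(False, index=values.index)
        return values.astype("string").isin([str(c) for c in self.no_income_codes])

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"name": self.name, "type": self.type}
        if self.categories:
            d["categories"] = list(self.categories)
        if self.missing_codes:
            d["missing_codes"] = list(self.missing_codes)
        if self.no_income_codes:
            d["no_income_codes"] = list(self.no_income_codes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CovariateSpec":
        return cls(
            name=d["name"],
            type=d.get("type", "categorical"),
            categories=tuple(d.get("categories", ())),
            missing_codes=tuple(d.get("missing_codes", ())),
            no_income_codes=tuple(d.get("no_income_codes", ())),
        )


@dataclass(frozen=True)
class Codebook:
    """Ordered domains plus covariates; validated on construction."""

    domains: tuple[DomainSpec, ...]
    covariates: tuple[CovariateSpec, ...] = ()
    name: str = "codebook"

    def __post_init__(self) -> None:
        names = [d.name for d in self.domains]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise CodebookError(f"duplicate domain name {dup!r}")
        seen: dict[str, str] = {}
        for d in self.domains:
            for v in d.variables:
                if v.column in seen:
                    raise CodebookError(
                        f"variable {v.column!r} assigned to both "
                        f"{seen[v.column]!r} and {d.name!r}"
                    )
                seen[v.column] = d.name

    @property
    def domain_names(self) -> list[str]:
        return [d.name for d in self.domains]

    @property
    def m(self) -> dict[str, int]:
        """Variable count per domain."""
        return {d.name: d.m for d in self.domains}

    @property
    def weights(self) -> dict[str, float]:
        return {d.name: d.weight for d in self.domains}

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def domain(self, name: str) -> DomainSpec:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "domains": [
                {
                    "name": d.name,
                    "weight": d.weight,
                    "variables": [v.to_dict() for v in d.variables],
                }
                for d in self.domains
            ],
            "covariates": [c.to_dict() for c in self.covariates],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Codebook":
        if "domains" not in d:
            raise CodebookError("codebook must have a top-level 'domains' key")
        domains = tuple(
            DomainSpec(
                name=dom["name"],
                weight=float(dom.get("weight", 1.0)),
                variables=tuple(VariableRule.from_dict(v) for v in dom["variables"]),
            )
            for dom in d["domains"]
        )
        covs = tuple(CovariateSpec.from_dict(c) for c in d.get("covariates", ()))
        return cls(domains=domains, covariates=covs, name=d.get("name", "codebook"))


def load_codebook(path: str | Path) -> Codebook:
    """Read and validate a codebook from JSON (or YAML, an accepted dialect).

    Domain order is preserved as listed.  Schema violations (duplicate
    variable assignment, unknown rule kinds, empty domains) raise
    :class:`CodebookError` naming the offending element.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise CodebookError(f"{path}: codebook root must be a mapping")
    return Codebook.from_dict(data)


# ---------------------------------------------------------------------------
# Recoding
# ---------------------------------------------------------------------------


@dataclass
class IndicatorMatrix:
    """Respondents x variables binary achievement matrix, grouped by domain.

    ``data`` holds one float column per codebook variable with values in
    {0.0, 1.0, NaN}; ``domains`` maps each domain name to its columns in
    codebook order; ``covariates`` is aligned to ``data`` row-for-row.
    """

    data: pd.DataFrame
    domains: dict[str, list[str]]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("indicator matrix entries must be 0, 1 or missing")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def respondent_ids(self) -> pd.Index:
        return self.data.index

    @property
    def m(self) -> dict[str, int]:
        return {name: len(cols) for name, cols in self.domains.items()}

    def domain_block(self, name: str) -> pd.DataFrame:
        return self.data[self.domains[name]]


def recode(raw_table: pd.DataFrame, codebook: Codebook) -> IndicatorMatrix:
    """Recode a raw survey table into the binary :class:`IndicatorMatrix`.

    Every codebook column must be present in ``raw_table``; each variable's
    rule produces a value in {0, 1, missing}; covariates are carried through
    with declared missing codes mapped to NaN.  No rows are dropped: the
    output has exactly the input's rows, in order.
    """
    missing_cols = [
        v.column for d in codebook.domains for v in d.variables
        if v.column not in raw_table.columns
    ]
    if missing_cols:
        raise RecodeError(f"raw table is missing codebook column {missing_cols[0]!r}")

    indicator_cols: dict[str, pd.Series] = {}
    for dom in codebook.domains:
        for rule in dom.variables:
            indicator_cols[rule.column] = rule.apply(raw_table[rule.column])
    data = pd.DataFrame(indicator_cols, index=raw_table.index)

    cov_cols: dict[str, pd.Series] = {}
    for cov in codebook.covariates:
        if cov.name not in raw_table.columns:
            raise RecodeError(f"raw table is missing covariate column {cov.name!r}")
        cov_cols[cov.name] = cov.clean(raw_table[cov.name])
        if cov.no_income_codes:
            cov_cols[cov.name + "_no_income"] = cov.no_income_mask(raw_table[cov.name])
    covariates = pd.DataFrame(cov_cols, index=raw_table.index)

    return IndicatorMatrix(
        data=data,
        domains={d.name: d.columns for d in codebook.domains},
        covariates=covariates,
        weights=codebook.weights,
    )


def recode_hopefulness(value, cutoff: int = DEFAULT_HOPEFULNESS_CUTOFF):
    """Dichotomise the 1-8 hopefulness scale: 1 iff value >= cutoff.

    Accepts a scalar or an array/Series; missing values stay missing.
    Values outside 1..8 raise a range error.
    """
    lo, hi = HOPEFULNESS_SCALE
    arr = pd.to_numeric(pd.Series(np.atleast_1d(value)), errors="coerce")
    scalar = np.ndim(value) == 0
    raw = pd.Series(np.atleast_1d(value))
    bad = arr.isna() & raw.notna()
    if bad.any():
        raise ValueError(f"hopefulness value {raw[bad].iloc[0]!r} is not numeric")
    out_of_range = arr.notna() & ((arr < lo) | (arr > hi))
    if out_of_range.any():
        raise ValueError(
            f"hopefulness value {arr[out_of_range].iloc[0]} outside the {lo}..{hi} scale"
        )
    out = (arr >= cutoff).astype(float)
    out[arr.isna()] = np.nan
    if scalar:
        v = out.iloc[0]
        return v if np.isnan(v) else int(v)
    return out.to_numpy()


@dataclass(frozen=True)
class IncomeGroup:
    """Binary weekly-income group with a distinct flag for reported 'no income'."""

    group: str | None  # "LOW", "HIGH", or None when missing
    no_income: bool = False


def regroup_income(
    weekly_income,
    boundary: float = INCOME_BOUNDARY,
    no_income_codes: Sequence[str] = ("No income", "no income"),
    missing_codes: Sequence[str] = ("", "Prefer not to say"),
):
    """Regroup weekly income into LOW (<= boundary, default $600) vs HIGH.

    The boundary is inclusive in LOW.  Declared 'no income' answers map to
    LOW but keep a distinct flag, since that group behaves differently (it
    is dominated by pension-age respondents with secure income).  Scalars
    return an :class:`IncomeGroup`; arrays return a DataFrame with columns
    ``group`` and ``no_income``.
    """
    scalar = np.ndim(weekly_income) == 0
    raw = pd.Series(np.atleast_1d(np.asarray(weekly_income, dtype=object)))
    as_str = raw.astype("string")
    no_income = as_str.isin([str(c) for c in no_income_codes])
    missing = raw.isna() | as_str.isin([str(c) for c in missing_codes])
    amount = pd.to_numeric(raw.where(~(no_income | missing)), errors="coerce")
    bad = amount.isna() & ~(no_income | missing)
    if bad.any():
        raise ValueError(f"income value {raw[bad].iloc[0]!r} is not an amount")
    if (amount < 0).any():
        raise ValueError(
            f"negative weekly income {amount[amount < 0].iloc[0]}"
        )
    group = pd.Series(pd.NA, index=raw.index, dtype="object")
    group[amount.notna() & (amount <= boundary)] = "LOW"
    group[amount.notna() & (amount > boundary)] = "HIGH"
    group[no_income] = "LOW"
    if scalar:
        g = group.iloc[0]
        return IncomeGroup(group=None if pd.isna(g) else g, no_income=bool(no_income.iloc[0]))
    return pd.DataFrame({"group": group, "no_income": no_income})
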