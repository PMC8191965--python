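"""Run orchestration, sample-representativeness calculator, report assembly.

Every printed percentage in the emitted reports is the underlying count
re-divided and rounded half-up to the documented precision (1 decimal place
for percentages by default) — there are no independently maintained totals.
Each run writes a manifest recording the configuration, seed and software
version, sufficient to reproduce the output bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .codebook import Codebook, load_codebook, recode, regroup_income
from .decompose import stratified_rates
from .index import build_profiles, driver_table, summarize
from .model import TermSpec, fit_maintenance_model

__all__ = [
    "margin_of_error",
    "round_half_up",
    "percentage",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger("wellcount")


def round_half_up(x: float, dp: int = 1) -> float:
    """Decimal half-up rounding (the convention of the published tables)."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, dp: int = 1) -> float:
    """A reported percentage: count / total * 100, rounded half-up to dp."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, dp)


def margin_of_error(
    n: int, confidence: float = 0.95, population: int | None = None
) -> float:
    """Normal-approximation margin of error for a proportion at p = 0.5.

    ``z_{(1+confidence)/2} * sqrt(0.25 / n)``, multiplied by the finite-
    population correction ``sqrt((N - n) / (N - 1))`` when a population size
    N is given.  Returned as a proportion (0.05 = five percent).
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    moe = z * np.sqrt(0.25 / n)
    if population is not None:
        if n > population:
            raise ValueError(f"sample n={n} exceeds population N={population}")
        if population > 1:
            moe *= np.sqrt((population - n) / (population - 1))
        else:
            moe = 0.0
    return float(moe)


class PipelineError(RuntimeError):
    """A pipeline stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    The default preset "SA2020" is the study configuration: six equally
    weighted domains, two-thirds within-domain thresholds, cross-domain
    cutoff k = 4 of 6, percentages rounded half-up to 1 decimal place.
    """

    raw_path: str | Path
    out_dir: str | Path
    codebook_path: str | Path | None = None
    preset: str = "SA2020"
    k: int | None = None
    stratifiers: tuple[str, ...] = ("gender", "age_group", "region", "income_group")
    fit_model: bool = True
    rounding_dp: int = 1
    seed: int = 0
    verbose: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["raw_path"] = str(self.raw_path)
        d["out_dir"] = str(self.out_dir)
        d["codebook_path"] = None if self.codebook_path is None else str(self.codebook_path)
        d["stratifiers"] = list(self.stratifiers)
        return d


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n")


def _clean_nan(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _clean_nan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_nan(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _default_model_terms(covariates: pd.DataFrame) -> tuple[pd.DataFrame, list[TermSpec]]:
    """Assemble the maintenance-model design used by the study.

    Income enters as the binary LOW/HIGH group (reference LOW), pre-pandemic
    hopefulness as the 1..8 ordinal treated as numeric, age as the ordered
    band index, gender as a three-level categorical with Male reference.
    """
    df = pd.DataFrame(index=covariates.index)
    grouped = regroup_income(covariates["weekly_income"].to_numpy())
    df["income_group"] = grouped["group"].to_numpy()
    df["hopefulness_pre"] = pd.to_numeric(covariates["hopefulness_pre"], errors="coerce")
    bands = ["18-24", "25-34", "35-49", "50-64", "65+"]
    df["age_index"] = covariates["age_group"].map({b: i for i, b in enumerate(bands)})
    df["gender"] = covariates["gender"]
    terms = [
        TermSpec("income_group", "categorical", reference="LOW", levels=("LOW", "HIGH")),
        TermSpec("hopefulness_pre", "numeric"),
        TermSpec("age_index", "numeric"),
        TermSpec("gender", "categorical", reference="Male",
                 levels=("Male", "Female", "Other/undisclosed")),
    ]
    return df, terms


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Recode, score, summarise, decompose and (optionally) model one survey.

    Writes CSV/JSON outputs plus a manifest to ``config.out_dir`` and
    returns the paths.  Any stage failure propagates as
    :class:`PipelineError` naming the stage, and partial outputs are
    removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Path] = {}

    def emit(name: str, filename: str) -> Path:
        p = out_dir / filename
        written.append(p)
        outputs[name] = p
        return p

    try:
        # --- load ---------------------------------------------------------
        stage = "load"
        raw = pd.read_csv(config.raw_path, dtype=object)
        if raw.empty:
            raise PipelineError(stage, f"raw table {config.raw_path} has no rows")
        if "respondent_id" in raw.columns:
            raw = raw.set_index("respondent_id")
        if config.codebook_path is not None:
            codebook = load_codebook(config.codebook_path)
        else:
            from .synth import default_codebook

            codebook = default_codebook()

        # --- recode and score --------------------------------------------
        stage = "recode"
        matrix = recode(raw, codebook)
        stage = "score"
        profiles = build_profiles(matrix, k=config.k)
        profiles.to_frame().to_csv(emit("profiles", "profiles.csv"))

        stage = "summarize"
        summary = summarize(profiles)
        _json_dump(_clean_nan(summary.to_dict()), emit("summary", "summary.json"))

        stage = "drivers"
        for group in ("deprived", "maintained"):
            try:
                dt = driver_table(profiles, group=group)
            except ValueError:
                continue  # group empty in this population
            dt["share_pct"] = dt["share_pct"].map(
                lambda v: round_half_up(v, config.rounding_dp)
            )
            dt.to_csv(emit(f"drivers_{group}", f"drivers_{group}.csv"))

        # --- stratified reports -------------------------------------------
        stage = "stratify"
        cov = profiles.covariates.copy()
        if "weekly_income" in cov.columns and "income_group" in config.stratifiers:
            cov["income_group"] = regroup_income(cov["weekly_income"].to_numpy())[
                "group"
            ].to_numpy()
        for strat in config.stratifiers:
            if strat not in cov.columns:
                logger.info("stratifier %s absent; skipped", strat)
                continue
            rep = stratified_rates(profiles, strat, covariates=cov)
            for col in ("maintained_pct", "deprived_pct"):
                rep[col] = rep[col].map(lambda v: round_half_up(v, config.rounding_dp))
            rep.to_csv(emit(f"stratified_{strat}", f"stratified_{strat}.csv"), index=False)

        # --- covariate model ----------------------------------------------
        if config.fit_model:
            stage = "fit"
            needed = {"weekly_income", "hopefulness_pre", "age_group", "gender"}
            if needed <= set(cov.columns):
                design, terms = _default_model_terms(cov)
                design["maintained"] = profiles.maintained
                result = fit_maintenance_model(design, outcome="maintained", terms=terms)
                result.table.to_csv(emit("regression_terms", "regression_terms.csv"))
                _json_dump(
                    _clean_nan(
                        {
                            k: v
                            for k, v in result.to_dict().items()
                            if k != "terms"
                        }
                    ),
                    emit("regression", "regression.json"),
                )
            else:
                logger.info("model covariates absent; fit skipped")

        # --- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
            "preset": config.preset,
            "codebook": codebook.name,
            "n_respondents": int(len(raw)),
            "outputs": sorted(p.name for p in written),
        }
        _json_dump(manifest, emit("manifest", "manifest.json"))
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
    return outputs
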