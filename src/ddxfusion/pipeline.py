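"""End-to-end pipeline: simulate (or load) → combine → evaluate → report.

`run_pipeline` produces a name-stable, diffable artifact set in the output
directory:

* ``rows.csv`` — the per-row paired evaluation table; every number in the
  report tables can be recomputed from it.
* ``accuracy.tsv`` / ``metrics.json`` — the accuracy table over
  (arm, method, stratum) with exact binomial CIs.
* ``mcnemar.tsv`` — paired index-vs-combined comparisons per arm/method.
* ``odds_ratios.tsv`` — logistic fits of index accuracy on the shared
  count, per arm and stratum.
* ``curve.csv`` — index accuracy by shared-diagnosis count (the
  concordance–accuracy curve), total and per stratum.
* ``config.yaml`` — echo of the fully resolved run configuration; a rerun
  from it with the same seed reproduces every artifact byte for byte.

Replicate rows are treated as independent observations; a clustering
caveat is logged because replicates of one patient share the index list.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CaseRecord,
    SimulationConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .stats import (
    COMBINATION_METHODS,
    SeparationError,
    accuracy_with_ci,
    expand_rows,
    fit_logistic_shared,
    mcnemar_paired,
    summarize_strata,
)

__all__ = ["RunConfig", "run_pipeline", "accuracy_by_shared_curve"]

logger = logging.getLogger("ddxfusion")

SMALL_STRATUM_ROWS = 10


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str
    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    cohort_format: str = "csv"
    methods: tuple[str, ...] = COMBINATION_METHODS
    ci_level: float = 0.95
    mcnemar_variant: str = "exact"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.cohort_path is None):
            raise ValueError(
                "exactly one cohort source is required: a simulation config "
                "or a cohort file path"
            )
        unknown = set(self.methods) - set(COMBINATION_METHODS)
        if unknown:
            raise ValueError(f"unknown combination methods: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if data.get("simulation") is not None:
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        if "methods" in data and data["methods"] is not None:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def accuracy_by_shared_curve(
    rows: pd.DataFrame,
    level: float = 0.95,
    strata: Sequence[str] = ("total", "common", "uncommon"),
) -> pd.DataFrame:
    """Index-list accuracy per observed shared-diagnosis count.

    One exact-CI accuracy estimate per (arm, stratum, shared_count) bin —
    the data behind the concordance–accuracy curve in which accuracy rises
    with the number of diagnoses the index list shares with the others.
    """
    out: list[dict] = []
    for arm in sorted(rows["arm"].unique()):
        arm_rows = rows[rows["arm"] == arm]
        for stratum in strata:
            sel = (
                arm_rows
                if stratum == "total"
                else arm_rows[arm_rows["stratum"] == stratum]
            )
            for count in sorted(sel["shared_count"].unique()):
                hits = sel.loc[sel["shared_count"] == count, "index_hit"]
                acc = accuracy_with_ci(hits.tolist(), level=level)
                out.append(
                    {
                        "arm": arm,
                        "stratum": stratum,
                        "shared_count": int(count),
                        "numerator": acc.numerator,
                        "denominator": acc.denominator,
                        "proportion": acc.proportion,
                        "ci_low": acc.ci_low,
                        "ci_high": acc.ci_high,
                    }
                )
    return pd.DataFrame(out)


def _mcnemar_table(
    rows: pd.DataFrame, methods: Sequence[str], variant: str
) -> pd.DataFrame:
    out: list[dict] = []
    arms = sorted(rows["arm"].unique())
    pairwise = [a for a in arms if a.startswith("2-system:")]
    groups: list[tuple[str, pd.DataFrame]] = []
    if len(pairwise) > 1:
        groups.append(("2-system", rows[rows["arm"].isin(pairwise)]))
    groups.extend((a, rows[rows["arm"] == a]) for a in arms)
    for arm, arm_rows in groups:
        for method in methods:
            res = mcnemar_paired(
                arm_rows["index_hit"].tolist(),
                arm_rows[f"{method}_hit"].tolist(),
                variant=variant,
            )
            out.append(
                {
                    "arm": arm,
                    "method": method,
                    "b_index_only": res.b,
                    "c_combined_only": res.c,
                    "p_value": res.p_value,
                    "variant": res.variant,
                }
            )
    return pd.DataFrame(out)


def _odds_ratio_table(rows: pd.DataFrame, level: float) -> pd.DataFrame:
    """Logistic fits of index accuracy on shared count per arm and stratum."""
    out: list[dict] = []
    arms = sorted(rows["arm"].unique())
    pairwise = [a for a in arms if a.startswith("2-system:")]
    groups: list[tuple[str, pd.DataFrame]] = []
    if len(pairwise) > 1:
        groups.append(("2-system", rows[rows["arm"].isin(pairwise)]))
    groups.extend(
        (a, rows[rows["arm"] == a]) for a in arms if not a.startswith("2-system:")
    )
    for arm, arm_rows in groups:
        for stratum in ("total", "common", "uncommon"):
            sel = (
                arm_rows
                if stratum == "total"
                else arm_rows[arm_rows["stratum"] == stratum]
            )
            record: dict = {"arm": arm, "stratum": stratum, "n_rows": len(sel)}
            try:
                fit = fit_logistic_shared(
                    sel["shared_count"].tolist(), sel["index_hit"].tolist(), level=level
                )
                record.update(
                    odds_ratio=fit.odds_ratio,
                    or_ci_low=fit.or_ci_low,
                    or_ci_high=fit.or_ci_high,
                    p_value=fit.p_value,
                    note="",
                )
            except (ValueError, SeparationError) as exc:
                record.update(
                    odds_ratio=np.nan,
                    or_ci_low=np.nan,
                    or_ci_high=np.nan,
                    p_value=np.nan,
                    note=str(exc),
                )
                logger.warning("logistic fit skipped for %s/%s: %s", arm, stratum, exc)
            out.append(record)
    return pd.DataFrame(out)


def _load_cohort(config: RunConfig) -> list[CaseRecord]:
    if config.simulation is not None:
        logger.info(
            "simulating cohort: %d cases x %d replicates, generators %s",
            config.simulation.n_cases,
            config.simulation.n_replicates,
            list(config.simulation.generators),
        )
        return generate_cohort(config.simulation)
    logger.info("reading cohort from %s (%s)", config.cohort_path, config.cohort_format)
    return read_cohort(config.cohort_path, format=config.cohort_format)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the artifact set.

    Returns a mapping from artifact name to path.  Identical configuration
    (including the simulation seed) yields byte-identical artifacts.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        cohort = _load_cohort(config)
        write_cohort(cohort, out_dir / "cohort", format="csv")

        rows = expand_rows(cohort)
        logger.info(
            "expanded %d case records into %d evaluation rows", len(cohort), len(rows)
        )
        logger.warning(
            "replicate rows from the same patient are treated as independent; "
            "accuracies and p-values ignore within-patient clustering"
        )
        for stratum in ("common", "uncommon"):
            n = int((rows["stratum"] == stratum).sum())
            if n < SMALL_STRATUM_ROWS:
                logger.warning(
                    "stratum %r has only %d rows; exact CIs will be wide", stratum, n
                )

        rows_path = out_dir / "rows.csv"
        rows.to_csv(rows_path, index=False)

        accuracy = summarize_strata(rows, level=config.ci_level)
        accuracy.to_csv(out_dir / "accuracy.tsv", sep="\t", index=False)
        mcnemar = _mcnemar_table(rows, config.methods, config.mcnemar_variant)
        mcnemar.to_csv(out_dir / "mcnemar.tsv", sep="\t", index=False)
        ors = _odds_ratio_table(rows, config.ci_level)
        ors.to_csv(out_dir / "odds_ratios.tsv", sep="\t", index=False)
        curve = accuracy_by_shared_curve(rows, level=config.ci_level)
        curve.to_csv(out_dir / "curve.csv", index=False)

        metrics = {
            "accuracy": accuracy.to_dict(orient="records"),
            "mcnemar": mcnemar.to_dict(orient="records"),
            "odds_ratios": ors.to_dict(orient="records"),
            "n_rows": len(rows),
            "n_case_records": len(cohort),
        }
        metrics_path = out_dir / "metrics.json"
        metrics_path.write_text(
            json.dumps(metrics, indent=1, allow_nan=True, default=float) + "\n",
            encoding="utf-8",
        )
        config_path = out_dir / "config.yaml"
        config_path.write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
        )
        return {
            "rows": rows_path,
            "accuracy": out_dir / "accuracy.tsv",
            "mcnemar": out_dir / "mcnemar.tsv",
            "odds_ratios": out_dir / "odds_ratios.tsv",
            "curve": out_dir / "curve.csv",
            "metrics": metrics_path,
            "config": config_path,
            "log": log_path,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
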