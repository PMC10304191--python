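"""CSV I/O, pipeline configuration and the orchestrating pipeline.

All tables are plain CSV with the explicit missing-value token "NA".
Readers validate schemas and reject malformed rows with their line
numbers; writer/reader pairs are lossless round trips for their
schemas.  ``run_pipeline`` ties simulate -> exposure -> genetics ->
fit -> predict -> report into one seeded, reproducible run whose log
records the seed, a config hash and input-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import genetics, regression
from .exposure import (
    FOOD_ITEMS,
    PESTICIDE_GROUPS,
    ContaminationTable,
    ReferenceDoses,
    cohort_exposure,
)

__all__ = [
    "PipelineConfig",
    "RiskReport",
    "read_cohort",
    "write_cohort",
    "read_reference_doses",
    "write_reference_doses",
    "run_pipeline",
    "mini_cohort",
]

logger = logging.getLogger("ocprisk")

NA = "NA"
STAGES = ("simulate", "exposure", "genetics", "fit", "predict", "report")

_BASE_COLUMNS = ["id", "village", "sex", "age", "weight", "smoking", "alcohol"]
_CONS_COLUMNS = [f"cons_{food}" for food in FOOD_ITEMS]
_OUTCOME_COLUMNS = ["health_latent", "health_rank", "aberration_latent", "aberration_pct"]


class CohortSchemaError(ValueError):
    pass


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, na_rep=NA)


def read_cohort(
    path, panel: Sequence[genetics.VariantDefinition] = genetics.DEFAULT_PANEL
) -> pd.DataFrame:
    """Read and validate a cohort table.

    Required columns: id, village, sex, age, weight, smoking, alcohol
    and the seven cons_<food> columns; genotype and outcome columns are
    optional.  Row-level problems (non-numeric or negative weight /
    consumption) are reported with their 1-based data line numbers.
    """
    frame = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    missing = [c for c in _BASE_COLUMNS + _CONS_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"cohort file {path} lacks required columns: {missing}")
    if len(frame) == 0:
        logger.warning("cohort file %s has a valid header but no rows", path)
        return frame
    problems: list[str] = []
    numeric = ["age", "weight"] + _CONS_COLUMNS
    for column in numeric:
        converted = pd.to_numeric(frame[column], errors="coerce")
        for idx in frame.index[converted.isna() & frame[column].notna()]:
            problems.append(f"row {idx + 1}: non-numeric {column} {frame.at[idx, column]!r}")
        frame[column] = converted
    for column in ("weight",):
        for idx in frame.index[frame[column] <= 0]:
            problems.append(f"row {idx + 1}: non-positive {column} {frame.at[idx, column]}")
    for column in _CONS_COLUMNS:
        for idx in frame.index[frame[column] < 0]:
            problems.append(f"row {idx + 1}: negative {column} {frame.at[idx, column]}")
    if problems:
        raise CohortSchemaError(
            f"cohort file {path} has malformed rows:\n" + "\n".join(problems)
        )
    for column in ("smoking", "alcohol"):
        frame[column] = frame[column].astype(int)
    for variant in panel:
        if variant.rsid in frame.columns and variant.marker_model == "codominant":
            frame[variant.rsid] = pd.to_numeric(frame[variant.rsid], errors="raise")
    return frame


def write_reference_doses(doses: ReferenceDoses, path) -> None:
    """Serialize reference doses as long CSV: table,key1,key2,value."""
    rows: list[dict[str, object]] = []
    for group, value in doses.adi.items():
        rows.append({"table": "adi", "key1": group, "key2": NA, "value": value})
    for group, value in doses.arfd.items():
        rows.append({"table": "arfd", "key1": group, "key2": NA, "value": value})
    if doses.mpc is not None:
        for food in doses.mpc.index:
            for group in doses.mpc.columns:
                value = doses.mpc.at[food, group]
                if pd.notna(value):
                    rows.append(
                        {"table": "mpc", "key1": food, "key2": group, "value": value}
                    )
    for food, value in doses.portion.items():
        rows.append({"table": "portion", "key1": food, "key2": NA, "value": value})
    for name, value in (
        ("ef_days_per_year", doses.ef_days_per_year),
        ("ed_days", doses.ed_days),
        ("at_days", doses.at_days),
    ):
        rows.append({"table": "constant", "key1": name, "key2": NA, "value": value})
    pd.DataFrame(rows).to_csv(path, index=False, na_rep=NA)


def read_reference_doses(path) -> ReferenceDoses:
    frame = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    required = {"table", "key1", "key2", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"reference-dose file must have columns {sorted(required)}")
    adi, arfd, portion = {}, {}, {}
    constants: dict[str, float] = {}
    mpc_rows: list[tuple[str, str, float]] = []
    for row in frame.itertuples(index=False):
        value = float(row.value)
        if row.table == "adi":
            adi[row.key1] = value
        elif row.table == "arfd":
            arfd[row.key1] = value
        elif row.table == "mpc":
            mpc_rows.append((row.key1, row.key2, value))
        elif row.table == "portion":
            portion[row.key1] = value
        elif row.table == "constant":
            constants[row.key1] = value
        else:
            raise ValueError(f"unknown reference-dose table {row.table!r}")
    mpc = None
    if mpc_rows:
        mpc = (
            pd.DataFrame(mpc_rows, columns=["food", "group", "value"])
            .pivot(index="food", columns="group", values="value")
        )
    return ReferenceDoses(
        adi=adi,
        arfd=arfd,
        mpc=mpc,
        portion=portion,
        ef_days_per_year=constants.get("ef_days_per_year", 365.0),
        ed_days=constants.get("ed_days", 25_550.0),
        at_days=constants.get("at_days", 25_550.0),
    )


def mini_cohort() -> pd.DataFrame:
    """Bundled 12-person hand-checkable cohort fixture."""
    from importlib import resources

    with resources.files("ocprisk.data").joinpath("mini_cohort.csv").open() as fh:
        return read_cohort(fh)


@dataclass
class PipelineConfig:
    """Paths, seed, stage toggles and method options of one run."""

    seed: int = 0
    out_dir: str = "ocprisk_out"
    stages: Sequence[str] = STAGES
    cohort_path: str | None = None
    contamination_path: str | None = None
    doses_path: str | None = None
    panel_path: str | None = None
    summary: str = "mean"  # X2/X3/X4 summary over contaminant groups
    coding: str = "dominant"  # genotype risk coding
    hwe_df: int = 2
    analysis_n: int = cohort_mod.ANALYSIS_N

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {**dataclasses.asdict(self), "stages": list(self.stages)}, fh
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        # out_dir is where results land, not what they are: excluded so
        # identical analyses hash identically wherever they are written
        payload = {**dataclasses.asdict(self), "stages": list(self.stages)}
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RiskReport:
    """Everything one pipeline run produced, regenerable from config+seed."""

    config: PipelineConfig
    cohort: pd.DataFrame
    village_exposure: pd.DataFrame | None = None
    genetics_summary: pd.DataFrame | None = None
    fits: dict = field(default_factory=dict)
    influence: dict = field(default_factory=dict)
    predicted: pd.DataFrame | None = None
    predictive_ability: dict = field(default_factory=dict)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> RiskReport:
    """Execute the enabled stages in dependency order and write outputs.

    Identical config + seed gives byte-identical output tables.  A
    disabled prerequisite makes the dependent stage fail with a
    dependency error rather than run on stale inputs.
    """
    stages = list(config.stages)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d config=%s", config.seed, config.digest())
    for label, path in (
        ("cohort", config.cohort_path),
        ("contamination", config.contamination_path),
        ("doses", config.doses_path),
        ("panel", config.panel_path),
    ):
        if path is not None:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file {path} does not exist")
            logger.info("input %s: %s sha256=%s", label, path, _checksum(path))

    panel = genetics.load_panel(config.panel_path)
    sim_config = cohort_mod.SimulationConfig(
        seed=config.seed, panel=panel, analysis_n=config.analysis_n
    )

    # --- cohort: simulated or loaded -----------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path, panel)
    elif "simulate" in stages:
        cohort = cohort_mod.analysis_cohort(sim_config)
        write_cohort(cohort, out_dir / "cohort.csv")
        sim_config_echo = {
            "seed": config.seed,
            "analysis_n": config.analysis_n,
            "n_simulated": int(sum(p.n_individuals for p in sim_config.profiles)),
            "noise_sd_health": sim_config.noise_sd_health,
            "noise_sd_genetic": sim_config.noise_sd_genetic,
        }
        (out_dir / "simulation_config.json").write_text(
            json.dumps(sim_config_echo, indent=2, sort_keys=True) + "\n"
        )
    else:
        raise ValueError(
            "no cohort available: enable the 'simulate' stage or provide cohort_path"
        )
    logger.info("cohort: %d individuals", len(cohort))

    if config.contamination_path is not None:
        contamination = ContaminationTable.from_csv(config.contamination_path)
        contamination_by_village: object = contamination
    else:
        contamination_by_village = cohort_mod.village_contamination(sim_config)
    doses = (
        read_reference_doses(config.doses_path)
        if config.doses_path is not None
        else cohort_mod.default_reference_doses()
    )

    report = RiskReport(config=config, cohort=cohort)

    if "exposure" in stages:
        exposure_table = cohort_exposure(cohort, contamination_by_village, PESTICIDE_GROUPS)
        flat = exposure_table.copy()
        flat.columns = [
            f"{group}_{stat}" if stat else group for group, stat in flat.columns
        ]
        flat.to_csv(out_dir / "village_exposure.csv", na_rep=NA)
        report.village_exposure = exposure_table
        logger.info("exposure: %d villages", len(exposure_table))

    if "genetics" in stages:
        summary = genetics.summarize_cohort_genotypes(cohort, panel, df=config.hwe_df)
        summary.to_csv(out_dir / "genetics_summary.csv", index=False, na_rep=NA)
        report.genetics_summary = summary
        logger.info("genetics: %d variants summarized", len(summary))

    design: pd.DataFrame | None = None
    if "fit" in stages or "predict" in stages:
        if "genetics" not in stages:
            raise ValueError(
                "dependency error: the 'fit'/'predict' stages need the "
                "'genetics' stage (cluster scores feed predictors X5-X7)"
            )
        design = regression.build_design(
            cohort, contamination_by_village, doses, panel,
            summary=config.summary, coding=config.coding,
        )
        design.to_csv(out_dir / "design_matrix.csv", index=False, na_rep=NA)

    if "fit" in stages:
        for outcome, column, critical in (
            ("health", "health_rank", regression.CRITICAL_T_HEALTH),
            ("genetic", "aberration_pct", regression.CRITICAL_T_GENETIC),
        ):
            if column not in cohort.columns or cohort[column].isna().any():
                raise ValueError(f"outcome column {column!r} missing; cannot fit")
            fit = regression.fit_ols(design, cohort[column])
            shares = regression.influence_shares(fit, design, cohort[column])
            table = fit.coef_table()
            table["significant"] = regression.coefficient_significance(fit, critical)
            table.to_csv(out_dir / f"fit_{outcome}.csv", na_rep=NA)
            shares.to_csv(out_dir / f"influence_{outcome}.csv", na_rep=NA)
            report.fits[outcome] = fit
            report.influence[outcome] = shares
            logger.info("fit %s: R2=%.4f adjR2=%.4f", outcome, fit.r2, fit.r2_adj)

    if "predict" in stages:
        predicted = pd.DataFrame(
            {
                "id": cohort["id"],
                "health_score": regression.predict_risk_frame(
                    design, regression.HEALTH_WEIGHTS
                ),
                "genetic_score": regression.predict_risk_frame(
                    design, regression.GENETIC_WEIGHTS
                ),
            }
        )
        predicted["health_high_risk"] = (
            predicted["health_score"] > predicted["health_score"].mean()
        )
        predicted["genetic_high_risk"] = (
            predicted["genetic_score"] > predicted["genetic_score"].mean()
        )
        predicted.to_csv(out_dir / "predicted_scores.csv", index=False, na_rep=NA)
        report.predicted = predicted
        for outcome, column, score in (
            ("health", "health_rank", "health_score"),
            ("genetic", "aberration_pct", "genetic_score"),
        ):
            if column in cohort.columns and cohort[column].notna().all():
                try:
                    report.predictive_ability[outcome] = regression.predictive_ability(
                        predicted[score], cohort[column]
                    )
                except ValueError:
                    report.predictive_ability[outcome] = float("nan")

    if "report" in stages:
        lines = [
            f"ocprisk report (seed={config.seed}, config={config.digest()})",
            f"individuals: {len(cohort)}",
        ]
        for outcome, fit in report.fits.items():
            lines.append(
                f"{outcome} model: R2={fit.r2:.4f} adjusted R2={fit.r2_adj:.4f} "
                f"explained variability {100 * fit.r2:.2f}%"
            )
        for outcome, value in report.predictive_ability.items():
            lines.append(f"{outcome} predictive ability: {value:.3f}")
        (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    logger.info("pipeline done")
    return report
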