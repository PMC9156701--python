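"""End-to-end pipeline: phenotyping -> spatial metrics -> patient aggregation
-> spatial immune score -> inference, with a provenance record sufficient to
re-run bit-identically."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    METRIC_COLUMNS,
    build_cohort_matrix,
    build_image_metric_table,
    build_sample_matrix,
)
from .phenotyping import assign_phenotypes
from .score import engagement_pdl1_groups, spatial_immune_score
from .stats import compare_groups, km_logrank, roc_compare

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    um_per_px: float = 0.496
    radius_t_um: float = 15.0
    radius_apc_ec_um: float = 40.0
    gcross_r_max_um: float = 50.0
    gcross_step_um: float = 1.0
    quantile_convention: str = "linear"
    test_policy: str = "auto"
    bh_alpha: float = 0.05
    group_rule: str = "median"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("um_per_px", "radius_t_um", "radius_apc_ec_um",
                     "gcross_r_max_um", "gcross_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.bh_alpha < 1.0:
            raise ValueError("bh_alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: "str | Path") -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    tables: "list[ImageCellTable]",
    cohort: pd.DataFrame,
    output_dir: "str | Path | None" = None,
) -> dict:
    """Execute the full analysis and write all result files.

    Returns a dict of in-memory results (patient matrix, scores, comparisons,
    ROC, survival, provenance).  Any stage failure aborts before outputs are
    written.  Deterministic for fixed inputs and config.
    """
    if not tables:
        raise ValueError("pipeline: no cell tables supplied")
    if cohort.empty:
        raise ValueError("pipeline: empty cohort table")
    results: dict = {}
    radius_overrides = _radius_overrides(config)

    stage = "phenotyping"
    try:
        tables = [
            dataclasses.replace(t, cells=assign_phenotypes(t.cells))
            if "phenotype" not in t.cells.columns else t
            for t in tables
        ]
        stage = "spatial_metrics/aggregation"
        gkw = dict(gcross_r_max_um=config.gcross_r_max_um,
                   gcross_step_um=config.gcross_step_um,
                   radii_um=radius_overrides)
        image_metrics = build_image_metric_table(tables, **gkw)
        sample_matrix = build_sample_matrix(tables, **gkw)
        matrix = build_cohort_matrix(tables, cohort, **gkw)
        stage = "scoring"
        score_result = spatial_immune_score(matrix, convention=config.quantile_convention)
        groups = engagement_pdl1_groups(matrix, rule=config.group_rule)
        stage = "stats_inference"
        comparisons = compare_groups(
            matrix, METRIC_COLUMNS, policy=config.test_policy, alpha=config.bh_alpha
        )
        roc_pdl1, roc_combined, delta_auc = roc_compare(matrix)
        survival = None
        if {"time_months", "event"} <= set(cohort.columns):
            surv_df = matrix.merge(
                score_result.scores[["patient_id", "dichotomy"]], on="patient_id"
            ).dropna(subset=["dichotomy"])
            surv_df = surv_df.rename(columns={"dichotomy": "stratum"})
            if surv_df["stratum"].nunique() >= 2 and surv_df["event"].sum() >= 1:
                survival = km_logrank(surv_df)
            else:
                logger.warning("survival analysis skipped: need >=2 score strata with events")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    results.update(
        image_metrics=image_metrics,
        sample_matrix=sample_matrix,
        patient_matrix=matrix,
        scores=score_result.scores,
        cutpoints=score_result.cutpoints,
        groups=groups,
        comparisons=comparisons,
        roc={"pdl1_only": roc_pdl1, "pdl1_plus_spatial": roc_combined,
             "delta_auc": delta_auc},
        survival=survival,
    )
    results["provenance"] = _provenance(config)
    if output_dir is not None:
        _write_outputs(results, config, Path(output_dir))
    return results


def _radius_overrides(config: RunConfig) -> dict:
    return {
        "CTL": config.radius_t_um, "HTL": config.radius_t_um,
        "Treg": config.radius_t_um,
        "APC": config.radius_apc_ec_um, "EC": config.radius_apc_ec_um,
    }


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "spatialtme",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }


def _write_outputs(results: dict, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    for name in ("image_metrics", "sample_matrix", "patient_matrix",
                 "scores", "groups", "comparisons"):
        df = results[name]
        df = df.copy()
        df["config_hash"] = h
        df.to_csv(outdir / f"{name}.csv", index=False)
    roc = results["roc"]
    roc_record = {
        "config_hash": h,
        "delta_auc": roc["delta_auc"],
        "models": {
            label: {
                "predictors": r.predictors,
                "coefficients": r.coefficients,
                "auc": r.auc,
                "separation_flagged": r.separation_flagged,
            }
            for label, r in roc.items()
            if label != "delta_auc"
        },
    }
    (outdir / "roc.json").write_text(json.dumps(roc_record, indent=2))
    for label, r in ((k, v) for k, v in roc.items() if k != "delta_auc"):
        curve = r.curve.copy()
        curve["config_hash"] = h
        curve.to_csv(outdir / f"roc_curve_{label}.csv", index=False)
    cut = dict(results["cutpoints"])
    cut["config_hash"] = h
    (outdir / "cutpoints.json").write_text(json.dumps(cut, indent=2))
    surv = results["survival"]
    if surv is not None:
        curves = surv.curves.copy()
        curves["config_hash"] = h
        curves.to_csv(outdir / "km_curves.csv", index=False)
        (outdir / "survival_tests.json").write_text(
            json.dumps(
                {
                    "config_hash": h,
                    "chi_sq": surv.chi_sq,
                    "p_value": surv.p_value,
                    "medians": {k: (None if pd.isna(v) else v) for k, v in surv.medians.items()},
                },
                indent=2,
            )
        )
    (outdir / "provenance.json").write_text(json.dumps(results["provenance"], indent=2))
    logger.info("wrote pipeline outputs to %s (config %s)", outdir, h)
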