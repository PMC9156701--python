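"""Collapse image-level metrics to patient-level values.

Each image is analysed independently; patient values are weighted means of
image values, weighted by the metric's per-image denominator count (focal
cells for engagement, ECs for TPS and EC nearest-neighbor summaries, CTLs for
the CTL->EC G-cross AUC).  With these weights the patient value equals the
estimate obtained by pooling all the patient's cells, which is the reading we
adopt for the per-patient "weighted mean".  Multi-sample patients pool all
their images.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .phenotyping import ImageCellTable, compute_tps
from .spatial import engagement, gcross, nearest_neighbor

logger = logging.getLogger(__name__)

#: Ordered (focal, target) engagement pairs carried through the analysis.
ENGAGEMENT_PAIRS = [
    ("APC", "T"),
    ("APC", "CTL"),
    ("HTL", "CTL"),
    ("Treg", "CTL"),
    ("EC", "T"),
    ("EC", "CTL"),
]

ENGAGEMENT_COLUMNS = {pair: f"eng_{pair[0].lower()}_{pair[1].lower()}" for pair in ENGAGEMENT_PAIRS}

#: All patient-level metric columns, in output order.
METRIC_COLUMNS = (
    ["tps_pct"]
    + list(ENGAGEMENT_COLUMNS.values())
    + ["mean_nn_ec_to_ctl_um", "gcross_auc_ctl_ec"]
)


def weighted_patient_mean(image_values, image_weights) -> float:
    """Weighted mean over a patient's images; missing (NaN) images dropped.

    Weights are the metric's per-image denominator counts.  Returns NaN when
    every image is missing or all usable weights are zero.
    """
    v = np.asarray(image_values, dtype=float)
    w = np.asarray(image_weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    ok = np.isfinite(v) & (w > 0)
    if not ok.any():
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def image_metrics(
    table: ImageCellTable,
    metrics: "list[str] | None" = None,
    gcross_r_max_um: float = 50.0,
    gcross_step_um: float = 1.0,
    radii_um: "dict[str, float] | None" = None,
) -> dict:
    """One image's metric values plus their aggregation weights.

    Returns a flat dict: identifiers, each metric value, and ``w_<metric>``
    denominator counts.  Undefined metrics (empty denominators) are NaN with
    weight 0.
    """
    wanted = set(METRIC_COLUMNS if metrics is None else metrics)
    row: dict = {
        "image_id": table.image_id,
        "sample_id": table.sample_id,
        "patient_id": table.patient_id,
        "n_cells": table.n_cells,
    }
    counts = table.phenotype_counts()
    if "tps_pct" in wanted:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["tps_pct"] = compute_tps(table)
        row["w_tps_pct"] = counts["EC"]
    for pair, col in ENGAGEMENT_COLUMNS.items():
        if col not in wanted:
            continue
        radius = None if radii_um is None else radii_um.get(pair[0])
        res = engagement(table, pair[0], pair[1], radius_um=radius)
        row[col] = res.fraction
        row[f"w_{col}"] = res.n_focal
    if "mean_nn_ec_to_ctl_um" in wanted:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nn = nearest_neighbor(table, "EC", "CTL")
        row["mean_nn_ec_to_ctl_um"] = nn.mean_um
        row["w_mean_nn_ec_to_ctl_um"] = len(nn.distances_um)
    if "gcross_auc_ctl_ec" in wanted:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc = gcross(table, "CTL", "EC", r_max_um=gcross_r_max_um, step_um=gcross_step_um)
        row["gcross_auc_ctl_ec"] = gc.auc
        row["w_gcross_auc_ctl_ec"] = counts["CTL"] if gc.defined else 0
    return row


def build_image_metric_table(
    tables: "list[ImageCellTable]", metrics: "list[str] | None" = None, **gcross_kw
) -> pd.DataFrame:
    return pd.DataFrame([image_metrics(t, metrics=metrics, **gcross_kw) for t in tables])


def build_sample_matrix(
    tables: "list[ImageCellTable]", metrics: "list[str] | None" = None, **gcross_kw
) -> pd.DataFrame:
    """Sample-level weighted means (same weighting as patients); supports
    within-patient heterogeneity checks for multi-sample patients."""
    img = build_image_metric_table(tables, metrics=metrics, **gcross_kw)
    metric_cols = [c for c in METRIC_COLUMNS if c in img.columns]
    rows = []
    for (pid, sid), grp in img.groupby(["patient_id", "sample_id"], sort=False):
        row = {"patient_id": pid, "sample_id": sid, "n_images": len(grp)}
        for col in metric_cols:
            row[col] = weighted_patient_mean(grp[col], grp[f"w_{col}"])
        rows.append(row)
    return pd.DataFrame(rows)


def build_cohort_matrix(
    tables: "list[ImageCellTable]",
    cohort: pd.DataFrame,
    metrics: "list[str] | None" = None,
    **gcross_kw,
) -> pd.DataFrame:
    """Patient-level analysis matrix: one row per patient, weighted-mean
    metric columns, response label and any survival columns carried through.

    Raises when an image belongs to a patient absent from the cohort table.
    """
    if "patient_id" not in cohort.columns:
        raise ValueError("cohort table must have a patient_id column")
    known = set(cohort["patient_id"])
    orphans = sorted({t.image_id for t in tables if t.patient_id not in known})
    if orphans:
        raise ValueError(
            f"images with unknown patient: {', '.join(orphans[:10])}"
            + (" ..." if len(orphans) > 10 else "")
        )
    img = build_image_metric_table(tables, metrics=metrics, **gcross_kw)
    metric_cols = [c for c in METRIC_COLUMNS if c in img.columns]
    rows = []
    for pid, grp in img.groupby("patient_id", sort=False):
        row = {"patient_id": pid, "n_images": len(grp)}
        for col in metric_cols:
            value = weighted_patient_mean(grp[col], grp[f"w_{col}"])
            if np.isnan(value):
                logger.warning("patient %s: metric %s missing in all images", pid, col)
            row[col] = value
        rows.append(row)
    matrix = pd.DataFrame(rows)
    carry = [c for c in ("response", "time_months", "event") if c in cohort.columns]
    per_patient = cohort.drop_duplicates("patient_id")[["patient_id", *carry]]
    matrix = matrix.merge(per_patient, on="patient_id", how="left")
    missing_resp = matrix.loc[matrix.get("response").isna(), "patient_id"].tolist() if "response" in matrix else []
    if missing_resp:
        raise ValueError(f"patients without response label: {missing_resp}")
    return matrix
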