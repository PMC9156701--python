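"""Quartile-based spatial immune score and engagement x PD-L1 grouping.

Three patient-level metrics — EC PD-L1 TPS, HTL->CTL engagement, and EC<-CTL
engagement — are each ranked against the whole cohort's quartiles and awarded
0-3 points (3 for the top quartile).  The 0-9 total is dichotomised at
<=3 (low) vs >=4 (high).  A separate three-group stratification crosses
dichotomised CTL-EC engagement with dichotomised TPS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Patient-metric column backing each score component.
SCORE_COMPONENTS = {
    "points_tps": "tps_pct",
    "points_ctl_htl": "eng_htl_ctl",
    "points_ctl_ec": "eng_ec_ctl",
}

DICHOTOMY_THRESHOLD = 3  # total <= 3 -> "low", >= 4 -> "high"


def quartile_cutpoints(values, convention: str = "linear") -> tuple[float, float, float]:
    """(P25, P50, P75) of the non-missing cohort values, linear interpolation
    by default."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        raise ValueError(f"need >=4 non-missing cohort values, got {len(v)}")
    q = np.percentile(v, [25, 50, 75], method=convention)
    if q[0] == q[2]:
        logger.warning("degenerate quartiles (ties): P25 == P75 == %g", q[0])
    return float(q[0]), float(q[1]), float(q[2])


def quartile_points(cohort_values, value: float, convention: str = "linear") -> float:
    """Points for one value against cohort quartiles: 3 if >= P75, 2 if >= P50,
    1 if >= P25, else 0; ties at a boundary take the higher points.  Missing
    value -> NaN."""
    p25, p50, p75 = quartile_cutpoints(cohort_values, convention)
    if not np.isfinite(value):
        return float("nan")
    if value >= p75:
        return 3
    if value >= p50:
        return 2
    if value >= p25:
        return 1
    return 0


@dataclass
class ScoreResult:
    """Per-patient score table plus the cohort cutpoints that produced it."""

    scores: pd.DataFrame  # patient_id, points_*, total, dichotomy
    cutpoints: dict  # component -> {p25, p50, p75}, plus convention


def spatial_immune_score(
    patient_metrics: pd.DataFrame, convention: str = "linear"
) -> ScoreResult:
    """Compute the 0-9 spatial immune score for every patient.

    Quartile boundaries are computed on the pooled cohort (responders and
    non-responders together) per component.  A patient missing any component
    gets a missing score (with a warning) but keeps whatever points were
    computable.
    """
    df = patient_metrics
    cutpoints: dict = {"convention": convention}
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    for points_col, metric_col in SCORE_COMPONENTS.items():
        p25, p50, p75 = quartile_cutpoints(df[metric_col], convention)
        cutpoints[points_col] = {"metric": metric_col, "p25": p25, "p50": p50, "p75": p75}
        v = df[metric_col].to_numpy(dtype=float)
        pts = np.select([v >= p75, v >= p50, v >= p25], [3.0, 2.0, 1.0], default=0.0)
        pts[~np.isfinite(v)] = np.nan
        out[points_col] = pts
    pts_matrix = out[list(SCORE_COMPONENTS)].to_numpy()
    total = pts_matrix.sum(axis=1)  # NaN if any component missing
    out["total"] = total
    out["dichotomy"] = np.where(
        np.isnan(total), None, np.where(total <= DICHOTOMY_THRESHOLD, "low", "high")
    )
    n_missing = int(np.isnan(total).sum())
    if n_missing:
        logger.warning(
            "%d patients excluded from the spatial immune score "
            "(missing component metric)", n_missing,
        )
    return ScoreResult(scores=out, cutpoints=cutpoints)


def engagement_pdl1_groups(
    patient_metrics: pd.DataFrame,
    rule: str = "median",
    tps_threshold_pct: float = 1.0,
) -> pd.DataFrame:
    """Three-group stratification from dichotomised CTL-EC engagement and TPS.

    Group "1": high engagement / high PD-L1; "2": high engagement / low PD-L1;
    "3": low engagement / low PD-L1; the remaining low-engagement/high-PD-L1
    corner is "other".  ``rule`` is ``"median"`` (cohort-median cutpoints for
    both axes, the default) or ``"tps_threshold"`` (engagement at the cohort
    median, TPS at an absolute percent threshold, e.g. >= 1%).
    """
    df = patient_metrics
    eng = df["eng_ec_ctl"].to_numpy(dtype=float)
    tps = df["tps_pct"].to_numpy(dtype=float)
    eng_cut = float(np.nanmedian(eng))
    if rule == "median":
        tps_cut = float(np.nanmedian(tps))
        high_tps = tps >= tps_cut
    elif rule == "tps_threshold":
        tps_cut = tps_threshold_pct
        high_tps = tps >= tps_threshold_pct
    else:
        raise ValueError(f"unknown rule {rule!r}")
    high_eng = eng >= eng_cut
    group = np.select(
        [high_eng & high_tps, high_eng & ~high_tps, ~high_eng & ~high_tps],
        ["1", "2", "3"],
        default="other",
    ).astype(object)
    group[~np.isfinite(eng) | ~np.isfinite(tps)] = None
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "group": group,
            "engagement_cutpoint": eng_cut,
            "tps_cutpoint": tps_cut,
        }
    )
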