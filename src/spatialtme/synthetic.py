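"""Synthetic multiplex-IHC cell maps and cohorts.

Generates per-image segmented-cell tables with the statistical structure the
downstream analysis assumes:

* epithelial tumor cells (EC) in Gaussian nests, immune/stromal cells uniform;
* tunable cross-type *attraction*: for an ordered (focal, target) pair with
  probability p, each focal cell is placed uniformly inside the focal
  engagement radius of a random target cell (guaranteeing engagement), else
  by its base process — so planted engagement fractions are direct
  calibration targets;
* Bernoulli PD-L1 positivity on ECs and APCs whose per-image rates are
  coupled through a shared latent variable, giving a tunable positive
  cross-correlation while preserving the marginal rates;
* responder/non-responder cohorts with exponential survival times tied to the
  planted response stratum.

Everything is deterministic given the config seed; per-image streams are
keyed by (cohort seed, patient index, image index) so cohorts reproduce under
any generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import numpy as np
import pandas as pd
from scipy import stats

from .phenotyping import ImageCellTable, PHENOTYPES, T_CELL, T_CELL_TYPES
from .spatial import engagement, engagement_radius_um

__all__ = [
    "ImageSimConfig",
    "SurvivalModel",
    "CohortSimConfig",
    "generate_image",
    "generate_cohort",
    "measure_engagement",
    "chance_engagement",
    "calibrate_attraction",
    "calibrate_attractions",
    "default_image_profile",
    "RESPONDER_TARGETS",
    "NONRESPONDER_TARGETS",
]

# Cohort-mean calibration targets for the bundled two-arm demo cohort:
# engagement fractions per ordered (focal, target) pair plus the EC PD-L1
# tumor proportion score (percent).  The Treg->CTL entries are fabricated
# (direction only: higher in non-responders).
RESPONDER_TARGETS = {
    "tps_pct": 20.6,
    ("APC", "T"): 0.886,
    ("APC", "CTL"): 0.718,
    ("HTL", "CTL"): 0.627,
    ("Treg", "CTL"): 0.30,
    ("EC", "T"): 0.757,
    ("EC", "CTL"): 0.541,
}
NONRESPONDER_TARGETS = {
    "tps_pct": 5.6,
    ("APC", "T"): 0.784,
    ("APC", "CTL"): 0.542,
    ("HTL", "CTL"): 0.425,
    ("Treg", "CTL"): 0.45,
    ("EC", "T"): 0.607,
    ("EC", "CTL"): 0.338,
}

_COUNT_FIELDS = {
    "EC": "n_ec", "CTL": "n_ctl", "HTL": "n_htl",
    "Treg": "n_treg", "APC": "n_apc", "OTHER": "n_other",
}


@dataclass
class ImageSimConfig:
    """Knobs for one synthetic 20x field.

    ``attraction`` maps ordered (focal, target) phenotype pairs to the
    probability that a focal cell is planted within its engagement radius of a
    random target cell; the target may be a concrete phenotype or ``"T"`` (any
    T cell).  With several pairs sharing a focal phenotype the probabilities
    are applied sequentially (p1; then p2 on the remainder; ...) so each cell
    is placed exactly once; concrete-target pairs are allocated before pairs
    targeting the "T" union.
    """

    field_width_px: int = 934
    field_height_px: int = 700
    um_per_px: float = 0.496
    n_ec: int = 120
    n_ctl: int = 10
    n_htl: int = 10
    n_treg: int = 5
    n_apc: int = 20
    n_other: int = 50
    ec_cluster_count: int = 4
    ec_cluster_sd_um: float = 30.0
    pdl1_ec_rate: float = 0.15
    pdl1_apc_rate: float = 0.25
    pdl1_correlation: float = 0.0
    pdl1_concentration: float = 40.0  # Beta concentration of per-image rates
    attraction: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        for ph, f in _COUNT_FIELDS.items():
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.ec_cluster_count <= 0 or self.ec_cluster_sd_um <= 0:
            raise ValueError("EC cluster parameters must be positive")
        for name in ("pdl1_ec_rate", "pdl1_apc_rate", "pdl1_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pdl1_concentration <= 0:
            raise ValueError("pdl1_concentration must be positive")
        for (f, t), p in self.attraction.items():
            if f not in PHENOTYPES:
                raise ValueError(f"unknown focal phenotype {f!r} in attraction")
            if t not in PHENOTYPES and t != T_CELL:
                raise ValueError(f"unknown target phenotype {t!r} in attraction")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"attraction[{(f, t)}] must be in [0, 1], got {p}")

    def count(self, phenotype: str) -> int:
        if phenotype == T_CELL:
            return self.n_ctl + self.n_htl + self.n_treg
        return int(getattr(self, _COUNT_FIELDS[phenotype]))

    def replace(self, **changes) -> "ImageSimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class SurvivalModel:
    """Exponential survival with administrative censoring.

    ``hazard_ratio`` multiplies the baseline hazard for patients in the
    planted low-score stratum (the non-responder arm), so values > 1 shorten
    non-responder survival.
    """

    baseline_hazard: float = 0.03  # events per month in the responder stratum
    hazard_ratio: float = 3.0
    censor_horizon_months: float = 36.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ValueError("hazard parameters must be > 0")
        if self.censor_horizon_months <= 0:
            raise ValueError("censor_horizon_months must be > 0")


@dataclass
class CohortSimConfig:
    n_patients: int = 52
    images_per_patient: int | tuple[int, int] = 2
    responder_fraction: float = 0.57
    responder_profile: ImageSimConfig = field(default_factory=lambda: ImageSimConfig())
    nonresponder_profile: ImageSimConfig = field(default_factory=lambda: ImageSimConfig())
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        ipp = self.images_per_patient
        if isinstance(ipp, int):
            if ipp < 1:
                raise ValueError("images_per_patient must be >= 1")
        else:
            lo, hi = ipp
            if lo < 1 or hi < lo:
                raise ValueError("images_per_patient range must satisfy 1 <= lo <= hi")


def _placement_order(attraction: dict[tuple[str, str], float]) -> list[str]:
    """Topological placement order so every attraction target is placed before
    its focal phenotype; raises on cyclic dependencies."""
    deps: dict[str, set[str]] = {ph: set() for ph in PHENOTYPES}
    for (focal, target), p in attraction.items():
        if p <= 0:
            continue
        targets = T_CELL_TYPES if target == T_CELL else (target,)
        deps[focal].update(t for t in targets if t != focal)
    try:
        order = list(TopologicalSorter(deps).static_order())
    except Exception as exc:  # CycleError
        raise ValueError(f"cyclic attraction dependencies: {exc}") from exc
    return order


def _uniform_positions(rng, n, w, h):
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def _clustered_positions(rng, n, w, h, n_clusters, sd_px, max_rounds=200):
    centers = _uniform_positions(rng, n_clusters, w, h)
    which = rng.integers(0, n_clusters, n)
    pos = centers[which] + rng.normal(0.0, sd_px, (n, 2))
    for _ in range(max_rounds):
        bad = ~_inside(pos, w, h)
        if not bad.any():
            break
        k = int(bad.sum())
        pos[bad] = centers[which[bad]] + rng.normal(0.0, sd_px, (k, 2))
    np.clip(pos[:, 0], 0, w, out=pos[:, 0])
    np.clip(pos[:, 1], 0, h, out=pos[:, 1])
    return pos


def _inside(pos, w, h):
    return (
        (pos[:, 0] >= 0) & (pos[:, 0] <= w) & (pos[:, 1] >= 0) & (pos[:, 1] <= h)
    )


def _near_targets(rng, targets, n, radius_px, w, h, max_rounds=200):
    """n points uniform in the radius-px disk around random target cells,
    rejected back inside the field (targets are in-field, so this
    terminates; stragglers collapse onto their target)."""
    t_idx = rng.integers(0, len(targets), n)
    pos = targets[t_idx] + _disk(rng, n, radius_px)
    for _ in range(max_rounds):
        bad = ~_inside(pos, w, h)
        if not bad.any():
            return pos
        k = int(bad.sum())
        t_idx[bad] = rng.integers(0, len(targets), k)
        pos[bad] = targets[t_idx[bad]] + _disk(rng, k, radius_px)
    bad = ~_inside(pos, w, h)
    pos[bad] = targets[t_idx[bad]]
    return pos


def _disk(rng, n, radius):
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _latent_rate(p: float, v: float, concentration: float) -> float:
    """Quantile of a Beta with mean p at latent level v; mean-preserving."""
    if p <= 0.0 or p >= 1.0:
        return p
    a = p * concentration
    b = (1.0 - p) * concentration
    return float(stats.beta.ppf(v, a, b))


def generate_image(
    config: ImageSimConfig,
    image_id: str = "img-000",
    sample_id: str = "s-000",
    patient_id: str = "p-000",
) -> ImageCellTable:
    """Generate one synthetic field.

    Cell counts per phenotype match the config exactly.  ECs follow the
    cluster process, every other phenotype is uniform, except that cells
    claimed by an attraction entry are planted within the focal engagement
    radius of a random target cell.  Raises when an attraction entry points at
    a phenotype with zero configured cells.
    """
    rng = np.random.default_rng(config.seed)
    w, h = float(config.field_width_px), float(config.field_height_px)
    attraction = {k: v for k, v in config.attraction.items() if v > 0}
    for (f, t) in attraction:
        if config.count(t) == 0:
            raise ValueError(
                f"attraction pair ({f!r}, {t!r}) targets a phenotype with zero cells"
            )
    order = _placement_order(attraction)
    sd_px = config.ec_cluster_sd_um / config.um_per_px
    positions: dict[str, np.ndarray] = {}
    for ph in order:
        n = config.count(ph)
        if n == 0:
            positions[ph] = np.empty((0, 2))
            continue
        # Concrete targets are allocated before the "T" union so that a
        # specific pair (e.g. EC<-CTL) keeps its own probability budget even
        # when a union pair (EC<-T) shares the focal phenotype.
        pairs = sorted(
            ((t, p) for (f, t), p in attraction.items() if f == ph),
            key=lambda tp: tp[0] == T_CELL,
        )
        choice = np.full(n, -1)
        remaining = np.ones(n, dtype=bool)
        for i, (_t, p) in enumerate(pairs):
            take = remaining & (rng.random(n) < p)
            choice[take] = i
            remaining &= ~take
        pos = np.empty((n, 2))
        n_base = int(remaining.sum())
        if ph == "EC":
            base = _clustered_positions(
                rng, n_base, w, h, config.ec_cluster_count, sd_px
            )
        else:
            base = _uniform_positions(rng, n_base, w, h)
        pos[remaining] = base
        radius_px = engagement_radius_um(ph) / config.um_per_px
        for i, (t, _p) in enumerate(pairs):
            idx = choice == i
            if not idx.any():
                continue
            targets = (
                np.vstack([positions[q] for q in T_CELL_TYPES])
                if t == T_CELL
                else positions[t]
            )
            pos[idx] = _near_targets(rng, targets, int(idx.sum()), radius_px, w, h)
        positions[ph] = pos

    # PD-L1: per-image EC/APC rates from a shared-latent uniform mixture.
    # Each arm's latent equals the shared uniform with probability
    # pdl1_correlation, so the rate correlation grows with the knob while the
    # Beta-quantile transform preserves the marginal means.  With the knob at
    # zero the rates are the configured constants (pure binomial images).
    rho = config.pdl1_correlation
    if rho > 0:
        u_shared = rng.random()
        u_ec, u_apc = rng.random(2)
        v_ec = u_shared if rng.random() < rho else u_ec
        v_apc = u_shared if rng.random() < rho else u_apc
        rate_ec = _latent_rate(config.pdl1_ec_rate, v_ec, config.pdl1_concentration)
        rate_apc = _latent_rate(config.pdl1_apc_rate, v_apc, config.pdl1_concentration)
    else:
        rate_ec = config.pdl1_ec_rate
        rate_apc = config.pdl1_apc_rate

    frames = []
    marker_map = {
        "CTL": dict(cd3=1, cd8=1),
        "HTL": dict(cd3=1),
        "Treg": dict(cd3=1, foxp3=1),
        "APC": dict(cd163=1),
        "EC": dict(panck=1),
        "OTHER": {},
    }
    for ph in PHENOTYPES:  # canonical order, independent of placement order
        pos = positions[ph]
        n = len(pos)
        df = pd.DataFrame(
            {
                "x_px": pos[:, 0],
                "y_px": pos[:, 1],
                "cd3": 0, "cd8": 0, "foxp3": 0, "cd163": 0, "panck": 0, "pdl1": 0,
                "phenotype": ph,
            }
        )
        for col, val in marker_map[ph].items():
            df[col] = val
        if ph == "EC" and n:
            df["pdl1"] = (rng.random(n) < rate_ec).astype(int)
        elif ph == "APC" and n:
            df["pdl1"] = (rng.random(n) < rate_apc).astype(int)
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", [f"{image_id}-c{i:05d}" for i in range(len(cells))])
    return ImageCellTable(
        image_id=image_id,
        sample_id=sample_id,
        patient_id=patient_id,
        cells=cells,
        um_per_px=config.um_per_px,
    )


def _image_seed(cohort_seed: int, patient_index: int, image_index: int) -> int:
    ss = np.random.SeedSequence([cohort_seed, patient_index, image_index])
    return int(ss.generate_state(1)[0])


def generate_cohort(
    config: CohortSimConfig,
) -> tuple[list[ImageCellTable], pd.DataFrame]:
    """Generate per-image cell tables plus a cohort table.

    The cohort table has one row per patient: patient_id, sample_id, response
    ("responder"/"non_responder"), time_months, event.  Responders are the
    first round(responder_fraction x n) patients; survival is exponential
    with the non-responder hazard multiplied by the model's hazard ratio and
    administrative censoring at the horizon.
    """
    n_resp = round(config.responder_fraction * config.n_patients)
    tables: list[ImageCellTable] = []
    rows = []
    sm = config.survival_model
    for i in range(config.n_patients):
        is_resp = i < n_resp
        profile = config.responder_profile if is_resp else config.nonresponder_profile
        pid = f"P{i:03d}"
        sid = f"{pid}-S0"
        prng = np.random.default_rng(
            np.random.SeedSequence([config.seed, i, 999_983])
        )
        ipp = config.images_per_patient
        n_img = ipp if isinstance(ipp, int) else int(prng.integers(ipp[0], ipp[1] + 1))
        for j in range(n_img):
            img_cfg = profile.replace(seed=_image_seed(config.seed, i, j))
            tables.append(
                generate_image(
                    img_cfg,
                    image_id=f"{pid}-I{j:03d}",
                    sample_id=sid,
                    patient_id=pid,
                )
            )
        hazard = sm.baseline_hazard * (1.0 if is_resp else sm.hazard_ratio)
        t = float(prng.exponential(1.0 / hazard))
        event = t <= sm.censor_horizon_months
        rows.append(
            {
                "patient_id": pid,
                "sample_id": sid,
                "response": "responder" if is_resp else "non_responder",
                "time_months": min(t, sm.censor_horizon_months),
                "event": int(event),
                "n_images": n_img,
            }
        )
    return tables, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration: planted attraction -> measured engagement
# ---------------------------------------------------------------------------

def measure_engagement(
    config: ImageSimConfig,
    pairs: "list[tuple[str, str]]",
    n_images: int,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Pooled engagement fraction per (focal, target) pair over n_images
    independent fields (focal-count weighted, i.e. engaged/focal pooled)."""
    engaged = {pair: 0 for pair in pairs}
    focal = {pair: 0 for pair in pairs}
    for k in range(n_images):
        img = generate_image(
            config.replace(seed=_image_seed(seed, 0, k)), image_id=f"cal-{k:04d}"
        )
        for pair in pairs:
            res = engagement(img, pair[0], pair[1])
            engaged[pair] += res.n_engaged
            focal[pair] += res.n_focal
    return {
        pair: (engaged[pair] / focal[pair] if focal[pair] else float("nan"))
        for pair in pairs
    }


def chance_engagement(
    config: ImageSimConfig,
    pair: tuple[str, str],
    n_images: int = 100,
    seed: int = 0,
) -> float:
    """Monte-Carlo baseline engagement for a pair with its attraction zeroed
    (all other attraction entries left as configured)."""
    attraction = dict(config.attraction)
    attraction.pop(pair, None)
    null_cfg = config.replace(attraction=attraction)
    return measure_engagement(null_cfg, [pair], n_images, seed=seed)[pair]


def calibrate_attraction(
    config: ImageSimConfig,
    pair: tuple[str, str],
    target_fraction: float,
    n_images: int = 100,
    seed: int = 0,
) -> float:
    """Attraction probability p such that the measured engagement of ``pair``
    is approximately ``target_fraction``.

    Uses measured = p + (1 - p) * u, with u the chance-engagement baseline
    from a null-attraction run — exact when ``pair`` is the only attraction
    entry for its focal phenotype.  Raises when the target sits below chance.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    u = chance_engagement(config, pair, n_images=n_images, seed=seed)
    if not np.isfinite(u):
        raise ValueError(f"chance engagement undefined for pair {pair}")
    if target_fraction < u:
        raise ValueError(
            f"target engagement {target_fraction:.3f} for {pair} is below the "
            f"chance baseline {u:.3f}; reduce target-cell density"
        )
    if u >= 1.0:
        return 0.0
    return float((target_fraction - u) / (1.0 - u))


def calibrate_attractions(
    config: ImageSimConfig,
    targets: dict[tuple[str, str], float],
    n_images: int = 80,
    n_iter: int = 4,
    n_images_final: int | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Jointly calibrate several attraction entries by Newton-style fixed-point
    iteration against Monte-Carlo engagement measurements.

    Handles interacting pairs (shared focal phenotypes, nested targets such as
    CTL within "T") that the single-pair closed form cannot.  Because each
    update replaces the previous error with the latest measurement's noise,
    the final iteration uses a larger batch (``n_images_final``, default
    3 x ``n_images``) to pin down the result.
    """
    if n_images_final is None:
        n_images_final = 3 * n_images
    pairs = list(targets)
    base_attr = {k: v for k, v in config.attraction.items() if k not in targets}
    null_cfg = config.replace(attraction=base_attr)
    u = measure_engagement(null_cfg, pairs, n_images, seed=seed)
    p: dict[tuple[str, str], float] = {}
    for pair in pairs:
        if targets[pair] < u[pair]:
            raise ValueError(
                f"target engagement {targets[pair]:.3f} for {pair} is below "
                f"the chance baseline {u[pair]:.3f}"
            )
        slope = max(1.0 - u[pair], 1e-6)
        p[pair] = float(np.clip((targets[pair] - u[pair]) / slope, 0.0, 1.0))
    for it in range(n_iter):
        batch = n_images_final if it == n_iter - 1 else n_images
        cfg = config.replace(attraction={**base_attr, **p})
        m = measure_engagement(cfg, pairs, batch, seed=seed + 1 + it)
        for pair in pairs:
            slope = max(1.0 - u[pair], 1e-6)
            p[pair] = float(
                np.clip(p[pair] + (targets[pair] - m[pair]) / slope, 0.0, 1.0)
            )
    return p


def default_image_profile(**overrides) -> ImageSimConfig:
    """Baseline field profile used by the demo cohort (no attraction planted).

    Uses a larger field than the ImageSimConfig default so that chance
    engagement sits comfortably below the calibration targets for every
    (focal, target) pair — at the 934x700 px default the 40 um baseline is too
    close to several target fractions for the attraction knob to have room in
    both directions.
    """
    defaults = dict(
        field_width_px=1300,
        field_height_px=1000,
        n_ec=120,
        n_ctl=10,
        n_htl=20,
        n_treg=8,
        n_apc=24,
        n_other=60,
    )
    defaults.update(overrides)
    return ImageSimConfig(**defaults)
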