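import numpy as np
import pandas as pd
import pytest

from spatialtme.phenotyping import pdl1_correlation
from spatialtme.spatial import engagement
from spatialtme.synthetic import (
    CohortSimConfig,
    ImageSimConfig,
    SurvivalModel,
    calibrate_attraction,
    chance_engagement,
    default_image_profile,
    generate_cohort,
    generate_image,
    measure_engagement,
)


def small_profile(**kw):
    defaults = dict(
        field_width_px=600, field_height_px=500,
        n_ec=40, n_ctl=15, n_htl=10, n_treg=5, n_apc=10, n_other=20,
        seed=0,
    )
    defaults.update(kw)
    return ImageSimConfig(**defaults)


class TestConfigValidation:
    def test_negative_count(self):
        with pytest.raises(ValueError, match="n_ctl"):
            ImageSimConfig(n_ctl=-1)

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError, match="pdl1_ec_rate"):
            ImageSimConfig(pdl1_ec_rate=1.2)

    def test_bad_attraction_probability(self):
        with pytest.raises(ValueError, match="attraction"):
            ImageSimConfig(attraction={("CTL", "EC"): 1.5})

    def test_unknown_phenotype_in_attraction(self):
        with pytest.raises(ValueError, match="NK"):
            ImageSimConfig(attraction={("NK", "EC"): 0.5})

    def test_zero_dimension(self):
        with pytest.raises(ValueError, match="dimensions"):
            ImageSimConfig(field_width_px=0)

    def test_survival_model_positivity(self):
        with pytest.raises(ValueError):
            SurvivalModel(baseline_hazard=0.0)

    def test_cohort_needs_patients(self):
        with pytest.raises(ValueError, match="n_patients"):
            CohortSimConfig(n_patients=0)


class TestGenerateImage:
    def test_seeded_determinism(self):
        cfg = small_profile(seed=11, attraction={("CTL", "EC"): 0.4})
        a = generate_image(cfg)
        b = generate_image(cfg)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_different_seeds_differ(self):
        a = generate_image(small_profile(seed=1))
        b = generate_image(small_profile(seed=2))
        assert not a.cells[["x_px", "y_px"]].equals(b.cells[["x_px", "y_px"]])

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_exact_phenotype_counts(self, seed):
        cfg = small_profile(seed=seed)
        counts = generate_image(cfg).phenotype_counts()
        assert counts == {
            "EC": 40, "CTL": 15, "HTL": 10, "Treg": 5, "APC": 10, "OTHER": 20
        }

    @pytest.mark.parametrize("seed", [0, 5, 99])
    def test_coordinates_inside_field(self, seed):
        cfg = small_profile(seed=seed, attraction={("CTL", "EC"): 0.8, ("HTL", "CTL"): 0.5})
        img = generate_image(cfg)
        assert img.cells["x_px"].between(0, cfg.field_width_px).all()
        assert img.cells["y_px"].between(0, cfg.field_height_px).all()

    def test_full_attraction_forces_engagement(self):
        cfg = ImageSimConfig(
            n_ctl=50, n_ec=50, n_htl=0, n_treg=0, n_apc=0, n_other=0,
            attraction={("CTL", "EC"): 1.0}, seed=3,
        )
        img = generate_image(cfg)
        assert engagement(img, "CTL", "EC").fraction == 1.0

    def test_attraction_to_empty_phenotype_errors(self):
        cfg = small_profile(n_ec=0, attraction={("CTL", "EC"): 0.5})
        with pytest.raises(ValueError, match="'CTL'.*'EC'"):
            generate_image(cfg)

    def test_cyclic_attraction_errors(self):
        cfg = small_profile(attraction={("CTL", "EC"): 0.5, ("EC", "CTL"): 0.5})
        with pytest.raises(ValueError, match="cyclic"):
            generate_image(cfg)

    def test_markers_consistent_with_phenotype(self):
        from spatialtme.phenotyping import assign_phenotypes

        img = generate_image(small_profile(seed=21, pdl1_ec_rate=0.5, pdl1_apc_rate=0.5))
        redone = assign_phenotypes(img.cells.drop(columns="phenotype"))
        assert (redone["phenotype"] == img.cells["phenotype"]).all()

    def test_half_attraction_hits_planted_rate(self):
        # measured engagement should be p + (1 - p) * u, with u the chance
        # baseline from an independent brute-force Monte-Carlo oracle
        p = 0.5
        cfg = ImageSimConfig(
            n_ctl=200, n_ec=30, n_htl=0, n_treg=0, n_apc=0, n_other=0,
            ec_cluster_count=4, ec_cluster_sd_um=30.0,
            attraction={("CTL", "EC"): p}, seed=17,
        )
        u = _oracle_chance_ctl_ec(cfg, n_images=150, seed=4)
        measured = measure_engagement(cfg, [("CTL", "EC")], 100, seed=9)[("CTL", "EC")]
        assert measured == pytest.approx(p + (1 - p) * u, abs=0.05)

    def test_pdl1_rate_concentration(self):
        cfg = small_profile(pdl1_ec_rate=0.3, pdl1_correlation=0.5, n_ec=100)
        rates = []
        for k in range(200):
            img = generate_image(cfg.replace(seed=k))
            rates.append(img.select("EC")["pdl1"].mean())
        assert np.mean(rates) == pytest.approx(0.3, abs=0.02)

    def test_pdl1_uncorrelated_at_zero(self):
        cfg = small_profile(pdl1_ec_rate=0.2, pdl1_apc_rate=0.3, n_ec=60, n_apc=30,
                            pdl1_correlation=0.0)
        fracs = [
            (img.select("EC")["pdl1"].mean(), img.select("APC")["pdl1"].mean())
            for img in (generate_image(cfg.replace(seed=k)) for k in range(500))
        ]
        r = pdl1_correlation(*map(np.array, zip(*fracs))).r
        assert abs(r) < 0.1

    def test_pdl1_correlation_nondecreasing(self):
        rs = []
        for rho in (0.0, 0.5, 1.0):
            cfg = default_image_profile(
                pdl1_ec_rate=0.2, pdl1_apc_rate=0.3, pdl1_correlation=rho
            )
            fracs = [
                (img.select("EC")["pdl1"].mean(), img.select("APC")["pdl1"].mean())
                for img in (generate_image(cfg.replace(seed=k)) for k in range(300))
            ]
            rs.append(pdl1_correlation(*map(np.array, zip(*fracs))).r)
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.4


def _oracle_chance_ctl_ec(cfg, n_images, seed):
    """Independent Monte-Carlo oracle for chance CTL-EC engagement with no
    attraction: re-simulates the base processes (uniform CTLs, clustered ECs)
    and brute-forces pairwise distances."""
    rng = np.random.default_rng(seed)
    w, h = cfg.field_width_px, cfg.field_height_px
    sd = cfg.ec_cluster_sd_um / cfg.um_per_px
    radius_px = 15.0 / cfg.um_per_px
    engaged = total = 0
    for _ in range(n_images):
        centers = rng.uniform([0, 0], [w, h], (cfg.ec_cluster_count, 2))
        ec = centers[rng.integers(0, cfg.ec_cluster_count, cfg.n_ec)] + rng.normal(
            0, sd, (cfg.n_ec, 2)
        )
        ec = np.clip(ec, [0, 0], [w, h])
        ctl = rng.uniform([0, 0], [w, h], (cfg.n_ctl, 2))
        d2 = ((ctl[:, None, :] - ec[None, :, :]) ** 2).sum(-1)
        engaged += int((d2.min(axis=1) <= radius_px**2).sum())
        total += cfg.n_ctl
    return engaged / total


class TestGenerateCohort:
    def test_responder_allocation(self):
        cfg = CohortSimConfig(
            n_patients=100, images_per_patient=1, responder_fraction=0.57,
            responder_profile=small_profile(), nonresponder_profile=small_profile(),
            seed=0,
        )
        _, cohort = generate_cohort(cfg)
        assert (cohort["response"] == "responder").sum() == 57

    def test_determinism(self):
        cfg = CohortSimConfig(
            n_patients=4, images_per_patient=2,
            responder_profile=small_profile(), nonresponder_profile=small_profile(),
            seed=42,
        )
        t1, c1 = generate_cohort(cfg)
        t2, c2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_arms_use_their_profiles(self):
        cfg = CohortSimConfig(
            n_patients=10, images_per_patient=1, responder_fraction=0.5,
            responder_profile=small_profile(n_ctl=30),
            nonresponder_profile=small_profile(n_ctl=5),
            seed=1,
        )
        tables, cohort = generate_cohort(cfg)
        by_pid = {t.patient_id: t for t in tables}
        for _, row in cohort.iterrows():
            n_ctl = by_pid[row.patient_id].phenotype_counts()["CTL"]
            assert n_ctl == (30 if row.response == "responder" else 5)

    def test_images_per_patient_range(self):
        cfg = CohortSimConfig(
            n_patients=30, images_per_patient=(1, 3),
            responder_profile=small_profile(), nonresponder_profile=small_profile(),
            seed=3,
        )
        tables, cohort = generate_cohort(cfg)
        assert cohort["n_images"].between(1, 3).all()
        assert cohort["n_images"].nunique() > 1
        assert len(tables) == cohort["n_images"].sum()

    def test_survival_fields(self):
        cfg = CohortSimConfig(
            n_patients=40, images_per_patient=1,
            responder_profile=small_profile(), nonresponder_profile=small_profile(),
            survival_model=SurvivalModel(baseline_hazard=0.05, hazard_ratio=2.0,
                                         censor_horizon_months=24.0),
            seed=5,
        )
        _, cohort = generate_cohort(cfg)
        assert (cohort["time_months"] <= 24.0).all()
        assert cohort["event"].isin([0, 1]).all()
        censored = cohort["time_months"] == 24.0
        assert (cohort.loc[censored, "event"] == 0).all()

    def test_hazard_ratio_direction(self):
        # HR 4 should make non-responders die visibly faster at n = 200
        cfg = CohortSimConfig(
            n_patients=200, images_per_patient=1, responder_fraction=0.5,
            responder_profile=small_profile(), nonresponder_profile=small_profile(),
            survival_model=SurvivalModel(baseline_hazard=0.02, hazard_ratio=4.0),
            seed=8,
        )
        _, cohort = generate_cohort(cfg)
        med = cohort.groupby("response")["time_months"].median()
        assert med["non_responder"] < med["responder"]


class TestCalibration:
    def test_chance_engagement_matches_measure(self):
        cfg = small_profile(attraction={("CTL", "EC"): 0.9})
        u = chance_engagement(cfg, ("CTL", "EC"), n_images=50, seed=2)
        direct = measure_engagement(
            cfg.replace(attraction={}), [("CTL", "EC")], 50, seed=2
        )[("CTL", "EC")]
        assert u == pytest.approx(direct)

    def test_single_pair_calibration_roundtrip(self):
        cfg = default_image_profile(seed=0)
        target = 0.55
        p = calibrate_attraction(cfg, ("EC", "CTL"), target, n_images=120, seed=6)
        measured = measure_engagement(
            cfg.replace(attraction={("EC", "CTL"): p}), [("EC", "CTL")], 150, seed=31
        )[("EC", "CTL")]
        assert measured == pytest.approx(target, abs=0.02)

    def test_infeasible_target_raises(self):
        cfg = default_image_profile(seed=0)
        with pytest.raises(ValueError, match="below the chance baseline"):
            calibrate_attraction(cfg, ("EC", "T"), 0.01, n_images=30, seed=1)
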