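"""Synthetic cohort generator: determinism, closure with the extraction
stage, lesion-thickness coupling, and configuration validation."""

import numpy as np
import pytest

from fcpoct import (
    BIOMARKERS,
    EyeRecord,
    Lesion,
    LesionSet,
    Transform2D,
    extract_cohort,
    simulate_cohort,
    simulate_landmarks,
    simulate_thickness_stack,
    table2_scenario,
)
from fcpoct.core import ConfigError
from fcpoct.synthetic_cohort import (
    CohortConfig,
    LesionParams,
    _normative_sensitivity,
    rasterize_lesions,
)

from .conftest import ZERO_SDS, brute_disc_fraction, noise_free_config, small_config


class TestCohortStructure:
    def test_empty_cohort_without_error(self):
        cfg = table2_scenario(n_patients_amd=0, n_eyes_amd=0, n_controls=0)
        cohort = simulate_cohort(cfg)
        assert cohort.eyes == [] and cohort.visits == {}

    def test_default_scenario_matches_study_design(self):
        """54 AMD eyes of 49 patients, 27 control eyes, up to 4 visits."""
        cohort = simulate_cohort(table2_scenario(seed=2))
        amd = cohort.amd_eyes
        assert len(amd) == 54
        assert len({e.patient_id for e in amd}) == 49
        assert len(cohort.control_eyes) == 27
        assert all(len(cohort.visits[e.eye_id]) == 4 for e in amd)
        assert all(len(cohort.visits[e.eye_id]) == 1
                   for e in cohort.control_eyes)
        for eye in amd:
            months = [v.months_since_baseline for v in cohort.visits[eye.eye_id]]
            assert months == sorted(months) and months[0] == 0.0

    def test_determinism_bit_identical(self):
        a = simulate_cohort(small_config(seed=21))
        b = simulate_cohort(small_config(seed=21))
        import pandas as pd
        pd.testing.assert_frame_equal(a.truth, b.truth)
        ea = a.amd_eyes[0].eye_id
        va, vb = a.visits[ea][0], b.visits[ea][0]
        assert np.array_equal(va.mesopic_db, vb.mesopic_db)
        assert np.array_equal(va.thickness_stack.layer("RPEDC"),
                              vb.thickness_stack.layer("RPEDC"))
        assert np.array_equal(va.lesion_set.mask("ped"),
                              vb.lesion_set.mask("ped"))

    def test_sensitivities_respect_dynamic_range(self, tiny_cohort):
        cfg = tiny_cohort.config
        for vlist in tiny_cohort.visits.values():
            for v in vlist:
                for arr in (v.mesopic_db, v.scotopic_db):
                    assert arr.min() >= cfg.sensitivity_floor_db
                    assert arr.max() <= cfg.sensitivity_ceiling_db

    def test_controls_carry_no_lesions(self, tiny_cohort):
        for eye in tiny_cohort.control_eyes:
            for v in tiny_cohort.visits[eye.eye_id]:
                for b in BIOMARKERS:
                    assert not v.lesion_set.mask(b).any()


class TestGenerativeClosure:
    def test_zero_variance_sensitivities_equal_linear_predictor(self):
        """With every variance component at zero, each emitted sensitivity
        equals the linear predictor recomputed here from the lesion masks
        (independent brute-force grading) and the configured effects."""
        cfg = noise_free_config(seed=17, n_visits_max=1)
        cohort = simulate_cohort(cfg)
        grid = cohort.grid
        beta = cfg.fixed_effects_cross_sectional["mesopic"]
        r_k = np.hypot(grid.centers[:, 0], grid.centers[:, 1])
        for eye in cohort.amd_eyes:
            visit = cohort.visits[eye.eye_id][0]
            t = cohort.true_transforms[(eye.eye_id, 0)]
            centers = grid.centers @ t.A.T
            eff = grid.extraction_diameter_deg * t.scale
            geom = visit.lesion_set.geometry
            for k in range(grid.n_points):
                pred = (_normative_sensitivity(cfg, "mesopic", r_k[k])
                        + beta["intercept"]
                        + beta["age"] * eye.age_at_baseline
                        + beta["pseudophakic"] * eye.pseudophakic)
                for b in BIOMARKERS:
                    frac, _ = brute_disc_fraction(
                        visit.lesion_set.mask(b), geom, centers[k], eff)
                    if frac > 0:
                        pred += beta[f"flag_{b}"]
                pred = np.clip(pred, cfg.sensitivity_floor_db,
                               cfg.sensitivity_ceiling_db)
                assert visit.mesopic_db[k] == pytest.approx(pred, abs=1e-9)

    def test_presence_rate_matches_placement_geometry(self):
        """Empirical per-stimulus PED rate agrees with an independent
        Monte-Carlo evaluation of the lesion placement model."""
        cfg = small_config(n_patients_amd=7, n_eyes_amd=8, n_visits_max=1)
        params = cfg.lesion_params["ped"]
        # independent oracle: analytic circle-circle overlap per stimulus
        rng = np.random.default_rng(999)
        from fcpoct import default_grid
        grid = default_grid()
        disc_r = grid.extraction_diameter_deg / 2.0
        oracle_eye_rates = []
        for _ in range(2000):
            covered = np.zeros(56, bool)
            if rng.random() < params.prevalence:
                count = rng.integers(params.count_range[0],
                                     params.count_range[1] + 1)
                for _ in range(count):
                    rad = cfg.lesion_field_radius_deg * np.sqrt(rng.random())
                    ang = rng.uniform(0, 2 * np.pi)
                    c = np.array([rad * np.cos(ang), rad * np.sin(ang)])
                    lr = rng.uniform(*params.diameter_um) / (
                        2 * cfg.microns_per_degree)
                    d = np.linalg.norm(grid.centers - c, axis=1)
                    covered |= d <= lr + disc_r
            oracle_eye_rates.append(covered.mean())
        # pipeline: graded flags over 20 replicate cohorts (baseline visits)
        emp_eye_rates = []
        for seed in range(20):
            cohort = simulate_cohort(small_config(
                seed=300 + seed, n_patients_amd=7, n_eyes_amd=8,
                n_visits_max=1))
            for eye in cohort.amd_eyes:
                t = cohort.true_transforms[(eye.eye_id, 0)]
                rows = cohort.truth
                sel = rows[rows["eye_id"] == eye.eye_id]
                emp_eye_rates.append(sel["flag_ped"].mean())
        o, e = np.array(oracle_eye_rates), np.array(emp_eye_rates)
        se = np.sqrt(o.var() / len(o) + e.var() / len(e))
        assert abs(o.mean() - e.mean()) <= 3 * se + 0.01  # +1% pixelation


class TestThicknessCoupling:
    def _stack(self, cfg, lesions):
        eye = EyeRecord("P1", "E1", "left", 70.0, False, "amd")
        geom = cfg.geometry("left")
        lesion_set = rasterize_lesions(lesions, geom, cfg.microns_per_degree)
        rng = np.random.default_rng(0)
        offsets = {layer: 0.0 for layer in
                   cfg.thickness_offset_sds_um}
        return lesion_set, simulate_thickness_stack(
            eye, lesion_set, cfg, rng, offsets=offsets)

    def test_lesion_free_zero_noise_equals_baseline(self):
        from fcpoct.synthetic_cohort import _baseline_maps
        cfg = table2_scenario(thickness_noise_sd_um=0.0, map_size_px=128)
        _, stack = self._stack(cfg, {})
        base = _baseline_maps(stack.geometry)
        np.testing.assert_allclose(stack.layer("RPEDC"),
                                   base["RPEDC"].astype(np.float32),
                                   atol=1e-5)

    def test_ped_bump_height_matches_lesion(self):
        cfg = table2_scenario(thickness_noise_sd_um=0.0, map_size_px=256)
        lesions = {"ped": [Lesion("ped", (0.0, 0.0), 1200.0, 250.0)]}
        lesion_set, stack = self._stack(cfg, lesions)
        _, base_stack = self._stack(cfg, {})
        excess = (stack.layer("RPEDC").astype(float)
                  - base_stack.layer("RPEDC").astype(float))
        inside = excess[lesion_set.mask("ped")]
        assert inside.max() == pytest.approx(250.0, rel=0.02)

    def test_crora_thins_outer_layers_inside_mask(self):
        cfg = table2_scenario(thickness_noise_sd_um=0.0, map_size_px=128)
        lesions = {"crora": [Lesion("crora", (1.0, 1.0), 600.0)]}
        lesion_set, stack = self._stack(cfg, lesions)
        _, base_stack = self._stack(cfg, {})
        mask = lesion_set.mask("crora")
        for layer in ("ONL", "OS", "RPEDC"):
            inside = stack.layer(layer)[mask].mean()
            outside = base_stack.layer(layer)[mask].mean()
            assert inside < outside

    def test_all_thicknesses_non_negative(self, tiny_cohort):
        for vlist in tiny_cohort.visits.values():
            for v in vlist:
                for layer, arr in v.thickness_stack.layers.items():
                    assert arr.min() >= 0.0

    def test_irora_and_crora_masks_disjoint(self, tiny_cohort):
        for vlist in tiny_cohort.visits.values():
            for v in vlist:
                assert not (v.lesion_set.mask("irora")
                            & v.lesion_set.mask("crora")).any()


class TestLandmarks:
    def test_zero_noise_landmarks_are_exact_transform_images(self):
        eye = EyeRecord("P1", "E1", "left", 70.0, False, "amd")
        t = Transform2D.similarity(1.02, 1.5, (0.3, -0.2))
        rng = np.random.default_rng(0)
        lm_oct, lm_fcp = simulate_landmarks(eye, t, 6, 0.0, rng)
        np.testing.assert_allclose(lm_fcp.points(), t.apply(lm_oct.points()),
                                   atol=1e-12)

    def test_identity_transform_zero_noise_frames_identical(self):
        eye = EyeRecord("P1", "E1", "right", 70.0, False, "amd")
        rng = np.random.default_rng(1)
        lm_oct, lm_fcp = simulate_landmarks(
            eye, Transform2D.identity(), 4, 0.0, rng)
        np.testing.assert_allclose(lm_fcp.points(), lm_oct.points())
        assert lm_oct.optic_disc[0] > 0  # right eye, temporal disc flipped

    def test_noise_rms_matches_stated_model(self):
        """RMS(FCP - T(OCT)) ~ sigma*sqrt(2) for isotropic click noise."""
        eye = EyeRecord("P1", "E1", "left", 70.0, False, "amd")
        t = Transform2D.similarity(1.0, 0.0, (0.0, 0.0))
        sq = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lm_oct, lm_fcp = simulate_landmarks(eye, t, 10, 0.1, rng)
            resid = lm_fcp.points() - t.apply(lm_oct.points())
            sq.append(np.mean(np.sum(resid**2, axis=1)))
        # pooled over 100 replicates: RMS ~ sigma * sqrt(2) = 0.14
        assert 0.05 <= np.sqrt(np.mean(sq)) <= 0.2


class TestConfigValidation:
    @pytest.mark.parametrize("mutate,match", [
        (lambda c: c.lesion_params.__setitem__(
            "ped", LesionParams(0.3, (1, 2), (500.0, 900.0),
                                (200.0, 300.0))), "PED basal diameter"),
        (lambda c: c.lesion_params.__setitem__(
            "ped", LesionParams(0.3, (1, 2), (1000.0, 1500.0),
                                (100.0, 150.0))), "PED height"),
        (lambda c: c.lesion_params.__setitem__(
            "crora", LesionParams(0.2, (1, 2), (100.0, 400.0))),
         "cRORA extent"),
        (lambda c: c.lesion_params.__setitem__(
            "irora", LesionParams(0.2, (1, 2), (100.0, 400.0))),
         "iRORA extent"),
        (lambda c: setattr(c, "n_visits_max", 0), "n_visits_max"),
        (lambda c: setattr(c, "n_eyes_amd", 200), "2 eyes per patient"),
        (lambda c: setattr(c, "sensitivity_floor_db", 25.0), "floor"),
        (lambda c: c.random_effect_sds.__setitem__("patient", -1.0), ">= 0"),
    ])
    def test_invalid_configs_rejected(self, mutate, match):
        cfg = table2_scenario()
        mutate(cfg)
        with pytest.raises(ConfigError, match=match):
            simulate_cohort(cfg)

    def test_config_dict_round_trip(self):
        cfg = table2_scenario(seed=33)
        clone = CohortConfig.from_dict(cfg.to_dict())
        assert clone == cfg
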