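"""Synthetic cohort, trajectory, diffusion and map generators."""

import numpy as np
import pandas as pd
import pytest

from adcontinuum.synthetic import (
    BRAIN_MEASURES,
    GroupSpec,
    TrajectorySpec,
    default_group_specs,
    default_trajectory_scenario,
    generate_cohort,
    generate_dwi_voxel,
    generate_memory,
    generate_predictors,
    generate_stat_maps,
    sample_severities,
)


# ------------------------------------------------------------------ cohort
class TestCohort:
    def test_default_cohort_matches_reference_group_sizes(self):
        cohort = generate_cohort(seed=0)
        counts = cohort.group.value_counts()
        assert len(cohort) == 151
        assert counts["HC"] == 51 and counts["aMCI"] == 54 and counts["AD"] == 46
        assert cohort.id.is_unique

    def test_healthy_controls_have_zero_severity(self):
        cohort = generate_cohort(seed=1)
        assert (cohort.loc[cohort.group == "HC", "severity"] == 0).all()

    def test_same_seed_reproduces_identical_table(self):
        a = generate_cohort(seed=5)
        b = generate_cohort(seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(seed=6)
        assert not a.severity.equals(c.severity)

    def test_diagnostic_bounds_hold_on_large_draws(self):
        """aMCI < 4 and AD >= 4 on 1e5 draws; half-point granularity."""
        specs = {s.label: s for s in default_group_specs()}
        rng = np.random.default_rng(11)
        amci = sample_severities(specs["aMCI"], 100_000, rng)
        assert amci.max() < 4.0 and amci.min() >= 0.0
        rng = np.random.default_rng(13)
        ad = sample_severities(specs["AD"], 100_000, rng)
        assert ad.min() >= 4.0 and ad.max() <= 18.0
        for v in (amci, ad):
            assert np.allclose(v * 2, np.round(v * 2))

    def test_group_means_calibrated_at_tenfold_size(self):
        """Sample severity mean within 2 SE of the generating spec mean."""
        for spec in default_group_specs(scale=10):
            rng = np.random.default_rng(7)
            draws = sample_severities(spec, spec.n, rng)
            if spec.severity_sd == 0:
                assert np.all(draws == spec.severity_mean)
                continue
            se = draws.std(ddof=1) / np.sqrt(spec.n)
            # truncation + rounding shift the mean; allow the truncated-
            # normal mean as reference, computed from the spec directly
            from scipy.stats import truncnorm

            lo, hi, _ = spec.severity_bounds
            a = (lo - spec.severity_mean) / spec.severity_sd
            b = (hi - spec.severity_mean) / spec.severity_sd
            ref = truncnorm.mean(a, b, loc=spec.severity_mean, scale=spec.severity_sd)
            assert abs(draws.mean() - ref) < 2 * se + 0.25  # 0.25 = half rounding step

    def test_specs_and_scenario_build_from_config_dicts(self):
        from adcontinuum.synthetic import group_specs_from_config, scenario_from_config

        specs = group_specs_from_config([
            {"label": "HC", "n": 5, "severity_mean": 0, "severity_sd": 0,
             "severity_bounds": [0, 0, True]},
            {"label": "AD", "n": 4, "severity_mean": 6.7, "severity_sd": 2.8,
             "severity_bounds": [4, 18, True], "age_mean": 75.2},
        ])
        assert specs[1].age_mean == 75.2
        assert len(generate_cohort(specs, seed=0)) == 9
        scen = scenario_from_config(
            [{"predictor_name": "FW", "control_points": [[0, -0.5], [2, -0.9]]}])
        assert scen[0](np.array([2.0]))[0] == -0.9

    def test_invalid_group_spec_names_group(self):
        with pytest.raises(ValueError, match="bad"):
            GroupSpec("bad", 10, 2.0, 1.0, (3.0, 1.0, True))
        with pytest.raises(ValueError, match="positive"):
            GroupSpec("HC", 0, 0.0, 0.0, (0.0, 0.0, True))


# ------------------------------------------------------------------ trajectories
class TestTrajectories:
    def test_scenario_contains_ten_predictors(self, scenario):
        names = [t.predictor_name for t in scenario]
        assert len(names) == 10
        assert set(BRAIN_MEASURES) < set(names)

    def test_fw_minimum_is_the_stated_early_peak(self, scenario):
        fw = next(t for t in scenario if t.predictor_name == "FW")
        grid = np.arange(0, 18.01, 0.1)
        vals = fw(grid)
        assert np.isclose(vals.min(), -0.9, atol=1e-9)
        assert grid[np.argmin(vals)] < 4.0
        # secondary negative bump in the AD range, smaller than the peak
        assert vals[grid >= 14].min() < -0.2
        assert vals[grid >= 14].min() > -0.9

    def test_hip_peak_sits_at_the_amci_ad_boundary(self, scenario):
        hip = next(t for t in scenario if t.predictor_name == "GMV-HIP")
        grid = np.arange(0, 18.01, 0.1)
        vals = hip(grid)
        assert 4.0 <= grid[np.argmax(vals)] <= 5.0
        # the 0.1-step grid brackets the true peak at t=4.75
        assert np.isclose(vals.max(), 2.4, atol=5e-3)
        assert np.isclose(hip(np.array([4.75]))[0], 2.4, atol=1e-9)

    def test_stated_positive_peaks(self, scenario):
        grid = np.arange(0, 18.01, 0.1)
        expected = {"FA_T-fornix": 4.5, "GMV-mPFC": 4.5, "GMV-PCC": 1.4}
        for tr in scenario:
            if tr.predictor_name in expected:
                assert np.isclose(tr(grid).max(), expected[tr.predictor_name], atol=1e-9)

    def test_nuisance_trajectories_identically_zero(self, scenario):
        grid = np.linspace(0, 18, 37)
        for tr in scenario:
            if tr.predictor_name in ("age", "gender", "handedness", "ethnicity"):
                assert np.all(tr(grid) == 0.0)

    def test_constant_trajectory_from_single_control_point(self):
        tr = TrajectorySpec("x", ((0.0, 0.8),))
        assert np.all(tr(np.linspace(0, 18, 10)) == 0.8)

    def test_control_point_validation(self):
        with pytest.raises(ValueError, match="strictly increase"):
            TrajectorySpec("x", ((0.0, 1.0), (0.0, 2.0)))
        with pytest.raises(ValueError, match=r"\[0, 18\]"):
            TrajectorySpec("x", ((-1.0, 1.0), (2.0, 2.0)))
        with pytest.raises(ValueError, match="interpolation"):
            TrajectorySpec("x", ((0.0, 1.0), (2.0, 2.0)), interpolation="spline")


# ------------------------------------------------------------------ predictors
class TestPredictors:
    def test_noiseless_limit_is_deterministic_in_severity(self):
        cohort = generate_cohort(seed=2)
        a = generate_predictors(cohort, noise_sd=0.0, seed=1)
        b = generate_predictors(cohort, noise_sd=0.0, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_free_water_rises_with_severity(self):
        cohort = generate_cohort(default_group_specs(scale=1000 / 151), seed=3)
        pred = generate_predictors(cohort, seed=3)
        r = np.corrcoef(pred["FW"], cohort["severity"])[0, 1]
        assert r > 0.3
        # grey matter deteriorates (negative slope)
        r_gm = np.corrcoef(pred["GMV-HIP"], cohort["severity"])[0, 1]
        assert r_gm < -0.3

    def test_seed_determinism_and_validation(self):
        cohort = generate_cohort(seed=4)
        pd.testing.assert_frame_equal(
            generate_predictors(cohort, seed=8), generate_predictors(cohort, seed=8)
        )
        with pytest.raises(ValueError, match="noise_sd"):
            generate_predictors(cohort, noise_sd=-1.0)
        with pytest.raises(ValueError, match="empty"):
            generate_predictors(cohort.iloc[:0])


# ------------------------------------------------------------------ memory
class TestMemory:
    def test_null_model_gives_identically_zero_scores(self, scenario):
        cohort = generate_cohort(seed=5)
        pred = generate_predictors(cohort, seed=5)
        null = [TrajectorySpec(t.predictor_name, ((0.0, 0.0),)) for t in scenario]
        out = generate_memory(cohort, pred, null, eps_sd=0.0, seed=0)
        assert np.all(out.memory_z == 0.0)

    def test_constant_coefficient_closed_form(self, scenario):
        """beta_FC = 2 constant, others 0, no noise: y = 2 * standardized FC."""
        cohort = generate_cohort(seed=6)
        pred = generate_predictors(cohort, seed=6)
        scen = [
            TrajectorySpec(t.predictor_name,
                           ((0.0, 2.0),) if t.predictor_name == "FC-DMN" else ((0.0, 0.0),))
            for t in scenario
        ]
        out = generate_memory(cohort, pred, scen, eps_sd=0.0, seed=0)
        x = pred["FC-DMN"].to_numpy()
        xs = (x - x.mean()) / x.std()
        assert np.allclose(out.memory_z, 2.0 * xs, atol=1e-10)

    def test_variance_matches_independent_oracle(self, scenario):
        """var(y) at n=5000 against a from-scratch reimplementation."""
        from scipy.interpolate import PchipInterpolator

        specs = default_group_specs(scale=5000 / 151)
        cohort = generate_cohort(specs, seed=9)
        pred = generate_predictors(cohort, seed=9)
        eps_sd = 1.0
        out = generate_memory(cohort, pred, scenario, eps_sd=eps_sd, seed=9)
        # oracle: rebuild the signal with independent interpolation and
        # standardization code, then add the noise variance analytically
        t = cohort.severity.to_numpy()
        signal = np.zeros(len(t))
        for tr in scenario:
            s = np.array([p[0] for p in tr.control_points])
            b = np.array([p[1] for p in tr.control_points])
            beta = np.full(len(t), b[0]) if len(s) == 1 else PchipInterpolator(s, b)(
                np.clip(t, s[0], s[-1]))
            x = pred[tr.predictor_name].to_numpy()
            signal += beta * (x - x.mean()) / x.std()
        oracle_var = signal.var() + eps_sd**2
        assert abs(out.memory_z.var() - oracle_var) / oracle_var < 0.05

    def test_row_mismatch_raises(self, scenario):
        cohort = generate_cohort(seed=7)
        pred = generate_predictors(cohort, seed=7)
        with pytest.raises(ValueError, match="row counts"):
            generate_memory(cohort.iloc[:-1], pred, scenario)


# ------------------------------------------------------------------ diffusion
class TestDWIVoxel:
    def test_default_protocol_has_68_volumes(self, gtab):
        assert len(gtab) == 68
        assert gtab.b0_mask.sum() == 7
        assert (gtab.bvals[gtab.dw_mask] == 1150.0).all()

    def test_pure_free_water_attenuation(self, gtab):
        sig = generate_dwi_voxel(1.0, np.eye(3) * 1e-3, gtab, S0=500.0)
        att = sig[gtab.dw_mask] / 500.0
        assert np.allclose(att, np.exp(-1150 * 3e-3), atol=1e-12)

    def test_pure_isotropic_tissue_attenuation(self, gtab):
        d = 0.8e-3
        sig = generate_dwi_voxel(0.0, np.eye(3) * d, gtab, S0=1.0)
        assert np.allclose(sig[gtab.dw_mask], np.exp(-1150 * d), atol=1e-12)

    def test_invalid_fraction_and_tensor_raise(self, gtab):
        with pytest.raises(ValueError, match="outside"):
            generate_dwi_voxel(1.5, np.eye(3) * 1e-3, gtab)
        with pytest.raises(ValueError, match="semidefinite"):
            generate_dwi_voxel(0.5, -np.eye(3) * 1e-3, gtab)

    def test_rician_noise_is_seeded(self, gtab):
        a = generate_dwi_voxel(0.3, np.eye(3) * 1e-3, gtab, noise_sd=0.02, seed=4)
        b = generate_dwi_voxel(0.3, np.eye(3) * 1e-3, gtab, noise_sd=0.02, seed=4)
        c = generate_dwi_voxel(0.3, np.eye(3) * 1e-3, gtab, noise_sd=0.02, seed=5)
        assert np.array_equal(a, b) and not np.array_equal(a, c)
        assert np.all(a >= 0)  # Rician magnitudes


# ------------------------------------------------------------------ stat maps
class TestStatMaps:
    def test_null_field_has_empty_truth_mask(self):
        cohort = pd.DataFrame({"memory_z": np.random.default_rng(0).normal(size=12)})
        maps, truth = generate_stat_maps(
            (8, 8, 8), [{"center": (4, 4, 4), "radius": 2, "amplitude": 0.0}],
            cohort, seed=0)
        assert maps.shape == (12, 8, 8, 8)
        assert not truth.any()

    def test_effect_clusters_are_marked_and_coupled_to_memory(self):
        rng = np.random.default_rng(1)
        cohort = pd.DataFrame({"memory_z": rng.normal(size=40)})
        maps, truth = generate_stat_maps(
            (10, 10, 10), [{"center": (5, 5, 5), "radius": 2, "amplitude": 3.0}],
            cohort, noise_sd=0.5, seed=1)
        assert truth.sum() > 0
        inside = maps[:, truth].mean(axis=1)
        r = np.corrcoef(inside, cohort.memory_z)[0, 1]
        assert r > 0.9

    def test_grid_validation(self):
        cohort = pd.DataFrame({"memory_z": [0.0, 1.0]})
        with pytest.raises(ValueError, match="positive"):
            generate_stat_maps((-4, 4, 4), [], cohort)
        with pytest.raises(ValueError, match="outside"):
            generate_stat_maps((4, 4, 4),
                               [{"center": (9, 1, 1), "radius": 1, "amplitude": 1.0}],
                               cohort)
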