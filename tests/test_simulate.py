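import numpy as np
import pandas as pd
import pytest

from tauvbm.biofluids import apply_gate
from tauvbm.simulate import (
    Hotspot,
    SimulationConfig,
    baseline_template,
    generate_athletes,
    generate_biofluids,
    generate_controls,
    generate_neuropsych,
    gm_mask,
    make_atlas,
    tau_excess_field,
)
from tauvbm.volume_io import SubjectRecord


class TestConfigValidation:
    def test_grid_minimum(self):
        with pytest.raises(ValueError, match=">= 8"):
            SimulationConfig(seed=1, grid_dims=(6, 16, 16))

    def test_hotspot_outside_grid_fatal(self):
        with pytest.raises(ValueError, match="outside grid"):
            SimulationConfig(seed=1, tau_hotspots=(Hotspot((20, 4, 4), 2.0, 0.5),))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="sigma_gm"):
            SimulationConfig(seed=1, sigma_gm=-0.1)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_cfg):
        r1, v1 = generate_controls(small_cfg)
        r2, v2 = generate_controls(small_cfg)
        assert [r.age for r in r1] == [r.age for r in r2]
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a.data, b.data)
        a1 = generate_athletes(small_cfg)
        a2 = generate_athletes(small_cfg)
        np.testing.assert_array_equal(a1[2][0].data, a2[2][0].data)

    def test_different_seed_changes_noise_not_structure(self, small_cfg):
        _, v1 = generate_controls(small_cfg)
        _, v2 = generate_controls(small_cfg.with_(seed=99))
        assert not np.array_equal(v1[0].data, v2[0].data)
        # structural parts are seed-independent
        np.testing.assert_array_equal(
            tau_excess_field(small_cfg), tau_excess_field(small_cfg.with_(seed=99))
        )
        np.testing.assert_array_equal(gm_mask(small_cfg), gm_mask(small_cfg.with_(seed=99)))

    def test_independent_samples_differ(self, small_cfg):
        _, v0 = generate_controls(small_cfg, sample=0)
        _, v1 = generate_controls(small_cfg, sample=1)
        assert not np.array_equal(v0[0].data, v1[0].data)


class TestControls:
    def test_noise_free_maps_follow_the_stated_linear_model(self, small_cfg):
        cfg = small_cfg.with_(sigma_gm=0.0, n_controls=3)
        records, vols = generate_controls(cfg)
        template = baseline_template(cfg)
        age_c = np.mean(cfg.control_age_range)
        for r, v in zip(records, vols):
            expected = (
                template
                + cfg.beta_age * (r.age - age_c)
                + cfg.beta_tiv * (r.tiv - cfg.tiv_mean)
            )
            np.testing.assert_allclose(v.data, expected, atol=1e-12)

    def test_age_slope_recovered_by_ols_oracle(self):
        # regress mean GM on age and TIV over n=200: slope within 3 SE
        cfg = SimulationConfig(seed=42, n_controls=200)
        records, vols = generate_controls(cfg)
        mask = gm_mask(cfg)
        y = np.array([v.data[mask].mean() for v in vols])
        X = np.column_stack(
            [np.ones(200), [r.age for r in records], [r.tiv for r in records]]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        cov = (resid @ resid / (200 - 3)) * np.linalg.inv(X.T @ X)
        se_age = np.sqrt(cov[1, 1])
        assert abs(beta[1] - cfg.beta_age) < 3 * se_age


class TestAthletes:
    def test_no_hotspots_no_noise_gives_flat_suvr(self, small_cfg):
        cfg = small_cfg.with_(
            tau_hotspots=(), tau_diffuse=0.0, tau_noise_sd=0.0, n_athletes=2
        )
        _, _, suvr, _ = generate_athletes(cfg)
        np.testing.assert_allclose(suvr[0].data, cfg.tau_baseline, atol=1e-12)

    def test_zero_coupling_gm_matches_control_model_in_tau_regions(self):
        # null case: with coupling off, athlete GM deviates from the control
        # prediction only by noise, even inside the tau hotspots
        cfg = SimulationConfig(seed=3, coupling_beta=0.0, n_athletes=50)
        records, gms, suvrs, _ = generate_athletes(cfg)
        template = baseline_template(cfg)
        age_c = np.mean(cfg.control_age_range)
        hot = tau_excess_field(cfg) > 0.35
        devs = []
        for r, g in zip(records, gms):
            pred = (
                template + cfg.beta_age * (r.age - age_c) + cfg.beta_tiv * (r.tiv - cfg.tiv_mean)
            )
            devs.append((g.data - pred)[hot].mean() / cfg.sigma_gm)
        assert abs(np.mean(devs)) < 0.1  # ~0 in units of the voxel noise SD

    def test_coupling_recovered_by_direct_averaging_oracle(self):
        cfg = SimulationConfig(seed=4, coupling_beta=-0.5, n_athletes=50)
        records, gms, suvrs, _ = generate_athletes(cfg)
        template = baseline_template(cfg)
        age_c = np.mean(cfg.control_age_range)
        mask = gm_mask(cfg)
        est, exc = [], []
        for r, g, s in zip(records, gms, suvrs):
            pred = (
                template + cfg.beta_age * (r.age - age_c) + cfg.beta_tiv * (r.tiv - cfg.tiv_mean)
            )
            excess = np.maximum(s.data - 1.0, 0.0)[mask]
            est.append((g.data - pred)[mask].mean())
            exc.append(excess.mean())
        # atrophy per unit excess, averaged over subjects
        slope = np.mean(est) / np.mean(exc)
        se = np.std(np.array(est) / np.mean(exc), ddof=1) / np.sqrt(50)
        assert abs(slope - cfg.coupling_beta) < 2 * se + 1e-3

    def test_scanner_and_window_proportions(self):
        cfg = SimulationConfig(seed=5, n_athletes=400)
        records, *_ = generate_athletes(cfg)
        p_petct = np.mean([r.scanner == "PETCT" for r in records])
        p_long = np.mean([r.scan_window == "W80_100" for r in records])
        assert p_petct == pytest.approx(0.66, abs=0.08)
        assert p_long == pytest.approx(0.787, abs=0.07)


class TestNeuropsych:
    def _recs(self, n):
        return [
            SubjectRecord(f"a{i}", 50.0, 1500.0, "athlete", 15.0, "PETCT", "W80_100")
            for i in range(n)
        ]

    def test_noiseless_composite_is_exactly_linear_in_pct(self):
        cfg = SimulationConfig(seed=6, memory_sigma=0.0, memory_slope=-0.05)
        recs = self._recs(3)
        pct = pd.Series({"a0": 10.0, "a1": 0.0, "a2": 30.0})
        df = generate_neuropsych(recs, pct, cfg).set_index("subject_id")
        mem = df[["ravlt_trials_z", "ravlt_delay_z", "rvdlt_trials_z"]].mean(axis=1)
        assert mem["a0"] == pytest.approx(-0.5, abs=1e-12)
        assert mem["a1"] == pytest.approx(0.0, abs=1e-12)
        assert mem["a2"] == pytest.approx(-1.5, abs=1e-12)

    def test_zero_slope_gives_null_correlation(self):
        cfg = SimulationConfig(seed=7, memory_slope=0.0)
        n = 200
        recs = self._recs(n)
        pct = pd.Series({f"a{i}": float(v) for i, v in enumerate(np.linspace(0, 40, n))})
        df = generate_neuropsych(recs, pct, cfg).set_index("subject_id")
        mem = df[["ravlt_trials_z", "ravlt_delay_z", "rvdlt_trials_z"]].mean(axis=1)
        r = np.corrcoef(mem.loc[pct.index], pct)[0, 1]
        assert abs(r) < 2.0 / np.sqrt(n)

    def test_slope_recovered_by_ols_oracle(self):
        cfg = SimulationConfig(seed=8, memory_slope=-0.05, memory_sigma=0.5)
        n = 200
        recs = self._recs(n)
        pct = pd.Series({f"a{i}": float(v) for i, v in enumerate(np.linspace(0, 40, n))})
        df = generate_neuropsych(recs, pct, cfg).set_index("subject_id")
        mem = df[["ravlt_trials_z", "ravlt_delay_z", "rvdlt_trials_z"]].mean(axis=1).loc[pct.index]
        X = np.column_stack([np.ones(n), pct.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, mem.to_numpy(), rcond=None)
        resid = mem.to_numpy() - X @ beta
        se = np.sqrt(
            (resid @ resid / (n - 2)) * np.linalg.inv(X.T @ X)[1, 1]
        )
        assert abs(beta[1] - cfg.memory_slope) < 3 * se

    def test_speed_and_executive_are_tau_independent(self):
        cfg = SimulationConfig(seed=9)
        n = 200
        recs = self._recs(n)
        pct = pd.Series({f"a{i}": float(v) for i, v in enumerate(np.linspace(0, 40, n))})
        df = generate_neuropsych(recs, pct, cfg).set_index("subject_id")
        speed = df[["tmt_a_z", "digit_fwd_z", "sdmt_written_z"]].mean(axis=1).loc[pct.index]
        assert abs(np.corrcoef(speed, pct)[0, 1]) < 3.0 / np.sqrt(n)

    def test_length_mismatch_fatal(self):
        cfg = SimulationConfig(seed=10)
        with pytest.raises(ValueError, match="a1"):
            generate_neuropsych(self._recs(2), pd.Series({"a0": 1.0}), cfg)


class TestBiofluids:
    def _recs(self, n):
        return [
            SubjectRecord(f"a{i:02d}", 45.0 + i % 30, 1500.0, "athlete", 15.0, "PETCT", "W80_100")
            for i in range(n)
        ]

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 50)])
    def test_extreme_fractions(self, fraction, expected):
        cfg = SimulationConfig(seed=11)
        recs = self._recs(50)
        panels = generate_biofluids(recs, fraction, cfg)
        ages = {r.subject_id: r.age for r in recs}
        res = apply_gate(panels, ages=ages)
        assert len(res.excluded) == expected

    def test_gate_output_matches_generator_labels_exactly(self):
        cfg = SimulationConfig(seed=12)
        recs = self._recs(50)
        panels = generate_biofluids(recs, 0.2, cfg)
        ages = {r.subject_id: r.age for r in recs}
        res = apply_gate(panels, ages=ages)
        truth = set(panels.loc[panels.true_positive, "subject_id"])
        assert set(res.excluded) == truth
        assert len(truth) == round(0.2 * 50)


class TestAtlasAndMasks:
    def test_atlas_partitions_gm_with_named_regions(self, small_cfg):
        atlas = make_atlas(small_cfg)
        gm = gm_mask(small_cfg)
        assert set(np.unique(atlas.labels[gm])) - {0} == set(atlas.regions())
        assert (atlas.labels[~gm] == 0).all()
        names = set(atlas.name_table.values())
        assert "hippocampus_like_left" in names and "anterior_left_superior" in names

    def test_deep_regions_sit_in_low_tau_territory(self):
        cfg = SimulationConfig(seed=13)
        atlas = make_atlas(cfg)
        field = tau_excess_field(cfg)
        deep = np.isin(
            atlas.labels,
            [lab for lab, n in atlas.name_table.items() if "like" in n],
        )
        cortical = (atlas.labels > 0) & ~deep
        assert field[deep].mean() < 0.5 * field[cortical].mean()
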