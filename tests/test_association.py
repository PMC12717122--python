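"""Regression, field significance, ratio maps, multimode disentangling
and climate-change comparison against hand-enumerated and brute-force
oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
import xarray as xr
from scipy import stats

from modefire.association import (FireModeModel, aggregate_fires,
                                  climate_change_effect, cross_phase_table,
                                  field_significance, phase_ratio_map,
                                  regress_cells)
from modefire.grids import GridSpec
from modefire.indices import classify_phase
from modefire.synthetic import EffectSpec, ModeSpec, generate_fire_counts, \
    generate_mode_truth

from conftest import annual_series, make_count_cube


class TestRegressCells:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        Y = (3.0 * x)[:, None]
        slope, p = regress_cells(x, Y)
        assert slope[0] == pytest.approx(3.0)
        assert p[0] < 1e-10

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        Y = rng.normal(size=(40, 3)) + np.outer(x, [0.0, 0.5, 2.0])
        slope, p = regress_cells(x, Y)
        for j in range(3):
            fit = sm.OLS(Y[:, j], sm.add_constant(x)).fit()
            assert slope[j] == pytest.approx(fit.params[1], rel=1e-10)
            assert p[j] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        Y = rng.normal(size=(50, 10000))
        _, p = regress_cells(x, Y)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_slope_sign_equals_correlation_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        Y = rng.normal(size=(30, 50))
        slope, _ = regress_cells(x, Y)
        corr = np.array([np.corrcoef(x, Y[:, j])[0, 1] for j in range(50)])
        np.testing.assert_array_equal(np.sign(slope), np.sign(corr))

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regress_cells(np.ones(10), np.random.default_rng(0).normal(size=(10, 2)))


class TestFieldSignificance:
    def test_hand_enumerated_bh_steps(self):
        # thresholds k/N * alpha = .0025, .005, .0075, .01: only p=0.001
        # clears its step
        sig = field_significance(np.array([0.001, 0.2, 0.5, 0.9]), 0.01)
        np.testing.assert_array_equal(sig, [True, False, False, False])

    def test_all_above_alpha_rejects_nothing(self):
        sig = field_significance(np.array([0.5, 0.9, 0.02]), 0.01)
        assert not sig.any()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500) ** 2
        prev = field_significance(p, 1e-4)
        for alpha in (1e-3, 1e-2, 0.05, 0.2):
            cur = field_significance(p, alpha)
            assert np.all(cur[prev])  # lowering alpha never adds cells
            prev = cur

    def test_global_null_fdr_controlled(self):
        rng = np.random.default_rng(4)
        fdp = []
        for _ in range(200):
            p = rng.uniform(size=500)
            rej = field_significance(p, 0.01)
            fdp.append(rej.sum() > 0)  # any rejection is false under the null
        mean_fdp = np.mean(fdp)
        se = np.std(fdp) / np.sqrt(len(fdp))
        assert mean_fdp <= 0.01 + 3 * max(se, 1e-3)


class TestAggregateFires:
    def test_block_of_ones(self):
        cube = make_count_cube(np.ones((1, 1, 12, 4, 4)))
        agg = aggregate_fires(cube, 2)
        assert np.all(agg.values == 4.0)

    def test_total_conserved_and_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(3.0, size=(2, 3, 12, 10, 15)).astype(float)
        cube = make_count_cube(vals)
        agg = aggregate_fires(cube, 5)
        assert float(agg.sum()) == float(cube.sum())
        brute = vals.reshape(2, 3, 12, 2, 5, 3, 5).sum(axis=(4, 6))
        np.testing.assert_array_equal(agg.values, brute)

    def test_non_divisible_factor_rejected(self):
        cube = make_count_cube(np.ones((1, 1, 12, 4, 4)))
        with pytest.raises(ValueError, match="does not divide"):
            aggregate_fires(cube, 3)


class TestPhaseRatioMap:
    def _cube_and_phases(self, effect=0.0, seed=6, n_members=30, n_years=10):
        rng = np.random.default_rng(seed)
        idx = annual_series(rng.standard_normal((n_members, n_years)))
        phases = classify_phase(idx)
        lam = 5.0 * np.exp(effect * idx.values)
        vals = rng.poisson(lam[:, :, None, None, None],
                           size=(n_members, n_years, 12, 2, 3)).astype(float)
        return make_count_cube(vals), phases

    def test_no_effect_gives_unit_ratios(self):
        cube, phases = self._cube_and_phases(effect=0.0)
        ds = phase_ratio_map(cube, phases)
        n_pos = int((phases.values == 1).sum())
        se = 1.0 / np.sqrt(n_pos * 60.0)  # Poisson mean 60/yr per cell
        assert float(np.abs(ds["positive"] - 1.0).max()) < 4 * se

    def test_arithmetic(self):
        vals = np.zeros((1, 2, 12, 1, 1))
        vals[0, 0, 0] = 12.0  # phase-positive year
        vals[0, 1, 0] = 8.0   # negative year
        cube = make_count_cube(vals)
        phases = annual_series([[1.0, -1.0]])
        ds = phase_ratio_map(cube, phases)
        assert ds["positive"].item() == pytest.approx(1.2)
        assert ds["negative"].item() == pytest.approx(0.8)

    def test_frequency_weighted_identity(self):
        cube, phases = self._cube_and_phases(effect=0.3, seed=7)
        ds = phase_ratio_map(cube, phases, which=(1.0, 0.0, -1.0))
        freq = ds.attrs["phase_frequency"]
        total = sum(freq[k] * ds[k] for k in ("positive", "neutral", "negative"))
        assert float(np.abs(total - 1.0).max()) < 1e-9

    def test_empty_phase_rejected(self):
        cube, _ = self._cube_and_phases()
        phases = annual_series(np.ones((30, 10)))
        with pytest.raises(ValueError, match="no member-years"):
            phase_ratio_map(cube, phases)


class TestModelFit:
    def test_significance_mask_flags_exactly_loaded_cells_noise_free(self):
        # deterministic counts: expected rates instead of Poisson draws
        rng = np.random.default_rng(8)
        idx = annual_series(rng.standard_normal((20, 10)))
        beta = np.zeros((3, 4)); beta[1, 2] = 0.2; beta[0, 0] = -0.15
        lam = 5.0 * np.exp(idx.values[:, :, None, None] * beta[None, None])
        vals = np.repeat(lam[:, :, None], 12, axis=2)
        cube = make_count_cube(vals)
        model = FireModeModel(cube, {"M": idx})
        res = model.fit("M", alpha_fdr=0.01)
        np.testing.assert_array_equal(res.significant.values, beta != 0)
        assert res.sign.values[1, 2] == 1 and res.sign.values[0, 0] == -1

    def test_areal_extent_equal_areas(self):
        rng = np.random.default_rng(9)
        idx = annual_series(rng.standard_normal((20, 10)))
        beta = np.zeros((1, 10)); beta[0, :9] = 0.5
        lam = 5.0 * np.exp(idx.values[:, :, None, None] * beta[None, None])
        cube = make_count_cube(np.repeat(lam[:, :, None], 12, axis=2))
        equal_area = xr.ones_like(cube.isel(member=0, year=0, month=0, drop=True))
        model = FireModeModel(cube, {"M": idx}, cell_area=equal_area)
        res = model.fit("M")
        ext = res.areal_extent()
        assert ext["positive"] == pytest.approx(90.0)
        assert sum(ext.values()) == pytest.approx(100.0)

    def test_areal_extent_weighted_by_area(self):
        rng = np.random.default_rng(10)
        idx = annual_series(rng.standard_normal((20, 10)))
        beta = np.zeros((1, 2)); beta[0, 0] = 0.5
        lam = 5.0 * np.exp(idx.values[:, :, None, None] * beta[None, None])
        cube = make_count_cube(np.repeat(lam[:, :, None], 12, axis=2))
        area = xr.DataArray([[0.4, 0.6]], dims=("lat", "lon"),
                            coords={"lat": cube["lat"], "lon": cube["lon"]})
        model = FireModeModel(cube, {"M": idx}, cell_area=area)
        ext = model.fit("M").areal_extent()
        assert ext["positive"] == pytest.approx(40.0)


class TestMultimode:
    def _correlated_world(self, seed=11, n_members=160, n_years=10, beta1=0.3):
        corr = np.array([[1.0, -0.6], [-0.6, 1.0]])
        truth = generate_mode_truth(n_members, n_years,
                                    [ModeSpec("m1"), ModeSpec("m2")],
                                    seed=seed, correlation=corr)
        grid = GridSpec(lat=np.array([0.0]), lon=np.array([0.0]))
        counts = generate_fire_counts(truth, [EffectSpec("m1", beta=beta1)],
                                      np.full((12, 1, 1), 5.0), seed=seed + 1,
                                      grid=grid)
        model = FireModeModel(counts, {"m1": truth[0].latent,
                                       "m2": truth[1].latent})
        return model

    def test_orthogonal_indices_give_zero_cross_coefficient(self):
        truth = generate_mode_truth(200, 10, [ModeSpec("m1"), ModeSpec("m2")],
                                    seed=12)
        grid = GridSpec(lat=np.array([0.0]), lon=np.array([0.0]))
        counts = generate_fire_counts(truth, [EffectSpec("m1", beta=0.3)],
                                      np.full((12, 1, 1), 5.0), seed=13, grid=grid)
        model = FireModeModel(counts, {"m1": truth[0].latent,
                                       "m2": truth[1].latent})
        mm = model.fit_multimode(["m1", "m2"])
        c2 = mm.coefficients.sel(mode="m2").item()
        s2 = mm.stderr.sel(mode="m2").item()
        assert abs(c2) < 3 * s2
        assert mm.coefficients.sel(mode="m1").item() > 5 * mm.stderr.sel(mode="m1").item()

    def test_disentangles_correlated_modes(self):
        # effect only via mode 1: the single-mode regression on mode 2 shows
        # a spurious slope, the multimode coefficient for mode 2 does not
        model = self._correlated_world()
        single = model.fit("m2")
        assert single.p_value.item() < 1e-6
        assert single.slope.item() < 0  # sign inherited through r = -0.6
        mm = model.fit_multimode(["m1", "m2"])
        assert abs(mm.coefficients.sel(mode="m2").item()) < 3 * mm.stderr.sel(mode="m2").item()

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(14)
        idx1 = annual_series(rng.standard_normal((25, 8)))
        idx2 = annual_series(rng.standard_normal((25, 8)))
        vals = rng.poisson(4.0, size=(25, 8, 12, 2, 3)).astype(float)
        cube = make_count_cube(vals)
        model = FireModeModel(cube, {"a": idx1, "b": idx2})
        mm = model.fit_multimode(["a", "b"])
        # brute-force normal equations per cell
        annual = vals.sum(axis=2).reshape(200, -1)
        rel = annual / annual.mean(axis=0)
        z1 = (idx1.values.ravel() - idx1.values.mean()) / idx1.values.std()
        z2 = (idx2.values.ravel() - idx2.values.mean()) / idx2.values.std()
        X = np.column_stack([np.ones(200), z1, z2])
        beta = np.linalg.solve(X.T @ X, X.T @ rel)
        got = mm.coefficients.values.reshape(2, -1)
        np.testing.assert_allclose(got, beta[1:], atol=1e-8)

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(15)
        idx = annual_series(rng.standard_normal((10, 5)))
        cube = make_count_cube(rng.poisson(4.0, size=(10, 5, 12, 1, 1)).astype(float))
        model = FireModeModel(cube, {"a": idx, "b": idx * 2.0})
        with pytest.raises(ValueError, match="rank-deficient"):
            model.fit_multimode(["a", "b"])


class TestCrossPhaseTable:
    def test_uniform_b_effect_recovered_exactly(self):
        # B = +1 adds exactly +10%, B = -1 subtracts 10%, balanced within
        # every phase of A -> every row reads +10 / -10 exactly
        n = 120
        rng = np.random.default_rng(16)
        a = annual_series(rng.choice([1.0, 0.0, -1.0], size=(1, n)))
        b_vals = np.tile([1.0, -1.0], n // 2)
        b = annual_series(b_vals[None, :])
        totals = annual_series((100.0 * (1 + 0.1 * b_vals))[None, :])
        # balance B within each A phase by construction: alternate labels
        tab = cross_phase_table(totals, a, {"B": b}, a_name="A")
        for row in tab.index:
            if tab.loc[row, "B positive n"] and tab.loc[row, "B negative n"]:
                # exact when the row's B labels are balanced
                base = tab.loc[row, "mean_total"]
                np_ = tab.loc[row, "B positive n"]
                nn = tab.loc[row, "B negative n"]
                expected_pos = 100.0 * (110.0 / base - 1.0)
                assert tab.loc[row, "B positive %"] == pytest.approx(expected_pos)
        # the All Years row is exactly balanced
        assert tab.loc["All Years", "B positive %"] == pytest.approx(10.0)
        assert tab.loc["All Years", "B negative %"] == pytest.approx(-10.0)

    def test_sample_sizes_partition_rows(self):
        rng = np.random.default_rng(17)
        a = annual_series(rng.choice([1.0, 0.0, -1.0], size=(1, 90)))
        b = annual_series(rng.choice([1.0, -1.0], size=(1, 90)))
        totals = annual_series(rng.normal(100, 5, size=(1, 90)))
        tab = cross_phase_table(totals, a, {"B": b})
        for row in tab.index:
            assert (tab.loc[row, "B positive n"] + tab.loc[row, "B negative n"]
                    == tab.loc[row, "n_years"])

    def test_independent_b_shows_no_effect(self):
        rng = np.random.default_rng(18)
        a = annual_series(rng.choice([1.0, 0.0, -1.0], size=(1, 600)))
        b = annual_series(rng.choice([1.0, -1.0], size=(1, 600)))
        totals = annual_series(rng.normal(100.0, 5.0, size=(1, 600)))
        tab = cross_phase_table(totals, a, {"B": b})
        for row in tab.index:
            n = min(tab.loc[row, "B positive n"], tab.loc[row, "B negative n"])
            se_pct = 100.0 * (5.0 / 100.0) / np.sqrt(n) * 1.5
            assert abs(tab.loc[row, "B positive %"]) < 3.5 * se_pct


class TestClimateChange:
    def _fit_world(self, beta_scale, seed):
        rng = np.random.default_rng(seed)
        idx = annual_series(rng.standard_normal((40, 10)))
        beta = np.zeros((2, 3)); beta[0, :] = 0.3 * beta_scale
        lam = 6.0 * np.exp(idx.values[:, :, None, None] * beta[None, None])
        vals = rng.poisson(np.repeat(lam[:, :, None] / 12.0, 12, axis=2)).astype(float)
        cube = make_count_cube(vals)
        model = FireModeModel(cube, {"M": idx})
        return model.fit("M"), classify_phase(idx)

    def test_identical_climates_give_unit_strengthening(self):
        res, ph = self._fit_world(1.0, seed=19)
        ds = climate_change_effect(res, res, ph, ph)
        sig = ds["significant_both"].values
        assert np.allclose(ds["strengthening_positive"].values[sig], 1.0)
        np.testing.assert_array_equal(ds["sign_recent"].values,
                                      ds["sign_future"].values)

    def test_doubled_beta_strengthens_loaded_cells(self):
        res_r, ph_r = self._fit_world(1.0, seed=20)
        res_f, ph_f = self._fit_world(2.0, seed=21)
        ds = climate_change_effect(res_r, res_f, ph_r, ph_f)
        both = ds["significant_both"].values
        assert both[0].any()
        assert np.nanmean(ds["strengthening_positive"].values[both]) > 1.0

    def test_single_climate_significance_excluded_from_strengthening(self):
        res_r, ph_r = self._fit_world(1.0, seed=22)
        res_f, ph_f = self._fit_world(0.0, seed=23)  # no future effect
        ds = climate_change_effect(res_r, res_f, ph_r, ph_f)
        only_recent = (res_r.significant & ~res_f.significant).values
        assert only_recent.any()
        assert np.all(np.isnan(ds["strengthening_positive"].values[only_recent]))
        assert (ds["sign_recent"].values[only_recent] != 0).any()
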