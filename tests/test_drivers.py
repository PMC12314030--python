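"""Deviance partitioning, correlation-driver smooths and sign concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import divermap as dm
from divermap.correlation import CellSample
from divermap.drivers import DegenerateScalingError
from divermap.smooth import CollinearityError

from conftest import full_mask


def _cell_sample(n=2000, seed=0, signal="plant", noise=0.5):
    """Synthetic global sample: fungal driven by plant alone (or nothing)."""
    rng = np.random.default_rng(seed)
    data = {"row": np.zeros(n, int), "col": np.arange(n),
            "zone_id": np.full(n, -1)}
    data["plant"] = rng.normal(size=n)
    for c in dm.drivers.GLOBAL_COVARIATES:
        data[c] = rng.normal(size=n)
    if signal == "plant":
        data["fungal"] = 2.0 * data["plant"] + rng.normal(scale=noise, size=n)
    elif signal == "none":
        data["fungal"] = rng.normal(size=n)
    return CellSample(pd.DataFrame(data), "global", -1, n, seed)


class TestPartialDeviance:
    def test_direct_arithmetic(self):
        assert dm.partial_deviance_explained(40.0, 60.0, 100.0) == pytest.approx(20.0)

    def test_full_equals_reduced_gives_zero(self):
        assert dm.partial_deviance_explained(40.0, 40.0, 100.0) == 0.0

    def test_non_nested_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="non-nested"):
            assert dm.partial_deviance_explained(60.0, 40.0, 100.0) == 0.0

    def test_zero_null_deviance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            dm.partial_deviance_explained(1.0, 2.0, 0.0)


class TestGlobalDriverModel:
    def test_plant_term_dominates_when_only_plant_matters(self):
        fit = dm.fit_global_driver_model(_cell_sample(signal="plant"))
        assert fit.partition.partial_pct > 50.0
        # the same quantity via independent refits of an OLS-free path
        assert fit.partition.partial_pct == pytest.approx(
            100.0 * (fit.partition.deviance_reduced - fit.partition.deviance_full)
            / fit.partition.deviance_null)

    def test_null_world_explains_under_5pct(self):
        fit = dm.fit_global_driver_model(_cell_sample(signal="none", n=10_000))
        assert fit.deviance_explained_pct < 5.0
        assert fit.partition.partial_pct < 5.0

    def test_deterministic_refit(self):
        a = dm.fit_global_driver_model(_cell_sample(seed=3))
        b = dm.fit_global_driver_model(_cell_sample(seed=3))
        assert a.partition.deviance_full == b.partition.deviance_full
        assert a.partition.partial_pct == b.partition.partial_pct

    def test_partial_deviance_invariant_to_affine_covariate_rescale(self):
        sample = _cell_sample(seed=4)
        base = dm.fit_global_driver_model(sample).partition.partial_pct
        rescaled = CellSample(sample.table.copy(), "global", -1,
                              sample.requested_n, 4)
        rescaled.table["temperature"] = 100.0 * rescaled.table["temperature"] - 7.0
        again = dm.fit_global_driver_model(rescaled).partition.partial_pct
        assert again == pytest.approx(base, abs=1e-6)

    def test_missing_covariates_rejected(self):
        sample = _cell_sample()
        with pytest.raises(ValueError, match="missing"):
            dm.fit_global_driver_model(sample, covariates=("no_such_column",))


class TestCorrelationDriverModel:
    @staticmethod
    def _zone_table(n_zones=120, seed=0, stability_effect=True):
        rng = np.random.default_rng(seed)
        stability = rng.uniform(0, 1, n_zones)
        rho = (0.8 * stability if stability_effect else np.zeros(n_zones))
        rho = rho + rng.normal(scale=0.05, size=n_zones)
        return pd.DataFrame({
            "zone_id": np.arange(1, n_zones + 1),
            "rho": np.clip(rho, -1, 1),
            "host_pct": rng.uniform(0, 100, n_zones),
            "climate_stability": stability,
            "human_development": rng.uniform(0, 60, n_zones),
        })

    def test_recovers_constructed_stability_driver(self):
        fit = dm.fit_correlation_driver_model(self._zone_table(), covariates=())
        assert fit.model.term_contribution("climate_stability").std() > 0
        assert fit.term_partial_deviance("climate_stability") > 50.0
        x, _ = fit.partial_residuals("climate_stability")
        contrib = fit.model.term_contribution("climate_stability")
        order = np.argsort(x)
        # fitted partial effect increases monotonically across the range
        smoothed = np.interp(np.linspace(x.min(), x.max(), 10),
                             x[order], contrib[order])
        assert np.all(np.diff(smoothed) > -0.02)
        assert smoothed[-1] > smoothed[0] + 0.3

    def test_null_covariate_partial_effect_is_flat(self):
        fit = dm.fit_correlation_driver_model(self._zone_table(seed=1),
                                              covariates=())
        slope, lo, hi = fit.partial_slope("human_development")
        assert lo <= 0.0 <= hi

    def test_duplicate_covariate_columns_rejected(self):
        tbl = self._zone_table()
        tbl["stability_copy"] = tbl["climate_stability"]
        with pytest.raises(CollinearityError):
            dm.fit_correlation_driver_model(
                tbl, drivers=("host_pct", "climate_stability",
                              "human_development", "stability_copy"),
                covariates=())

    def test_insufficient_zones_rejected(self):
        with pytest.raises(ValueError, match="ecoregions"):
            dm.fit_correlation_driver_model(self._zone_table(n_zones=30),
                                            covariates=())


class TestZoneSignModels:
    @staticmethod
    def _zone_sample(slope_p, slope_f, n=200, seed=0):
        rng = np.random.default_rng(seed)
        env = np.linspace(0, 10, n) + rng.normal(scale=0.01, size=n)
        plant = 20 + slope_p * env + rng.normal(scale=1.0, size=n)
        fungal = 15 + slope_f * env + rng.normal(scale=1.0, size=n)
        host = 50 + rng.normal(scale=5.0, size=n)
        tbl = pd.DataFrame({"row": np.zeros(n, int), "col": np.arange(n),
                            "zone_id": np.ones(n, int), "plant": plant,
                            "fungal": fungal, "temperature": env,
                            "am_host_pct": host})
        return CellSample(tbl, "ecoregion", 1, n, seed)

    def test_both_increasing_gives_positive_pair(self):
        sp = dm.fit_zone_sign_models(self._zone_sample(2.0, 1.5),
                                     "temperature", "am_host_pct")
        assert sp.plant_coef > 0 and sp.fungal_coef > 0
        assert sp.plant_p < 0.05 and sp.fungal_p < 0.05
        assert sp.signs_agree and sp.rho_sign == 1

    def test_two_zone_fixture_recovers_opposite_signs(self, two_zone_world):
        b = two_zone_world
        p = dm.RichnessLayer(b.true["plant"].values, "raw")
        f = dm.RichnessLayer(b.true["AM"].values, "raw")
        samples, _ = dm.sample_cells(
            p, f, full_mask(b.shape), b.zones, "ecoregion", quota=500,
            min_cells=3, seed=0,
            extras={"temperature": b.covariates["temperature"],
                    "am_host_pct": b.covariates["am_host_pct"]})
        by_zone = {s.zone_id: dm.fit_zone_sign_models(s, "temperature",
                                                      "am_host_pct")
                   for s in samples}
        assert by_zone[1].signs_agree
        assert not by_zone[2].signs_agree
        assert by_zone[2].plant_coef > 0 > by_zone[2].fungal_coef

    def test_coefficients_match_normal_equations_oracle(self):
        sample = self._zone_sample(1.0, -1.0, n=60, seed=5)
        sp = dm.fit_zone_sign_models(sample, "temperature", "am_host_pct")

        def scale(v):
            v = np.asarray(v, float)
            return (v - v.min()) / (v.max() - v.min())

        env = scale(sample.table["temperature"])
        plant = scale(sample.table["plant"])
        fungal = scale(sample.table["fungal"])
        host = scale(sample.table["am_host_pct"])
        x = np.column_stack([np.ones(60), env, fungal, host])
        beta = np.linalg.solve(x.T @ x, x.T @ plant)
        assert sp.plant_coef == pytest.approx(beta[1], abs=1e-8)

    def test_too_few_unique_env_values_rejected(self):
        sample = self._zone_sample(1.0, 1.0)
        sample.table["temperature"] = np.repeat(np.arange(5.0), 40)
        with pytest.raises(ValueError, match="unique"):
            dm.fit_zone_sign_models(sample, "temperature", "am_host_pct")

    def test_constant_variable_degenerate_scaling(self):
        sample = self._zone_sample(1.0, 1.0)
        sample.table["am_host_pct"] = 50.0
        with pytest.raises(DegenerateScalingError):
            dm.fit_zone_sign_models(sample, "temperature", "am_host_pct")


def _sign_pair(zone, pc, fc, rho, p=0.001):
    return dm.SignPair(zone, "temperature", pc, p, fc, p, rho, 100)


class TestSignConcordance:
    def test_hand_chi_squared_on_fixed_table(self):
        pairs = []
        zone = 1
        for count, (agree, pos) in [(30, (True, True)), (10, (True, False)),
                                    (8, (False, True)), (25, (False, False))]:
            for _ in range(count):
                pc = 1.0
                fc = 1.0 if agree else -1.0
                rho = 0.5 if pos else -0.5
                pairs.append(_sign_pair(zone, pc, fc, rho))
                zone += 1
        res = dm.sign_concordance_test(pairs)
        obs = np.array([[30, 10], [8, 25]], dtype=float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        chi2_hand = float(((obs - expected) ** 2 / expected).sum())
        np.testing.assert_array_equal(res.table, obs.astype(int))
        assert res.chi2 == pytest.approx(chi2_hand, abs=1e-9)
        assert res.p == pytest.approx(1 - stats.chi2.cdf(chi2_hand, 1), abs=1e-12)

    @pytest.mark.parametrize("n", [10, 40, 160])
    def test_perfectly_concordant_p_shrinks_with_n(self, n):
        pairs = ([_sign_pair(i, 1.0, 1.0, 0.5) for i in range(n)]
                 + [_sign_pair(n + i, 1.0, -1.0, -0.5) for i in range(n)])
        res = dm.sign_concordance_test(pairs)
        assert res.chi2 == pytest.approx(2 * n)
        assert res.p < stats.chi2.sf(2 * min(10, n), 1) + 1e-12

    def test_uniform_table_is_exactly_null(self):
        pairs = []
        i = 0
        for agree in (True, False):
            for pos in (True, False):
                for _ in range(12):
                    pairs.append(_sign_pair(i, 1.0, 1.0 if agree else -1.0,
                                            0.5 if pos else -0.5))
                    i += 1
        res = dm.sign_concordance_test(pairs)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_p_filter_removes_rows_never_flips_signs(self):
        strong = [_sign_pair(i, 1.0, 1.0, 0.5) for i in range(20)]
        strong += [_sign_pair(100 + i, -1.0, 1.0, -0.5) for i in range(20)]
        weak = [_sign_pair(200 + i, -5.0, -5.0, 0.9, p=0.5) for i in range(10)]
        res = dm.sign_concordance_test(strong + weak)
        assert res.n_used == 40 and res.n_excluded == 10
        np.testing.assert_array_equal(res.table, [[20, 0], [0, 20]])

    def test_degenerate_table_rejected(self):
        pairs = [_sign_pair(i, 1.0, 1.0, 0.5) for i in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            dm.sign_concordance_test(pairs)


class TestCollinearitySensitivity:
    def _pairs(self):
        pairs = ([_sign_pair(i, 1.0, 1.0, 0.5) for i in range(30)]
                 + [_sign_pair(30 + i, 1.0, -1.0, -0.5) for i in range(30)])
        return pairs

    def test_no_zone_exceeds_cutoff_is_identity(self):
        pairs = self._pairs()
        corr = {sp.zone_id: 0.2 for sp in pairs}
        out = dm.collinearity_sensitivity(pairs, corr)
        base = dm.sign_concordance_test(pairs)
        assert (out["dropped_fraction"] == 0.0).all()
        assert out["chi2"].iloc[0] == pytest.approx(base.chi2)

    def test_all_zones_exceed_reports_error(self):
        pairs = self._pairs()
        corr = {sp.zone_id: 0.99 for sp in pairs}
        out = dm.collinearity_sensitivity(pairs, corr)
        assert (out["note"] != "").all() and out["chi2"].isna().all()

    def test_constructed_10pct_high_collinearity(self):
        pairs = self._pairs()
        corr = {sp.zone_id: (0.95 if sp.zone_id < 6 else 0.5) for sp in pairs}
        out = dm.collinearity_sensitivity(pairs, corr, cutoffs=(0.85,))
        assert out["dropped_fraction"].iloc[0] == pytest.approx(0.1)


class TestNormalityScreen:
    @staticmethod
    def _scan_of(draws_fn, n_zones=200, n=500, seed=0):
        rng = np.random.default_rng(seed)
        samples = {}
        rows = []
        for z in range(1, n_zones + 1):
            x = draws_fn(rng, n)
            tbl = pd.DataFrame({"row": np.zeros(n, int), "col": np.arange(n),
                                "zone_id": np.full(n, z), "plant": x,
                                "fungal": x})
            samples[("plant-AM", "ecoregion", z)] = CellSample(
                tbl, "ecoregion", z, n, seed)
            rows.append({"scale": "ecoregion", "zone_id": z,
                         "pair": "plant-AM", "rho": 0.5, "p": 0.01, "n": n})
        return dm.ScanResult(pd.DataFrame(rows), samples)

    def test_type_one_error_calibrated_on_normal_zones(self):
        scan = self._scan_of(lambda rng, n: rng.normal(size=n))
        table = dm.normality_screen(scan, "plant-AM", responses=("plant",))
        rate = table["flagged"].mean()
        assert 0.01 <= rate <= 0.10  # nominal 5%, binomial noise over 200 zones

    def test_exponential_zones_flagged_with_high_power(self):
        scan = self._scan_of(lambda rng, n: rng.exponential(size=n), n_zones=50)
        table = dm.normality_screen(scan, "plant-AM", responses=("plant",))
        assert table["flagged"].mean() > 0.99

    def test_constant_vector_not_testable(self):
        scan = self._scan_of(lambda rng, n: np.full(n, 3.0), n_zones=2)
        table = dm.normality_screen(scan, "plant-AM", responses=("plant",))
        assert (table["note"] == "not-testable").all()
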