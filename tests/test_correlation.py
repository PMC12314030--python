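"""Sampling, Spearman scans, biome t-tests and per-zone smooth fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import divermap as dm
from divermap.correlation import CellSample

from conftest import full_mask


def _sample_from_arrays(plant, fungal, **extra):
    n = len(plant)
    data = {"row": np.zeros(n, int), "col": np.arange(n), "zone_id": np.ones(n, int),
            "plant": np.asarray(plant, float), "fungal": np.asarray(fungal, float)}
    data.update({k: np.asarray(v, float) for k, v in extra.items()})
    return CellSample(pd.DataFrame(data), "ecoregion", 1, n, 0)


class TestSampleCells:
    def _world_layers(self, small_world):
        p = dm.RichnessLayer(small_world.true["plant"].values, "raw")
        f = dm.RichnessLayer(small_world.true["AM"].values, "raw")
        return p, f

    def test_small_zone_excluded_and_reported(self, small_world):
        p, f = self._world_layers(small_world)
        mask = np.zeros(small_world.shape, dtype=bool)
        # leave only 50 eligible cells in ecoregion 1, all cells elsewhere
        zone1 = small_world.zones.cells_in_ecoregion(1)
        mask[~zone1] = True
        idx = np.argwhere(zone1)[:50]
        mask[idx[:, 0], idx[:, 1]] = True
        samples, excluded = dm.sample_cells(p, f, dm.CellMask(mask),
                                            small_world.zones, "ecoregion",
                                            quota=1000, min_cells=100, seed=0)
        assert 1 in excluded["zone_id"].tolist()
        assert excluded.set_index("zone_id").loc[1, "n_eligible"] == 50
        assert all(s.zone_id != 1 for s in samples)

    def test_small_zone_uses_all_cells_when_above_minimum(self, small_world):
        p, f = self._world_layers(small_world)
        samples, excluded = dm.sample_cells(p, f, full_mask(small_world.shape),
                                            small_world.zones, "ecoregion",
                                            quota=1000, min_cells=100, seed=0)
        assert excluded.empty
        for s in samples:  # every zone has 400 cells < quota -> all used
            assert s.achieved_n == 400

    def test_same_seed_identical_and_no_duplicates(self, small_world):
        p, f = self._world_layers(small_world)
        a, _ = dm.sample_cells(p, f, full_mask(small_world.shape),
                               small_world.zones, "biome", quota=300, seed=42)
        b, _ = dm.sample_cells(p, f, full_mask(small_world.shape),
                               small_world.zones, "biome", quota=300, seed=42)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.table, sb.table)
            cells = list(zip(sa.table["row"], sa.table["col"]))
            assert len(cells) == len(set(cells))

    def test_no_masked_cells_anywhere_rejected(self, small_world):
        p, f = self._world_layers(small_world)
        empty = dm.CellMask(np.zeros(small_world.shape, dtype=bool))
        with pytest.raises(ValueError, match="no masked cells"):
            dm.sample_cells(p, f, empty, small_world.zones, "global", quota=10)

    def test_quota_must_be_positive(self, small_world):
        p, f = self._world_layers(small_world)
        with pytest.raises(ValueError):
            dm.sample_cells(p, f, full_mask(small_world.shape),
                            small_world.zones, "global", quota=0)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        plant = np.linspace(1, 9, 30)
        rec = dm.spearman_correlation(_sample_from_arrays(plant, plant ** 2))
        assert rec.rho == 1.0

    def test_negation_gives_minus_one(self):
        plant = np.linspace(1, 9, 30)
        rec = dm.spearman_correlation(_sample_from_arrays(plant, -plant))
        assert rec.rho == -1.0

    def test_five_point_rank_formula(self):
        # d^2 sums to 4: rho = 1 - 6*4/(5*24) = 0.8
        rec = dm.spearman_correlation(
            _sample_from_arrays([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert rec.rho == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_flagged_not_zeroed(self):
        rec = dm.spearman_correlation(_sample_from_arrays([1, 1, 1, 1], [1, 2, 3, 4]))
        assert np.isnan(rec.rho) and rec.note == "constant_input"

    def test_fewer_than_three_cells_rejected(self):
        with pytest.raises(ValueError):
            dm.spearman_correlation(_sample_from_arrays([1, 2], [3, 4]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 24 - 1), st.sampled_from(["exp", "cube", "affine"]))
    def test_invariance_under_increasing_transforms(self, seed, kind):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        fn = {"exp": np.exp, "cube": lambda v: v ** 3,
              "affine": lambda v: 3.0 * v + 1.0}[kind]
        base = dm.spearman_correlation(_sample_from_arrays(x, y)).rho
        txd = dm.spearman_correlation(_sample_from_arrays(fn(x), y)).rho
        assert txd == pytest.approx(base, abs=1e-12)


class TestScanAllScales:
    def test_mixed_sign_world_attenuates_globally(self):
        # two biomes with opposite-sign targets: global |rho| below mean |zonal|
        cfg = dm.WorldConfig(nrows=60, ncols=60, n_biomes=2,
                             ecoregions_per_biome=2, rho=[0.6, 0.6, -0.6, -0.6],
                             autocorr_length=1.0, noise_cv=0.05, seed=21)
        b = dm.make_world(cfg)
        pairs = {"plant-AM": dm.harmonize_pair(
            b.studies["plant"], b.studies["AM"], b.uncertainty["plant"],
            b.uncertainty["AM"], pair="plant-AM", zones=b.zones)}
        scan = dm.scan_all_scales(pairs, b.zones,
                                  quotas={"global": 2000, "biome": 1000,
                                          "ecoregion": 500},
                                  min_cells=100, seed=0)
        rec = scan.records
        global_rho = rec[rec["scale"] == "global"]["rho"].iloc[0]
        zonal = rec[rec["scale"] == "ecoregion"]["rho"].abs()
        assert abs(global_rho) < zonal.mean()
        assert abs(global_rho) < zonal.max()

    def test_records_match_direct_per_zone_computation(self, two_zone_world):
        b = two_zone_world
        pairs = {"plant-AM": dm.harmonize_pair(
            b.studies["plant"], b.studies["AM"], b.uncertainty["plant"],
            b.uncertainty["AM"], pair="plant-AM", zones=b.zones)}
        scan = dm.scan_all_scales(pairs, b.zones,
                                  quotas={"global": 500, "biome": 500,
                                          "ecoregion": 500},
                                  min_cells=3, seed=0)
        hp = pairs["plant-AM"]
        for eco in (1, 2):
            got = scan.records[(scan.records["scale"] == "ecoregion")
                               & (scan.records["zone_id"] == eco)]["rho"].iloc[0]
            sel = b.zones.cells_in_ecoregion(eco) & hp.mask.retained
            expect = stats.spearmanr(hp.plant_consensus.values[sel],
                                     hp.fungal_consensus.values[sel]).statistic
            assert got == pytest.approx(expect, abs=1e-12)

    def test_achieved_n_recorded(self, harmonized_small, small_world):
        scan = dm.scan_all_scales(harmonized_small, small_world.zones,
                                  quotas={"global": 1000, "biome": 700,
                                          "ecoregion": 200},
                                  min_cells=100, seed=1)
        rec = scan.records
        assert (rec[rec["scale"] == "ecoregion"]["n"] <= 200).all()
        assert set(rec["pair"]) == {"plant-AM", "plant-ECM"}


class TestBiomeSignTest:
    def test_zero_variance_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            dm.one_sample_sign_test(np.full(10, 0.5))

    def test_symmetric_null_gives_large_p(self):
        rhos = np.concatenate([np.linspace(-0.5, 0.5, 101)])
        t, p, mean = dm.one_sample_sign_test(rhos)
        assert p > 0.99 and abs(mean) < 1e-12

    def test_power_at_shifted_mean(self):
        # rho ~ N(0.3, 0.1), n=30: analytic power of the t-test > 0.99
        rng = np.random.default_rng(0)
        rejections = sum(
            dm.one_sample_sign_test(rng.normal(0.3, 0.1, size=30))[1] < 0.05
            for _ in range(50))
        assert rejections == 50

    def test_biome_table_layout(self, harmonized_small, small_world):
        scan = dm.scan_all_scales(harmonized_small, small_world.zones,
                                  quotas={"global": 500, "biome": 500,
                                          "ecoregion": 300},
                                  min_cells=100, seed=2)
        table = dm.biome_sign_test(scan.records, small_world.zones)
        assert set(table["biome_id"]) == set(small_world.zones.biome_ids())
        # rho targets are 0.8 everywhere: every biome should reject upward
        ok = table[table["note"] == ""]
        assert (ok["mean_rho"] > 0).all() and (ok["p"] < 0.05).all()


class TestRichnessSmooth:
    def test_perfect_linear_relationship(self):
        x = np.linspace(0, 10, 200)
        rec = dm.fit_richness_smooth(_sample_from_arrays(x, 3 * x + 2), k=3)
        assert rec.deviance_explained_pct >= 99.9

    def test_independent_noise_explains_little(self):
        rng = np.random.default_rng(5)
        rec = dm.fit_richness_smooth(
            _sample_from_arrays(rng.normal(size=1000), rng.normal(size=1000)), k=3)
        assert rec.deviance_explained_pct < 5.0

    def test_hump_beats_straight_line(self):
        rng = np.random.default_rng(6)
        x = np.linspace(-2, 2, 400)
        y = 4 - x ** 2 + rng.normal(scale=0.3, size=400)
        rec = dm.fit_richness_smooth(_sample_from_arrays(x, y), k=3)
        slope, intercept = np.polyfit(x, y, 1)
        line_r2 = 100 * (1 - np.sum((y - slope * x - intercept) ** 2)
                         / np.sum((y - y.mean()) ** 2))
        assert rec.deviance_explained_pct > line_r2 + 10

    def test_matches_linear_r2_when_truth_is_linear(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 600)
        y = 1.5 * x + rng.normal(scale=1.0, size=600)
        rec = dm.fit_richness_smooth(_sample_from_arrays(x, y), k=3)
        lm_r2 = 100 * stats.pearsonr(x, y).statistic ** 2
        assert rec.deviance_explained_pct == pytest.approx(lm_r2, abs=1.0)
        assert 0.0 <= rec.deviance_explained_pct <= 100.0

    def test_requires_ten_observations_per_basis_function(self):
        with pytest.raises(ValueError, match="10"):
            dm.fit_richness_smooth(
                _sample_from_arrays(np.arange(20.0), np.arange(20.0)), k=3)


class TestCompareMetrics:
    @staticmethod
    def _tables(strengths, seed=0):
        rng = np.random.default_rng(seed)
        corr_rows, fit_rows = [], []
        for zid, s in enumerate(strengths, start=1):
            x = np.linspace(0, 1, 300)
            y = s * x + rng.normal(scale=0.4, size=300)
            sample = _sample_from_arrays(x, y)
            rec = dm.spearman_correlation(sample)
            fit = dm.fit_richness_smooth(sample, k=3)
            corr_rows.append({"scale": "ecoregion", "zone_id": zid, "rho": rec.rho})
            fit_rows.append({"scale": "ecoregion", "zone_id": zid,
                             "deviance_explained_pct": fit.deviance_explained_pct})
        return pd.DataFrame(corr_rows), pd.DataFrame(fit_rows)

    def test_metrics_agree_on_monotone_worlds(self):
        corr, fits = self._tables([0.2, 0.6, 1.0, 1.6, 2.4, 4.0])
        assert dm.compare_metrics(corr, fits) == 1.0

    def test_shuffled_pairing_destroys_agreement(self):
        corr, fits = self._tables(np.linspace(0.1, 4.0, 30))
        shuffled = fits.copy()
        rng = np.random.default_rng(1)
        shuffled["deviance_explained_pct"] = rng.permutation(
            shuffled["deviance_explained_pct"].to_numpy())
        rho = dm.compare_metrics(corr, shuffled)
        # permutation null band for n=30 at 99%: ~0.47
        assert abs(rho) < 0.47

    def test_minimum_three_matched_zones(self):
        corr, fits = self._tables([0.5, 1.0])
        with pytest.raises(ValueError):
            dm.compare_metrics(corr, fits)
        corr3, fits3 = self._tables([0.5, 1.0, 2.0])
        assert np.isfinite(dm.compare_metrics(corr3, fits3))
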