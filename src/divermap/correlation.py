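"""Stratified cell sampling and plant-fungal correlation estimation.

Correlations are Spearman rank correlations (midrank ties), computed from
random grid cells drawn without replacement: a global draw, a draw per
biome, and a draw per ecoregion.  Ecoregions below a minimum cell count are
excluded and reported.  Per-ecoregion smooth fits (penalized regression
splines, k=3) provide a nonlinearity-tolerant companion metric, percent
deviance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedPair
from .layers import CellMask, RichnessLayer, ZoneMap, check_same_grid
from .smooth import AdditiveModel

DEFAULT_QUOTAS = {"global": 10_000, "biome": 10_000, "ecoregion": 1000}
_SCALE_CODE = {"global": 0, "biome": 1, "ecoregion": 2}


@dataclass
class CellSample:
    """Sampled cells for one zone (or the globe) with extracted values."""

    table: pd.DataFrame  # columns: row, col, zone_id, plant, fungal, extras...
    scale: str
    zone_id: int
    requested_n: int
    seed: int

    @property
    def achieved_n(self) -> int:
        return len(self.table)


@dataclass
class CorrelationRecord:
    scale: str
    zone_id: int
    pair: str
    rho: float
    p: float
    n: int
    note: str = ""


@dataclass
class SmoothFitRecord:
    scale: str
    zone_id: int
    pair: str
    deviance_explained_pct: float
    k: int
    n: int
    note: str = ""


def _zone_rng(seed: int, scale: str, zone_id: int) -> np.random.Generator:
    # independent substream per zone, so results do not depend on zone order
    ss = np.random.SeedSequence(seed, spawn_key=(_SCALE_CODE[scale], zone_id + 1))
    return np.random.default_rng(ss)


def sample_cells(plant: RichnessLayer, fungal: RichnessLayer, mask: CellMask,
                 zones: ZoneMap, scale: str, quota: int, min_cells: int = 1,
                 seed: int = 0,
                 extras: Mapping[str, np.ndarray] | None = None,
                 ) -> tuple[list[CellSample], pd.DataFrame]:
    """Draw up to `quota` distinct masked cells per zone, uniformly.

    Zones with fewer than ``min_cells`` eligible cells are excluded and
    listed in the returned report.  ``extras`` maps column name -> grid to
    extract alongside richness (covariates, raw richness, ...).
    """
    if quota <= 0:
        raise ValueError("quota must be positive")
    if scale not in _SCALE_CODE:
        raise ValueError(f"unknown scale {scale!r}")
    check_same_grid(plant.values, fungal.values, mask.retained, zones.zones)
    eligible = mask.retained & plant.valid & fungal.valid
    if not eligible.any():
        raise ValueError("no masked cells available anywhere")

    if scale == "global":
        zone_sel = {-1: np.ones(zones.shape, dtype=bool)}
    elif scale == "biome":
        zone_sel = {b: zones.cells_in_biome(b) for b in zones.biome_ids()}
    else:
        zone_sel = {e: zones.cells_in_ecoregion(e) for e in zones.ecoregion_ids()}

    extras = dict(extras or {})
    for name, grid in extras.items():
        check_same_grid(plant.values, grid)

    samples: list[CellSample] = []
    excluded = []
    for zone_id, sel in zone_sel.items():
        idx = np.flatnonzero(eligible & sel)
        if idx.size < max(min_cells, 3):
            excluded.append({"scale": scale, "zone_id": zone_id,
                             "n_eligible": int(idx.size), "min_cells": min_cells})
            continue
        n = min(quota, idx.size)
        rng = _zone_rng(seed, scale, zone_id)
        chosen = np.sort(rng.choice(idx, size=n, replace=False))
        rows, cols = np.unravel_index(chosen, zones.shape)
        data = {
            "row": rows, "col": cols,
            "zone_id": zones.zones[rows, cols],
            "plant": plant.values[rows, cols],
            "fungal": fungal.values[rows, cols],
        }
        for name, grid in extras.items():
            data[name] = np.asarray(grid, dtype=float)[rows, cols]
        samples.append(CellSample(pd.DataFrame(data), scale, int(zone_id), quota, seed))
    return samples, pd.DataFrame(excluded,
                                 columns=["scale", "zone_id", "n_eligible", "min_cells"])


def spearman_correlation(sample: CellSample, pair: str = "",
                         plant_col: str = "plant", fungal_col: str = "fungal",
                         ) -> CorrelationRecord:
    """Spearman rho on one sample; constant inputs are flagged, not zeroed."""
    x = sample.table[plant_col].to_numpy()
    y = sample.table[fungal_col].to_numpy()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationRecord(sample.scale, sample.zone_id, pair,
                                 np.nan, np.nan, n, note="constant_input")
    rho, p = stats.spearmanr(x, y)
    return CorrelationRecord(sample.scale, sample.zone_id, pair, float(rho), float(p), n)


@dataclass
class ScanResult:
    """Correlation records plus the exact samples they came from."""

    records: pd.DataFrame
    samples: dict[tuple[str, str, int], CellSample] = field(repr=False, default_factory=dict)
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sample(self, pair: str, scale: str, zone_id: int) -> CellSample:
        return self.samples[(pair, scale, zone_id)]


def scan_all_scales(pairs: Mapping[str, HarmonizedPair], zones: ZoneMap,
                    quotas: Mapping[str, int] = DEFAULT_QUOTAS,
                    min_cells: int = 100, seed: int = 0,
                    extras: Mapping[str, Mapping[str, np.ndarray]] | None = None,
                    ) -> ScanResult:
    """One Spearman record per scale x zone x taxon pair.

    ``extras`` maps pair name -> {column: grid} extracted with each sample
    (used downstream for covariate means).  The ecoregion minimum-cell rule
    uses ``min_cells``; global and biome draws only need enough cells for a
    correlation.
    """
    rows = []
    samples: dict[tuple[str, str, int], CellSample] = {}
    excluded_frames = []
    for pair_name, hp in pairs.items():
        pair_extras = (extras or {}).get(pair_name, {})
        for scale in ("global", "biome", "ecoregion"):
            scale_min = min_cells if scale == "ecoregion" else 3
            zone_samples, excl = sample_cells(
                hp.plant_consensus, hp.fungal_consensus, hp.mask, zones,
                scale=scale, quota=quotas[scale], min_cells=scale_min,
                seed=seed, extras=pair_extras)
            if len(excl):
                excl = excl.assign(pair=pair_name)
                excluded_frames.append(excl)
            for s in zone_samples:
                rec = spearman_correlation(s, pair=pair_name)
                rows.append(rec.__dict__)
                samples[(pair_name, scale, s.zone_id)] = s
    records = pd.DataFrame(rows)
    excluded = (pd.concat(excluded_frames, ignore_index=True)
                if excluded_frames else pd.DataFrame())
    return ScanResult(records, samples, excluded)


def one_sample_sign_test(rhos: np.ndarray) -> tuple[float, float, float]:
    """Two-sided one-sample t-test of ecoregion correlations against zero."""
    rhos = np.asarray(rhos, dtype=float)
    rhos = rhos[np.isfinite(rhos)]
    if rhos.size < 2:
        raise ValueError("need at least 2 ecoregion correlations")
    if np.std(rhos, ddof=1) == 0:
        raise ValueError("zero variance among correlations: t undefined")
    t, p = stats.ttest_1samp(rhos, 0.0)
    return float(t), float(p), float(rhos.mean())


def biome_sign_test(records: pd.DataFrame, zones: ZoneMap) -> pd.DataFrame:
    """Per-biome one-sample t-tests of ecoregion-level correlations."""
    eco = records[records["scale"] == "ecoregion"]
    rows = []
    for pair in sorted(eco["pair"].unique()):
        sub = eco[eco["pair"] == pair]
        biome_of = dict(zones.biome_of)
        for biome in zones.biome_ids():
            rhos = sub[sub["zone_id"].map(biome_of) == biome]["rho"].to_numpy()
            row = {"pair": pair, "biome_id": biome, "n_ecoregions": int(np.isfinite(rhos).sum())}
            try:
                t, p, mean_rho = one_sample_sign_test(rhos)
                row.update(t=t, p=p, mean_rho=mean_rho, note="")
            except ValueError as exc:
                row.update(t=np.nan, p=np.nan,
                           mean_rho=float(np.nanmean(rhos)) if len(rhos) else np.nan,
                           note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def fit_richness_smooth(sample: CellSample, k: int = 3, alpha: float = 0.0,
                        pair: str = "") -> SmoothFitRecord:
    """Smooth fit of fungal on plant richness; percent deviance explained."""
    n = sample.achieved_n
    if n < 10 * k:
        raise ValueError(f"need n >= 10*k = {10 * k} cells, have {n}")
    x = sample.table["plant"].to_numpy()
    y = sample.table["fungal"].to_numpy()
    try:
        model = AdditiveModel(y, {"plant": x}, k=k, alpha=alpha)
        dev_pct = model.deviance_explained_pct
        note = ""
    except (ValueError, ZeroDivisionError) as exc:
        return SmoothFitRecord(sample.scale, sample.zone_id, pair, np.nan, k, n,
                               note=str(exc))
    return SmoothFitRecord(sample.scale, sample.zone_id, pair, dev_pct, k, n, note)


def fit_ecoregion_smooths(scan: ScanResult, pair: str, k: int = 3) -> pd.DataFrame:
    rows = []
    for (p, scale, zone_id), sample in scan.samples.items():
        if p != pair or scale != "ecoregion":
            continue
        try:
            rec = fit_richness_smooth(sample, k=k, pair=pair)
            rows.append(rec.__dict__)
        except ValueError as exc:
            rows.append(dict(scale=scale, zone_id=zone_id, pair=pair,
                             deviance_explained_pct=np.nan, k=k,
                             n=sample.achieved_n, note=str(exc)))
    return pd.DataFrame(rows)


def compare_metrics(corr: pd.DataFrame, fits: pd.DataFrame) -> float:
    """Spearman between |rho| and smooth-fit deviance explained across zones."""
    c = corr[corr["scale"] == "ecoregion"][["zone_id", "rho"]]
    f = fits[fits["scale"] == "ecoregion"][["zone_id", "deviance_explained_pct"]]
    merged = c.merge(f, on="zone_id").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 matched ecoregions")
    rho, _ = stats.spearmanr(merged["rho"].abs(), merged["deviance_explained_pct"])
    return float(rho)
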