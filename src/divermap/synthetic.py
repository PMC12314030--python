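"""Synthetic geospatial worlds with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: spatially autocorrelated richness fields with per-ecoregion
plant-fungal Spearman targets (Gaussian-copula construction), paired noisy
"study" replicates per taxon with matching heteroscedastic uncertainty
surfaces in three reporting dialects, rectangular biome/ecoregion tiles,
and environmental covariates that can be wired to drive richness with
region-specific signs.

Richness link: ``S = round(exp(mu + sigma * G))`` clipped at 1, where G is
the (unit-variance) Gaussian score.  The per-zone Spearman between plant and
fungal scores is set exactly on the copula scale by mixing a shared field U
with a taxon-private field V using the Pearson weight r = 2*sin(pi*rho/6),
so the population Spearman equals the requested rho_e; any monotone link
preserves it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .layers import RichnessLayer, UncertaintyLayer, ZoneMap

TAXA = ("plant", "AM", "ECM")
COVARIATES = (
    "temperature", "precipitation", "ph", "soc", "nitrogen", "phosphorus",
    "elevation", "am_host_pct", "ecm_host_pct", "climate_stability",
    "human_development",
)

_DEFAULT_DIALECTS = {
    # mirrors the mix of reporting conventions across the four source studies
    "plant": ("iqr_ratio_percent", "cv_percent"),
    "AM": ("cv_percent", "sd"),
    "ECM": ("cv_percent", "sd"),
}

_DEFAULT_MEAN_LOG = {"plant": 6.0, "AM": 4.5, "ECM": 4.0}


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    ``rho`` is the per-ecoregion target Spearman between plant and fungal
    richness: a scalar (applied to all ecoregions), a sequence ordered by
    ecoregion id, or a mapping {ecoregion_id: rho}.  ``autocorr_length`` is
    the correlation range in cells (<= 1 means spatially independent cells).
    ``noise_cv`` sets each study replicate's observation noise: the per-cell
    noise SD is ``noise_cv * true richness``, modulated by a smooth field so
    uncertainty surfaces are heteroscedastic.  ``env_effects`` maps
    ecoregion id -> {covariate: (beta_plant, beta_fungal)}; effects are
    injected additively on the Gaussian scale before the richness link, so
    the sign table is exact ground truth for sign-concordance analyses.
    """

    nrows: int = 60
    ncols: int = 60
    n_biomes: int = 4
    ecoregions_per_biome: int = 4
    rho: float | Sequence[float] | Mapping[int, float] = 0.5
    autocorr_length: float = 3.0
    noise_cv: float = 0.2
    dialects: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_DIALECTS))
    env_effects: Mapping[int, Mapping[str, tuple[float, float]]] | None = None
    zone_covariate_shift: Mapping[int, Mapping[str, float]] | None = None
    mean_log: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEAN_LOG))
    sd_log: float = 0.6
    fungal_guilds: tuple[str, ...] = ("AM", "ECM")
    pre_logged_studies: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    @property
    def n_ecoregions(self) -> int:
        return self.n_biomes * self.ecoregions_per_biome

    def validate(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_biomes <= 0 or self.ecoregions_per_biome <= 0:
            raise ValueError("need at least one biome and one ecoregion per biome")
        if self.nrows < self.n_biomes or self.ncols < self.ecoregions_per_biome:
            raise ValueError("an ecoregion would be smaller than one cell")
        if self.noise_cv < 0:
            raise ValueError("noise level must be >= 0")
        for rho in self.rho_table().values():
            if not np.isfinite(rho) or not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho target {rho} outside [-1, 1]")

    def rho_table(self) -> dict[int, float]:
        """Target Spearman per ecoregion id (ids are 1-based)."""
        ids = range(1, self.n_ecoregions + 1)
        if isinstance(self.rho, Mapping):
            return {i: float(self.rho[i]) for i in ids}
        if np.isscalar(self.rho):
            return {i: float(self.rho) for i in ids}
        seq = list(self.rho)
        if len(seq) != self.n_ecoregions:
            raise ValueError("rho sequence length must equal the ecoregion count")
        return {i: float(seq[i - 1]) for i in ids}

    def to_json(self) -> str:
        def _convert(obj):
            if isinstance(obj, Mapping):
                return {str(k): _convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_convert(v) for v in obj]
            return obj
        return json.dumps({k: _convert(v) for k, v in self.__dict__.items()}, sort_keys=True)


@dataclass
class WorldBundle:
    """Everything :func:`make_world` produces, on one shared grid."""

    config: WorldConfig
    zones: ZoneMap
    true: dict[str, RichnessLayer]
    studies: dict[str, tuple[RichnessLayer, RichnessLayer]]
    uncertainty: dict[str, tuple[UncertaintyLayer, UncertaintyLayer]]
    noise_sd: dict[str, tuple[np.ndarray, np.ndarray]]
    covariates: dict[str, np.ndarray]

    @property
    def shape(self) -> tuple[int, int]:
        return self.zones.shape

    def is_pre_logged(self, taxon: str, study_index: int) -> bool:
        return (taxon, study_index) in self.config.pre_logged_studies


def _tile_zones(cfg: WorldConfig) -> ZoneMap:
    """Biomes are horizontal bands; ecoregions are vertical strips within."""
    zones = np.empty((cfg.nrows, cfg.ncols), dtype=np.int64)
    row_edges = np.linspace(0, cfg.nrows, cfg.n_biomes + 1).astype(int)
    col_edges = np.linspace(0, cfg.ncols, cfg.ecoregions_per_biome + 1).astype(int)
    lookup: dict[int, int] = {}
    for b in range(cfg.n_biomes):
        for e in range(cfg.ecoregions_per_biome):
            eco = b * cfg.ecoregions_per_biome + e + 1
            zones[row_edges[b]:row_edges[b + 1], col_edges[e]:col_edges[e + 1]] = eco
            lookup[eco] = b + 1
    return ZoneMap(zones, lookup)


def _gaussian_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Unit-variance Gaussian field with correlation range ~ `length` cells."""
    z = rng.standard_normal(shape)
    if length > 1.0:
        z = gaussian_filter(z, sigma=length / 2.0, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z


def _covariate_map(name: str, c: np.ndarray) -> np.ndarray:
    """Map a standardized Gaussian field to plausible covariate units.

    Every map is strictly monotone increasing in the underlying field, so
    injected Gaussian-scale response signs survive on the covariate scale.
    """
    if name == "temperature":
        return 15.0 + 10.0 * c
    if name == "precipitation":
        return np.exp(6.5 + 0.8 * c)
    if name == "ph":
        return 6.0 + 0.8 * c
    if name == "soc":
        return np.exp(3.0 + 0.7 * c)
    if name == "nitrogen":
        return np.exp(0.5 + 0.5 * c)
    if name == "phosphorus":
        return np.exp(2.0 + 0.6 * c)
    if name == "elevation":
        return 600.0 + 450.0 * c
    if name in ("am_host_pct", "ecm_host_pct"):
        return 100.0 / (1.0 + np.exp(-0.9 * c))
    if name == "climate_stability":
        return 1.0 / (1.0 + np.exp(-c))
    if name == "human_development":
        return 100.0 / (1.0 + np.exp(-(c - 1.0)))
    raise KeyError(name)


def make_world(config: WorldConfig) -> WorldBundle:
    """Generate a full synthetic world; same config + seed is bit-identical."""
    config.validate()
    cfg = config
    shape = (cfg.nrows, cfg.ncols)
    zones = _tile_zones(cfg)
    rho_by_zone = cfg.rho_table()

    ss = np.random.SeedSequence(cfg.seed)
    keys = (["U"] + [f"V_{g}" for g in cfg.fungal_guilds]
            + [f"C_{name}" for name in COVARIATES]
            + [f"noise_mod_{t}_{i}" for t in TAXA for i in (0, 1)]
            + [f"obs_{t}_{i}" for t in TAXA for i in (0, 1)])
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    u = _gaussian_field(rngs["U"], shape, cfg.autocorr_length)
    v = {g: _gaussian_field(rngs[f"V_{g}"], shape, cfg.autocorr_length)
         for g in cfg.fungal_guilds}

    # covariate fields on the Gaussian scale, with optional per-zone shifts
    cov_fields: dict[str, np.ndarray] = {}
    for name in COVARIATES:
        c = _gaussian_field(rngs[f"C_{name}"], shape, cfg.autocorr_length)
        if cfg.zone_covariate_shift:
            for eco, shifts in cfg.zone_covariate_shift.items():
                if name in shifts:
                    c = c + np.where(zones.zones == eco, float(shifts[name]), 0.0)
        cov_fields[name] = c
    covariates = {name: _covariate_map(name, cov_fields[name]) for name in COVARIATES}

    # Gaussian scores: copula mixing per ecoregion, then additive env effects
    scores: dict[str, np.ndarray] = {"plant": u.copy()}
    for g in cfg.fungal_guilds:
        xg = np.empty(shape)
        for eco, rho in rho_by_zone.items():
            r = 2.0 * np.sin(np.pi * rho / 6.0)  # Pearson weight hitting Spearman rho
            cells = zones.zones == eco
            xg[cells] = r * u[cells] + np.sqrt(max(0.0, 1.0 - r * r)) * v[g][cells]
        scores[g] = xg
    if cfg.env_effects:
        for eco, table in cfg.env_effects.items():
            cells = zones.zones == eco
            for cov_name, (beta_p, beta_f) in table.items():
                scores["plant"][cells] += beta_p * cov_fields[cov_name][cells]
                for g in cfg.fungal_guilds:
                    scores[g][cells] += beta_f * cov_fields[cov_name][cells]

    taxa = ("plant",) + tuple(cfg.fungal_guilds)
    true: dict[str, RichnessLayer] = {}
    studies: dict[str, tuple[RichnessLayer, RichnessLayer]] = {}
    uncertainty: dict[str, tuple[UncertaintyLayer, UncertaintyLayer]] = {}
    noise_sd: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in taxa:
        mu = float(cfg.mean_log.get(t, 4.0))
        s_true = np.maximum(np.round(np.exp(mu + cfg.sd_log * scores[t])), 1.0)
        true[t] = RichnessLayer(s_true, transform="raw", provenance=f"{t}-true")
        pair_layers, pair_unc, pair_sd = [], [], []
        for i in (0, 1):
            mod = _gaussian_field(rngs[f"noise_mod_{t}_{i}"], shape, cfg.autocorr_length)
            cv_cell = cfg.noise_cv * np.clip(1.0 + 0.4 * mod, 0.3, 2.0)
            sd_cell = cv_cell * s_true
            obs = s_true + rngs[f"obs_{t}_{i}"].standard_normal(shape) * sd_cell
            obs = np.maximum(obs, 0.0)
            prov = f"{t}-study{i}"
            if (t, i) in cfg.pre_logged_studies:
                layer = RichnessLayer(np.log1p(obs), transform="log1p", provenance=prov)
            else:
                layer = RichnessLayer(obs, transform="raw", provenance=prov)
            dialect = cfg.dialects.get(t, ("sd", "sd"))[i]
            if dialect == "cv_percent":
                uvals = 100.0 * np.divide(sd_cell, s_true,
                                          out=np.zeros_like(sd_cell), where=s_true > 0)
            elif dialect == "sd":
                uvals = sd_cell
            elif dialect == "iqr_ratio_percent":
                # IQR of a normal is 1.349 SD; ratio is relative to the median
                uvals = 100.0 * 1.349 * np.divide(sd_cell, s_true,
                                                  out=np.zeros_like(sd_cell),
                                                  where=s_true > 0)
            else:
                raise ValueError(f"unknown uncertainty dialect {dialect!r}")
            pair_layers.append(layer)
            pair_unc.append(UncertaintyLayer(uvals, dialect=dialect, provenance=prov))
            pair_sd.append(sd_cell)
        studies[t] = (pair_layers[0], pair_layers[1])
        uncertainty[t] = (pair_unc[0], pair_unc[1])
        noise_sd[t] = (pair_sd[0], pair_sd[1])

    return WorldBundle(config=cfg, zones=zones, true=true, studies=studies,
                       uncertainty=uncertainty, noise_sd=noise_sd,
                       covariates=covariates)


# ---------------------------------------------------------------------------
# hand-enumerable fixtures

_FIXTURES = ("tiny-4x5", "two-zone-opposite-signs", "hotspot-known-overlap")


def _bundle_from_arrays(plant, fungal, zones, covariates=None, guild="AM") -> WorldBundle:
    cfg = WorldConfig(nrows=plant.shape[0], ncols=plant.shape[1], n_biomes=1,
                      ecoregions_per_biome=1, rho=0.0, noise_cv=0.0,
                      fungal_guilds=(guild,), seed=0)
    true = {"plant": RichnessLayer(plant, "raw", "plant-true"),
            guild: RichnessLayer(fungal, "raw", f"{guild}-true")}
    studies = {t: (RichnessLayer(l.values.copy(), "raw", f"{t}-study0"),
                   RichnessLayer(l.values.copy(), "raw", f"{t}-study1"))
               for t, l in true.items()}
    zeros = np.zeros_like(plant, dtype=float)
    unc = {t: (UncertaintyLayer(zeros.copy(), "sd", f"{t}-study0"),
               UncertaintyLayer(zeros.copy(), "sd", f"{t}-study1")) for t in true}
    nsd = {t: (zeros.copy(), zeros.copy()) for t in true}
    covs = {name: np.zeros_like(plant, dtype=float) for name in COVARIATES}
    if covariates:
        covs.update(covariates)
    return WorldBundle(cfg, zones, true, studies, unc, nsd, covs)


def make_fixture(name: str) -> WorldBundle:
    """Return a small hand-enumerable world from the fixture registry.

    - ``tiny-4x5``: 20 cells, one zone; plant richness is the distinct
      integers 1..20 in row-major order, fungal is a fixed permutation.
    - ``two-zone-opposite-signs``: temperature gradient; in zone 1 both taxa
      increase with temperature, in zone 2 plant increases and fungal
      decreases.
    - ``hotspot-known-overlap``: 100 cells; the plant and fungal top-5%
      (5-cell) sets overlap in exactly 2 cells.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {_FIXTURES}")

    if name == "tiny-4x5":
        plant = np.arange(1, 21, dtype=float).reshape(4, 5)
        # deterministic permutation: reverse rows then shift by 7
        fungal = np.roll(np.arange(1, 21, dtype=float)[::-1], 7).reshape(4, 5)
        zones = ZoneMap(np.ones((4, 5), dtype=np.int64), {1: 1})
        return _bundle_from_arrays(plant, fungal, zones)

    if name == "two-zone-opposite-signs":
        nrows, ncols = 10, 20
        col = np.tile(np.arange(ncols, dtype=float), (nrows, 1))
        temp = col  # temperature rises left to right
        z = np.where(col < 10, 1, 2).astype(np.int64)
        zones = ZoneMap(z, {1: 1, 2: 2})
        rng = np.random.default_rng(20240101)
        noise = rng.normal(scale=1.0, size=(4, nrows, ncols))
        plant = 50.0 + 2.0 * temp + noise[0]
        fungal = np.where(z == 1,
                          30.0 + 1.5 * temp + noise[1],
                          80.0 - 1.5 * temp + noise[2])
        host = 50.0 + 5.0 * np.tile(np.linspace(-1, 1, nrows)[:, None], (1, ncols))
        host = host + 0.5 * noise[3]
        covs = {"temperature": temp, "am_host_pct": host, "ecm_host_pct": host}
        return _bundle_from_arrays(np.maximum(plant, 1.0), np.maximum(fungal, 1.0),
                                   zones, covariates=covs)

    # hotspot-known-overlap: 10x10 grid, distinct values 1..100 per taxon
    plant = np.arange(1.0, 101.0).reshape(10, 10)           # top-5 cells: 95..99 flat
    fungal = np.empty(100)
    top_plant = [95, 96, 97, 98, 99]
    top_fungal = [98, 99, 10, 11, 12]                        # overlap {98, 99} -> 2 of 5
    rest = [i for i in range(100) if i not in top_fungal]
    fungal[rest] = np.arange(1.0, 96.0)
    fungal[top_fungal] = np.arange(96.0, 101.0)
    fungal = fungal.reshape(10, 10)
    zones = ZoneMap(np.ones((10, 10), dtype=np.int64), {1: 1})
    bundle = _bundle_from_arrays(plant, fungal, zones)
    assert len(set(top_plant) & set(top_fungal)) == 2
    return bundle


def make_overlap_world(overlap_fraction: float, shape: tuple[int, int] = (300, 300),
                       q: float = 95.0, seed: int = 0):
    """Construct plant/fungal layers whose top-(100-q)% regions overlap in a
    known fraction of the fungal hotspot.

    Returns ``(plant, fungal, expected_overlap_pct)``.  High-richness blocks
    of exactly (100-q)% of cells are placed with the requested intersection;
    continuous background noise keeps percentile thresholds untied.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap fraction must be in [0, 1]")
    nrows, ncols = shape
    n = nrows * ncols
    block = int(round(n * (100.0 - q) / 100.0))
    width = max(1, block // 30)
    depth = int(np.ceil(block / width))
    rng = np.random.default_rng(seed)
    plant = rng.uniform(0.0, 1.0, size=shape)
    fungal = rng.uniform(0.0, 1.0, size=shape)
    # plant block in the top-left corner; fungal block shifted right so the
    # column overlap equals the requested fraction of the block width
    flat = np.arange(n).reshape(shape)
    plant_cells = (flat // ncols < depth) & (flat % ncols < width)
    plant_cells &= plant_cells.cumsum().reshape(shape) <= block
    shift = int(round((1.0 - overlap_fraction) * width))
    fungal_cells = (flat // ncols < depth) & (flat % ncols >= shift) & (flat % ncols < shift + width)
    fungal_cells &= fungal_cells.cumsum().reshape(shape) <= block
    plant = plant + 10.0 * plant_cells
    fungal = fungal + 10.0 * fungal_cells
    expected = 100.0 * (plant_cells & fungal_cells).sum() / fungal_cells.sum()
    return (RichnessLayer(plant, "raw", "plant-overlap"),
            RichnessLayer(fungal, "raw", "fungal-overlap"),
            float(expected))


def write_world(bundle: WorldBundle, out_dir) -> dict[str, str]:
    """Write every layer of a world as rasters + the zone lookup + config."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry: dict[str, str] = {}

    def _reg(key, path):
        registry[key] = str(path)

    for t, layer in bundle.true.items():
        _reg(f"true_{t}", _io.write_raster(layer, out / f"true_{t}.tif"))
        for i in (0, 1):
            _reg(f"study_{t}_{i}", _io.write_raster(bundle.studies[t][i], out / f"study_{t}_{i}.tif"))
            _reg(f"uncertainty_{t}_{i}",
                 _io.write_raster(bundle.uncertainty[t][i], out / f"uncertainty_{t}_{i}.tif"))
    for name, arr in bundle.covariates.items():
        p = out / f"cov_{name}.tif"
        _io._write_array(p, arr, _io.DEFAULT_NODATA, {"kind": "covariate", "name": name})
        _reg(f"cov_{name}", p)
    _io.write_zonemap(bundle.zones, out / "zones.tif", out / "zones_lookup.csv")
    _reg("zones", out / "zones.tif")
    _reg("zones_lookup", out / "zones_lookup.csv")
    (out / "world_config.json").write_text(bundle.config.to_json())
    _reg("config", out / "world_config.json")
    return registry
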