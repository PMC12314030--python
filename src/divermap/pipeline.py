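"""End-to-end driver: simulate -> harmonize -> scan -> drivers -> mc -> hotspots.

Every stage writes tidy CSV/JSON outputs carrying the config hash in a
header comment, and a run manifest records what was produced.  Re-running
with the same config (which includes all seeds) reproduces every CSV
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drivers as drv
from . import harmonize as hz
from . import hotspots as hs
from . import io as _io
from . import montecarlo as mc
from .correlation import (DEFAULT_QUOTAS, biome_sign_test, compare_metrics,
                          fit_ecoregion_smooths, scan_all_scales)
from .synthetic import COVARIATES, WorldBundle, WorldConfig, make_world, write_world

_HOST_COL = {"AM": "am_host_pct", "ECM": "ecm_host_pct"}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    quotas: dict = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    min_cells: int = 100
    q_uncertainty: float = 95.0
    hotspot_q: float = 95.0
    env_vars: tuple[str, ...] = ("temperature", "precipitation", "ph")
    alpha: float = 0.05
    k_global: int = 3
    k_driver: int = 4
    driver_min_zones: int = 50
    mc_iterations: int = 1000
    mc_scales: tuple[str, ...] = ("global", "biome")
    out_dir: str = "divermap-run"

    def validate(self) -> None:
        self.world.validate()
        for scale, q in self.quotas.items():
            if q <= 0:
                raise ValueError(f"quota for {scale!r} must be positive")
        if self.min_cells < 3:
            raise ValueError("min_cells must be >= 3")
        if not 0 < self.q_uncertainty < 100 or not 0 < self.hotspot_q < 100:
            raise ValueError("percentiles must be in (0, 100)")
        if self.mc_iterations < 1:
            raise ValueError("mc_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_json(self) -> str:
        def _plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: _plain(v) for k, v in obj.__dict__.items()}
            if isinstance(obj, dict):
                return {str(k): _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj
        return json.dumps(_plain(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        # out_dir is a storage location, not part of the scientific config:
        # two runs of the same analysis must hash (and diff) identically
        blob = json.loads(self.to_json())
        blob.pop("out_dir", None)
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    files: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=2)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def _write_json(obj, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=str))
    return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all five analysis stages on a synthetic world."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash)
    chash = config.config_hash

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
        return _Timer()

    def _reg(key, path):
        manifest.files[key] = str(path)

    # 1. simulate ----------------------------------------------------------
    with _stage("simulate"):
        bundle = make_world(config.world)
        registry = write_world(bundle, out / "world")
        for key, path in registry.items():
            _reg(f"world/{key}", path)

    # 2. harmonize ---------------------------------------------------------
    with _stage("harmonize"):
        pairs: dict[str, hz.HarmonizedPair] = {}
        threshold_rows = []
        for guild in bundle.config.fungal_guilds:
            pair_name = f"plant-{guild}"
            hp = hz.harmonize_pair(
                bundle.studies["plant"], bundle.studies[guild],
                bundle.uncertainty["plant"], bundle.uncertainty[guild],
                pair=pair_name, q=config.q_uncertainty, zones=bundle.zones,
                plant_pre_logged=tuple(bundle.is_pre_logged("plant", i) for i in (0, 1)),
                fungal_pre_logged=tuple(bundle.is_pre_logged(guild, i) for i in (0, 1)))
            pairs[pair_name] = hp
            for key, thr in hp.thresholds.items():
                threshold_rows.append({"pair": pair_name, "mask": key, "threshold": thr})
            for key, shift in hp.cv_shifts.items():
                threshold_rows.append({"pair": pair_name, "mask": f"{key}_cv_shift",
                                       "threshold": shift})
            _reg(f"harmonize/{pair_name}/mask",
                 _io.write_raster(hp.mask, out / "harmonize" / f"mask_{pair_name}.tif"))
            _reg(f"harmonize/{pair_name}/plant_consensus",
                 _io.write_raster(hp.plant_consensus,
                                  out / "harmonize" / f"consensus_plant_{pair_name}.tif"))
            _reg(f"harmonize/{pair_name}/fungal_consensus",
                 _io.write_raster(hp.fungal_consensus,
                                  out / "harmonize" / f"consensus_fungal_{pair_name}.tif"))
            _reg(f"harmonize/{pair_name}/retained",
                 _write_csv(hp.retained, out / "harmonize" / f"retained_{pair_name}.csv", chash))
        _reg("harmonize/thresholds",
             _write_csv(pd.DataFrame(threshold_rows),
                        out / "harmonize" / "thresholds.csv", chash))

    # 3. scan --------------------------------------------------------------
    with _stage("scan"):
        extras = {}
        for guild in bundle.config.fungal_guilds:
            pair_name = f"plant-{guild}"
            grids = dict(bundle.covariates)
            grids["raw_plant"] = (bundle.studies["plant"][0].values
                                  + bundle.studies["plant"][1].values) / 2.0
            grids["raw_fungal"] = (bundle.studies[guild][0].values
                                   + bundle.studies[guild][1].values) / 2.0
            extras[pair_name] = grids
        scan = scan_all_scales(pairs, bundle.zones, quotas=config.quotas,
                               min_cells=config.min_cells,
                               seed=bundle.config.seed, extras=extras)
        _reg("scan/correlations",
             _write_csv(scan.records, out / "scan" / "correlations.csv", chash))
        _reg("scan/excluded",
             _write_csv(scan.excluded, out / "scan" / "excluded_zones.csv", chash))
        _reg("scan/biome_t_tests",
             _write_csv(biome_sign_test(scan.records, bundle.zones),
                        out / "scan" / "biome_t_tests.csv", chash))
        metric_comparison = {}
        for guild in bundle.config.fungal_guilds:
            pair_name = f"plant-{guild}"
            fits = fit_ecoregion_smooths(scan, pair_name, k=config.k_global)
            _reg(f"scan/smooth_fits_{pair_name}",
                 _write_csv(fits, out / "scan" / f"smooth_fits_{pair_name}.csv", chash))
            try:
                metric_comparison[pair_name] = compare_metrics(
                    scan.records[scan.records["pair"] == pair_name], fits)
            except ValueError as exc:
                manifest.warnings.append(f"compare_metrics {pair_name}: {exc}")
        _reg("scan/metric_comparison",
             _write_json(metric_comparison, out / "scan" / "metric_comparison.json"))

    # 4. drivers -----------------------------------------------------------
    with _stage("drivers"):
        partition_rows = []
        for guild in bundle.config.fungal_guilds:
            pair_name = f"plant-{guild}"
            host_col = _HOST_COL.get(guild, "am_host_pct")
            gsample = scan.sample(pair_name, "global", -1)
            gfit = drv.fit_global_driver_model(gsample, k=config.k_global,
                                               pair=pair_name)
            partition_rows.append({
                "pair": pair_name,
                "deviance_full": gfit.partition.deviance_full,
                "deviance_reduced": gfit.partition.deviance_reduced,
                "deviance_null": gfit.partition.deviance_null,
                "plant_partial_deviance_pct": gfit.partition.partial_pct,
                "model_deviance_explained_pct": gfit.deviance_explained_pct,
                "n": gfit.n,
            })
            # ecoregion-level correlation-driver model
            ztab = drv.build_zone_driver_table(scan, pair_name, host_col)
            _reg(f"drivers/zone_table_{pair_name}",
                 _write_csv(ztab, out / "drivers" / f"zone_table_{pair_name}.csv", chash))
            try:
                cfit = drv.fit_correlation_driver_model(
                    ztab, k=config.k_driver, min_zones=config.driver_min_zones)
                curves = []
                for term in cfit.model.terms:
                    x, pr = cfit.partial_residuals(term)
                    curves.append(pd.DataFrame({"term": term, "x": x,
                                                "partial_residual": pr}))
                _reg(f"drivers/partial_residuals_{pair_name}",
                     _write_csv(pd.concat(curves, ignore_index=True),
                                out / "drivers" / f"partial_residuals_{pair_name}.csv",
                                chash))
            except ValueError as exc:
                manifest.warnings.append(f"correlation-driver model {pair_name}: {exc}")
            # sign concordance per environmental variable
            concordance = {}
            sign_rows = []
            for env_var in config.env_vars:
                sps, dropped = drv.collect_sign_pairs(scan, pair_name, env_var,
                                                      host_col)
                for sp in sps:
                    sign_rows.append(dict(pair=pair_name, **sp.__dict__))
                try:
                    res = drv.sign_concordance_test(sps, alpha=config.alpha)
                    colin = drv.zone_covariate_collinearity(
                        scan, pair_name, (env_var, "plant", "fungal", host_col))
                    sens = drv.collinearity_sensitivity(sps, colin, alpha=config.alpha)
                    concordance[env_var] = {
                        "table": res.table.tolist(), "chi2": res.chi2, "p": res.p,
                        "chi2_corrected": res.chi2_corrected,
                        "p_corrected": res.p_corrected,
                        "n_used": res.n_used, "n_excluded": res.n_excluded,
                        "low_expected": res.low_expected,
                        "n_dropped_zones": int(len(dropped)),
                        "collinearity_sensitivity": sens.to_dict("records"),
                    }
                except ValueError as exc:
                    concordance[env_var] = {"error": str(exc)}
            _reg(f"drivers/concordance_{pair_name}",
                 _write_json(concordance, out / "drivers" / f"concordance_{pair_name}.json"))
            _reg(f"drivers/sign_pairs_{pair_name}",
                 _write_csv(pd.DataFrame(sign_rows),
                            out / "drivers" / f"sign_pairs_{pair_name}.csv", chash))
            _reg(f"drivers/normality_{pair_name}",
                 _write_csv(drv.normality_screen(scan, pair_name,
                                                 seed=bundle.config.seed),
                            out / "drivers" / f"normality_{pair_name}.csv", chash))
        _reg("drivers/deviance_partition",
             _write_csv(pd.DataFrame(partition_rows),
                        out / "drivers" / "deviance_partition.csv", chash))

    # 5. mc ----------------------------------------------------------------
    with _stage("mc"):
        mc_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # IQR normality caveat logged once below
            for guild in bundle.config.fungal_guilds:
                pair_name = f"plant-{guild}"
                sd_layers = {}
                for taxon in ("plant", guild):
                    sd_layers[taxon] = tuple(
                        mc.to_sd(bundle.uncertainty[taxon][i],
                                 bundle.studies[taxon][i]).sd
                        for i in (0, 1))
                zone_keys = [("global", -1)]
                if "biome" in config.mc_scales:
                    zone_keys += [("biome", b) for b in bundle.zones.biome_ids()]
                for scale, zone_id in zone_keys:
                    if scale not in config.mc_scales:
                        continue
                    key = (pair_name, scale, zone_id)
                    if key not in scan.samples:
                        continue
                    sample = scan.samples[key]
                    rows_idx = sample.table["row"].to_numpy()
                    cols_idx = sample.table["col"].to_numpy()
                    plant_in = tuple(
                        mc.make_study_input(bundle.studies["plant"][i],
                                            sd_layers["plant"][i], rows_idx, cols_idx,
                                            pre_logged=bundle.is_pre_logged("plant", i))
                        for i in (0, 1))
                    fungal_in = tuple(
                        mc.make_study_input(bundle.studies[guild][i],
                                            sd_layers[guild][i], rows_idx, cols_idx,
                                            pre_logged=bundle.is_pre_logged(guild, i))
                        for i in (0, 1))
                    dist = mc.perturb_and_correlate(
                        plant_in, fungal_in, n_iterations=config.mc_iterations,
                        seed=bundle.config.seed, pair=pair_name, scale=scale,
                        zone_id=zone_id)
                    ref = scan.records[
                        (scan.records["pair"] == pair_name)
                        & (scan.records["scale"] == scale)
                        & (scan.records["zone_id"] == zone_id)]["rho"].iloc[0]
                    summary = mc.mc_summary(dist, ref)
                    mc_rows.append({"pair": pair_name, "scale": scale,
                                    "zone_id": zone_id,
                                    "iterations": dist.n_iterations,
                                    "clamped": dist.clamped,
                                    **summary.__dict__})
        if any(u.dialect == "iqr_ratio_percent"
               for t in bundle.uncertainty.values() for u in t):
            manifest.warnings.append(
                "IQR-ratio uncertainty dialect converted to SD under a "
                "normality assumption on the source replicates")
        _reg("mc/summaries",
             _write_csv(pd.DataFrame(mc_rows), out / "mc" / "summaries.csv", chash))

    # 6. hotspots ----------------------------------------------------------
    with _stage("hotspots"):
        overlap_frames = []
        for guild in bundle.config.fungal_guilds:
            pair_name = f"plant-{guild}"
            hp = pairs[pair_name]
            p_union = hs.union_hotspots(
                *[hs.hotspot_mask(s, hp.mask, config.hotspot_q)
                  for s in bundle.studies["plant"]])
            f_union = hs.union_hotspots(
                *[hs.hotspot_mask(s, hp.mask, config.hotspot_q)
                  for s in bundle.studies[guild]])
            summary = hs.overlap_summary(f_union, p_union, bundle.zones)
            recomputed = hs.within_biome_overlap(
                bundle.studies["plant"], bundle.studies[guild], hp.mask,
                bundle.zones, q=config.hotspot_q)
            both = pd.concat([summary, recomputed], ignore_index=True)
            both.insert(0, "pair", pair_name)
            overlap_frames.append(both)
            host_col = _HOST_COL.get(guild, "am_host_pct")
            host_grid = bundle.covariates[host_col]
            host_means = {
                b: float(host_grid[bundle.zones.cells_in_biome(b) & hp.mask.retained].mean())
                for b in bundle.zones.biome_ids()}
            try:
                hvh = hs.overlap_vs_host_prevalence(summary, host_means)
            except ValueError as exc:
                hvh = {"error": str(exc)}
            _reg(f"hotspots/host_prevalence_{pair_name}",
                 _write_json(hvh, out / "hotspots" / f"host_prevalence_{pair_name}.json"))
        _reg("hotspots/overlap",
             _write_csv(pd.concat(overlap_frames, ignore_index=True),
                        out / "hotspots" / "overlap.csv", chash))

    _reg("manifest", out / "manifest.json")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
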