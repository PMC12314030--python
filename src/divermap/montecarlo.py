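"""Monte-Carlo propagation of per-cell prediction uncertainty into the
plant-fungal correlations.

Each source study reports spread in its own dialect; everything is first
converted to a per-cell SD (CV%: /100 x mean; IQR-ratio%: /100 x median
x 1.35, a normal-theory approximation).  Then, holding the original random
cell sample fixed, every iteration (1) perturbs each study's richness value
by Uniform(-SD, +SD), (2) log1p-transforms layers not already on the log
scale, (3) standardizes with the full layer's constants (not the sample's),
(4) averages the two studies per taxon, and (5) recomputes the Spearman
correlation.  The spread of the resulting correlation distribution measures
how fragile the baseline estimate is to prediction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .layers import RichnessLayer, UncertaintyLayer, check_same_grid

IQR_TO_SD_CONSTANT = 1.35
LOG_CLAMP_EPS = 1e-9


@dataclass
class SpreadConversion:
    sd: UncertaintyLayer
    input_dialect: str
    constant: float


def cv_to_sd(u: UncertaintyLayer, mean_layer: RichnessLayer) -> SpreadConversion:
    """CV% -> SD: divide by 100, multiply by the cell mean."""
    if u.dialect != "cv_percent":
        raise ValueError(f"expected cv_percent dialect, got {u.dialect!r}")
    check_same_grid(u.values, mean_layer.values)
    sd = u.values / 100.0 * mean_layer.values
    return SpreadConversion(UncertaintyLayer(np.abs(sd), "sd", u.provenance),
                            "cv_percent", 0.01)


def sd_to_cv(u: UncertaintyLayer, mean_layer: RichnessLayer) -> UncertaintyLayer:
    """SD -> CV% (inverse of :func:`cv_to_sd`, for round-trip checks)."""
    if u.dialect != "sd":
        raise ValueError(f"expected sd dialect, got {u.dialect!r}")
    check_same_grid(u.values, mean_layer.values)
    cv = 100.0 * u.values / mean_layer.values
    return UncertaintyLayer(np.abs(cv), "cv_percent", u.provenance)


def iqr_ratio_to_sd(u: UncertaintyLayer, median_layer: RichnessLayer) -> SpreadConversion:
    """IQR/median% -> SD: /100 x median x 1.35.

    Valid when the underlying replicate distribution is roughly normal
    (IQR of a normal is 1.349 SD); the median layer is treated as the mean
    downstream.
    """
    if u.dialect != "iqr_ratio_percent":
        raise ValueError(f"expected iqr_ratio_percent dialect, got {u.dialect!r}")
    check_same_grid(u.values, median_layer.values)
    warnings.warn("IQR-ratio -> SD conversion assumes normally distributed "
                  "replicates", stacklevel=2)
    sd = u.values / 100.0 * median_layer.values * IQR_TO_SD_CONSTANT
    return SpreadConversion(UncertaintyLayer(np.abs(sd), "sd", u.provenance),
                            "iqr_ratio_percent", IQR_TO_SD_CONSTANT)


def to_sd(u: UncertaintyLayer, central: RichnessLayer) -> SpreadConversion:
    """Dispatch any dialect to an SD layer."""
    if u.dialect == "sd":
        return SpreadConversion(u, "sd", 1.0)
    if u.dialect == "cv_percent":
        return cv_to_sd(u, central)
    if u.dialect == "iqr_ratio_percent":
        return iqr_ratio_to_sd(u, central)
    raise ValueError(f"cannot convert dialect {u.dialect!r} to SD")


@dataclass
class McStudyInput:
    """One study layer restricted to the fixed cell sample."""

    values: np.ndarray        # richness at the sampled cells (study's own scale)
    sd: np.ndarray            # per-cell SD at the same cells
    pre_logged: bool          # values already log1p-transformed at source
    standardize_mean: float   # full-layer log-scale constants
    standardize_sd: float


def make_study_input(layer: RichnessLayer, sd_layer: UncertaintyLayer,
                     rows: np.ndarray, cols: np.ndarray,
                     pre_logged: bool = False) -> McStudyInput:
    """Extract sampled-cell values + SDs and the full-layer standardization
    constants (computed from the whole raster, as the procedure requires)."""
    if sd_layer.dialect != "sd":
        raise ValueError("sd_layer must be in the sd dialect; convert first")
    check_same_grid(layer.values, sd_layer.values)
    full = layer.values[layer.valid]
    logged = full if pre_logged or layer.transform == "log1p" else np.log1p(full)
    m, s = float(np.mean(logged)), float(np.std(logged))
    if s == 0:
        raise ValueError("zero variance in full layer; cannot standardize")
    return McStudyInput(layer.values[rows, cols].astype(float),
                        sd_layer.values[rows, cols].astype(float),
                        pre_logged or layer.transform == "log1p", m, s)


@dataclass
class McCorrelationDistribution:
    pair: str
    scale: str
    zone_id: int
    rhos: np.ndarray
    n_iterations: int
    seed: int
    clamped: int  # perturbed values below -1 clamped before log1p


def _one_iteration(plant_pair, fungal_pair, rng) -> tuple[float, int]:
    clamped = 0
    consensus = {}
    for taxon, pair in (("plant", plant_pair), ("fungal", fungal_pair)):
        zs = []
        for inp in pair:
            v = inp.values + rng.uniform(-1.0, 1.0, size=inp.values.shape) * inp.sd
            if inp.pre_logged:
                logged = v
            else:
                below = v < -1.0
                clamped += int(below.sum())
                logged = np.log1p(np.where(below, -1.0 + LOG_CLAMP_EPS, v))
            zs.append((logged - inp.standardize_mean) / inp.standardize_sd)
        consensus[taxon] = (zs[0] + zs[1]) / 2.0
    rho, _ = stats.spearmanr(consensus["plant"], consensus["fungal"])
    return float(rho), clamped


def perturb_and_correlate(plant_inputs: tuple[McStudyInput, McStudyInput],
                          fungal_inputs: tuple[McStudyInput, McStudyInput],
                          n_iterations: int = 1000, seed: int = 0,
                          pair: str = "", scale: str = "global",
                          zone_id: int = -1,
                          sd_scale: float = 1.0) -> McCorrelationDistribution:
    """Run the 5-step error-adjustment loop on one fixed cell sample.

    ``sd_scale`` scales all SDs (for attenuation sensitivity runs); the
    per-iteration random stream depends only on (seed, iteration), so runs
    at different ``sd_scale`` use common random numbers.
    """
    if n_iterations < 1:
        raise ValueError("need at least 1 iteration")
    rhos = np.empty(n_iterations)
    clamped = 0
    scaled_plant = tuple(McStudyInput(i.values, i.sd * sd_scale, i.pre_logged,
                                      i.standardize_mean, i.standardize_sd)
                         for i in plant_inputs)
    scaled_fungal = tuple(McStudyInput(i.values, i.sd * sd_scale, i.pre_logged,
                                       i.standardize_mean, i.standardize_sd)
                          for i in fungal_inputs)
    root = np.random.SeedSequence(seed)
    for it, ss in enumerate(root.spawn(n_iterations)):
        rng = np.random.default_rng(ss)
        rhos[it], c = _one_iteration(scaled_plant, scaled_fungal, rng)
        clamped += c
    return McCorrelationDistribution(pair, scale, zone_id, rhos,
                                     n_iterations, seed, clamped)


@dataclass
class McSummary:
    mean: float
    median: float
    q025: float
    q975: float
    reference_rho: float
    sign_fraction: float
    sign_stable: bool


def mc_summary(dist: McCorrelationDistribution, reference_rho: float) -> McSummary:
    """Distribution summary plus sign stability against the baseline rho."""
    rhos = dist.rhos
    if rhos.size < 2:
        raise ValueError("need at least 2 iterations to summarize")
    ref_sign = np.sign(reference_rho)
    frac = float(np.mean(np.sign(rhos) == ref_sign))
    return McSummary(float(rhos.mean()), float(np.median(rhos)),
                     float(np.percentile(rhos, 2.5)),
                     float(np.percentile(rhos, 97.5)),
                     float(reference_rho), frac, frac == 1.0)
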