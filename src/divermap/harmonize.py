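"""Consensus-layer construction and uncertainty masking.

Two independently published richness predictions per taxon are put on a
common scale (log1p then z-standardization), averaged cellwise into a
consensus layer, and screened two ways: cells in the top 5% of each study's
own prediction uncertainty are dropped, and so are cells where the two
studies disagree most (top 5% of the two-layer coefficient of variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layers import (CellMask, LayerStateError, RichnessLayer,
                     UncertaintyLayer, ZoneMap, check_same_grid)

CV_SHIFT_EPS = 1e-6


def log1p_standardize(layer: RichnessLayer, already_logged: bool = False) -> RichnessLayer:
    """log(x+1)-transform (unless already logged) then center and scale.

    ``already_logged`` marks a layer whose values are on the log scale even
    though its transform state says ``raw`` (some source studies publish
    pre-logged rasters).
    """
    if layer.transform == "standardized":
        raise LayerStateError("layer is already standardized")
    valid = layer.valid
    if not valid.any():
        raise ValueError("all-nodata layer cannot be standardized")
    vals = layer.values
    if layer.transform == "raw" and not already_logged:
        if (vals[valid] < 0).any():
            raise ValueError("raw richness must be >= 0 before log1p")
        logged = np.where(valid, np.log1p(vals), np.nan)
    else:
        logged = vals.copy()
    mean = np.nanmean(logged)
    sd = np.nanstd(logged)
    # relative threshold: a numerically-constant layer can carry a ~1 ulp SD
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise ValueError("zero variance: standardization undefined")
    out = (logged - mean) / sd
    return RichnessLayer(out, transform="standardized", provenance=layer.provenance)


def consensus_mean(a: RichnessLayer, b: RichnessLayer) -> RichnessLayer:
    """Cellwise mean of two standardized layers; nodata if either is nodata."""
    check_same_grid(a.values, b.values)
    if a.transform != "standardized" or b.transform != "standardized":
        raise LayerStateError("consensus requires standardized inputs")
    both = a.valid & b.valid
    out = np.where(both, (a.values + b.values) / 2.0, np.nan)
    return RichnessLayer(out, transform="standardized", provenance="consensus")


def pairwise_cv(a: RichnessLayer, b: RichnessLayer) -> tuple[UncertaintyLayer, float]:
    """Two-layer disagreement CV: half the absolute difference over the mean.

    Standardized layers contain negatives, so both are first shifted by one
    common constant, ``-(global minimum across both) + 1e-6``, making all
    values strictly positive.  The shift changes CV magnitudes but, with two
    values, not their rank order - which is all the percentile exclusion
    downstream uses.  Returns the CV layer (dialect ``cv_ratio``) and the
    shift applied.
    """
    check_same_grid(a.values, b.values)
    if a.transform != b.transform:
        raise LayerStateError("pairwise_cv requires layers in the same state")
    if a.transform != "standardized":
        raise LayerStateError("pairwise_cv expects standardized inputs")
    both = a.valid & b.valid
    gmin = np.nanmin([np.nanmin(a.values), np.nanmin(b.values)])
    shift = -float(gmin) + CV_SHIFT_EPS
    av = a.values + shift
    bv = b.values + shift
    mean = (av + bv) / 2.0
    cv = np.where(both, np.abs(av - bv) / 2.0 / mean, np.nan)
    layer = UncertaintyLayer(np.abs(cv), dialect="cv_ratio",
                             provenance=f"cv({a.provenance},{b.provenance})")
    return layer, shift


def percentile_mask(u: UncertaintyLayer, q: float = 95.0) -> tuple[CellMask, float]:
    """Retain cells with spread <= the q-th percentile of valid spread values.

    Linear-interpolation (type-7) percentile; ties at the threshold are
    retained, so "the top (100-q)%" means strictly greater.  Returns the
    mask and the threshold used.
    """
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    valid = u.valid
    if not valid.any():
        raise ValueError("empty uncertainty layer")
    threshold = float(np.percentile(u.values[valid], q))
    retained = valid & (u.values <= threshold)
    mask = CellMask(retained, provenance=[f"{u.provenance}<=p{q:g}"])
    return mask, threshold


def combine_masks(masks: list[CellMask]) -> CellMask:
    """Logical AND across masks; provenance concatenated."""
    if not masks:
        raise ValueError("need at least one mask")
    check_same_grid(*[m.retained for m in masks])
    retained = masks[0].retained.copy()
    provenance = list(masks[0].provenance)
    for m in masks[1:]:
        retained &= m.retained
        provenance.extend(m.provenance)
    return CellMask(retained, provenance=provenance)


def retained_fraction(mask: CellMask, zones: ZoneMap | None = None,
                      valid: np.ndarray | None = None) -> pd.DataFrame:
    """Percent of retained cells among available cells, globally and per zone.

    ``valid`` optionally restricts "available" to non-nodata cells of the
    underlying layers (defaults to all grid cells).
    """
    if valid is None:
        valid = np.ones(mask.shape, dtype=bool)
    check_same_grid(mask.retained, valid)
    rows = []

    def _pct(sel):
        denom = int((valid & sel).sum())
        if denom == 0:
            return np.nan, 0
        return 100.0 * int((mask.retained & valid & sel).sum()) / denom, denom

    everywhere = np.ones(mask.shape, dtype=bool)
    pct, n = _pct(everywhere)
    rows.append({"scope": "global", "zone_id": -1, "retained_pct": pct, "n_available": n})
    if zones is not None:
        check_same_grid(mask.retained, zones.zones)
        for biome in zones.biome_ids():
            pct, n = _pct(zones.cells_in_biome(biome))
            rows.append({"scope": "biome", "zone_id": biome, "retained_pct": pct,
                         "n_available": n})
        for eco in zones.ecoregion_ids():
            pct, n = _pct(zones.cells_in_ecoregion(eco))
            rows.append({"scope": "ecoregion", "zone_id": eco, "retained_pct": pct,
                         "n_available": n})
    return pd.DataFrame(rows)


@dataclass
class HarmonizedPair:
    """Everything the downstream stages need for one plant-fungal comparison."""

    pair: str                      # "plant-AM" or "plant-ECM"
    plant_consensus: RichnessLayer
    fungal_consensus: RichnessLayer
    mask: CellMask
    thresholds: dict[str, float]
    cv_shifts: dict[str, float]
    retained: pd.DataFrame


def harmonize_pair(plant_studies, fungal_studies, plant_uncertainty,
                   fungal_uncertainty, pair: str, q: float = 95.0,
                   zones: ZoneMap | None = None,
                   plant_pre_logged=(False, False),
                   fungal_pre_logged=(False, False)) -> HarmonizedPair:
    """Run the full harmonization recipe for one taxon pair.

    Builds per-study uncertainty masks (top-(100-q)% excluded), standardizes
    and averages the study layers into consensus maps, adds the two
    cross-study disagreement masks, and intersects all six.
    """
    thresholds: dict[str, float] = {}
    cv_shifts: dict[str, float] = {}
    masks: list[CellMask] = []
    for label, unc_pair in (("plant", plant_uncertainty), ("fungal", fungal_uncertainty)):
        for i, u in enumerate(unc_pair):
            m, thr = percentile_mask(u, q)
            thresholds[f"{label}_study{i}_uncertainty"] = thr
            masks.append(m)

    std = {}
    for label, studies, flags in (("plant", plant_studies, plant_pre_logged),
                                  ("fungal", fungal_studies, fungal_pre_logged)):
        std[label] = tuple(log1p_standardize(layer, already_logged=flag)
                           for layer, flag in zip(studies, flags))
        cv_layer, shift = pairwise_cv(*std[label])
        cv_shifts[label] = shift
        m, thr = percentile_mask(cv_layer, q)
        thresholds[f"{label}_disagreement_cv"] = thr
        masks.append(m)

    mask = combine_masks(masks)
    valid = np.ones(mask.shape, dtype=bool)
    for label in ("plant", "fungal"):
        for layer in std[label]:
            valid &= layer.valid
    retained = retained_fraction(mask, zones, valid=valid)
    return HarmonizedPair(
        pair=pair,
        plant_consensus=consensus_mean(*std["plant"]),
        fungal_consensus=consensus_mean(*std["fungal"]),
        mask=mask, thresholds=thresholds, cv_shifts=cv_shifts, retained=retained,
    )
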