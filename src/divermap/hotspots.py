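"""Percentile richness hotspots and plant-fungal overlap accounting.

A hotspot is a retained cell whose richness is *strictly greater* than the
chosen upper percentile of retained values (the deliberate asymmetry with
uncertainty masks, which retain at <=).  Hotspots are detected on the
individual study layers, unioned within each taxon (cells flagged by one or
both studies, with the agreement level kept), and overlap is reported as a
percentage of the fungal hotspot area (plant-denominator percentages are a
secondary output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layers import CellMask, RichnessLayer, ZoneMap, check_same_grid

DEFAULT_PERCENTILES = (80.0, 85.0, 90.0, 95.0, 98.0)


@dataclass
class HotspotMask:
    hotspot: np.ndarray            # boolean grid
    source: str
    q: float
    threshold: float
    agreement: np.ndarray | None = None  # 1 or 2 studies per hotspot cell

    @property
    def shape(self) -> tuple[int, int]:
        return self.hotspot.shape

    @property
    def n_cells(self) -> int:
        return int(self.hotspot.sum())


def hotspot_mask(layer: RichnessLayer, mask: CellMask, q: float = 95.0) -> HotspotMask:
    """Cells above the q-th percentile of mask-retained richness values."""
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    check_same_grid(layer.values, mask.retained)
    retained = mask.retained & layer.valid
    if not retained.any():
        raise ValueError("no retained cells: cannot locate hotspots")
    threshold = float(np.percentile(layer.values[retained], q))
    hot = retained & (layer.values > threshold)
    return HotspotMask(hot, layer.provenance, q, threshold)


def union_hotspots(a: HotspotMask, b: HotspotMask) -> HotspotMask:
    """Cells flagged by either study; agreement grid counts 1 vs 2 flags."""
    check_same_grid(a.hotspot, b.hotspot)
    union = a.hotspot | b.hotspot
    agreement = a.hotspot.astype(np.int8) + b.hotspot.astype(np.int8)
    return HotspotMask(union, f"union({a.source},{b.source})",
                       a.q, np.nan, agreement=agreement)


def _overlap_row(fungal_hot: np.ndarray, plant_hot: np.ndarray, scope: str,
                 zone_id: int, fungal_agree=None, plant_agree=None) -> dict:
    f_area = int(fungal_hot.sum())
    p_area = int(plant_hot.sum())
    overlap = int((fungal_hot & plant_hot).sum())
    row = {
        "scope": scope, "zone_id": zone_id,
        "fungal_hotspot_cells": f_area, "plant_hotspot_cells": p_area,
        "overlap_cells": overlap,
        "overlap_pct_of_fungal": 100.0 * overlap / f_area if f_area else np.nan,
        "overlap_pct_of_plant": 100.0 * overlap / p_area if p_area else np.nan,
    }
    for label, agree, hot in (("fungal", fungal_agree, fungal_hot),
                              ("plant", plant_agree, plant_hot)):
        if agree is not None:
            row[f"{label}_cells_1study"] = int(((agree == 1) & hot).sum())
            row[f"{label}_cells_2study"] = int(((agree == 2) & hot).sum())
    return row


def overlap_summary(fungal: HotspotMask, plant: HotspotMask,
                    zones: ZoneMap | None = None) -> pd.DataFrame:
    """Overlap accounting, globally and (if zones given) cross-tabulated by
    biome using the *global* hotspot thresholds."""
    check_same_grid(fungal.hotspot, plant.hotspot)
    if fungal.n_cells == 0:
        raise ValueError("empty fungal hotspot set")
    rows = [_overlap_row(fungal.hotspot, plant.hotspot, "global", -1,
                         fungal.agreement, plant.agreement)]
    if zones is not None:
        check_same_grid(fungal.hotspot, zones.zones)
        for biome in zones.biome_ids():
            sel = zones.cells_in_biome(biome)
            rows.append(_overlap_row(fungal.hotspot & sel, plant.hotspot & sel,
                                     "biome", biome, fungal.agreement, plant.agreement))
    return pd.DataFrame(rows)


def within_biome_overlap(plant_studies, fungal_studies, mask: CellMask,
                         zones: ZoneMap, q: float = 95.0) -> pd.DataFrame:
    """Recompute hotspots with percentile thresholds taken *within* each
    biome's own retained cells, then summarize overlap per biome."""
    rows = []
    for biome in zones.biome_ids():
        sel = zones.cells_in_biome(biome)
        biome_mask = CellMask(mask.retained & sel, provenance=[f"biome{biome}"])
        if not (biome_mask.retained).any():
            continue
        try:
            p_union = union_hotspots(*[hotspot_mask(s, biome_mask, q) for s in plant_studies])
            f_union = union_hotspots(*[hotspot_mask(s, biome_mask, q) for s in fungal_studies])
        except ValueError:
            continue
        rows.append(_overlap_row(f_union.hotspot, p_union.hotspot,
                                 "biome_recomputed", biome,
                                 f_union.agreement, p_union.agreement))
    return pd.DataFrame(rows)


def overlap_vs_host_prevalence(biome_summaries: pd.DataFrame,
                               host_means: dict[int, float]) -> dict:
    """Spearman between per-biome overlap percent and mean host biomass %.

    Tests whether overlap concentrates where potential host plants dominate.
    """
    sub = biome_summaries[biome_summaries["scope"].str.startswith("biome")]
    merged = sub.assign(host_pct=sub["zone_id"].map(host_means)).dropna(
        subset=["overlap_pct_of_fungal", "host_pct"])
    if len(merged) < 3:
        raise ValueError("need at least 3 biomes")
    x = merged["overlap_pct_of_fungal"].to_numpy()
    y = merged["host_pct"].to_numpy()
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return {"rho": np.nan, "p": np.nan, "n": len(merged), "note": "constant_input"}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(merged), "note": ""}
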