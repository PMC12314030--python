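"""Gridded layer containers shared by every pipeline stage.

All layers live on a common rectangular grid.  Missing cells (ocean, masked,
unsampled) are represented as NaN internally; the on-disk nodata sentinel is
handled by :mod:`divermap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

TransformState = Literal["raw", "log1p", "standardized"]
Dialect = Literal["cv_percent", "sd", "iqr_ratio_percent", "cv_ratio"]


class GridMismatchError(ValueError):
    """Two layers that must share a grid do not."""


class LayerStateError(ValueError):
    """A layer is in the wrong transform state for the requested operation."""


def check_same_grid(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise GridMismatchError(f"layers do not share one grid: {sorted(shapes)}")


@dataclass
class RichnessLayer:
    """A gridded surface of (possibly transformed) species-richness values.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells.
    transform
        Where the layer sits in the raw -> log1p -> standardized chain.
    provenance
        Study identifier, or ``"consensus"`` for a cross-study mean.
    """

    values: np.ndarray
    transform: TransformState = "raw"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid of non-nodata cells."""
        return np.isfinite(self.values)

    def copy_with(self, **kw) -> "RichnessLayer":
        return replace(self, **kw)


@dataclass
class UncertaintyLayer:
    """Per-cell prediction spread with a dialect tag.

    Dialects mirror how source studies report uncertainty: ``cv_percent``
    (bootstrap CV as a percentage of the mean), ``sd`` (absolute standard
    deviation), ``iqr_ratio_percent`` (IQR as a percentage of the median),
    and ``cv_ratio`` (a unitless two-layer disagreement CV, see
    :func:`divermap.harmonize.pairwise_cv`).
    """

    values: np.ndarray
    dialect: Dialect = "sd"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("uncertainty spread must be >= 0 on valid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class CellMask:
    """Boolean retention grid. True = cell retained for analysis."""

    retained: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.ndim != 2:
            raise ValueError("mask must be a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.retained.shape

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class ZoneMap:
    """Integer ecoregion grid plus the ecoregion -> biome lookup.

    ``zones`` uses -1 as the nodata sentinel.  Every non-nodata cell must
    carry an ecoregion id present in ``biome_of``.
    """

    zones: np.ndarray
    biome_of: Mapping[int, int]

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones, dtype=np.int64)
        if self.zones.ndim != 2:
            raise ValueError("zone map must be a 2-D grid")
        present = set(np.unique(self.zones[self.zones >= 0]).tolist())
        missing = present - set(self.biome_of)
        if missing:
            raise ValueError(f"ecoregion ids missing from biome lookup: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.zones.shape

    @property
    def valid(self) -> np.ndarray:
        return self.zones >= 0

    def ecoregion_ids(self) -> list[int]:
        return sorted(np.unique(self.zones[self.zones >= 0]).tolist())

    def biome_ids(self) -> list[int]:
        return sorted(set(self.biome_of.values()))

    def biome_grid(self) -> np.ndarray:
        """Grid of biome ids (-1 on nodata)."""
        out = np.full(self.zones.shape, -1, dtype=np.int64)
        for eco, biome in self.biome_of.items():
            out[self.zones == eco] = biome
        return out

    def cells_in_ecoregion(self, eco_id: int) -> np.ndarray:
        return self.zones == eco_id

    def cells_in_biome(self, biome_id: int) -> np.ndarray:
        members = [e for e, b in self.biome_of.items() if b == biome_id]
        out = np.zeros(self.zones.shape, dtype=bool)
        for e in members:
            out |= self.zones == e
        return out
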