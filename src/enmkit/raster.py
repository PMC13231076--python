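"""In-memory raster containers: predictor stacks and classification rasters.

A :class:`PredictorStack` holds named, co-registered environmental layers
(e.g. bioclim variables, soil properties, slope, land use) as float arrays
with ``NaN`` marking nodata. All layers share one :class:`~enmkit.grid.GridSpec`
and — after construction — one unified nodata mask, mirroring how a GIS
pre-aligned stack behaves inside a distribution model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DomainError
from .grid import GridSpec

__all__ = ["PredictorStack", "ClassificationRaster", "extract_env", "ensemble_mean"]


class PredictorStack:
    """Ordered, named raster layers on a shared grid.

    Parameters
    ----------
    grid:
        Shared geometry.
    layers:
        Mapping name -> 2-D float array of ``grid.shape``; NaN is nodata.
    units:
        Optional mapping name -> unit string (carried through, never parsed).
    categorical:
        Names of layers holding integer class codes (e.g. land use). These are
        exempt from moment-based operations downstream.
    """

    def __init__(self, grid: GridSpec, layers: dict[str, np.ndarray],
                 units: dict[str, str] | None = None,
                 categorical: set[str] | frozenset[str] | None = None):
        if not layers:
            raise ConfigError("a stack needs at least one layer")
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise AlignmentError(
                    f"layer {name!r} has shape {arr.shape}, grid is {grid.shape}")
            self.layers[name] = arr
        self.units = dict(units or {})
        self.categorical = frozenset(categorical or ())
        self._unify_mask()

    def _unify_mask(self) -> None:
        """Propagate nodata: a cell missing in any layer is missing in all."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        if mask.any():
            for arr in self.layers.values():
                arr[mask] = np.nan
        self._invalid = mask

    # -- basic introspection --------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where every layer has data."""
        return ~self._invalid

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)

    # -- conversions ----------------------------------------------------
    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        """Valid cells as rows, layers as columns; index = flat cell index."""
        names = list(names) if names is not None else self.names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise AlignmentError(f"layers not in stack: {missing}")
        ok = self.valid_mask.ravel()
        data = {n: self.layers[n].ravel()[ok] for n in names}
        return pd.DataFrame(data, index=np.flatnonzero(ok))

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise AlignmentError(f"layers not in stack: {missing}")
        return PredictorStack(
            self.grid,
            {n: self.layers[n].copy() for n in names},
            units={n: u for n, u in self.units.items() if n in names},
            categorical=self.categorical & set(names),
        )

    def copy(self) -> "PredictorStack":
        return PredictorStack(self.grid, {n: a.copy() for n, a in self.layers.items()},
                              units=dict(self.units), categorical=self.categorical)


@dataclass
class ClassificationRaster:
    """Binary classification map, optionally with the fused probability surface."""

    grid: GridSpec
    labels: np.ndarray
    probability: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise AlignmentError(
                f"labels shape {self.labels.shape} != grid {self.grid.shape}")
        vals = np.unique(self.labels[~np.isnan(self.labels.astype(float))])
        if not np.isin(vals, (0, 1)).all():
            raise DomainError(f"labels must be binary 0/1, found values {vals[:5]}")
        if self.probability is not None:
            self.probability = np.asarray(self.probability, dtype=float)
            if self.probability.shape != self.grid.shape:
                raise AlignmentError("probability grid does not match labels grid")

    @property
    def positive_count(self) -> int:
        return int(np.nansum(self.labels == 1))


def extract_env(stack: PredictorStack, points: pd.DataFrame,
                drop_invalid: bool = False) -> pd.DataFrame:
    """Attach the environmental row under each point to the point table.

    Points must carry ``x``/``y`` columns in map coordinates. Points over a
    nodata cell are kept but flagged ``valid=False`` (or dropped when
    ``drop_invalid``), so downstream modelling can exclude them while the
    caller can still audit what was lost.
    """
    if not {"x", "y"} <= set(points.columns):
        raise ConfigError("point table must have columns 'x' and 'y'")
    row, col = stack.grid.rowcol(points["x"].to_numpy(), points["y"].to_numpy())
    out = points[["x", "y"]].reset_index(drop=True).copy()
    for name, arr in stack.layers.items():
        out[name] = arr[row, col]
    out["valid"] = stack.valid_mask[row, col]
    if drop_invalid:
        out = out[out["valid"]].reset_index(drop=True)
    return out


def ensemble_mean(stacks: list[PredictorStack]) -> PredictorStack:
    """Per-cell, per-layer arithmetic mean of equally weighted ensemble members.

    The standard way of collapsing several GCM projections of the same
    scenario into one stack. A cell that is nodata in any member is nodata
    in the mean.
    """
    if not stacks:
        raise ConfigError("ensemble_mean needs at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if not s.grid.same_geometry(first.grid):
            raise AlignmentError("ensemble members are on different grids")
        if s.names != first.names:
            raise AlignmentError(
                f"layer-name mismatch: {s.names} vs {first.names}")
    layers = {}
    for name in first.names:
        layers[name] = np.mean([s.layers[name] for s in stacks], axis=0)
    return PredictorStack(first.grid, layers, units=dict(first.units),
                          categorical=first.categorical)
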