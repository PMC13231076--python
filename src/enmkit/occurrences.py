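"""From classification raster to de-biased occurrence records.

This module covers the remote-sensing end of the workflow: fusing tiled
classifier probabilities into one map, scoring the map against reference
labels, sampling occurrence points from positive pixels, thinning them to
one per environmental grid cell (spatial rarefaction), and checking
area-fraction concordance against an independent per-unit reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (AlignmentError, ConfigError, DomainError,
                     InsufficientDataError, OutOfBoundsError)
from .grid import GridSpec
from .raster import ClassificationRaster

__all__ = [
    "SegMetrics", "AreaStats", "fuse_and_binarize", "segmentation_metrics",
    "sample_occurrences", "thin_by_grid", "area_concordance",
]


@dataclass(frozen=True)
class SegMetrics:
    """Pixel-level confusion counts and the four derived scores.

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    f1        = 2 * precision * recall / (precision + recall)
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else float("nan")


@dataclass
class AreaStats:
    """Per-unit area-percentage concordance with MAE/RMSE summaries."""

    table: pd.DataFrame  # columns: unit, estimated, reference, abs_error
    mae: float
    rmse: float


# ---------------------------------------------------------------------------
# Tile fusion
# ---------------------------------------------------------------------------

def fuse_and_binarize(tiles: list[tuple[np.ndarray, tuple[int, int]]],
                      layout: GridSpec, threshold: float) -> ClassificationRaster:
    """Mosaic probability tiles by per-pixel maximum, then threshold.

    ``tiles`` is a list of ``(probability_array, (row_offset, col_offset))``
    where offsets index the layout's array (row 0 = north). Overlapping
    pixels keep the maximum probability — the fusion rule that minimizes
    omission at tile seams. The binary map is 1 where the fused probability
    is >= ``threshold``. Pixels covered by no tile get probability 0.
    """
    if not 0 <= threshold <= 1:
        raise DomainError(f"threshold must be in [0, 1], got {threshold}")
    fused = np.zeros(layout.shape, dtype=float)
    covered = np.zeros(layout.shape, dtype=bool)
    for arr, (roff, coff) in tiles:
        arr = np.asarray(arr, dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise DomainError("tile probabilities must lie in [0, 1]")
        r1, c1 = roff + arr.shape[0], coff + arr.shape[1]
        if roff < 0 or coff < 0 or r1 > layout.nrows or c1 > layout.ncols:
            raise OutOfBoundsError(
                f"tile at offset ({roff}, {coff}) with shape {arr.shape} "
                f"exceeds layout {layout.shape}")
        window = fused[roff:r1, coff:c1]
        np.maximum(window, np.nan_to_num(arr, nan=0.0), out=window)
        covered[roff:r1, coff:c1] = True
    labels = (fused >= threshold).astype(np.int8)
    labels[~covered] = 0
    return ClassificationRaster(layout, labels, probability=fused)


# ---------------------------------------------------------------------------
# Segmentation scoring
# ---------------------------------------------------------------------------

def segmentation_metrics(predicted: ClassificationRaster,
                         truth: ClassificationRaster) -> SegMetrics:
    """Confusion counts of a binary map against reference labels."""
    if not predicted.grid.same_geometry(truth.grid):
        raise AlignmentError("predicted and truth rasters are on different grids")
    p = np.asarray(predicted.labels).ravel()
    t = np.asarray(truth.labels).ravel()
    return SegMetrics(
        tp=int(np.sum((p == 1) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


# ---------------------------------------------------------------------------
# Occurrence sampling and thinning
# ---------------------------------------------------------------------------

def sample_occurrences(class_raster: ClassificationRaster, n: int,
                       seed: int = 0) -> pd.DataFrame:
    """Uniform sample, without replacement, of n positive-pixel cell centers."""
    rows, cols = np.nonzero(class_raster.labels == 1)
    if n > rows.size:
        raise InsufficientDataError(
            f"requested {n} occurrences but the raster has only {rows.size} positive pixels")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False)
    x, y = class_raster.grid.xy(rows[pick], cols[pick])
    return pd.DataFrame({"x": x, "y": y})


def thin_by_grid(points: pd.DataFrame, env_grid: GridSpec) -> pd.DataFrame:
    """Spatial rarefaction: keep at most one point per environmental cell.

    The representative is the **first** point, in stable input order, that
    falls in each cell, so the result is deterministic given the input
    ordering and thinning is idempotent. An empty table passes through.
    """
    if len(points) == 0:
        return points.reset_index(drop=True)
    row, col = env_grid.rowcol(points["x"].to_numpy(), points["y"].to_numpy())
    cell = row * env_grid.ncols + col
    keep = ~pd.Series(cell).duplicated(keep="first").to_numpy()
    return points.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Area concordance
# ---------------------------------------------------------------------------

def area_concordance(estimated: pd.DataFrame, reference: pd.DataFrame,
                     unit_col: str = "unit", value_col: str = "percent") -> AreaStats:
    """Per-unit |reference - estimated| with MAE and RMSE summaries.

    Both tables carry one row per administrative unit with the unit's
    mapped-area percentage. Units must match exactly; unmatched names raise
    an error listing them.
    """
    est = estimated.set_index(unit_col)[value_col]
    ref = reference.set_index(unit_col)[value_col]
    only_est = sorted(set(est.index) - set(ref.index))
    only_ref = sorted(set(ref.index) - set(est.index))
    if only_est or only_ref:
        raise AlignmentError(
            f"unit mismatch: only in estimated {only_est}, only in reference {only_ref}")
    ref = ref.reindex(est.index)
    abs_err = (ref - est).abs()
    table = pd.DataFrame({
        "unit": est.index,
        "estimated": est.to_numpy(),
        "reference": ref.to_numpy(),
        "abs_error": abs_err.to_numpy(),
    }).reset_index(drop=True)
    mae = float(abs_err.mean())
    rmse = float(np.sqrt((abs_err ** 2).mean()))
    return AreaStats(table=table, mae=mae, rmse=rmse)
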