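"""Ordinal suitability tiers anchored at the MTSS threshold.

Two published anchoring rules are supported, both cutting the lowest class
at the MTSS threshold ``t``:

* ``threshold-multiples`` (scheme A): boundaries ``(t, 2t, 3t)`` — every
  class is ``t`` wide; requires ``3t < 1``.
* ``equal-above-threshold`` (scheme B): boundaries
  ``(t, t + (1-t)/3, t + 2(1-t)/3)`` — the suitable range ``[t, 1]`` is
  split into three equal intervals.

Intervals are half-open ``[0,b1) [b1,b2) [b2,b3)`` with the top class
closed: a cell exactly at ``b3`` is tier 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DomainError
from .grid import GridSpec

__all__ = ["TierScheme", "TierMap", "make_scheme", "classify_tiers", "tier_areas",
           "DEFAULT_LABELS"]

DEFAULT_LABELS = ("least", "generally", "moderately", "highly")

_SCHEME_ALIASES = {
    "threshold-multiples": "threshold-multiples",
    "a": "threshold-multiples",
    "equal-above-threshold": "equal-above-threshold",
    "b": "equal-above-threshold",
}


@dataclass(frozen=True)
class TierScheme:
    mtss: float
    scheme: str
    boundaries: tuple[float, float, float]
    labels: tuple[str, str, str, str] = DEFAULT_LABELS


@dataclass
class TierMap:
    grid: GridSpec
    tiers: np.ndarray           # int grid, -1 = nodata, 0..3 = tier index
    scheme: TierScheme

    def counts(self) -> np.ndarray:
        """Cell counts per tier 0..3 (nodata excluded)."""
        return np.array([(self.tiers == t).sum() for t in range(4)])


def make_scheme(t: float, scheme: str = "threshold-multiples",
                labels: tuple[str, str, str, str] = DEFAULT_LABELS) -> TierScheme:
    """Build the 4-class boundary set from the MTSS threshold."""
    if not 0 < t < 1:
        raise ConfigError(f"threshold must be in (0, 1), got {t}")
    key = _SCHEME_ALIASES.get(scheme.lower())
    if key is None:
        raise ConfigError(f"unknown scheme {scheme!r}; use 'threshold-multiples' "
                          "(A) or 'equal-above-threshold' (B)")
    if key == "threshold-multiples":
        if 3 * t >= 1:
            raise ConfigError(
                f"threshold-multiples scheme needs 3t < 1, got t={t}")
        bounds = (t, 2 * t, 3 * t)
    else:
        step = (1.0 - t) / 3.0
        bounds = (t, t + step, t + 2 * step)
    return TierScheme(mtss=t, scheme=key, boundaries=bounds, labels=tuple(labels))


def classify_tiers(suitability: np.ndarray, scheme: TierScheme,
                   grid: GridSpec | None = None) -> TierMap:
    """Assign each cell its ordinal tier; NaN cells propagate as -1."""
    suit = np.asarray(suitability, dtype=float)
    finite = suit[np.isfinite(suit)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise DomainError("suitability values must lie in [0, 1]")
    if grid is None:
        grid = GridSpec(nrows=suit.shape[0], ncols=suit.shape[1], cell_size=1.0)
    if suit.shape != grid.shape:
        raise AlignmentError(f"suitability shape {suit.shape} != grid {grid.shape}")
    b1, b2, b3 = scheme.boundaries
    tiers = np.full(suit.shape, -1, dtype=np.int8)
    ok = np.isfinite(suit)
    # searchsorted with side='right' makes every interval closed on the left.
    tiers[ok] = np.searchsorted(np.array([b1, b2, b3]), suit[ok], side="right")
    return TierMap(grid=grid, tiers=tiers, scheme=scheme)


def tier_areas(tier_map: TierMap, cell_area: float | None = None,
               mask: np.ndarray | None = None) -> pd.DataFrame:
    """Area per tier (optionally per unit of an integer zone raster).

    ``cell_area`` defaults to the grid's cell area; the per-tier areas
    always sum to the valid-cell area of (each unit of) the map.
    """
    if cell_area is None:
        cell_area = tier_map.grid.cell_area
    if cell_area <= 0:
        raise ConfigError(f"cell_area must be positive, got {cell_area}")
    tiers = tier_map.tiers
    labels = tier_map.scheme.labels
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != tiers.shape:
            raise AlignmentError(f"mask shape {mask.shape} != tiers {tiers.shape}")
        units = [u for u in np.unique(mask) if not (isinstance(u, float) and np.isnan(u))]
    else:
        mask = np.zeros_like(tiers)
        units = [0]
    rows = []
    for u in units:
        in_unit = mask == u
        for t in range(4):
            count = int(np.sum(in_unit & (tiers == t)))
            rows.append({"unit": u, "tier": t, "label": labels[t],
                         "area": count * cell_area})
    out = pd.DataFrame(rows)
    if len(units) == 1:
        out = out.drop(columns="unit")
    return out
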