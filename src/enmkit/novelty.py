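"""Extrapolation diagnostics: MESS, most-dissimilar variable, envelope drift.

The multivariate environmental similarity surface (MESS) scores each cell
of a projection stack against a reference envelope (typically the
environmental values at the occurrence records). Per variable, with
``f`` = percentage of reference values strictly below the cell's value:

* ``f = 0``        -> ``100 * (value - min) / (max - min)``  (negative below range)
* ``0 < f <= 50``  -> ``2 f``
* ``50 < f < 100`` -> ``2 (100 - f)``
* ``f = 100``      -> ``100 * (max - value) / (max - min)``  (negative above range)

The cell's MESS is the minimum over variables; negative values flag
conditions outside the reference range (novel environments). The variable
attaining the minimum is the most dissimilar (MoD). Risk tiers follow the
published cuts: MESS > 0 reliable, [-10, 0] moderate, < -10 high risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DegenerateReferenceError
from .raster import PredictorStack

__all__ = ["ReferenceEnvelope", "NoveltyMap",
           "mess_similarity", "mess_map", "classify_risk", "envelope_shift",
           "RISK_RELIABLE", "RISK_MODERATE", "RISK_HIGH"]

RISK_RELIABLE, RISK_MODERATE, RISK_HIGH = 0, 1, 2
RISK_LABELS = {RISK_RELIABLE: "reliable", RISK_MODERATE: "moderate",
               RISK_HIGH: "high"}


@dataclass
class ReferenceEnvelope:
    """Sorted per-variable reference values defining the training envelope."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for name, v in self.values.items():
            v = np.sort(np.asarray(v, dtype=float))
            v = v[np.isfinite(v)]
            if np.unique(v).size < 2:
                raise DegenerateReferenceError(
                    f"reference for {name!r} needs >= 2 distinct values")
            clean[name] = v
        self.values = clean

    @property
    def variables(self) -> list[str]:
        return list(self.values)

    @classmethod
    def from_table(cls, env: pd.DataFrame,
                   variables: list[str] | None = None) -> "ReferenceEnvelope":
        variables = variables or list(env.columns)
        return cls({v: env[v].to_numpy() for v in variables})


@dataclass
class NoveltyMap:
    mess: np.ndarray       # per-cell minimum similarity (NaN at nodata)
    mod: np.ndarray        # variable index of the minimum, -1 at nodata
    risk: np.ndarray       # risk tier per classify_risk, -1 at nodata
    variables: list[str]


def _similarity_vector(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Piecewise MESS similarity of many values against one sorted reference.

    'Fraction below' counts reference values strictly less than the cell
    value; ties at the value are not below.
    """
    ref = np.asarray(reference, dtype=float)
    lo, hi = ref[0], ref[-1]
    span = hi - lo
    if span <= 0:
        raise DegenerateReferenceError("reference max equals min")
    v = np.asarray(values, dtype=float)
    f = 100.0 * np.searchsorted(ref, v, side="left") / ref.size
    out = np.empty_like(v)
    below = f == 0
    above = f == 100
    lower = (f > 0) & (f <= 50)
    upper = (f > 50) & (f < 100)
    out[below] = 100.0 * (v[below] - lo) / span
    out[lower] = 2.0 * f[lower]
    out[upper] = 2.0 * (100.0 - f[upper])
    out[above] = 100.0 * (hi - v[above]) / span
    out[np.isnan(v)] = np.nan
    return out


def mess_similarity(value: float, reference: np.ndarray) -> float:
    """Similarity of a single value to a reference sample (percent scale)."""
    return float(_similarity_vector(np.array([value]),
                                    np.sort(np.asarray(reference, dtype=float)))[0])


def classify_risk(mess_value):
    """Risk tier from a MESS value: >0 reliable, [-10, 0] moderate, <-10 high."""
    v = np.asarray(mess_value, dtype=float)
    out = np.full(v.shape, RISK_MODERATE, dtype=np.int8)
    out[v > 0] = RISK_RELIABLE
    out[v < -10] = RISK_HIGH
    if out.shape == ():
        return int(out)
    return out


def mess_map(envelope: ReferenceEnvelope, proj: PredictorStack) -> NoveltyMap:
    """Per-cell MESS, most-dissimilar variable and risk tier over a stack.

    MoD ties resolve to the first variable in envelope order.
    """
    missing = [v for v in envelope.variables if v not in proj]
    if missing:
        raise AlignmentError(f"projection stack lacks envelope layers: {missing}")
    shape = proj.grid.shape
    nvar = len(envelope.variables)
    sims = np.empty((nvar,) + shape)
    for i, name in enumerate(envelope.variables):
        sims[i] = _similarity_vector(proj[name], envelope.values[name])
    mess = np.nanmin(sims, axis=0)
    # argmin over the variable axis; first-variable tie-break is argmin's default
    filled = np.where(np.isnan(sims), np.inf, sims)
    mod = np.argmin(filled, axis=0).astype(np.int8)
    invalid = np.isnan(mess)
    mod[invalid] = -1
    risk = classify_risk(np.where(invalid, 0.0, mess)).astype(np.int8)
    risk[invalid] = -1
    return NoveltyMap(mess=mess, mod=mod, risk=risk,
                      variables=list(envelope.variables))


def envelope_shift(baseline: PredictorStack, future: PredictorStack,
                   variables: list[str] | None = None,
                   direction_tolerance: float = 1e-9) -> pd.DataFrame:
    """Compare per-variable distributions between baseline and future stacks.

    Densities are histograms on shared Freedman-Diaconis bins over the
    pooled values, so the overlap coefficient (sum of bin-wise minima of
    the two probability masses) is well defined and symmetric. Displacement
    is reported on both the mean and the median; the direction label
    follows the sign of the mean displacement.
    """
    if not baseline.grid.same_geometry(future.grid):
        raise AlignmentError("baseline and future stacks are on different grids")
    variables = variables or [v for v in baseline.names if v in future.names]
    missing = ([v for v in variables if v not in baseline]
               + [v for v in variables if v not in future])
    if missing:
        raise AlignmentError(f"variables missing from a stack: {sorted(set(missing))}")
    rows = []
    for name in variables:
        b = baseline[name][baseline.valid_mask]
        f = future[name][future.valid_mask]
        pooled = np.concatenate([b, f])
        edges = np.histogram_bin_edges(pooled, bins="fd")
        if len(edges) < 3:
            edges = np.histogram_bin_edges(pooled, bins=10)
        p, _ = np.histogram(b, bins=edges)
        q, _ = np.histogram(f, bins=edges)
        p = p / p.sum()
        q = q / q.sum()
        overlap = float(np.minimum(p, q).sum())
        d_mean = float(f.mean() - b.mean())
        d_median = float(np.median(f) - np.median(b))
        if d_mean > direction_tolerance:
            direction = "rightward"
        elif d_mean < -direction_tolerance:
            direction = "leftward"
        else:
            direction = "none"
        rows.append({"variable": name, "mean_displacement": d_mean,
                     "median_displacement": d_median, "overlap": overlap,
                     "direction": direction})
    return pd.DataFrame(rows)
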