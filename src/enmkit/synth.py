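"""Synthetic landscapes, virtual species and classifier outputs.

Every downstream stage of the pipeline — occurrence derivation, variable
screening, MaxEnt tuning, RF cross-checking, novelty analysis — is testable
against known ground truth produced here:

* :func:`gen_predictor_stack` builds spatially smooth, cross-correlated
  random fields that emulate bioclim-style predictor layers.
* :func:`gen_virtual_species` computes a true suitability surface from
  user-declared response curves (the "virtual species" device standard in
  SDM methodology work), so niche optima and dominant drivers are known
  exactly.
* :func:`gen_classifier_output` turns true suitability into a fine-scale
  binary map corrupted to hit target precision/recall, emulating the output
  of a semantic-segmentation classifier used as an occurrence source.
* :func:`gen_future_stack` applies location/scale shifts per variable,
  emulating climate-scenario stacks whose distributions drift beyond the
  reference envelope.

All generators are pure functions of (config, seed): no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DomainError
from .grid import GridSpec
from .raster import ClassificationRaster, PredictorStack

__all__ = [
    "LayerSpec", "Response", "VirtualSpeciesConfig", "ClassifierSpec",
    "gen_predictor_stack", "gen_virtual_species", "gen_classifier_output",
    "gen_future_stack", "sample_presences",
]


@dataclass(frozen=True)
class LayerSpec:
    """Marginal description of one synthetic layer.

    smoothness is the standard deviation, in cells, of the gaussian kernel
    used to filter white noise; larger values give longer-range spatial
    autocorrelation.
    """

    name: str
    mean: float
    sd: float
    smoothness: float = 5.0


@dataclass(frozen=True)
class Response:
    """Response of the virtual species to one variable.

    shape 'gaussian': exp(-((v - optimum)/breadth)^2 / 2), peak 1 at optimum.
    shape 'logistic': 1 / (1 + exp(-(v - optimum)/breadth)), increasing.
    shape 'flat': constant 1 (variable is ecologically irrelevant).
    """

    shape: str
    optimum: float = 0.0
    breadth: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "logistic", "flat"):
            raise ConfigError(f"unknown response shape {self.shape!r}")
        if self.breadth <= 0:
            raise ConfigError("response breadth must be > 0")

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.shape == "gaussian":
            return np.exp(-0.5 * ((v - self.optimum) / self.breadth) ** 2)
        if self.shape == "logistic":
            return 1.0 / (1.0 + np.exp(-(v - self.optimum) / self.breadth))
        return np.ones_like(v)


@dataclass(frozen=True)
class VirtualSpeciesConfig:
    responses: dict[str, Response] = field(default_factory=dict)
    combination: str = "product"  # or "geometric-mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.combination not in ("product", "geometric-mean"):
            raise ConfigError(f"unknown combination rule {self.combination!r}")
        if not self.responses:
            raise ConfigError("virtual species needs at least one response")


@dataclass(frozen=True)
class ClassifierSpec:
    """Quality and resolution of the emulated classification raster."""

    fine_factor: int = 1
    target_precision: float = 1.0
    target_recall: float = 1.0
    prevalence: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fine_factor < 1 or int(self.fine_factor) != self.fine_factor:
            raise ConfigError("fine_factor must be an integer >= 1")
        for name in ("target_precision", "target_recall"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.prevalence < 1:
            raise ConfigError(f"prevalence must be in (0, 1), got {self.prevalence}")


# ---------------------------------------------------------------------------
# Predictor stacks
# ---------------------------------------------------------------------------

def gen_predictor_stack(grid: GridSpec, layer_specs: list[LayerSpec],
                        correlation: np.ndarray | None = None,
                        seed: int = 0,
                        categorical: set[str] | None = None) -> PredictorStack:
    """Smooth gaussian random fields with requested moments and cross-correlation.

    White noise is filtered with a per-layer gaussian kernel, standardized
    field-by-field, mixed through the Cholesky factor of ``correlation``,
    and finally rescaled to each layer's requested mean and sd. With a
    non-trivial correlation matrix the realized cross-correlations are
    approximate (smoothing lengths interact with mixing), which suffices for
    screening-stage tests.
    """
    specs = [s if isinstance(s, LayerSpec) else LayerSpec(*s) for s in layer_specs]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate layer names in specs: {names}")
    k = len(specs)
    if correlation is None:
        correlation = np.eye(k)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (k, k):
        raise ConfigError(f"correlation must be {k}x{k}, got {correlation.shape}")
    if not np.allclose(correlation, correlation.T, atol=1e-10):
        raise ConfigError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(correlation), 1.0, atol=1e-10):
        raise ConfigError("correlation matrix must have unit diagonal")
    # PSD check with a small tolerance for round-off.
    eigmin = np.linalg.eigvalsh(correlation).min()
    if eigmin < -1e-10:
        raise ConfigError(f"correlation matrix is not PSD (min eigenvalue {eigmin:.3g})")
    shifted = correlation + np.eye(k) * max(0.0, -eigmin + 1e-12)
    chol = np.linalg.cholesky(shifted)

    rng = np.random.default_rng(seed)
    fields = np.empty((k,) + grid.shape)
    for i, spec in enumerate(specs):
        noise = rng.standard_normal(grid.shape)
        if spec.smoothness > 0:
            noise = ndimage.gaussian_filter(noise, sigma=spec.smoothness, mode="reflect")
        noise -= noise.mean()
        sd = noise.std()
        fields[i] = noise / sd if sd > 0 else noise
    mixed = np.tensordot(chol, fields, axes=(1, 0))
    layers: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        f = mixed[i]
        f = (f - f.mean()) / (f.std() if f.std() > 0 else 1.0)
        layers[spec.name] = spec.mean + spec.sd * f
    return PredictorStack(grid, layers, categorical=categorical)


# ---------------------------------------------------------------------------
# Virtual species
# ---------------------------------------------------------------------------

def gen_virtual_species(stack: PredictorStack, config: VirtualSpeciesConfig) -> np.ndarray:
    """True suitability in [0, 1] from per-variable responses.

    Under the product rule, suitability is exactly 1 only where every
    variable sits at its response's peak, and declines as any variable
    departs its optimum.
    """
    unknown = [v for v in config.responses if v not in stack]
    if unknown:
        raise ConfigError(f"response variables not in stack: {unknown}")
    parts = [resp.evaluate(stack[name]) for name, resp in config.responses.items()]
    prod = np.prod(parts, axis=0)
    if config.combination == "geometric-mean":
        suit = prod ** (1.0 / len(parts))
    else:
        suit = prod
    return suit


def sample_presences(true_suit: np.ndarray, grid: GridSpec, n: int,
                     seed: int = 0):
    """Draw presence cells with probability proportional to true suitability.

    The canonical virtual-species protocol for validating distribution
    models: occupancy is graded, so occurrence density tapers away from the
    niche optimum instead of cutting off at a hard range edge. Cells are
    drawn without replacement; returns a point table of cell centers.
    """
    import pandas as pd

    suit = np.asarray(true_suit, dtype=float)
    if suit.shape != grid.shape:
        raise ConfigError(f"suitability shape {suit.shape} != grid {grid.shape}")
    w = np.nan_to_num(suit, nan=0.0).ravel()
    if w.sum() <= 0:
        raise ConfigError("suitability has no positive mass to sample from")
    n_pos = int(np.sum(w > 0))
    if n > n_pos:
        raise ConfigError(f"requested {n} presences but only {n_pos} cells have "
                          "positive suitability")
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, replace=False, p=w / w.sum())
    row, col = np.unravel_index(idx, grid.shape)
    x, y = grid.xy(row, col)
    return pd.DataFrame({"x": x, "y": y})


# ---------------------------------------------------------------------------
# Classifier-output emulation
# ---------------------------------------------------------------------------

def gen_classifier_output(true_suit: np.ndarray, grid: GridSpec,
                          spec: ClassifierSpec
                          ) -> tuple[ClassificationRaster, ClassificationRaster]:
    """Fine-scale binary classification with controlled precision/recall.

    True labels are the top ``prevalence`` fraction of the suitability
    surface (quantile cut, so segmentation metrics are exactly computable);
    predicted labels corrupt them by deleting positives (to hit recall) and
    adding false positives (to hit precision). Returns
    ``(predicted, truth)`` on the refined grid.
    """
    true_suit = np.asarray(true_suit, dtype=float)
    if true_suit.shape != grid.shape:
        raise ConfigError(f"suitability shape {true_suit.shape} != grid {grid.shape}")
    if np.nanmin(true_suit) < 0 or np.nanmax(true_suit) > 1:
        raise DomainError("true suitability must lie in [0, 1]")
    fine_grid = grid.refine(spec.fine_factor)
    fine_suit = np.kron(true_suit, np.ones((spec.fine_factor, spec.fine_factor)))
    cut = np.nanquantile(fine_suit, 1.0 - spec.prevalence)
    truth = (fine_suit >= cut).astype(np.int8)

    rng = np.random.default_rng(spec.seed)
    predicted = truth.copy()
    pos = np.flatnonzero(truth.ravel() == 1)
    neg = np.flatnonzero(truth.ravel() == 0)
    n_pos = pos.size
    # Recall: delete a fixed number of true positives.
    n_miss = int(round(n_pos * (1.0 - spec.target_recall)))
    if n_miss > 0:
        drop = rng.choice(pos, size=n_miss, replace=False)
        predicted.ravel()[drop] = 0
    tp = n_pos - n_miss
    # Precision: add false positives so TP / (TP + FP) ~= target.
    n_fp = int(round(tp * (1.0 - spec.target_precision) / spec.target_precision))
    if n_fp > 0:
        if n_fp > neg.size:
            raise ConfigError("not enough negatives to reach the requested precision")
        add = rng.choice(neg, size=n_fp, replace=False)
        predicted.ravel()[add] = 1
    return (ClassificationRaster(fine_grid, predicted),
            ClassificationRaster(fine_grid, truth))


# ---------------------------------------------------------------------------
# Future (shifted) stacks
# ---------------------------------------------------------------------------

def gen_future_stack(stack: PredictorStack,
                     shifts: dict[str, tuple[float, float]],
                     seed: int = 0) -> PredictorStack:
    """Location/scale-shift named layers: ``new = old * scale + delta``.

    ``shifts`` maps variable name -> (delta_mean, scale_sd). The affine map
    rescales spread by ``scale_sd`` and translates the distribution by
    ``delta_mean`` — the canonical way of emulating a scenario whose
    probability density has drifted rightward. Unnamed layers are carried
    through unchanged. ``seed`` is accepted for interface symmetry; the
    default shift is deterministic.
    """
    unknown = [v for v in shifts if v not in stack]
    if unknown:
        raise ConfigError(f"shift variables not in stack: {unknown}")
    layers = {}
    for name, arr in stack.layers.items():
        if name in shifts:
            delta, scale = shifts[name]
            layers[name] = arr * scale + delta
        else:
            layers[name] = arr.copy()
    return PredictorStack(stack.grid, layers, units=dict(stack.units),
                          categorical=stack.categorical)
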