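"""Presence-background maximum-entropy model.

The model is the Gibbs density over background cells

    q_beta(x) = exp(beta . f(x)) / Z,   Z = sum over background of exp(beta . f)

whose coefficients maximize the L1-penalized presence log-likelihood

    (1/m) sum_i beta . f(x_i) - log Z - sum_j lambda_j |beta_j|

with per-feature penalties ``lambda_j = RM * beta_class(m) * sd_j / sqrt(m)``
following the published defaults of the reference implementation (class
weights interpolated by presence sample size m, sd over presence features).
The objective is convex; it is solved by L-BFGS-B on the positive/negative
split of beta, which gives exact zeros at the bound and hence a sparse model.

Outputs:

* ``raw`` — q_beta normalized to sum to 1 over the background,
* ``cloglog`` — ``1 - exp(-exp(H) * raw)`` with H the entropy of the fitted
  background distribution (the default display transform of the reference
  implementation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ConfigError, ConvergenceError, InsufficientDataError, StateError
from .features import FeatureSet, build_features
from .raster import PredictorStack

__all__ = ["MaxEntModel", "fit_maxent", "aicc", "default_lambdas", "response_curve"]

_ZERO_TOL = 1e-8  # |beta| below this counts as an inactive feature

# Class-weight interpolation tables (sample size -> base weight), the
# published defaults of the reference MaxEnt implementation.
_BETA_TABLES = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
}


def _class_weight(kind: str, m: int) -> float:
    xs, ys = _BETA_TABLES[kind]
    return float(np.interp(m, xs, ys))


def default_lambdas(features: FeatureSet, occ_X: np.ndarray, rm: float) -> np.ndarray:
    """Per-feature L1 weights: RM x class weight x presence sd / sqrt(m)."""
    m = occ_X.shape[0]
    sd = occ_X.std(axis=0, ddof=0)
    sd = np.maximum(sd, 1e-3)  # floor keeps constant-at-presence features penalized
    kinds = features.kinds()
    base = np.array([_class_weight(k, m) for k in kinds])
    return rm * base * sd / np.sqrt(m)


def _fit_beta(occ_X: np.ndarray, bg_X: np.ndarray, lambdas: np.ndarray,
              tol: float = 1e-7, max_iter: int = 2000) -> tuple[np.ndarray, float]:
    """Minimize logsumexp(bg_X b) - mean(occ_X b) + sum lambda |b|.

    Returns (beta, objective). The L1 term is handled exactly by writing
    beta = u - v with u, v >= 0 and bounding both from below.
    """
    m, nfeat = occ_X.shape
    p_occ = occ_X.mean(axis=0)
    lam = np.broadcast_to(np.asarray(lambdas, dtype=float), (nfeat,))

    def fg(w: np.ndarray):
        beta = w[:nfeat] - w[nfeat:]
        s = bg_X @ beta
        lz = logsumexp(s)
        q = np.exp(s - lz)
        e_bg = q @ bg_X
        f = lz - p_occ @ beta + lam @ (w[:nfeat] + w[nfeat:])
        g = e_bg - p_occ
        return f, np.concatenate([g + lam, -g + lam])

    w0 = np.zeros(2 * nfeat)
    res = minimize(fg, w0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * nfeat),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7,
                            "maxcor": 20})
    if not res.success and res.status == 1:
        raise ConvergenceError(
            f"L-BFGS-B hit the iteration cap ({max_iter}); final objective {res.fun:.6g}")
    beta = res.x[:nfeat] - res.x[nfeat:]
    beta[np.abs(beta) < _ZERO_TOL] = 0.0
    return beta, float(res.fun)


@dataclass
class MaxEntModel:
    """A fitted maximum-entropy presence-background model."""

    features: FeatureSet
    beta: np.ndarray
    rm: float
    lambdas: np.ndarray
    log_z: float            # logsumexp of beta.f over the background
    entropy: float          # entropy H of the fitted background distribution
    n_background: int
    objective: float        # final penalized objective value (minimized)
    bg_means: pd.Series = field(repr=False)     # background column means / modes
    bg_range: pd.DataFrame = field(repr=False)  # per-variable min/max (background)

    # -- diagnostics ----------------------------------------------------
    @property
    def k(self) -> int:
        """Number of active (non-zero) coefficients."""
        return int(np.sum(np.abs(self.beta) > _ZERO_TOL))

    def log_raw(self, env: pd.DataFrame) -> np.ndarray:
        """log of the background-normalized raw output at environmental rows."""
        X = self.features.transform(env)
        return X @ self.beta - self.log_z

    def predict_env(self, env: pd.DataFrame, output: str = "cloglog") -> np.ndarray:
        raw = np.exp(self.log_raw(env))
        if output == "raw":
            return raw
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ConfigError(f"unknown output transform {output!r}")

    def predict(self, env: PredictorStack | pd.DataFrame,
                output: str = "cloglog") -> np.ndarray:
        """Suitability over a stack (2-D grid, NaN at nodata) or a table (1-D)."""
        if isinstance(env, pd.DataFrame):
            return self.predict_env(env, output=output)
        needed = self.features.variables
        frame = env.to_frame(needed)  # raises AlignmentError on missing layers
        vals = self.predict_env(frame, output=output)
        out = np.full(env.grid.shape, np.nan)
        out.ravel()[frame.index.to_numpy()] = vals
        return out

    def gain(self, occ_env: pd.DataFrame, regularized: bool = True) -> float:
        """Training gain: mean log raw at presences relative to a uniform model."""
        g = float(self.log_raw(occ_env).mean() + np.log(self.n_background))
        if regularized:
            g -= float(self.lambdas @ np.abs(self.beta))
        return g

    def log_likelihood(self, occ_env: pd.DataFrame) -> float:
        """Sum of log standardized raw probabilities at occurrence records."""
        return float(self.log_raw(occ_env).sum())


def fit_maxent(occ_env: pd.DataFrame, bg_env: pd.DataFrame, rm: float = 1.0,
               fc: str = "LQH", hinge_knots: int = 50,
               threshold_knots: int | None = None,
               categorical: tuple[str, ...] | set[str] = (),
               features: FeatureSet | None = None,
               tol: float = 1e-7, max_iter: int = 2000) -> MaxEntModel:
    """Fit the penalized maximum-entropy model from environmental tables.

    ``occ_env`` and ``bg_env`` carry one row per presence / background point
    and one column per predictor. A pre-built :class:`FeatureSet` can be
    supplied to share feature construction across fits (tuning does this).
    """
    occ_env = occ_env.reset_index(drop=True)
    bg_env = bg_env.reset_index(drop=True)
    if len(occ_env) < 2:
        raise InsufficientDataError("need at least 2 occurrence records")
    if len(bg_env) <= len(occ_env):
        raise InsufficientDataError("background must be larger than the occurrence set")
    if features is None:
        features = build_features(bg_env, fc=fc, hinge_knots=hinge_knots,
                                  threshold_knots=threshold_knots,
                                  categorical=categorical)
    occ_X = features.transform(occ_env)
    bg_X = features.transform(bg_env)
    # Presences are added to the normalization set (the reference
    # implementation's "add samples to background"): this bounds the
    # penalized likelihood even under perfect separation.
    bg_X = np.vstack([bg_X, occ_X])
    lambdas = default_lambdas(features, occ_X, rm)
    beta, obj = _fit_beta(occ_X, bg_X, lambdas, tol=tol, max_iter=max_iter)

    s = bg_X @ beta
    log_z = float(logsumexp(s))
    q = np.exp(s - log_z)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))

    bg_means = {}
    for col in bg_env.columns:
        if col in features.cat_levels:
            bg_means[col] = bg_env[col].mode().iloc[0]
        else:
            bg_means[col] = float(bg_env[col].mean())
    bg_range = pd.DataFrame({
        "min": pd.Series(features.var_min), "max": pd.Series(features.var_max)})
    return MaxEntModel(features=features, beta=beta, rm=rm, lambdas=lambdas,
                       log_z=log_z, entropy=entropy,
                       n_background=len(bg_env) + len(occ_env),
                       objective=obj, bg_means=pd.Series(bg_means), bg_range=bg_range)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike criterion; +inf sentinel when n <= k + 1.

    ``log_likelihood`` is the sum of log standardized raw probabilities at
    the occurrence records and ``k`` the number of non-zero coefficients.
    A candidate with ``n <= k + 1`` is disqualified (sentinel), not an error.
    """
    if n <= k + 1:
        return float("inf")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def response_curve(model: MaxEntModel, variable: str, n_points: int = 100,
                   output: str = "cloglog") -> pd.DataFrame:
    """Marginal response: sweep one variable, hold the others at background means.

    Categorical covariates are held at their background mode; a categorical
    target variable is swept across its observed levels instead of a linear
    grid. Returns a two-column frame ``(value, suitability)``.
    """
    if variable not in model.bg_means.index:
        raise ConfigError(f"variable {variable!r} is not in the model")
    if model.k == 0:
        pass  # constant model: curve is flat by construction
    if variable in model.features.cat_levels:
        sweep = model.features.cat_levels[variable].astype(float)
    else:
        lo = model.features.var_min[variable]
        hi = model.features.var_max[variable]
        sweep = np.linspace(lo, hi, n_points)
    env = pd.DataFrame({c: np.repeat(v, len(sweep))
                        for c, v in model.bg_means.items()})
    env[variable] = sweep
    suit = model.predict_env(env, output=output)
    return pd.DataFrame({"value": sweep, "suitability": suit})
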