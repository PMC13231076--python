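"""Interpretive diagnostics: contributions, permutation importance, jackknife.

Percent contribution is path-dependent: it credits each variable with the
share of penalized-likelihood improvement accumulated while coordinate-wise
refitting walks from the null model to the optimum. It is a heuristic (the
path matters), so permutation importance — the normalized drop in training
AUC when a variable's values are shuffled across presences and background —
is always reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import StateError
from .evaluation import auc
from .maxent import MaxEntModel, default_lambdas

__all__ = ["variable_importance", "jackknife_gains"]


def _cd_contributions(occ_X: np.ndarray, bg_X: np.ndarray, lam: np.ndarray,
                      defs, max_passes: int = 40, tol: float = 1e-5
                      ) -> dict[str, float]:
    """Coordinate descent from beta=0 crediting objective gains to variables.

    Each coordinate update takes a prox-Newton step (1-D Newton on the
    smooth part, soft-thresholded by its L1 weight, halved until the convex
    objective decreases). The objective decrease of every accepted step is
    credited to the feature's source variable(s); product features split the
    credit evenly between their two variables.
    """
    m, nfeat = occ_X.shape
    p_occ = occ_X.mean(axis=0)
    beta = np.zeros(nfeat)
    s_bg = np.zeros(bg_X.shape[0])

    def objective(s):
        return logsumexp(s) - p_occ @ beta + lam @ np.abs(beta)

    credit: dict[str, float] = {}
    obj = objective(s_bg)
    for _ in range(max_passes):
        obj_start = obj
        for j in range(nfeat):
            x = bg_X[:, j]
            lz = logsumexp(s_bg)
            q = np.exp(s_bg - lz)
            mu = q @ x
            grad = mu - p_occ[j]
            hess = max(q @ (x * x) - mu * mu, 1e-8)
            z = beta[j] - grad / hess
            new = np.sign(z) * max(abs(z) - lam[j] / hess, 0.0)
            step = new - beta[j]
            if step == 0.0:
                continue
            while abs(step) > 1e-12:
                cand_beta = beta[j] + step
                s_new = s_bg + step * x
                f_new = (logsumexp(s_new) - (p_occ @ beta + p_occ[j] * step)
                         + lam @ np.abs(beta) + lam[j] * (abs(cand_beta) - abs(beta[j])))
                if f_new <= obj:
                    break
                step *= 0.5
            else:
                continue
            gain = obj - f_new
            beta[j] = cand_beta
            s_bg = s_new
            obj = f_new
            vars_ = defs[j].variables
            for v in vars_:
                credit[v] = credit.get(v, 0.0) + gain / len(vars_)
        if obj_start - obj < tol:
            break
    return credit


def variable_importance(model: MaxEntModel, occ_env: pd.DataFrame,
                        bg_env: pd.DataFrame, n_permutations: int = 1,
                        seed: int = 0) -> pd.DataFrame:
    """Percent contribution and permutation importance, each summing to 100.

    ``n_permutations=0`` skips the permutation column (reported as zeros);
    the screening stage uses this to price only the contribution path.
    """
    if model.beta is None:  # defensive; fit_maxent always sets it
        raise StateError("model is not fitted")
    occ_env = occ_env.reset_index(drop=True)
    bg_env = bg_env.reset_index(drop=True)
    fs = model.features
    occ_X = fs.transform(occ_env)
    bg_X = fs.transform(bg_env)
    lam = default_lambdas(fs, occ_X, model.rm)

    # CD retraces the fit's objective, samples included in the normalization.
    credit = _cd_contributions(occ_X, np.vstack([bg_X, occ_X]), lam, fs.defs)
    variables = fs.variables
    contrib = np.array([credit.get(v, 0.0) for v in variables])
    total = contrib.sum()
    contrib = 100.0 * contrib / total if total > 0 else np.zeros_like(contrib)

    # Permutation importance: shuffle a variable across presence+background,
    # re-evaluate, normalize the training-AUC drops.
    base_occ = occ_X @ model.beta
    base_bg = bg_X @ model.beta
    base_auc = auc(base_occ, base_bg)
    rng = np.random.default_rng(seed)
    drops = np.zeros(len(variables))
    n_occ = len(occ_env)
    combined = pd.concat([occ_env, bg_env], ignore_index=True)
    for i, v in enumerate(variables if n_permutations > 0 else []):
        d = 0.0
        for _ in range(n_permutations):
            perm = combined.copy()
            perm[v] = rng.permutation(perm[v].to_numpy())
            s = fs.transform(perm) @ model.beta
            d += base_auc - auc(s[:n_occ], s[n_occ:])
        drops[i] = max(d / n_permutations, 0.0)
    total_d = drops.sum()
    perm_imp = 100.0 * drops / total_d if total_d > 0 else np.zeros_like(drops)

    out = pd.DataFrame({
        "variable": variables,
        "contribution": contrib,
        "permutation_importance": perm_imp,
    }).sort_values("contribution", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def jackknife_gains(occ_env: pd.DataFrame, bg_env: pd.DataFrame,
                    variables: list[str] | None = None, rm: float = 1.0,
                    fc: str = "LQH", hinge_knots: int = 50,
                    categorical: tuple[str, ...] | set[str] = ()) -> pd.DataFrame:
    """Leave-one-in / leave-one-out regularized training gains per variable.

    Fits 2V+1 models: each variable alone, all variables without it, and the
    full set. Gains are regularized training gains relative to the uniform
    background model.
    """
    from .maxent import fit_maxent  # local import avoids a cycle at module load

    if variables is None:
        variables = list(occ_env.columns.intersection(bg_env.columns))
    if len(variables) < 2:
        raise StateError("jackknife needs at least 2 variables")

    def _gain(cols: list[str]) -> float:
        model = fit_maxent(occ_env[cols], bg_env[cols], rm=rm, fc=fc,
                           hinge_knots=hinge_knots,
                           categorical=tuple(set(categorical) & set(cols)))
        return model.gain(occ_env[cols])

    full_gain = _gain(variables)
    rows = []
    for v in variables:
        rows.append({
            "variable": v,
            "gain_with_only": _gain([v]),
            "gain_without": _gain([c for c in variables if c != v]),
        })
    out = pd.DataFrame(rows)
    out.attrs["full_gain"] = full_gain
    return out
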