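"""Discrimination and calibration metrics for presence-background models.

* :func:`auc` — rank probability that a presence outscores a background
  point (ties count 1/2).
* :func:`mtss_threshold` / :func:`tss` — the maximum-training-sensitivity-
  plus-specificity threshold and the true skill statistic, with background
  points standing in for absences (the presence-only convention).
* :func:`boyce_index` — continuous Boyce index: Spearman correlation of
  moving-window predicted-to-expected presence ratios against window
  midpoints; a calibration metric designed for presence-only data.
* :func:`crossvalidate` — random k-fold protocol reporting per-fold and
  mean AUC/TSS/CBI plus the all-data MTSS threshold.

The prediction rule is ``score >= threshold`` everywhere (closed at the
threshold), matching the tiering module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .errors import DomainError, InsufficientDataError

__all__ = ["EvalReport", "auc", "mtss_threshold", "tss", "boyce_index",
           "crossvalidate"]


def auc(scores_presence, scores_background) -> float:
    """Area under the ROC curve from two score samples (ties = 1/2)."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise DomainError("AUC needs non-empty presence and background scores")
    y = np.concatenate([np.ones(sp.size), np.zeros(sb.size)])
    s = np.concatenate([sp, sb])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def _sens_spec(sp: np.ndarray, sr: np.ndarray, thresholds: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sensitivity/specificity at each threshold (rule: score >= t)."""
    sp_sorted = np.sort(sp)
    sr_sorted = np.sort(sr)
    sens = 1.0 - np.searchsorted(sp_sorted, thresholds, side="left") / sp.size
    spec = np.searchsorted(sr_sorted, thresholds, side="left") / sr.size
    return sens, spec


def mtss_threshold(scores_presence, scores_reference) -> float:
    """Threshold (among observed scores) maximizing sensitivity + specificity.

    Ties are broken toward the lowest such threshold, so the suitable class
    is as inclusive as the optimum allows.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sr = np.asarray(scores_reference, dtype=float)
    if sp.size == 0 or sr.size == 0:
        raise DomainError("MTSS needs non-empty score sets")
    candidates = np.unique(np.concatenate([sp, sr]))
    sens, spec = _sens_spec(sp, sr, candidates)
    total = sens + spec
    best = np.flatnonzero(total == total.max())[0]  # lowest threshold among ties
    return float(candidates[best])


def tss(scores_presence, scores_reference, threshold: float) -> float:
    """True skill statistic = sensitivity + specificity - 1 at a threshold."""
    if not np.isfinite(threshold):
        raise DomainError("threshold must be finite")
    sp = np.asarray(scores_presence, dtype=float)
    sr = np.asarray(scores_reference, dtype=float)
    sens = float(np.mean(sp >= threshold))
    spec = float(np.mean(sr < threshold))
    return sens + spec - 1.0


def boyce_index(scores_presence, scores_landscape, n_windows: int = 101,
                window_fraction: float = 0.1) -> float:
    """Continuous Boyce index.

    A window of width ``window_fraction`` x score range slides across the
    landscape score range at ``n_windows`` positions. Per window, P is the
    fraction of presence scores inside it and E the fraction of landscape
    scores; windows with E = 0 are skipped. CBI is the Spearman rank
    correlation between window midpoints and P/E — 1 means suitability
    ranks perfectly predict relative occurrence density.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sl = np.asarray(scores_landscape, dtype=float)
    if sl.size < 100:
        raise InsufficientDataError("landscape sample must have >= 100 scores")
    if sp.size == 0:
        raise DomainError("presence scores must be non-empty")
    lo, hi = sl.min(), sl.max()
    if hi <= lo:
        raise DomainError("landscape scores are constant; CBI undefined")
    width = window_fraction * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    p = np.empty(n_windows)
    e = np.empty(n_windows)
    for i, mid in enumerate(mids):
        a, b = mid - width / 2, mid + width / 2
        p[i] = np.mean((sp >= a) & (sp <= b))
        e[i] = np.mean((sl >= a) & (sl <= b))
    keep = e > 0
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} windows hold landscape scores; CBI undefined")
    ratio = p[keep] / e[keep]
    rho = spearmanr(mids[keep], ratio).statistic
    return float(rho)


@dataclass
class EvalReport:
    """Cross-validation results: per-fold metrics, means, threshold, folds."""

    folds: pd.DataFrame          # one row per fold
    means: pd.Series             # column means of `folds`
    mtss: float                  # MTSS threshold of the all-data model
    fold_assignments: np.ndarray
    seed: int


def crossvalidate(occ_env: pd.DataFrame, bg_env: pd.DataFrame,
                  model_config: dict | None = None, k: int = 4,
                  seed: int = 0, landscape_env: pd.DataFrame | None = None
                  ) -> EvalReport:
    """Random k-fold cross-validation of a fixed MaxEnt configuration.

    Folds partition the occurrences (sizes differ by at most one); each
    fold's model trains on the remaining occurrences with the full
    background, and is scored on the held-out fold. TSS is evaluated at the
    fold's own MTSS (background as pseudo-absence); CBI against the
    landscape sample (``landscape_env`` defaults to the background).
    """
    from .maxent import fit_maxent  # deferred: evaluation is imported by tuning

    config = dict(model_config or {})
    occ_env = occ_env.reset_index(drop=True)
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    if len(occ_env) < k:
        raise InsufficientDataError(f"{len(occ_env)} occurrences cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    assignments = np.arange(len(occ_env)) % k
    rng.shuffle(assignments)
    if landscape_env is None:
        landscape_env = bg_env

    rows = []
    for f in range(k):
        train = occ_env[assignments != f]
        test = occ_env[assignments == f]
        model = fit_maxent(train, bg_env, **config)
        s_train = model.predict_env(train)
        s_test = model.predict_env(test)
        s_bg = model.predict_env(bg_env)
        s_land = model.predict_env(landscape_env)
        t = mtss_threshold(s_train, s_bg)
        try:
            cbi = boyce_index(s_test, s_land)
        except InsufficientDataError:
            cbi = np.nan
        rows.append({
            "fold": f,
            "auc_train": auc(s_train, s_bg),
            "auc_test": auc(s_test, s_bg),
            "tss_test": tss(s_test, s_bg, t),
            "cbi_test": cbi,
        })
    folds = pd.DataFrame(rows)
    folds["auc_diff"] = (folds["auc_train"] - folds["auc_test"]).abs()

    full = fit_maxent(occ_env, bg_env, **config)
    mtss = mtss_threshold(full.predict_env(occ_env), full.predict_env(bg_env))
    return EvalReport(folds=folds, means=folds.drop(columns="fold").mean(),
                      mtss=float(mtss), fold_assignments=assignments, seed=seed)
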