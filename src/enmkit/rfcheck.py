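"""Algorithm-independence cross-check with a balanced-bootstrap random forest.

A random forest is fitted to presences vs pseudo-absences drawn from the
background. Because the background vastly outnumbers presences, each of
``n_iterations`` fits downsamples the background, without replacement, to
exactly the presence count (one-to-one class balance); the held-out
background forms that iteration's test set. Metrics are averaged across
iterations and the per-iteration probability maps are averaged into one
suitability surface, which is thresholded at its own MTSS and tiered with
the equal-above-threshold scheme.

The tree learner itself is scikit-learn's :class:`RandomForestClassifier`;
the bespoke content here is the sampling/aggregation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import AlignmentError, ConfigError, InsufficientDataError
from .evaluation import auc, boyce_index, mtss_threshold, tss
from .raster import PredictorStack
from .tiering import TierMap, classify_tiers, make_scheme

__all__ = ["RFProtocolConfig", "RFCheckResult", "balanced_rf_check",
           "tier_concordance"]


@dataclass(frozen=True)
class RFProtocolConfig:
    """Protocol settings; the tree hyperparameters mirror the tuned values."""

    n_iterations: int = 10
    ntree: int = 70
    mtry: int = 1
    nodesize: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_iterations", "ntree", "mtry", "nodesize"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")


@dataclass
class RFCheckResult:
    metrics: pd.DataFrame        # one row per iteration
    means: pd.Series
    mean_map: np.ndarray         # averaged probability surface (NaN at nodata)
    mtss: float
    tier_map: TierMap


def balanced_rf_check(occ_env: pd.DataFrame, bg_env: pd.DataFrame,
                      stack: PredictorStack,
                      config: RFProtocolConfig = RFProtocolConfig(),
                      variables: list[str] | None = None) -> RFCheckResult:
    """Run the balanced-bootstrap RF protocol and tier the mean map."""
    variables = variables or [c for c in occ_env.columns
                              if c in bg_env.columns and c in stack.layers]
    if not variables:
        raise AlignmentError("no shared variables between tables and stack")
    n_pres = len(occ_env)
    n_bg = len(bg_env)
    if n_bg < n_pres:
        raise ConfigError(
            f"background ({n_bg}) must be at least the presence count ({n_pres})")
    if n_pres < 2:
        raise InsufficientDataError("need at least 2 presences")

    X_occ = occ_env[variables].to_numpy()
    X_bg = bg_env[variables].to_numpy()
    frame = stack.to_frame(variables)
    X_land = frame.to_numpy()

    rng = np.random.default_rng(config.seed)
    rows = []
    prob_sum = np.zeros(len(X_land))
    for it in range(config.n_iterations):
        pick = rng.choice(n_bg, size=n_pres, replace=False)
        held = np.setdiff1d(np.arange(n_bg), pick)
        X = np.vstack([X_occ, X_bg[pick]])
        y = np.concatenate([np.ones(n_pres), np.zeros(n_pres)])
        assert (y == 1).sum() == (y == 0).sum()  # 1:1 balance, by construction
        forest = RandomForestClassifier(
            n_estimators=config.ntree, max_features=config.mtry,
            min_samples_leaf=config.nodesize,
            random_state=int(rng.integers(2 ** 31 - 1)))
        forest.fit(X, y)
        s_pres = forest.predict_proba(X_occ)[:, 1]
        s_test = forest.predict_proba(X_bg[held])[:, 1]
        s_land = forest.predict_proba(X_land)[:, 1]
        t = mtss_threshold(s_pres, s_test)
        try:
            cbi = boyce_index(s_pres, s_land)
        except Exception:
            cbi = np.nan
        rows.append({"iteration": it, "auc": auc(s_pres, s_test),
                     "tss": tss(s_pres, s_test, t), "cbi": cbi,
                     "n_presence": n_pres, "n_pseudoabsence": int(pick.size),
                     "n_test_background": int(held.size)})
        prob_sum += s_land

    metrics = pd.DataFrame(rows)
    mean_land = prob_sum / config.n_iterations
    mean_map = np.full(stack.grid.shape, np.nan)
    mean_map.ravel()[frame.index.to_numpy()] = mean_land

    # Score presences on the mean map for the final threshold. With x/y
    # available the map value under each point is used; otherwise presences
    # are rescored through a mean over the per-iteration forests' inputs.
    if {"x", "y"} <= set(occ_env.columns):
        row, col = stack.grid.rowcol(occ_env["x"].to_numpy(), occ_env["y"].to_numpy())
        s_pres_mean = mean_map[row, col]
        s_pres_mean = s_pres_mean[np.isfinite(s_pres_mean)]
    else:
        s_pres_mean = np.array([])
    if s_pres_mean.size == 0:
        raise ConfigError("occ_env must carry x/y columns inside the stack extent")
    mtss = mtss_threshold(s_pres_mean, mean_land)
    scheme = make_scheme(min(max(mtss, 1e-6), 1 - 1e-6), "equal-above-threshold")
    tier_map = classify_tiers(mean_map, scheme, grid=stack.grid)
    return RFCheckResult(metrics=metrics, means=metrics.drop(columns="iteration").mean(),
                         mean_map=mean_map, mtss=float(mtss), tier_map=tier_map)


def tier_concordance(tiers_a: TierMap, tiers_b: TierMap) -> dict:
    """Per-tier Jaccard overlap and the full 4x4 cell-count confusion table."""
    if not tiers_a.grid.same_geometry(tiers_b.grid):
        raise AlignmentError("tier maps are on different grids")
    a = tiers_a.tiers
    b = tiers_b.tiers
    jaccard = {}
    for t in range(4):
        inter = int(np.sum((a == t) & (b == t)))
        union = int(np.sum((a == t) | (b == t)))
        jaccard[t] = inter / union if union else float("nan")
    confusion = np.zeros((4, 4), dtype=int)
    valid = (a >= 0) & (b >= 0)
    for i in range(4):
        for j in range(4):
            confusion[i, j] = int(np.sum(valid & (a == i) & (b == j)))
    return {"jaccard": jaccard,
            "confusion": pd.DataFrame(confusion,
                                      index=[f"a_tier{t}" for t in range(4)],
                                      columns=[f"b_tier{t}" for t in range(4)])}
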