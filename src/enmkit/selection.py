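"""Multi-stage predictor screening: correlation, contributions, VIF.

The cascade mirrors the screening practice standard in distribution
modelling with many candidate predictors:

1. Pearson correlation over the environmental sample flags pairs with
   ``|r|`` above a threshold (default 0.8).
2. An initial MaxEnt model (bootstrap replicates, 75/25 train split)
   supplies per-variable percent contributions, used as the retention
   priority.
3. Variance inflation factors quantify residual multicollinearity; the
   screen iterates — worst correlation pair first, then worst VIF, dropping
   the lower-contribution member each time and recomputing — until all
   pairwise ``|r| <=`` threshold and all VIF are below their cap
   (default 10).

Ties in contribution break alphabetically by variable name so the cascade
is deterministic given the contribution table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SelectionError
from .maxent import fit_maxent

__all__ = ["ScreeningReport", "correlation_screen", "initial_contributions",
           "vif", "select_variables"]


@dataclass
class ScreeningReport:
    correlation: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    vif: pd.Series
    contributions: pd.Series
    retained: list[str]
    log: list[dict] = field(default_factory=list)


def correlation_screen(env: pd.DataFrame, r_threshold: float = 0.8
                       ) -> tuple[list[tuple[str, str, float]], pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations; pairs with |r| strictly above threshold.

    Returns ``(flagged_pairs, matrix, constant_columns)``; constant columns
    cannot be correlated and are reported separately rather than flagged.
    """
    if len(env) < 3:
        raise InsufficientDataError("correlation screen needs >= 3 rows")
    constant = [c for c in env.columns if env[c].nunique(dropna=True) <= 1]
    work = env.drop(columns=constant)
    corr = work.corr(method="pearson")
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) > r_threshold:
                flagged.append((a, b, float(r)))
    flagged.sort(key=lambda t: -abs(t[2]))
    return flagged, corr, constant


def initial_contributions(occ_env: pd.DataFrame, bg_env: pd.DataFrame,
                          n_reps: int = 10, train_fraction: float = 0.75,
                          seed: int = 0, fc: str = "LQ", rm: float = 1.0,
                          hinge_knots: int = 10,
                          categorical: tuple[str, ...] | set[str] = ()
                          ) -> pd.Series:
    """Mean percent contribution across bootstrap replicates of a light model.

    Each replicate trains on a random ``train_fraction`` of the occurrences
    (the initial-screen protocol); contributions per replicate sum to 100.
    """
    from .interpret import variable_importance  # lazy: interpret imports maxent

    if len(occ_env) < 10:
        raise InsufficientDataError(
            f"initial contributions need >= 10 occurrences, got {len(occ_env)}")
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_fraction * len(occ_env))))
    acc: dict[str, float] = {}
    for _ in range(n_reps):
        idx = rng.choice(len(occ_env), size=n_train, replace=False)
        occ = occ_env.iloc[idx]
        model = fit_maxent(occ, bg_env, rm=rm, fc=fc, hinge_knots=hinge_knots,
                           categorical=categorical)
        imp = variable_importance(model, occ, bg_env, n_permutations=0,
                                  seed=int(rng.integers(2 ** 31 - 1)))
        for _, r in imp.iterrows():
            acc[r["variable"]] = acc.get(r["variable"], 0.0) + r["contribution"]
    out = pd.Series({k: v / n_reps for k, v in acc.items()}).sort_values(
        ascending=False)
    out.name = "contribution"
    return out


def vif(env: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    Each variable is regressed on all others (with intercept). Exact
    collinearity yields an infinite sentinel rather than an exception.
    """
    cols = list(env.columns)
    if len(env) <= len(cols):
        raise InsufficientDataError("VIF needs more rows than variables")
    X = env.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    out = {}
    for j, name in enumerate(cols):
        y = X[:, j + 1]
        others = np.delete(X, j + 1, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot <= 0:
            out[name] = float("inf")
            continue
        one_minus_r2 = ss_res / ss_tot
        out[name] = float("inf") if one_minus_r2 < 1e-12 else 1.0 / one_minus_r2
    return pd.Series(out, name="vif")


def select_variables(env: pd.DataFrame, contributions: pd.Series,
                     r_threshold: float = 0.8, vif_threshold: float = 10.0
                     ) -> ScreeningReport:
    """Iteratively resolve correlation then VIF violations.

    At each step the worst violation is found — the pair with highest
    ``|r|`` above threshold, else the variable with highest VIF at or above
    the cap — and the lower-contribution participant is dropped (for a VIF
    violation, the violator itself is dropped only if no flagged pair
    remains). Correlations and VIFs are recomputed after every drop.
    """
    current = [c for c in env.columns]
    missing = [c for c in current if c not in contributions.index]
    if missing:
        raise SelectionError(f"contributions missing for {missing}")
    log: list[dict] = []

    def _prio(name: str) -> tuple[float, str]:
        # higher contribution wins; ties break alphabetically (a before b)
        return (-float(contributions[name]), name)

    while True:
        if not current:
            raise SelectionError("screening eliminated every variable")
        flagged, corr, _ = correlation_screen(env[current], r_threshold) \
            if len(current) > 1 else ([], env[current].corr(), [])
        if flagged:
            a, b, r = flagged[0]
            drop = max(a, b, key=lambda n: _prio(n))
            keep = a if drop == b else b
            log.append({"dropped": drop, "reason": f"|r|={abs(r):.3f}>"
                        f"{r_threshold} with {keep}",
                        "competitor": keep})
            current.remove(drop)
            continue
        if len(current) > 1 and len(env) > len(current):
            v = vif(env[current])
            worst = v.idxmax()
            if v[worst] >= vif_threshold:
                # drop the lowest-contribution member among high-VIF variables
                high = v[v >= vif_threshold].index
                drop = max(high, key=lambda n: _prio(n))
                log.append({"dropped": drop,
                            "reason": f"VIF={v[drop]:.2f}>={vif_threshold}",
                            "competitor": worst})
                current.remove(drop)
                continue
        break

    final_flagged, final_corr, _ = correlation_screen(env[current], r_threshold) \
        if len(current) > 1 else ([], env[current].corr(), [])
    final_vif = vif(env[current]) if 1 < len(current) < len(env) else pd.Series(
        {c: 1.0 for c in current}, name="vif")
    return ScreeningReport(
        correlation=final_corr, flagged_pairs=final_flagged, vif=final_vif,
        contributions=contributions.reindex(current), retained=current, log=log)
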