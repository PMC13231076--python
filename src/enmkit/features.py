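"""Feature construction for the maximum-entropy model.

Predictor variables are rescaled to [0, 1] using their background range and
expanded into basis functions by feature class:

==========  =============================================================
letter      features per continuous variable
==========  =============================================================
L linear    the scaled variable itself
Q quadratic its square
P product   pairwise products of scaled variables
H hinge     forward and reverse hinges at quantile knots (piecewise linear)
T threshold step indicators at quantile knots
==========  =============================================================

Categorical variables (e.g. a land-use code layer) are expanded into one
indicator per observed level, included regardless of the feature-class set
and exempt from Q/P/H/T expansion. Every feature evaluates into [0, 1] on
the background by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["FeatureDef", "FeatureSet", "build_features", "FC_SETS"]

#: The canonical tuning ladder of feature-class combinations.
FC_SETS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")

_LETTER_TO_KIND = {
    "L": "linear", "Q": "quadratic", "P": "product",
    "H": "hinge", "T": "threshold",
}


@dataclass(frozen=True)
class FeatureDef:
    kind: str                 # linear|quadratic|product|hinge|threshold|categorical
    variables: tuple[str, ...]
    knot: float | None = None     # hinge/threshold knot on the [0,1] scale
    direction: int = 0            # hinge: +1 forward, -1 reverse
    level: float | None = None    # categorical level

    def label(self) -> str:
        if self.kind == "categorical":
            return f"{self.variables[0]}=={self.level:g}"
        if self.kind == "hinge":
            tag = "fwd" if self.direction > 0 else "rev"
            return f"h{tag}({self.variables[0]}@{self.knot:.4f})"
        if self.kind == "threshold":
            return f"thr({self.variables[0]}@{self.knot:.4f})"
        if self.kind == "product":
            return f"{self.variables[0]}*{self.variables[1]}"
        if self.kind == "quadratic":
            return f"{self.variables[0]}^2"
        return self.variables[0]


class FeatureSet:
    """Feature definitions plus the background scaling needed to evaluate them."""

    def __init__(self, defs: list[FeatureDef], var_min: dict[str, float],
                 var_max: dict[str, float], cat_levels: dict[str, np.ndarray]):
        self.defs = list(defs)
        self.var_min = dict(var_min)
        self.var_max = dict(var_max)
        self.cat_levels = {k: np.asarray(v) for k, v in cat_levels.items()}

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.defs:
            for v in d.variables:
                seen.setdefault(v)
        return list(seen)

    def labels(self) -> list[str]:
        return [d.label() for d in self.defs]

    def kinds(self) -> np.ndarray:
        return np.array([d.kind for d in self.defs])

    def scale(self, name: str, values: np.ndarray) -> np.ndarray:
        """Clamp-scale raw variable values to [0, 1] by the background range."""
        lo, hi = self.var_min[name], self.var_max[name]
        span = hi - lo
        if span <= 0:
            return np.zeros_like(np.asarray(values, dtype=float))
        return np.clip((np.asarray(values, dtype=float) - lo) / span, 0.0, 1.0)

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        """Evaluate every feature on an environmental table -> (n, F) in [0,1]."""
        n = len(env)
        z: dict[str, np.ndarray] = {}
        for name in self.var_min:
            if name in env.columns:
                z[name] = self.scale(name, env[name].to_numpy())
        out = np.empty((n, len(self.defs)))
        for j, d in enumerate(self.defs):
            v = d.variables[0]
            if d.kind == "linear":
                out[:, j] = z[v]
            elif d.kind == "quadratic":
                out[:, j] = z[v] ** 2
            elif d.kind == "product":
                out[:, j] = z[v] * z[d.variables[1]]
            elif d.kind == "hinge":
                k = d.knot
                if d.direction > 0:
                    out[:, j] = np.clip((z[v] - k) / (1.0 - k), 0.0, 1.0)
                else:
                    out[:, j] = np.clip((k - z[v]) / k, 0.0, 1.0)
            elif d.kind == "threshold":
                out[:, j] = (z[v] >= d.knot).astype(float)
            elif d.kind == "categorical":
                out[:, j] = (env[v].to_numpy() == d.level).astype(float)
            else:  # pragma: no cover - construction guards against this
                raise ConfigError(f"unknown feature kind {d.kind!r}")
        return out

    def column_indices(self, fc: str) -> np.ndarray:
        """Column indices of the features active under a feature-class string."""
        kinds = {_LETTER_TO_KIND[c] for c in _parse_fc(fc)}
        kinds.add("categorical")
        return np.array([j for j, d in enumerate(self.defs) if d.kind in kinds],
                        dtype=int)

    def subset(self, fc: str) -> "FeatureSet":
        idx = self.column_indices(fc)
        return FeatureSet([self.defs[j] for j in idx], self.var_min, self.var_max,
                          self.cat_levels)


def _parse_fc(fc: str) -> str:
    fc = fc.upper()
    bad = set(fc) - set(_LETTER_TO_KIND)
    if bad:
        raise ConfigError(f"unknown feature-class letters {sorted(bad)} in {fc!r}")
    return fc


def build_features(background: pd.DataFrame, fc: str = "LQHPT",
                   hinge_knots: int = 50, threshold_knots: int | None = None,
                   categorical: tuple[str, ...] | set[str] = ()) -> FeatureSet:
    """Define the feature basis from a background environmental table.

    Scaling ranges, hinge knots and threshold knots all come from the
    background sample (quantile knots, ``hinge_knots`` per direction per
    variable). ``fc`` controls which families are generated; categorical
    variables always contribute indicator features only.
    """
    fc = _parse_fc(fc)
    if hinge_knots < 2:
        raise ConfigError(f"hinge_knots must be >= 2, got {hinge_knots}")
    if threshold_knots is None:
        threshold_knots = hinge_knots
    categorical = set(categorical)
    cont = [c for c in background.columns if c not in categorical]
    if not cont and not categorical:
        raise ConfigError("background table has no variables")

    var_min = {c: float(np.nanmin(background[c])) for c in cont}
    var_max = {c: float(np.nanmax(background[c])) for c in cont}
    cat_levels = {c: np.unique(background[c].dropna().to_numpy()) for c in categorical}

    defs: list[FeatureDef] = []
    if "L" in fc:
        defs += [FeatureDef("linear", (c,)) for c in cont]
    if "Q" in fc:
        defs += [FeatureDef("quadratic", (c,)) for c in cont]
    if "P" in fc:
        for i, a in enumerate(cont):
            for b in cont[i + 1:]:
                defs.append(FeatureDef("product", (a, b)))
    if "H" in fc:
        for c in cont:
            for k in _quantile_knots(background[c], var_min[c], var_max[c], hinge_knots):
                defs.append(FeatureDef("hinge", (c,), knot=k, direction=+1))
                defs.append(FeatureDef("hinge", (c,), knot=k, direction=-1))
    if "T" in fc:
        for c in cont:
            for k in _quantile_knots(background[c], var_min[c], var_max[c],
                                     threshold_knots):
                defs.append(FeatureDef("threshold", (c,), knot=k))
    for c in sorted(categorical):
        for level in cat_levels[c]:
            defs.append(FeatureDef("categorical", (c,), level=float(level)))
    return FeatureSet(defs, var_min, var_max, cat_levels)


def _quantile_knots(values: pd.Series, lo: float, hi: float, n: int) -> np.ndarray:
    """Interior quantile knots on the scaled [0, 1] axis; degenerate vars get none."""
    span = hi - lo
    if span <= 0:
        return np.array([])
    z = (values.dropna().to_numpy() - lo) / span
    q = np.quantile(z, (np.arange(n) + 1) / (n + 1))
    q = np.clip(q, 1e-6, 1 - 1e-6)
    # Spread exact duplicates (heavy-tailed samples) onto a uniform grid instead.
    if np.unique(q).size < q.size:
        q = np.unique(np.concatenate([q, (np.arange(n) + 1) / (n + 1)]))[:n]
    return q
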