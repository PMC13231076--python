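"""Shared fixtures: small synthetic landscapes and one full recovery study.

The ``recovery_study`` fixture is deliberately expensive (full tuning grid on
a 150x150 landscape) and session-scoped so the parameter-recovery and
cross-check tests share a single computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import enmkit as ek
from enmkit.synth import sample_presences


def sample_background(stack: ek.PredictorStack, n: int, seed: int) -> pd.DataFrame:
    """Uniform background sample over valid cells, env attached."""
    rng = np.random.default_rng(seed)
    ok = np.flatnonzero(stack.valid_mask.ravel())
    pick = rng.choice(ok, size=min(n, ok.size), replace=False)
    rows, cols = np.unravel_index(pick, stack.grid.shape)
    x, y = stack.grid.xy(rows, cols)
    return ek.extract_env(stack, pd.DataFrame({"x": x, "y": y}), drop_invalid=True)


@pytest.fixture(scope="session")
def small_stack() -> ek.PredictorStack:
    """A 60x60 six-layer landscape used by cheap unit tests."""
    grid = ek.GridSpec(60, 60, 1.0)
    return ek.gen_predictor_stack(grid, [
        ek.LayerSpec("bio16", 880.0, 60.0, 5.0),
        ek.LayerSpec("bio15", 65.0, 4.0, 5.0),
        ek.LayerSpec("bio3", 28.0, 3.0, 4.0),
        ek.LayerSpec("bio8", 24.0, 2.0, 4.0),
    ], seed=11)


@pytest.fixture(scope="session")
def recovery_study() -> dict:
    """Full study on a virtual species with one dominant gaussian driver.

    bio16 is the driver (narrow optimum at 876); bio15 carries a weak
    secondary response; four other layers are pure noise. Presences are
    sampled proportional to true suitability (graded occupancy), thinned to
    the environmental grid, and modelled against a 10,000-point background.
    """
    grid = ek.GridSpec(150, 150, 1.0)
    stack = ek.gen_predictor_stack(grid, [
        ek.LayerSpec("bio16", 880.0, 60.0, 6.0),
        ek.LayerSpec("bio15", 65.0, 4.0, 6.0),
        ek.LayerSpec("bio3", 28.0, 3.0, 5.0),
        ek.LayerSpec("bio5", 32.0, 2.0, 5.0),
        ek.LayerSpec("bio8", 24.0, 2.0, 5.0),
        ek.LayerSpec("bio9", 14.0, 3.0, 5.0),
    ], seed=101)
    species = ek.VirtualSpeciesConfig(responses={
        "bio16": ek.Response("gaussian", 876.0, 8.0),
        "bio15": ek.Response("gaussian", 65.8, 4.0),
    })
    true_suit = ek.gen_virtual_species(stack, species)
    occ = ek.thin_by_grid(sample_presences(true_suit, grid, 900, seed=103), grid)
    occ_env = ek.extract_env(stack, occ, drop_invalid=True)
    bg_env = sample_background(stack, 10_000, seed=104)
    cols = ["bio16", "bio15", "bio3", "bio5", "bio8", "bio9"]

    tune = ek.tune_grid(occ_env[cols], bg_env[cols], k_folds=2, seed=105,
                        hinge_knots=10)
    model = tune.model
    importance = ek.variable_importance(model, occ_env[cols], bg_env[cols],
                                        seed=106)
    curve = ek.response_curve(model, "bio16")
    s_occ = model.predict_env(occ_env[cols])
    s_bg = model.predict_env(bg_env[cols])
    mtss = ek.mtss_threshold(s_occ, s_bg)
    suit_map = model.predict(stack.subset(cols))
    scheme = ek.make_scheme(mtss, "a" if 3 * mtss < 1 else "b")
    mx_tiers = ek.classify_tiers(suit_map, scheme, grid=grid)
    rf = ek.balanced_rf_check(occ_env, bg_env, stack.subset(cols),
                              ek.RFProtocolConfig(seed=107), variables=cols)
    concordance = ek.tier_concordance(mx_tiers, rf.tier_map)
    return {
        "grid": grid, "stack": stack, "true_suit": true_suit,
        "true_optimum": 876.0, "driver": "bio16", "cols": cols,
        "occ_env": occ_env, "bg_env": bg_env,
        "tune": tune, "model": model, "importance": importance,
        "curve": curve, "mtss": mtss, "suit_map": suit_map,
        "maxent_tiers": mx_tiers, "rf": rf, "concordance": concordance,
        "scores": (s_occ, s_bg),
    }
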