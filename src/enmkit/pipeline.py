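"""End-to-end orchestration: simulate -> occurrences -> screen -> tune ->
project -> evaluate -> tiers -> rfcheck -> novelty.

A run is driven by one nested config dict (see :func:`default_config`,
loadable from YAML) and one global seed. Per-stage seeds are derived by
stable hashing of the stage name against the global seed, so toggling a
stage never changes another stage's randomness. Every produced file is
recorded in a manifest (path, sha256, stage, timing) written as
``manifest.json``; re-running with an unchanged config and intact outputs
is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, EnmkitError
from .evaluation import crossvalidate, mtss_threshold
from .grid import GridSpec
from .novelty import ReferenceEnvelope, envelope_shift, mess_map
from .occurrences import sample_occurrences, segmentation_metrics, thin_by_grid
from .raster import extract_env
from .raster_io import write_points, write_raster, write_stack
from .rfcheck import RFProtocolConfig, balanced_rf_check, tier_concordance
from .selection import initial_contributions, select_variables
from .synth import (ClassifierSpec, LayerSpec, Response, VirtualSpeciesConfig,
                    gen_classifier_output, gen_future_stack, gen_predictor_stack,
                    gen_virtual_species)
from .tiering import classify_tiers, make_scheme, tier_areas
from .tuning import DEFAULT_RM_VALUES, tune_grid
from .features import FC_SETS

__all__ = ["default_config", "load_config", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "occurrences", "screen", "tune", "project", "evaluate",
          "tiers", "rfcheck", "novelty")

_DEPS = {
    "simulate": (),
    "occurrences": ("simulate",),
    "screen": ("occurrences",),
    "tune": ("screen",),
    "project": ("tune",),
    "evaluate": ("tune",),
    "tiers": ("project", "evaluate"),
    "rfcheck": ("screen",),
    "novelty": ("occurrences",),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def default_config(seed: int = 0) -> dict:
    """A complete synthetic demo configuration (sizes chosen for desk runs)."""
    return {
        "seed": seed,
        "grid": {"nrows": 100, "ncols": 100, "cell_size": 1.0},
        "layers": [
            {"name": "bio16", "mean": 880.0, "sd": 60.0, "smoothness": 6.0},
            {"name": "bio15", "mean": 65.0, "sd": 4.0, "smoothness": 6.0},
            {"name": "bio3", "mean": 28.0, "sd": 3.0, "smoothness": 5.0},
            {"name": "bio5", "mean": 32.0, "sd": 2.0, "smoothness": 5.0},
            {"name": "bio8", "mean": 24.0, "sd": 2.0, "smoothness": 5.0},
            {"name": "bio9", "mean": 14.0, "sd": 3.0, "smoothness": 5.0},
        ],
        "correlation": None,
        "species": {
            "responses": {
                "bio16": {"shape": "gaussian", "optimum": 876.0, "breadth": 8.0},
                "bio15": {"shape": "gaussian", "optimum": 65.8, "breadth": 4.0},
            },
            "combination": "product",
        },
        "classifier": {"fine_factor": 2, "target_precision": 0.972,
                       "target_recall": 0.935, "prevalence": 0.10},
        "future_shifts": {"bio16": [80.0, 1.1], "bio15": [3.0, 1.0],
                          "bio8": [3.0, 1.0]},
        "occurrences": {"n_sample": 1000, "n_background": 2000},
        "screen": {"r_threshold": 0.8, "vif_threshold": 10.0,
                   "n_reps": 5, "train_fraction": 0.75},
        "tune": {"rm_values": list(DEFAULT_RM_VALUES), "fc_sets": list(FC_SETS),
                 "k_folds": 4, "hinge_knots": 10},
        "evaluate": {"k_folds": 4},
        "rf": {"n_iterations": 10, "ntree": 70, "mtry": 1, "nodesize": 1},
        "novelty": {"variables": None},  # default: all screened bioclim layers
        "stages": list(STAGES),
        "format": "ascii",
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    base = default_config(cfg.get("seed", 0))
    base.update(cfg)
    return base


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.artifacts: list[dict] = []
        self.stage_status: dict[str, str] = {}
        self.timings: dict[str, float] = {}
        # in-memory products
        self.stack = self.future = self.true_suit = None
        self.predicted = self.truth = None
        self.occ = self.occ_env = self.bg_env = None
        self.retained: list[str] | None = None
        self.tune_result = None
        self.suit_map = self.future_map = None
        self.eval_report = None

    def add(self, stage: str, name: str, path: Path) -> None:
        self.artifacts.append({"stage": stage, "name": name,
                               "path": str(path.relative_to(self.outdir)),
                               "sha256": _sha256(path)})

    def seed(self, stage: str) -> int:
        return stage_seed(self.config["seed"], stage)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    A stage failure is recorded, its dependents are skipped, and the
    manifest's ``failed`` flag is set; completed artifacts remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = _config_hash(config)
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and not old.get("failed"):
            if all((outdir / a["path"]).exists()
                   and _sha256(outdir / a["path"]) == a["sha256"]
                   for a in old["artifacts"]):
                return old  # idempotent re-run

    run = _Run(config, outdir)
    enabled = [s for s in STAGES if s in config.get("stages", STAGES)]
    handlers = {
        "simulate": _stage_simulate, "occurrences": _stage_occurrences,
        "screen": _stage_screen, "tune": _stage_tune, "project": _stage_project,
        "evaluate": _stage_evaluate, "tiers": _stage_tiers,
        "rfcheck": _stage_rfcheck, "novelty": _stage_novelty,
    }
    failed = False
    for stage in enabled:
        deps = _DEPS[stage]
        if any(run.stage_status.get(d) in ("failed", "skipped")
               for d in deps if d in enabled):
            run.stage_status[stage] = "skipped"
            continue
        t0 = time.perf_counter()
        try:
            handlers[stage](run)
            run.stage_status[stage] = "ok"
        except EnmkitError as exc:
            run.stage_status[stage] = "failed"
            run.timings[stage] = time.perf_counter() - t0
            run.artifacts.append({"stage": stage, "name": "failure",
                                  "path": "", "error": str(exc)})
            failed = True
            continue
        run.timings[stage] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "seed": config["seed"],
        "config_hash": chash,
        "config": config,
        "stages": run.stage_status,
        "timings_s": {k: round(v, 3) for k, v in run.timings.items()},
        "artifacts": [a for a in run.artifacts if a.get("path")],
        "failures": [a for a in run.artifacts if not a.get("path")],
        "failed": failed,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _grid(config: dict) -> GridSpec:
    g = config["grid"]
    return GridSpec(nrows=g["nrows"], ncols=g["ncols"], cell_size=g["cell_size"],
                    origin_x=g.get("origin_x", 0.0), origin_y=g.get("origin_y", 0.0))


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    grid = _grid(cfg)
    specs = [LayerSpec(**d) for d in cfg["layers"]]
    corr = np.asarray(cfg["correlation"]) if cfg.get("correlation") is not None else None
    run.stack = gen_predictor_stack(grid, specs, correlation=corr,
                                    seed=run.seed("simulate"))
    responses = {k: Response(**v) for k, v in cfg["species"]["responses"].items()}
    vs = VirtualSpeciesConfig(responses=responses,
                              combination=cfg["species"].get("combination", "product"))
    run.true_suit = gen_virtual_species(run.stack, vs)
    cspec = ClassifierSpec(seed=run.seed("simulate") + 1, **cfg["classifier"])
    run.predicted, run.truth = gen_classifier_output(run.true_suit, grid, cspec)
    run.future = gen_future_stack(
        run.stack, {k: tuple(v) for k, v in cfg["future_shifts"].items()},
        seed=run.seed("simulate") + 2)

    fmt = cfg.get("format", "ascii")
    ext = ".asc" if fmt == "ascii" else ".tif"
    for p in write_stack(run.stack, run.outdir / "stack", fmt=fmt):
        run.add("simulate", f"stack/{p.name}", p)
    for p in write_stack(run.future, run.outdir / "future_stack", fmt=fmt):
        run.add("simulate", f"future_stack/{p.name}", p)
    p = run.outdir / f"true_suitability{ext}"
    write_raster(p, grid, run.true_suit)
    run.add("simulate", "true_suitability", p)
    p = run.outdir / f"classification{ext}"
    write_raster(p, run.predicted.grid, run.predicted.labels.astype(float))
    run.add("simulate", "classification", p)


def _stage_occurrences(run: _Run) -> None:
    cfg = run.config
    seg = segmentation_metrics(run.predicted, run.truth)
    seg_df = pd.DataFrame([{
        "tp": seg.tp, "tn": seg.tn, "fp": seg.fp, "fn": seg.fn,
        "accuracy": seg.accuracy, "precision": seg.precision,
        "recall": seg.recall, "f1": seg.f1,
    }])
    p = run.outdir / "segmentation_metrics.csv"
    seg_df.to_csv(p, index=False)
    run.add("occurrences", "segmentation_metrics", p)

    n = min(cfg["occurrences"]["n_sample"], run.predicted.positive_count)
    raw = sample_occurrences(run.predicted, n, seed=run.seed("occurrences"))
    thin = thin_by_grid(raw, run.stack.grid)
    run.occ_env = extract_env(run.stack, thin, drop_invalid=True)
    run.occ = run.occ_env[["x", "y"]]

    rng = np.random.default_rng(run.seed("occurrences") + 1)
    ok = np.flatnonzero(run.stack.valid_mask.ravel())
    n_bg = min(cfg["occurrences"]["n_background"], ok.size)
    pick = rng.choice(ok, size=n_bg, replace=False)
    rows, cols = np.unravel_index(pick, run.stack.grid.shape)
    bx, by = run.stack.grid.xy(rows, cols)
    run.bg_env = extract_env(run.stack, pd.DataFrame({"x": bx, "y": by}),
                             drop_invalid=True)

    for name, frame in (("occurrences", run.occ_env), ("background", run.bg_env)):
        p = run.outdir / f"{name}.csv"
        write_points(frame, p)
        run.add("occurrences", name, p)


def _env_cols(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c not in ("x", "y", "valid")]


def _stage_screen(run: _Run) -> None:
    cfg = run.config["screen"]
    cols = _env_cols(run.occ_env)
    occ = run.occ_env[cols]
    bg = run.bg_env[cols]
    contrib = initial_contributions(occ, bg, n_reps=cfg["n_reps"],
                                    train_fraction=cfg["train_fraction"],
                                    seed=run.seed("screen"))
    report = select_variables(pd.concat([occ, bg], ignore_index=True), contrib,
                              r_threshold=cfg["r_threshold"],
                              vif_threshold=cfg["vif_threshold"])
    run.retained = report.retained
    p = run.outdir / "screening_report.csv"
    pd.DataFrame({
        "variable": report.contributions.index,
        "contribution": report.contributions.to_numpy(),
        "vif": report.vif.reindex(report.contributions.index).to_numpy(),
    }).to_csv(p, index=False)
    run.add("screen", "screening_report", p)
    p = run.outdir / "screening_log.json"
    p.write_text(json.dumps({"retained": report.retained, "log": report.log},
                            indent=2))
    run.add("screen", "screening_log", p)


def _stage_tune(run: _Run) -> None:
    cfg = run.config["tune"]
    cols = run.retained
    run.tune_result = tune_grid(
        run.occ_env[cols], run.bg_env[cols],
        rm_values=tuple(cfg["rm_values"]), fc_sets=tuple(cfg["fc_sets"]),
        k_folds=cfg["k_folds"], seed=run.seed("tune"),
        hinge_knots=cfg["hinge_knots"])
    p = run.outdir / "tuning_table.csv"
    run.tune_result.table.to_csv(p, index=False)
    run.add("tune", "tuning_table", p)
    p = run.outdir / "tuning_selection.json"
    sel = run.tune_result.selected
    p.write_text(json.dumps({"fc": sel["fc"], "rm": sel["rm"],
                             "rationale": run.tune_result.rationale}, default=str))
    run.add("tune", "tuning_selection", p)


def _stage_project(run: _Run) -> None:
    model = run.tune_result.model
    ext = ".asc" if run.config.get("format", "ascii") == "ascii" else ".tif"
    run.suit_map = model.predict(run.stack.subset(run.retained))
    run.future_map = model.predict(run.future.subset(run.retained))
    for name, arr in (("suitability_current", run.suit_map),
                      ("suitability_future", run.future_map)):
        p = run.outdir / f"{name}{ext}"
        write_raster(p, run.stack.grid, arr)
        run.add("project", name, p)


def _stage_evaluate(run: _Run) -> None:
    cfg = run.config
    sel = run.tune_result.selected
    cols = run.retained
    run.eval_report = crossvalidate(
        run.occ_env[cols], run.bg_env[cols],
        model_config={"fc": sel["fc"], "rm": float(sel["rm"]),
                      "hinge_knots": cfg["tune"]["hinge_knots"]},
        k=cfg["evaluate"]["k_folds"], seed=run.seed("evaluate"))
    p = run.outdir / "evaluation.csv"
    run.eval_report.folds.to_csv(p, index=False)
    run.add("evaluate", "evaluation", p)


def _stage_tiers(run: _Run) -> None:
    t = run.eval_report.mtss
    scheme_name = "threshold-multiples" if 3 * t < 1 else "equal-above-threshold"
    scheme = make_scheme(t, scheme_name)
    tiers = classify_tiers(run.suit_map, scheme, grid=run.stack.grid)
    run.tier_map = tiers
    ext = ".asc" if run.config.get("format", "ascii") == "ascii" else ".tif"
    p = run.outdir / f"tiers_current{ext}"
    write_raster(p, run.stack.grid, tiers.tiers.astype(float))
    run.add("tiers", "tiers_current", p)
    p = run.outdir / "tier_areas.csv"
    tier_areas(tiers).to_csv(p, index=False)
    run.add("tiers", "tier_areas", p)


def _stage_rfcheck(run: _Run) -> None:
    cfg = run.config["rf"]
    rf_cfg = RFProtocolConfig(n_iterations=cfg["n_iterations"], ntree=cfg["ntree"],
                              mtry=cfg["mtry"], nodesize=cfg["nodesize"],
                              seed=run.seed("rfcheck"))
    result = balanced_rf_check(run.occ_env, run.bg_env,
                               run.stack.subset(run.retained), rf_cfg,
                               variables=run.retained)
    run.rf_result = result
    p = run.outdir / "rf_metrics.csv"
    result.metrics.to_csv(p, index=False)
    run.add("rfcheck", "rf_metrics", p)
    ext = ".asc" if run.config.get("format", "ascii") == "ascii" else ".tif"
    p = run.outdir / f"rf_mean_suitability{ext}"
    write_raster(p, run.stack.grid, result.mean_map)
    run.add("rfcheck", "rf_mean_suitability", p)
    if getattr(run, "tier_map", None) is not None:
        conc = tier_concordance(run.tier_map, result.tier_map)
        p = run.outdir / "rf_concordance.csv"
        conc["confusion"].assign(
            jaccard=[conc["jaccard"][t] for t in range(4)]).to_csv(p)
        run.add("rfcheck", "rf_concordance", p)


def _stage_novelty(run: _Run) -> None:
    cfg = run.config["novelty"]
    variables = cfg.get("variables") or [
        v for v in _env_cols(run.occ_env) if v.startswith("bio")]
    envelope = ReferenceEnvelope.from_table(run.occ_env, variables)
    nov = mess_map(envelope, run.future)
    ext = ".asc" if run.config.get("format", "ascii") == "ascii" else ".tif"
    for name, arr in (("mess", nov.mess), ("mod", nov.mod.astype(float)),
                      ("risk", nov.risk.astype(float))):
        p = run.outdir / f"novelty_{name}{ext}"
        write_raster(p, run.stack.grid, arr)
        run.add("novelty", f"novelty_{name}", p)
    shift = envelope_shift(run.stack, run.future, variables)
    p = run.outdir / "envelope_shift.csv"
    shift.to_csv(p, index=False)
    run.add("novelty", "envelope_shift", p)
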