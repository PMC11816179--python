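"""Configuration-driven end-to-end planning runs and model comparison.

The workflow is: (A) per-scenario dose-influence matrices on the phantom,
(B) interval dose model (center + SVD-compressed radius), (C) fluence
optimization for the selected plan model, (D) robustness evaluation on
the 5x5x5 scenario grid.  ``run_plan`` executes A-D for one model;
``compare_models`` reuses the expensive A/B stages across models and
produces the machine-readable robustness-vs-price table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_engine import BeamSetup, compute_dij, make_bixel_layout
from .evaluation import (
    RobustnessParams, cdvh, default_dose_bins, delta_map, price_of_robustness,
    robustness_index, scenario_dose_stats,
)
from .interval_model import build_interval_model
from .objectives import (
    ObjectiveSpec, PlanObjective, Prescription, default_objective_table,
)
from .optimizer import OptimizerConfig, initial_fluence, optimize_fluence
from .phantom import (
    MarginSpec, ProstatePhantomConfig, add_derived_structures, make_prostate_phantom,
)
from .scenarios import SetupErrorModel, make_eval_grid, make_opt_scenarios

log = logging.getLogger("intervalrt")

PLAN_MODELS = ("nominal", "ptv", "minimax", "interval")

# Published configuration schema: key -> (type, validator, description).
CONFIG_SCHEMA = {
    "model": (str, lambda v: v in PLAN_MODELS, "plan model id"),
    "theta": ((int, float), lambda v: v >= 0, "Bertoluzza spread weight, >= 0"),
    "omega_ctv": ((int, float), lambda v: v >= 0, "weight of the CTV interval term"),
    "prescription_gy": ((int, float), lambda v: v > 0, "prescribed dose, Gy"),
    "sigma_mm": (list, lambda v: len(v) == 3 and all(s > 0 for s in v),
                 "setup-error sigma (LR, AP, IS), mm"),
    "c1": ((int, float), lambda v: v > 0, "Delta-score expectation tolerance"),
    "c2": ((int, float), lambda v: v > 0, "Delta-score spread tolerance"),
    "svd_threshold": ((int, float), lambda v: 0 < v <= 1, "variance-explained cutoff"),
    "seed": (int, lambda v: v >= 0, "phantom generation seed"),
    "max_iter": (int, lambda v: v >= 1, "optimizer iteration cap"),
    "beta": ((int, float), lambda v: v > 0, "minimax smoothing inverse temperature"),
    "margins_mm": (list, lambda v: len(v) == 4 and all(m >= 0 for m in v),
                   "PTV margins (LR, anterior, posterior, IS), mm"),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    model: str = "interval"
    theta: float = 10.0
    omega_ctv: float = 0.01
    prescription_gy: float = 78.0
    sigma_mm: tuple[float, float, float] = (5.0, 10.0, 5.0)
    margins_mm: tuple[float, float, float, float] = (7.0, 7.0, 4.0, 7.0)
    c1: float = 0.05
    c2: float = 0.05
    svd_threshold: float = 0.99
    seed: int = 0
    max_iter: int = 300
    beta: float = 1e3
    phantom: ProstatePhantomConfig = field(default_factory=ProstatePhantomConfig)
    beams: BeamSetup = field(default_factory=BeamSetup)

    def validate(self):
        d = self.to_dict()
        for key, (typ, check, desc) in CONFIG_SCHEMA.items():
            val = d[key]
            if not isinstance(val, typ):
                raise ValueError(f"config field '{key}' ({desc}): wrong type")
            if not check(val):
                raise ValueError(f"config field '{key}' ({desc}): invalid value {val!r}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigma_mm"] = list(self.sigma_mm)
        d["margins_mm"] = list(self.margins_mm)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @property
    def margin_spec(self) -> MarginSpec:
        lr, ant, post, is_ = self.margins_mm
        return MarginSpec(lr_mm=lr, ant_mm=ant, post_mm=post, is_mm=is_)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom = ProstatePhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("phantom", {}).items()
        })
        beams = BeamSetup(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("beams", {}).items()
        })
        for key in ("sigma_mm", "margins_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(phantom=phantom, beams=beams, **raw)
        return cfg.validate()

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class PlanWorkspace:
    """Shared expensive state (stages A and B) for one configuration.

    Holds the phantom with derived structures, the fixed bixel layout
    (covering the PTV so every plan model can shape dose to the largest
    target), the 13-scenario optimization matrices, the 5x5x5 evaluation
    matrices, the interval dose model, and the dose-pulling DVH fractions
    obtained from a preliminary nominal CTV-only plan.
    """

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        t0 = time.perf_counter()
        base = make_prostate_phantom(config.phantom, seed=config.seed)
        self.phantom = add_derived_structures(base, config.margin_spec, ring_anchor="CTV")
        # the margin-based model grows its rings from the PTV instead
        self.phantom_ptv_rings = add_derived_structures(
            base, config.margin_spec, ring_anchor="PTV"
        )
        log.info("stage A: phantom built (%.2fs)", time.perf_counter() - t0)

        model = SetupErrorModel(sigma_mm=tuple(config.sigma_mm))
        self.opt_set = make_opt_scenarios(model)
        self.eval_set = make_eval_grid(model)

        t0 = time.perf_counter()
        layout = make_bixel_layout(self.phantom, config.beams, target_name="PTV")
        self.layout = layout
        self.Dks_opt = [
            compute_dij(self.phantom, config.beams, s, target_name="PTV", layout=layout)
            for s in self.opt_set.shifts_mm
        ]
        self.Dks_eval = [
            compute_dij(self.phantom, config.beams, s, target_name="PTV", layout=layout)
            for s in self.eval_set.shifts_mm
        ]
        self.D_nominal = self.Dks_opt[self.opt_set.nominal_index]
        log.info(
            "stage A: %d+%d dose-influence matrices, m=%d bixels (%.2fs)",
            len(self.Dks_opt), len(self.Dks_eval), self.D_nominal.n_bixels,
            time.perf_counter() - t0,
        )

        t0 = time.perf_counter()
        self.interval = build_interval_model(
            self.Dks_opt, self.opt_set, variance_threshold=config.svd_threshold
        )
        log.info(
            "stage B: interval model rank %d / %d scenarios, variance explained %.4f (%.2fs)",
            self.interval.comp.rank, len(self.opt_set),
            self.interval.comp.variance_explained, time.perf_counter() - t0,
        )

        self.prescription = Prescription(config.prescription_gy)
        self._pull = self._dose_pulling_fractions()
        self.specs = default_objective_table(
            bladder_v60_fraction=self._pull["bladder_v60"],
            rectum_v40_fraction=self._pull["rectum_v40"],
        )

    # -- helpers -------------------------------------------------------

    def masks(self, plan_model: str) -> dict[str, np.ndarray]:
        ph = self.phantom_ptv_rings if plan_model == "ptv" else self.phantom
        return {name: ph.flat_mask(name) for name in ph.structures}

    def _dose_pulling_fractions(self) -> dict[str, float]:
        """VxGy fractions achieved by a preliminary nominal CTV-only plan.

        These become the bladder/rectum MaxDVH volume fractions, pulling
        each robust plan's OAR DVH toward what an unconstrained CTV plan
        already achieves.
        """
        ctv_specs = [
            ObjectiveSpec("CTV", "DoseMin", self.prescription.dose_gy, 30.0),
            ObjectiveSpec("CTV", "SqDev", self.prescription.dose_gy, 1.0),
        ]
        masks = self.masks("nominal")
        obj = PlanObjective("nominal", ctv_specs, masks, nominal=self.D_nominal)
        x0 = initial_fluence(
            self.D_nominal.matrix, masks["CTV"], self.prescription.dose_gy
        )
        res = optimize_fluence(obj, x0, OptimizerConfig(max_iter=min(self.config.max_iter, 200)))
        d = self.D_nominal.dose(res.x)
        from .evaluation import vx
        pull = {
            "bladder_v60": vx(d, masks["bladder"], 60.0) / 100.0,
            "rectum_v40": vx(d, masks["rectum"], 40.0) / 100.0,
        }
        log.info("dose-pulling fractions: %s", pull)
        return pull

    def objective(self, plan_model: str, theta: float | None = None) -> PlanObjective:
        cfg = self.config
        return PlanObjective(
            plan_model,
            self.specs,
            self.masks(plan_model),
            nominal=self.D_nominal,
            scenario_matrices=self.Dks_opt,
            interval=self.interval,
            prescription=self.prescription,
            theta=cfg.theta if theta is None else theta,
            omega_ctv=cfg.omega_ctv,
            beta=cfg.beta,
        )


@dataclass
class PlanBundle:
    """Everything `run_plan` produces for one optimized plan."""

    model: str
    theta: float
    fluence: np.ndarray
    objective_value: float
    trace: pd.DataFrame
    delta: np.ndarray
    ri: float
    price: dict[str, float]
    cdvh: object
    metrics: dict


def evaluate_plan(x, workspace: PlanWorkspace, plan_model: str) -> dict:
    """Stage D: robustness evaluation on the tagged evaluation grid."""
    ev = workspace.eval_set
    if ev.tag != "evaluation":
        raise ValueError("plan evaluation requires the evaluation scenario set")
    cfg = workspace.config
    stats = scenario_dose_stats(x, workspace.Dks_eval, ev.weights)
    params = RobustnessParams(c1=cfg.c1, c2=cfg.c2, prescription_gy=cfg.prescription_gy)
    masks = workspace.masks(plan_model)
    delta = delta_map(stats, params, masks["CTV"])
    ri = robustness_index(delta)
    D_nom_eval = workspace.Dks_eval[ev.nominal_index]
    price = price_of_robustness(x, D_nom_eval, masks)
    bins = default_dose_bins(cfg.prescription_gy)
    curves = cdvh(
        x, workspace.Dks_eval, ev.weights,
        {k: masks[k] for k in ("CTV", "bladder", "rectum")},
        bins, nominal_index=ev.nominal_index,
    )
    return {"stats": stats, "delta": delta, "ri": ri, "price": price, "cdvh": curves}


def run_plan(
    config: RunConfig,
    workspace: PlanWorkspace | None = None,
    out_dir=None,
    theta: float | None = None,
) -> PlanBundle:
    """Execute stages A-D for the configured plan model; optionally write outputs."""
    config.validate()
    ws = workspace or PlanWorkspace(config)
    plan_model = config.model
    theta = config.theta if theta is None else theta

    t0 = time.perf_counter()
    obj = ws.objective(plan_model, theta=theta)
    masks = ws.masks(plan_model)
    x0 = initial_fluence(ws.D_nominal.matrix, masks["CTV"], config.prescription_gy)
    res = optimize_fluence(obj, x0, OptimizerConfig(max_iter=config.max_iter))
    log.info(
        "stage C: %s plan optimized, objective %.4g, %d evaluations (%.2fs)",
        plan_model, res.objective, res.n_evaluations, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    ev = evaluate_plan(res.x, ws, plan_model)
    log.info("stage D: RI=%.3f price=%s (%.2fs)", ev["ri"], ev["price"],
             time.perf_counter() - t0)

    metrics = {
        "model": plan_model,
        "theta": float(theta),
        "ri": ev["ri"],
        "v60_bladder_pct": ev["price"]["v60_bladder_pct"],
        "v40_rectum_pct": ev["price"]["v40_rectum_pct"],
        "objective": res.objective,
        "converged": res.converged,
        "c1": config.c1,
        "c2": config.c2,
        "svd_rank": ws.interval.comp.rank,
        "svd_variance_explained": ws.interval.comp.variance_explained,
        "n_bixels": int(ws.D_nominal.n_bixels),
        "n_voxels": int(ws.D_nominal.n_voxels),
        "provenance": {
            "config_hash": config.config_hash(),
            "intervalrt_version": __version__,
            "numpy_version": np.__version__,
        },
    }
    bundle = PlanBundle(
        model=plan_model, theta=float(theta), fluence=res.x,
        objective_value=res.objective, trace=res.trace, delta=ev["delta"],
        ri=ev["ri"], price=ev["price"], cdvh=ev["cdvh"], metrics=metrics,
    )
    if out_dir is not None:
        _write_bundle(bundle, ws, Path(out_dir))
    return bundle


def _write_bundle(bundle: PlanBundle, ws: PlanWorkspace, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(_jsonable(bundle.metrics), fh, indent=2, sort_keys=True)
    bundle.cdvh.to_dataframe().to_csv(out_dir / "dvh.csv", index=False)
    bundle.trace.to_csv(out_dir / "trace.csv", index=False)
    np.savetxt(out_dir / "fluence.csv", bundle.fluence, delimiter=",")
    from .io import save_phantom
    save_phantom(out_dir / "bundle.h5", ws.phantom)
    ws.config.to_yaml(out_dir / "config.yaml")


def compare_models(
    config: RunConfig,
    models=("nominal", "ptv", "minimax", "interval"),
    theta_sweep=(10.0,),
    workspace: PlanWorkspace | None = None,
    out_path=None,
) -> pd.DataFrame:
    """Robustness-vs-price table: one row per (model, theta).

    theta applies to the interval model only; other models get one row
    each with theta recorded as NaN.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("compare_models needs at least 2 models")
    for m in models:
        if m not in PLAN_MODELS:
            raise ValueError(f"unknown plan model '{m}'")
    ws = workspace or PlanWorkspace(config)
    rows = []
    for m in models:
        thetas = list(theta_sweep) if m == "interval" else [None]
        for th in thetas:
            cfg_m = replace(config, model=m)
            bundle = run_plan(cfg_m, workspace=ws, theta=th)
            rows.append({
                "model": m,
                "theta": np.nan if th is None else float(th),
                "ri": bundle.ri,
                "v40_rectum_pct": bundle.price["v40_rectum_pct"],
                "v60_bladder_pct": bundle.price["v60_bladder_pct"],
                "objective": bundle.objective_value,
            })
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table
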