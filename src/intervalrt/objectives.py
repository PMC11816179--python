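"""Plan objective functions: Bertoluzza CTV term, penalty table, composites.

Four plan models share one penalty table (the clinical objective list):

* ``nominal``  — all terms evaluated on the nominal-scenario dose.
* ``ptv``      — as nominal, additionally activating the PTV-only rows of
  the table (the margin-based approach).
* ``minimax``  — a smoothed (log-sum-exp) maximum over the per-scenario
  nominal composites; the hard maximum is available for evaluation.
* ``interval`` — the CTV is scored by the Bertoluzza distance between the
  per-voxel dose interval [center, radius] and the degenerate
  prescription interval [p, 0], summed over CTV voxels:

      F_CTV = sum_i (center_i - p)^2 + theta * radius_i^2 ,

  with theta >= 0 trading nominal accuracy (theta small) against
  robustness (theta large).  Organ-at-risk penalties are evaluated on the
  conservative upper bound dbar = center + radius; CTV minimum-dose terms
  on the lower bound, CTV maximum-dose terms on dbar.

All composites expose analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .interval_model import IntervalDoseModel

PENALTY_KINDS = ("DoseMin", "DoseMax", "SqDev", "SqOver", "MaxDVH")


@dataclass(frozen=True)
class Interval:
    """Interval in center/radius form."""

    center: float
    radius: float

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("interval radius must be >= 0")


@dataclass(frozen=True)
class Prescription:
    """Prescribed dose p (Gy); as an interval it is the degenerate [p, 0]."""

    dose_gy: float = 78.0

    def __post_init__(self):
        if self.dose_gy <= 0:
            raise ValueError("prescription must be > 0")

    @property
    def interval(self) -> Interval:
        return Interval(self.dose_gy, 0.0)


def bertoluzza_distance(X: Interval, Y: Interval, theta: float) -> float:
    """Bertoluzza distance sqrt((xc-yc)^2 + theta (xr-yr)^2), theta >= 0."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return float(np.hypot(X.center - Y.center, np.sqrt(theta) * abs(X.radius - Y.radius)))


@dataclass(frozen=True)
class ObjectiveSpec:
    """One row of the penalty table.

    ``volume_fraction`` applies to MaxDVH only (fraction in [0, 1]; 0 makes
    the term a plain squared-overdose penalty).  ``ptv_only`` marks rows
    used exclusively by the margin-based model.
    """

    structure: str
    kind: str
    dose_gy: float
    weight: float
    volume_fraction: float | None = None
    ptv_only: bool = False

    def __post_init__(self):
        if self.kind not in PENALTY_KINDS:
            raise ValueError(f"unknown penalty type '{self.kind}'")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.kind == "MaxDVH":
            v = self.volume_fraction
            if v is None or not (0.0 <= v <= 1.0):
                raise ValueError("MaxDVH needs a volume fraction in [0, 1]")


def default_objective_table(
    bladder_v60_fraction: float = 0.05, rectum_v40_fraction: float = 0.30
) -> list[ObjectiveSpec]:
    """The prostate objective table used throughout the package.

    The bladder/rectum MaxDVH volume fractions are plan-pulling targets;
    the workbench replaces the defaults with the fractions achieved by a
    preliminary nominal CTV-only plan.
    """
    return [
        ObjectiveSpec("CTV", "DoseMin", 78.0, 30.0),
        ObjectiveSpec("CTV", "SqDev", 78.0, 0.01),
        ObjectiveSpec("CTV", "MaxDVH", 81.0, 10.0, volume_fraction=0.05),
        ObjectiveSpec("CTV", "DoseMax", 83.5, 100.0),
        ObjectiveSpec("PTV", "DoseMin", 78.0, 30.0, ptv_only=True),
        ObjectiveSpec("PTV", "MaxDVH", 81.0, 10.0, volume_fraction=0.05, ptv_only=True),
        ObjectiveSpec("PTV", "DoseMax", 83.5, 100.0, ptv_only=True),
        ObjectiveSpec("body", "SqOver", 39.0, 10.0),
        ObjectiveSpec("ring_0_20", "MaxDVH", 83.5, 100.0, volume_fraction=0.0),
        ObjectiveSpec("ring_20_50", "MaxDVH", 78.0, 100.0, volume_fraction=0.0),
        ObjectiveSpec("bladder", "MaxDVH", 60.0, 2.0, volume_fraction=bladder_v60_fraction),
        ObjectiveSpec("rectum", "MaxDVH", 40.0, 2.0, volume_fraction=rectum_v40_fraction),
    ]


def penalty(d: np.ndarray, spec: ObjectiveSpec, mask: np.ndarray):
    """Penalty value and gradient (w.r.t. the full dose vector).

    The value is the mean squared violation over the structure's voxels
    (grid-resolution independent); the spec weight is *not* applied here.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError(f"empty mask for structure '{spec.structure}'")
    d = np.asarray(d, float)
    ds = d[mask]
    N = ds.size
    dref = spec.dose_gy
    grad_s = np.zeros(N)

    if spec.kind == "DoseMin":
        dev = np.minimum(ds - dref, 0.0)
        val = np.sum(dev**2) / N
        grad_s = 2.0 * dev / N
    elif spec.kind in ("DoseMax", "SqOver"):
        dev = np.maximum(ds - dref, 0.0)
        val = np.sum(dev**2) / N
        grad_s = 2.0 * dev / N
    elif spec.kind == "SqDev":
        dev = ds - dref
        val = np.sum(dev**2) / N
        grad_s = 2.0 * dev / N
    elif spec.kind == "MaxDVH":
        v = spec.volume_fraction
        # dose currently received by the hottest fraction v of the structure;
        # only voxels between dref and that level are pushed down
        dQ = np.inf if v <= 0 else float(np.quantile(ds, 1.0 - v))
        active = (ds >= dref) & (ds <= dQ)
        dev = np.where(active, ds - dref, 0.0)
        val = np.sum(dev**2) / N
        grad_s = 2.0 * dev / N
    else:  # pragma: no cover - guarded by ObjectiveSpec
        raise ValueError(f"unknown penalty type '{spec.kind}'")

    grad = np.zeros_like(d)
    grad[mask] = grad_s
    return float(val), grad


def f_ctv_interval(
    x: np.ndarray,
    model: IntervalDoseModel,
    ctv_mask: np.ndarray,
    prescription: Prescription,
    theta: float,
):
    """Bertoluzza CTV objective over the dose interval, with gradient."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    ctv = np.asarray(ctv_mask, bool)
    if not ctv.any():
        raise ValueError("empty CTV")
    x = np.asarray(x, float)
    p = prescription.dose_gy
    dc = model.center_dose(x)
    resid = np.where(ctv, dc - p, 0.0)
    rsq = model.comp.radius_sq(x)
    val = float(np.sum(resid[ctv] ** 2) + theta * np.sum(rsq[ctv]))
    grad = 2.0 * (model.center.T @ resid)
    if theta > 0:
        grad = grad + theta * model.grad_radius_sq_masked(x, ctv)
    return val, grad


class PlanObjective:
    """Composite objective (value + analytic gradient) for one plan model.

    Parameters
    ----------
    mode : {"nominal", "ptv", "minimax", "interval"}
    specs : penalty table (list of ObjectiveSpec)
    masks : dict of flat boolean masks by structure name
    nominal : nominal-scenario dose-influence matrix (nominal/ptv modes)
    scenario_matrices : per-scenario matrices (minimax mode)
    interval : IntervalDoseModel (interval mode)
    theta : spread-weight of the Bertoluzza CTV term
    omega_ctv : weight of the Bertoluzza CTV term (plays the role of the
        CTV SqDev row, which is skipped in interval mode)
    beta : inverse temperature of the smoothed maximum (minimax mode);
        the smoothed value lies within log(K)/beta above the hard max
    """

    MODES = ("nominal", "ptv", "minimax", "interval")

    def __init__(
        self,
        mode: str,
        specs,
        masks,
        *,
        nominal=None,
        scenario_matrices=None,
        interval: IntervalDoseModel | None = None,
        prescription: Prescription | None = None,
        theta: float = 10.0,
        omega_ctv: float = 0.01,
        beta: float = 1e3,
        smooth_max: bool = True,
        ctv_name: str = "CTV",
    ):
        if mode not in self.MODES:
            raise ValueError(f"unknown plan model '{mode}'")
        self.mode = mode
        self.specs = list(specs)
        self.masks = {k: np.asarray(v, bool).ravel() for k, v in masks.items()}
        self.prescription = prescription or Prescription()
        self.theta = float(theta)
        self.omega_ctv = float(omega_ctv)
        self.beta = float(beta)
        self.smooth_max = smooth_max
        self.ctv_name = ctv_name
        self._nominal = getattr(nominal, "matrix", nominal)
        self._scen = (
            [getattr(M, "matrix", M) for M in scenario_matrices]
            if scenario_matrices is not None
            else None
        )
        self.interval = interval

        if mode in ("nominal", "ptv") and self._nominal is None:
            raise ValueError(f"{mode} mode needs the nominal dose-influence matrix")
        if mode == "minimax" and not self._scen:
            raise ValueError("minimax mode needs per-scenario matrices")
        if mode == "interval" and interval is None:
            raise ValueError("interval mode needs an IntervalDoseModel")
        if mode == "ptv" and "PTV" not in self.masks:
            raise ValueError("ptv mode needs a PTV mask")

    # -- shared pieces -------------------------------------------------

    def _active_specs(self):
        include_ptv = self.mode == "ptv"
        for spec in self.specs:
            if spec.ptv_only and not include_ptv:
                continue
            yield spec

    def _composite_on_dose(self, d):
        """Nominal-form composite on a dose vector: value + d-gradient."""
        val = 0.0
        gd = np.zeros_like(d)
        for spec in self._active_specs():
            v, g = penalty(d, spec, self.masks[spec.structure])
            val += spec.weight * v
            gd += spec.weight * g
        return val, gd

    # -- modes ---------------------------------------------------------

    def _nominal_value_grad(self, x):
        d = self._nominal @ x
        val, gd = self._composite_on_dose(d)
        return val, self._nominal.T @ gd

    def _minimax_value_grad(self, x):
        vals, grads = [], []
        for M in self._scen:
            d = M @ x
            v, gd = self._composite_on_dose(d)
            vals.append(v)
            grads.append(M.T @ gd)
        vals = np.asarray(vals)
        if not self.smooth_max:
            j = int(np.argmax(vals))
            return float(vals[j]), grads[j]
        b = self.beta
        M0 = vals.max()
        e = np.exp(b * (vals - M0))
        val = M0 + np.log(e.sum()) / b
        p = e / e.sum()
        grad = sum(pk * g for pk, g in zip(p, grads))
        return float(val), grad

    def _interval_value_grad(self, x):
        model = self.interval
        ctv = self.masks[self.ctv_name]
        val, grad = f_ctv_interval(x, model, ctv, self.prescription, self.theta)
        val *= self.omega_ctv
        grad = self.omega_ctv * grad
        dc = model.center_dose(x)
        r = model.radius(x)
        dbar, dlow = dc + r, dc - r
        g_up = np.zeros_like(dc)
        g_low = np.zeros_like(dc)
        for spec in self._active_specs():
            if spec.structure == self.ctv_name:
                if spec.kind == "SqDev":
                    continue  # replaced by the Bertoluzza term
                if spec.kind == "DoseMin":
                    v, g = penalty(dlow, spec, self.masks[spec.structure])
                    val += spec.weight * v
                    g_low += spec.weight * g
                    continue
            v, g = penalty(dbar, spec, self.masks[spec.structure])
            val += spec.weight * v
            g_up += spec.weight * g
        grad = grad + model.center.T @ (g_up + g_low)
        gdiff = g_up - g_low
        if np.any(gdiff):
            grad = grad + model.radius_jac_T_vec(x, gdiff)
        return float(val), grad

    def value_and_grad(self, x):
        x = np.asarray(x, float)
        if self.mode in ("nominal", "ptv"):
            return self._nominal_value_grad(x)
        if self.mode == "minimax":
            return self._minimax_value_grad(x)
        return self._interval_value_grad(x)

    __call__ = value_and_grad

    def value(self, x) -> float:
        return self.value_and_grad(x)[0]


def f_total(x, plan_model: str, specs, masks, **inputs):
    """Composite objective value + gradient for one plan model (thin wrapper)."""
    return PlanObjective(plan_model, specs, masks, **inputs).value_and_grad(x)
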