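"""Bound-constrained fluence optimization.

The solver is a projected quasi-Newton method (scipy's L-BFGS-B) on the
nonnegativity box x >= 0, using the composites' analytic gradients.
Initialization is deterministic: uniform fluence scaled so the mean CTV
center dose equals the prescription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass(frozen=True)
class OptimizerConfig:
    max_iter: int = 500
    gtol: float = 1e-6          # projected-gradient tolerance (relative scale)
    ftol: float = 1e-10
    backend: str = "lbfgsb"

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FluenceResult:
    x: np.ndarray
    objective: float
    trace: pd.DataFrame          # iteration, objective, grad_norm
    n_evaluations: int
    converged: bool
    message: str


def initial_fluence(center_matrix, ctv_mask_flat, prescription_gy: float) -> np.ndarray:
    """Uniform fluence scaled so the mean CTV center dose equals the prescription."""
    m = center_matrix.shape[1]
    ones = np.ones(m)
    mean_dose = float((center_matrix @ ones)[np.asarray(ctv_mask_flat, bool)].mean())
    if mean_dose <= 0:
        raise ValueError("CTV receives no dose from uniform fluence")
    return ones * (prescription_gy / mean_dose)


def optimize_fluence(objective, x0: np.ndarray, config: OptimizerConfig | None = None) -> FluenceResult:
    """Minimize a value+gradient objective over the box x >= 0.

    ``objective(x)`` must return ``(value, gradient)``.  Deterministic for
    fixed inputs; the trace records the objective at each accepted iterate.
    """
    config = config or OptimizerConfig()
    x0 = np.maximum(np.asarray(x0, float), 0.0)
    if x0.ndim != 1 or x0.size < 1:
        raise ValueError("x0 must be a nonempty 1D fluence vector")
    f0, g0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is not finite at the initial fluence")

    n_eval = 0
    last = {"f": f0, "g": g0}

    def fun(x):
        nonlocal n_eval
        n_eval += 1
        f, g = objective(x)
        last["f"], last["g"] = f, np.asarray(g, float)
        return f, last["g"]

    trace_rows = [(0, f0, float(np.linalg.norm(g0, np.inf)))]

    def callback(xk):
        trace_rows.append(
            (len(trace_rows), last["f"], float(np.linalg.norm(last["g"], np.inf)))
        )

    scale = max(abs(f0), 1.0)
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size,
        callback=callback,
        options={
            "maxiter": config.max_iter,
            "gtol": config.gtol * scale,
            "ftol": config.ftol,
            "maxcor": 20,
        },
    )
    trace = pd.DataFrame(trace_rows, columns=["iteration", "objective", "grad_norm"])
    return FluenceResult(
        x=np.maximum(res.x, 0.0),
        objective=float(res.fun),
        trace=trace,
        n_evaluations=n_eval + 1,
        converged=bool(res.success),
        message=str(res.message),
    )
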