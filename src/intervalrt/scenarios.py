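"""Gaussian setup-error model and scenario-set generation.

Setup errors are rigid patient shifts delta = (dx, dy, dz) drawn from an
uncorrelated zero-mean 3D normal with per-axis standard deviations
sigma = (sx, sy, sz) mapped to the LR, AP and IS directions.  Two discrete
scenario sets are used: a 13-scenario set for optimization (nominal plus
4 single-axis shifts per axis at +-0.5 sigma and +-1.0 sigma) and a
5x5x5 Cartesian grid for plan evaluation (per-axis offsets at multiples
of 0.75 sigma).  Scenario weights are proportional to the setup-error
density, renormalized over the finite set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SetupErrorModel:
    """Per-axis standard deviations (mm) of the setup error, LR / AP / IS."""

    sigma_mm: tuple[float, float, float] = (5.0, 10.0, 5.0)

    def __post_init__(self):
        if min(self.sigma_mm) <= 0:
            raise ValueError("all sigma must be > 0")


def setup_error_pdf(delta, model: SetupErrorModel):
    """Density of the uncorrelated zero-mean 3D normal setup-error model.

    Accepts a single shift (3,) or an array of shifts (K, 3).
    """
    d = np.atleast_2d(np.asarray(delta, float))
    sig = np.asarray(model.sigma_mm, float)
    dens = np.prod([stats.norm.pdf(d[:, a], scale=sig[a]) for a in range(3)], axis=0)
    return float(dens[0]) if np.ndim(delta) == 1 else dens


@dataclass(frozen=True)
class ScenarioSet:
    """Discrete rigid-shift scenarios with normalized probability weights."""

    shifts_mm: np.ndarray          # (K, 3)
    weights: np.ndarray            # (K,), sums to 1
    nominal_index: int
    tag: str = ""                  # "optimization" or "evaluation"

    def __post_init__(self):
        shifts = np.asarray(self.shifts_mm, float)
        w = np.asarray(self.weights, float)
        object.__setattr__(self, "shifts_mm", shifts)
        object.__setattr__(self, "weights", w)
        if shifts.ndim != 2 or shifts.shape[1] != 3:
            raise ValueError("shifts must have shape (K, 3)")
        if w.shape != (shifts.shape[0],):
            raise ValueError("one weight per scenario required")
        if (w < 0).any():
            raise ValueError("weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        if not np.all(shifts[self.nominal_index] == 0):
            raise ValueError("nominal scenario must have zero shift")

    def __len__(self) -> int:
        return self.shifts_mm.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.shifts_mm, columns=["dx_mm", "dy_mm", "dz_mm"])
        df["weight"] = self.weights
        df["is_nominal"] = False
        df.loc[self.nominal_index, "is_nominal"] = True
        return df


def _normalized(model: SetupErrorModel, shifts: np.ndarray, tag: str) -> ScenarioSet:
    dens = setup_error_pdf(shifts, model)
    w = dens / dens.sum()
    nominal = int(np.flatnonzero((shifts == 0).all(axis=1))[0])
    return ScenarioSet(shifts_mm=shifts, weights=w, nominal_index=nominal, tag=tag)


def make_opt_scenarios(model: SetupErrorModel) -> ScenarioSet:
    """13-scenario optimization set: nominal + 4 shifts per axis at 0.5-sigma steps."""
    sig = np.asarray(model.sigma_mm, float)
    shifts = [np.zeros(3)]
    for axis in range(3):
        for mult in (-1.0, -0.5, 0.5, 1.0):
            s = np.zeros(3)
            s[axis] = mult * sig[axis]
            shifts.append(s)
    return _normalized(model, np.asarray(shifts), tag="optimization")


def make_eval_grid(model: SetupErrorModel) -> ScenarioSet:
    """5x5x5 evaluation grid centered on perfect positioning, step 0.75 sigma."""
    sig = np.asarray(model.sigma_mm, float)
    levels = np.array([-1.5, -0.75, 0.0, 0.75, 1.5])
    shifts = np.array(
        [(lx * sig[0], ly * sig[1], lz * sig[2])
         for lx, ly, lz in itertools.product(levels, levels, levels)]
    )
    return _normalized(model, shifts, tag="evaluation")
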