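"""Robustness evaluation of an optimized fluence under the scenario grid.

A plan is scored against the *evaluation* scenario set (a 5x5x5 grid of
rigid shifts, never the 13-scenario optimization set): per-voxel expected
dose and standard deviation, the per-CTV-voxel Delta score

    Delta_i = ((E(d_i) - p) / (c1 p))^2 + (std(d_i) / (c2 p))^2 ,

the robustness index RI (fraction of CTV voxels with Delta_i < 1,
strictly), dose-volume histograms with confidence bands, and the
price-of-robustness VxGy metrics on the nominal-scenario dose
(V60Gy bladder, V40Gy rectum for prostate plans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RobustnessParams:
    """Tolerances of the Delta score, as fractions of the prescription.

    c1 scales the allowed deviation of the expected dose from p; c2 scales
    the allowed per-voxel standard deviation.  The defaults allow 5% of
    the prescription for each component.
    """

    c1: float = 0.05
    c2: float = 0.05
    prescription_gy: float = 78.0

    def __post_init__(self):
        if min(self.c1, self.c2, self.prescription_gy) <= 0:
            raise ValueError("c1, c2 and the prescription must be > 0")


@dataclass
class ScenarioDoseStats:
    expected: np.ndarray   # per-voxel E(d_i), Gy
    std: np.ndarray        # per-voxel std(d_i), Gy


def scenario_dose_stats(x, Dks, w) -> ScenarioDoseStats:
    """Weighted per-voxel mean and standard deviation of dose over scenarios."""
    x = np.asarray(x, float)
    mats = [getattr(D, "matrix", D) for D in Dks]
    w = np.asarray(w, float)
    if w.shape != (len(mats),):
        raise ValueError("one weight per scenario required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    doses = [M @ x for M in mats]
    E = sum(wk * d for wk, d in zip(w, doses))
    var = sum(wk * (d - E) ** 2 for wk, d in zip(w, doses))
    return ScenarioDoseStats(expected=E, std=np.sqrt(np.maximum(var, 0.0)))


def delta_map(stats: ScenarioDoseStats, params: RobustnessParams, ctv_mask) -> np.ndarray:
    """Delta score per CTV voxel (in mask order); a voxel is robust iff Delta < 1."""
    ctv = np.asarray(ctv_mask, bool).ravel()
    if not ctv.any():
        raise ValueError("empty CTV")
    p = params.prescription_gy
    E = stats.expected[ctv]
    s = stats.std[ctv]
    return ((E - p) / (params.c1 * p)) ** 2 + (s / (params.c2 * p)) ** 2


def robustness_index(delta: np.ndarray) -> float:
    """Fraction of CTV voxels with Delta strictly below 1."""
    delta = np.asarray(delta, float)
    if delta.size == 0:
        raise ValueError("empty Delta map")
    return float(np.mean(delta < 1.0))


def vx(d, mask, threshold_gy: float) -> float:
    """Percent of the structure's volume receiving at least ``threshold_gy``."""
    mask = np.asarray(mask, bool).ravel()
    if not mask.any():
        raise ValueError("empty mask")
    return float(100.0 * np.mean(np.asarray(d, float)[mask] >= threshold_gy))


def dvh(d, mask, bins) -> np.ndarray:
    """Cumulative DVH: percent volume at or above each dose bin edge."""
    mask = np.asarray(mask, bool).ravel()
    if not mask.any():
        raise ValueError("empty mask")
    ds = np.sort(np.asarray(d, float)[mask])
    n = ds.size
    # count of voxels with dose >= t for each bin edge t
    counts = n - np.searchsorted(ds, np.asarray(bins, float), side="left")
    return 100.0 * counts / n


def default_dose_bins(prescription_gy: float = 78.0, width_gy: float = 0.1) -> np.ndarray:
    return np.arange(0.0, 1.2 * prescription_gy + width_gy, width_gy)


@dataclass
class CDVH:
    """Confidence-band DVH: nominal curve, expected curve and std band per structure."""

    bins_gy: np.ndarray
    nominal: dict[str, np.ndarray]
    expected: dict[str, np.ndarray]
    std: dict[str, np.ndarray]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in self.nominal:
            rows.append(pd.DataFrame({
                "structure": name,
                "dose_gy": self.bins_gy,
                "nominal_pct": self.nominal[name],
                "expected_pct": self.expected[name],
                "std_pct": self.std[name],
            }))
        return pd.concat(rows, ignore_index=True)


def cdvh(x, Dks, w, masks: dict, bins, nominal_index: int = 0) -> CDVH:
    """Weighted moments of the per-scenario DVH curves, bin by bin."""
    x = np.asarray(x, float)
    mats = [getattr(D, "matrix", D) for D in Dks]
    w = np.asarray(w, float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    bins = np.asarray(bins, float)
    doses = [M @ x for M in mats]
    nominal, expected, std = {}, {}, {}
    for name, mask in masks.items():
        curves = np.stack([dvh(d, mask, bins) for d in doses])  # (K, nbins)
        E = w @ curves
        var = w @ (curves - E) ** 2
        nominal[name] = curves[nominal_index]
        expected[name] = E
        std[name] = np.sqrt(np.maximum(var, 0.0))
    return CDVH(bins_gy=bins, nominal=nominal, expected=expected, std=std)


def price_of_robustness(x, nominal_D, masks: dict) -> dict[str, float]:
    """OAR cost of the plan at perfect positioning: V60Gy bladder, V40Gy rectum."""
    for required in ("bladder", "rectum"):
        if required not in masks:
            raise ValueError(f"missing mask '{required}'")
    d = getattr(nominal_D, "matrix", nominal_D) @ np.asarray(x, float)
    return {
        "v60_bladder_pct": vx(d, masks["bladder"], 60.0),
        "v40_rectum_pct": vx(d, masks["rectum"], 40.0),
    }
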