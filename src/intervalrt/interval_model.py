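"""Interval dose-influence representation: center, radius and SVD compression.

Across K error scenarios with dose-influence matrices D_k and normalized
weights w_k, the per-voxel dose for fluence x is summarized as an
interval [center, radius]:

    center(x) = sum_k w_k D_k x  =  D_c x
    radius(x)_i = std over scenarios = sqrt( sum_k w_k ((D_k - D_c) x)_i^2 )

Equivalently radius(x)_i^2 = x^T R_i x with the per-voxel covariance-form
matrix R_i = sum_k w_k D_k[i]^T D_k[i] - D_c[i]^T D_c[i].  Materializing
R_i is quadratic in the bixel count, so the weighted deviation stack
E_k = sqrt(w_k) (D_k - D_c) is compressed by an SVD along the scenario
axis: with the thin SVD of the K x (n*m) unfolding, E_k = sum_r s_r
U_kr Phi_r, orthonormality of U gives

    radius(x)_i^2 = sum_r s_r^2 (Phi_r x)_i^2 ,

exact at full rank and monotonically under-estimating under truncation.
Modes are retained up to a cumulative variance-explained threshold
(default 99%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse


def _as_matrix(D):
    """Accept either a DoseInfluenceMatrix or a raw sparse/dense matrix."""
    return D.matrix if hasattr(D, "matrix") else D


def _check_weights(w, K):
    w = np.asarray(w, float)
    if w.shape != (K,):
        raise ValueError("one weight per scenario required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("scenario weights must sum to 1")
    return w


def build_center(Dks, w) -> sparse.csr_matrix:
    """Probability-weighted mean of the scenario dose-influence matrices."""
    mats = [_as_matrix(D) for D in Dks]
    w = _check_weights(w, len(mats))
    shape = mats[0].shape
    for M in mats:
        if M.shape != shape:
            raise ValueError("scenario matrices must share one shape")
    center = sum(wk * M for wk, M in zip(w, mats))
    return sparse.csr_matrix(center)


def radius_exact(x, Dks, w, center) -> np.ndarray:
    """Per-voxel dose standard deviation over scenarios, deviation form.

    Computed as sqrt(sum_k w_k ((D_k - D_c) x)^2); round-off negatives are
    impossible in this form and the result is exactly >= 0.
    """
    x = np.asarray(x, float)
    mats = [_as_matrix(D) for D in Dks]
    w = _check_weights(w, len(mats))
    dc = _as_matrix(center) @ x
    var = np.zeros_like(dc)
    for wk, M in zip(w, mats):
        dev = M @ x - dc
        var += wk * dev**2
    return np.sqrt(np.maximum(var, 0.0))


@dataclass
class CompressedRadius:
    """Scenario-axis SVD of the weighted deviation stack.

    ``radius(x)_i = sqrt( sum_r sigmas[r]^2 (modes[r] @ x)_i^2 )`` over the
    retained modes; truncation only removes nonnegative terms, so the
    compressed radius never exceeds the exact one.
    """

    sigmas: np.ndarray                 # (k,), descending, > 0
    modes: list                        # k sparse (n, m) mode matrices Phi_r
    variance_explained: float
    n_scenarios: int

    @property
    def rank(self) -> int:
        return len(self.sigmas)

    def radius(self, x) -> np.ndarray:
        return np.sqrt(self.radius_sq(x))

    def radius_sq(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.rank == 0:
            return np.zeros(self._n_voxels)
        out = np.zeros(self.modes[0].shape[0])
        for s, phi in zip(self.sigmas, self.modes):
            out += s**2 * (phi @ x) ** 2
        return out

    # set when rank == 0 so radius_sq still knows the voxel count
    _n_voxels: int = 0


def compress_radius(Dks, w, center, variance_threshold: float = 0.99) -> CompressedRadius:
    """SVD-compress the radius representation along the scenario axis.

    Retains the smallest number of modes whose cumulative squared singular
    values reach ``variance_threshold`` of the total.  With threshold 1.0
    the reconstruction is exact (rank <= K).
    """
    if not (0 < variance_threshold <= 1.0):
        raise ValueError("variance threshold must lie in (0, 1]")
    mats = [_as_matrix(D) for D in Dks]
    K = len(mats)
    if K < 2:
        raise ValueError("compression needs at least 2 scenarios")
    w = _check_weights(w, K)
    Dc = _as_matrix(center)
    Eks = [sparse.csr_matrix(np.sqrt(wk) * (M - Dc)) for wk, M in zip(w, mats)]

    # Gram matrix of the K x (n*m) unfolding; eigh gives the scenario-axis SVD
    G = np.empty((K, K))
    for a in range(K):
        for b in range(a, K):
            G[a, b] = G[b, a] = Eks[a].multiply(Eks[b]).sum()
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    n_vox = mats[0].shape[0]
    tol = 1e-12 * max(evals.max(initial=0.0), 0.0)
    pos = evals > max(tol, 0.0)
    if total <= 0 or not pos.any():
        # all scenarios identical: radius is identically zero
        return CompressedRadius(
            sigmas=np.empty(0), modes=[], variance_explained=1.0,
            n_scenarios=K, _n_voxels=n_vox,
        )
    evals, evecs = evals[pos], evecs[:, pos]
    frac = np.cumsum(evals) / total
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    k = min(k, len(evals))
    sigmas = np.sqrt(evals[:k])
    modes = []
    for r in range(k):
        phi = sum(evecs[a, r] * Eks[a] for a in range(K)) / sigmas[r]
        modes.append(sparse.csr_matrix(phi))
    return CompressedRadius(
        sigmas=sigmas, modes=modes,
        variance_explained=float(frac[k - 1]),
        n_scenarios=K, _n_voxels=n_vox,
    )


def radius_from_compressed(x, comp: CompressedRadius) -> np.ndarray:
    """Per-voxel radius from the compressed representation."""
    return comp.radius(x)


@dataclass
class IntervalDoseModel:
    """Center matrix plus compressed radius; the planning-time dose model."""

    center: sparse.csr_matrix
    comp: CompressedRadius
    scenario_shifts_mm: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.center.shape[0]

    @property
    def n_bixels(self) -> int:
        return self.center.shape[1]

    def center_dose(self, x) -> np.ndarray:
        return self.center @ np.asarray(x, float)

    def radius(self, x) -> np.ndarray:
        return self.comp.radius(x)

    def upper(self, x) -> np.ndarray:
        return self.center_dose(x) + self.radius(x)

    def lower(self, x) -> np.ndarray:
        return self.center_dose(x) - self.radius(x)

    def grad_radius_sq_masked(self, x, mask_flat) -> np.ndarray:
        """Gradient of sum_{i in mask} radius(x)_i^2 with respect to x."""
        x = np.asarray(x, float)
        g = np.zeros(self.n_bixels)
        for s, phi in zip(self.comp.sigmas, self.comp.modes):
            y = phi @ x
            y[~mask_flat] = 0.0
            g += 2.0 * s**2 * (phi.T @ y)
        return g

    def radius_jac_T_vec(self, x, gvec) -> np.ndarray:
        """J_r(x)^T g for the per-voxel radius map r(x); 0 where r(x) = 0."""
        x = np.asarray(x, float)
        r = self.radius(x)
        scale = np.zeros_like(r)
        nz = r > 0
        scale[nz] = gvec[nz] / r[nz]
        out = np.zeros(self.n_bixels)
        for s, phi in zip(self.comp.sigmas, self.comp.modes):
            y = phi @ x
            out += s**2 * (phi.T @ (y * scale))
        return out


def build_interval_model(Dks, scenario_set, variance_threshold: float = 0.99) -> IntervalDoseModel:
    """Assemble center + compressed radius from per-scenario matrices."""
    w = scenario_set.weights
    center = build_center(Dks, w)
    comp = compress_radius(Dks, w, center, variance_threshold)
    return IntervalDoseModel(
        center=center, comp=comp, scenario_shifts_mm=np.asarray(scenario_set.shifts_mm),
    )


def voxel_covariance_matrix(Dks, w, voxel: int) -> np.ndarray:
    """Explicit per-voxel covariance-form matrix R_i (dense, m x m).

    R_i = sum_k w_k D_k[i]^T D_k[i] - D_c[i]^T D_c[i]; then x^T R_i x is the
    squared dose radius at voxel i.  Intended for small instances only —
    the SVD-compressed path exists precisely to avoid materializing this.
    """
    mats = [_as_matrix(D) for D in Dks]
    w = _check_weights(w, len(mats))
    rows = [np.asarray(M[voxel].todense()).ravel() if sparse.issparse(M) else np.asarray(M[voxel]).ravel()
            for M in mats]
    dc = sum(wk * r for wk, r in zip(w, rows))
    R = sum(wk * np.outer(r, r) for wk, r in zip(w, rows)) - np.outer(dc, dc)
    return R
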