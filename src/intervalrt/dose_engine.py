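"""Toy pencil-beam dose engine producing sparse dose-influence matrices.

Each beam is a parallel (non-divergent) field of bixels laid out on a
plane through the isocenter.  The dose of bixel j at voxel i is

    d_ij = exp(-mu * depth_ij) * exp(-lateral_ij^2 / (2 sigma_pen^2))

where ``depth`` is the radiological path length inside the body from the
entry surface along the bixel's central ray and ``lateral`` is the
perpendicular distance of the voxel from that ray.  A rigid patient
shift delta is realized by translating the isocenter (hence every ray)
by -delta; scenario matrices are recomputed exactly rather than
interpolated from the nominal dose grid.

Gantry angles follow the axial convention: 0 deg irradiates from
anterior (beam travels toward -y), 90 deg from patient-left (+x), angles
increase clockwise when viewed from the feet.

Single-slice phantoms (nz = 1) are treated as the mid-plane of a field
that is long and uniform in the IS direction: the lateral falloff acts
in-plane only, so IS shifts leave the slice dose unchanged (they still
carry their probability weight in the scenario sets).  Full 3D phantoms
get the full 3D lateral Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .phantom import VoxelPhantom

DEFAULT_GANTRY_ANGLES = (0.0, 40.0, 80.0, 120.0, 160.0, 200.0, 240.0, 280.0, 320.0)


@dataclass(frozen=True)
class BeamSetup:
    """Beam geometry and toy physics constants.

    ``lattice_margin_mm`` pads the bixel lattice beyond the target
    projection (in addition to 3 penumbra sigmas) so that margin-expanded
    targets and shifted scenarios remain coverable.
    """

    gantry_angles_deg: tuple[float, ...] = DEFAULT_GANTRY_ANGLES
    bixel_width_mm: float = 5.0
    isocenter_mm: tuple[float, float, float] | None = None  # None -> CTV centroid
    mu_per_mm: float = 0.005
    penumbra_sigma_mm: float = 3.0
    lattice_margin_mm: float = 7.0
    sparsity_floor: float = 1e-4

    def __post_init__(self):
        if self.bixel_width_mm <= 0:
            raise ValueError("bixel width must be > 0")
        if self.mu_per_mm < 0:
            raise ValueError("attenuation coefficient must be >= 0")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be > 0")


@dataclass
class DoseInfluenceMatrix:
    """Sparse nonnegative map from m bixel fluences to n voxel doses (one scenario)."""

    matrix: sparse.csr_matrix      # (n_voxels, n_bixels)
    shift_mm: np.ndarray           # rigid patient shift this scenario represents
    beam_index: np.ndarray         # (m,) which beam each bixel belongs to
    bixel_lateral_mm: np.ndarray   # (m,) in-plane lattice coordinate
    bixel_z_mm: np.ndarray         # (m,) IS lattice coordinate

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bixels(self) -> int:
        return self.matrix.shape[1]

    def dose(self, x: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(x, float)


def _beam_axes(gantry_deg: float):
    g = np.deg2rad(gantry_deg)
    u = np.array([np.sin(g), -np.cos(g), 0.0])   # propagation direction
    v = np.array([np.cos(g), np.sin(g), 0.0])    # in-plane lateral axis
    ez = np.array([0.0, 0.0, 1.0])
    return u, v, ez


def _lattice_1d(lo: float, hi: float, pad: float, width: float) -> np.ndarray:
    span = (hi - lo) + 2 * pad
    n = max(1, int(np.ceil(span / width)))
    mid = 0.5 * (lo + hi)
    return mid + (np.arange(n) - (n - 1) / 2.0) * width


def make_bixel_layout(phantom: VoxelPhantom, beams: BeamSetup, target_name: str = "CTV"):
    """Fixed per-plan bixel lattice covering the (unshifted) target projection.

    Returns (beam_index, lateral, z, isocenter).  The lattice is identical
    for every scenario of a plan, so the bixel count m is constant.  For a
    single-slice phantom the IS axis collapses to one bixel row at the
    target's IS center.
    """
    target = phantom.mask(target_name)
    if not target.any():
        raise ValueError("empty fluence map: target has no voxels")
    iso = (
        np.asarray(beams.isocenter_mm, float)
        if beams.isocenter_mm is not None
        else phantom.centroid_mm(target_name)
    )
    coords = phantom.grid.coords()[phantom.flat_mask(target_name)]
    pad = beams.lattice_margin_mm + 3.0 * beams.penumbra_sigma_mm
    single_slice = phantom.grid.shape[2] == 1

    beam_idx, lats, zs = [], [], []
    for b, ang in enumerate(beams.gantry_angles_deg):
        _, v, ez = _beam_axes(ang)
        sv = (coords - iso) @ v
        sz = (coords - iso) @ ez
        lat_pts = _lattice_1d(sv.min(), sv.max(), pad, beams.bixel_width_mm)
        if single_slice:
            z_pts = np.array([0.5 * (sz.min() + sz.max())])
        else:
            z_pts = _lattice_1d(sz.min(), sz.max(), pad, beams.bixel_width_mm)
        for zp in z_pts:
            beam_idx.extend([b] * len(lat_pts))
            lats.extend(lat_pts)
            zs.extend([zp] * len(lat_pts))
    return np.asarray(beam_idx), np.asarray(lats), np.asarray(zs), iso


def _central_ray_depth(body_flat, grid, origin_pt, u, step):
    """Radiological depth along one ray: cumulative in-body path vs. ray parameter."""
    coords0 = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    extent = np.linalg.norm(np.asarray(grid.shape) * spacing)
    ts = np.arange(-extent, extent + step, step)
    pts = origin_pt[None, :] + ts[:, None] * u[None, :]
    idx = np.rint((pts - coords0) / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    inside = np.zeros(len(ts), bool)
    if ok.any():
        flat = np.ravel_multi_index(idx[ok].T, grid.shape)
        inside[ok] = body_flat[flat]
    depth = np.cumsum(inside) * step
    return ts, depth


def compute_dij(
    phantom: VoxelPhantom,
    beams: BeamSetup,
    shift_mm=(0.0, 0.0, 0.0),
    target_name: str = "CTV",
    layout=None,
) -> DoseInfluenceMatrix:
    """Dose-influence matrix for one rigid-shift scenario.

    ``layout`` (from :func:`make_bixel_layout`) may be passed to share the
    bixel lattice across scenarios; it is recomputed from the unshifted
    phantom otherwise.  Entries below ``sparsity_floor`` times the column
    maximum are dropped.
    """
    shift = np.asarray(shift_mm, float)
    if not np.all(np.isfinite(shift)):
        raise ValueError("shift must be finite")
    if layout is None:
        layout = make_bixel_layout(phantom, beams, target_name)
    beam_idx, lats, zs, iso = layout
    m = len(beam_idx)
    grid = phantom.grid
    coords = grid.coords()
    body_flat = phantom.flat_mask("body")
    iso_eff = iso - shift  # patient shifted by +delta == beams shifted by -delta
    sigma = beams.penumbra_sigma_mm
    floor = beams.sparsity_floor
    # lateral cutoff where the Gaussian alone falls below the floor
    cutoff = sigma * np.sqrt(-2.0 * np.log(max(floor, 1e-300)))
    step = min(grid.spacing) / 2.0
    single_slice = grid.shape[2] == 1

    rows, cols, vals = [], [], []
    for b, ang in enumerate(np.asarray(beams.gantry_angles_deg, float)):
        sel = beam_idx == b
        if not sel.any():
            continue
        u, v, ez = _beam_axes(ang)
        rel = coords - iso_eff
        ru, rv, rz = rel @ u, rel @ v, rel @ ez
        for j in np.flatnonzero(sel):
            if single_slice:
                lat2 = (rv - lats[j]) ** 2
            else:
                lat2 = (rv - lats[j]) ** 2 + (rz - zs[j]) ** 2
            gauss = np.exp(-lat2 / (2.0 * sigma**2))
            cand = np.flatnonzero(lat2 <= cutoff**2)
            if cand.size == 0:
                continue
            origin_pt = iso_eff + lats[j] * v + zs[j] * ez
            if single_slice:
                # project the ray into the slice plane: the field is
                # z-uniform, so depth is measured in-plane
                origin_pt = origin_pt.copy()
                origin_pt[2] = grid.origin[2]
            ts, depth = _central_ray_depth(body_flat, grid, origin_pt, u, step)
            d_vox = np.interp(ru[cand], ts, depth)
            dose = np.exp(-beams.mu_per_mm * d_vox) * gauss[cand]
            keep = dose >= floor * dose.max()
            rows.append(cand[keep])
            cols.append(np.full(keep.sum(), j))
            vals.append(dose[keep])

    if not rows:
        raise ValueError("empty fluence map: no bixel deposits dose")
    D = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(grid.n_voxels, m),
    )
    return DoseInfluenceMatrix(
        matrix=D, shift_mm=shift, beam_index=beam_idx,
        bixel_lateral_mm=lats, bixel_z_mm=zs,
    )


def compute_scenario_dijs(phantom, beams, scenario_set, target_name: str = "CTV"):
    """Dose-influence matrices for every scenario, sharing one bixel layout."""
    layout = make_bixel_layout(phantom, beams, target_name)
    return [
        compute_dij(phantom, beams, s, target_name=target_name, layout=layout)
        for s in scenario_set.shifts_mm
    ]
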