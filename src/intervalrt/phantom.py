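"""Synthetic prostate-like voxel phantoms and structure-mask geometry.

A phantom is a regular voxel grid (axis convention: x = left-right,
y = anterior-posterior with positive y anterior, z = inferior-superior)
carrying named boolean structure masks.  The generator emulates a
prostate-like axial geometry: an ellipsoidal CTV flanked anteriorly by a
bladder and posteriorly by a rectum, all inside an elliptical body
contour.  Margin expansion (CTV -> PTV) and ring structures are derived
here as well.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel grid; ``nz == 1`` gives a single axial slice.

    ``origin`` is the physical coordinate (mm) of the center of voxel
    (0, 0, 0); voxel (i, j, k) is centered at ``origin + (i, j, k) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(sp <= 0 for sp in self.spacing):
            raise ValueError("grid spacings must be > 0")
        if self.origin is None:
            # center the grid on the physical origin
            org = tuple(-(n - 1) / 2.0 * sp for n, sp in zip(self.shape, self.spacing))
            object.__setattr__(self, "origin", org)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def coords(self) -> np.ndarray:
        """Physical coordinates (mm) of all voxel centers, shape (n, 3), C order."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass(frozen=True)
class MarginSpec:
    """Anisotropic CTV->PTV margins in mm; AP is asymmetric (anterior/posterior)."""

    lr_mm: float = 7.0
    ant_mm: float = 7.0
    post_mm: float = 4.0
    is_mm: float = 7.0

    def __post_init__(self):
        if min(self.lr_mm, self.ant_mm, self.post_mm, self.is_mm) < 0:
            raise ValueError("margins must be >= 0")


@dataclass
class VoxelPhantom:
    """Voxel grid plus named boolean structure masks (all subsets of 'body')."""

    grid: VoxelGrid
    structures: dict[str, np.ndarray]

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"unknown structure '{name}'") from None

    def flat_mask(self, name: str) -> np.ndarray:
        return self.mask(name).ravel(order="C")

    def centroid_mm(self, name: str) -> np.ndarray:
        m = self.mask(name)
        if not m.any():
            raise ValueError(f"structure '{name}' is empty")
        idx = np.argwhere(m)
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(self.grid.spacing)


@dataclass(frozen=True)
class ProstatePhantomConfig:
    """Geometry of the synthetic prostate slice/volume (all lengths in mm).

    Structure centers are (x, y, z) offsets from the grid center; semi-axes
    define ellipsoids.  ``jitter_mm`` adds a small random displacement to
    the CTV/bladder/rectum centers (seeded) to emulate inter-patient
    variation; the default is 0 (fully deterministic geometry).
    """

    shape: tuple[int, int, int] = (60, 60, 1)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_semiaxes: tuple[float, float, float] = (85.0, 75.0, 1.0e4)
    ctv_center: tuple[float, float, float] = (0.0, -10.0, 0.0)
    ctv_semiaxes: tuple[float, float, float] = (23.0, 20.0, 20.0)
    bladder_center: tuple[float, float, float] = (0.0, 38.0, 0.0)
    bladder_semiaxes: tuple[float, float, float] = (30.0, 25.0, 25.0)
    rectum_center: tuple[float, float, float] = (0.0, -45.0, 0.0)
    rectum_semiaxes: tuple[float, float, float] = (15.0, 12.0, 30.0)
    jitter_mm: float = 0.0


def _ellipsoid_mask(grid: VoxelGrid, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    coords = grid.coords()
    semi = np.maximum(np.asarray(semiaxes, float), 1e-12)
    q = ((coords - center) / semi) ** 2
    return (q.sum(axis=1) <= 1.0).reshape(grid.shape)


def _check_inside_grid(grid: VoxelGrid, name: str, center: np.ndarray, semiaxes: np.ndarray):
    lo = np.asarray(grid.origin) - np.asarray(grid.spacing) / 2
    hi = lo + np.asarray(grid.shape) * np.asarray(grid.spacing)
    semi = np.asarray(semiaxes, float)
    # the degenerate single-slice axis is exempt: a z semi-axis larger than
    # the slice thickness just means the structure spans the slice
    for a, label in enumerate("xyz"):
        if grid.shape[a] == 1:
            continue
        if center[a] - semi[a] < lo[a] or center[a] + semi[a] > hi[a]:
            raise ValueError(f"structure '{name}' extends outside grid along {label}")


def make_prostate_phantom(
    config: ProstatePhantomConfig | None = None, seed: int = 0
) -> VoxelPhantom:
    """Generate the synthetic prostate phantom.

    Deterministic for a fixed (config, seed).  Raises if a structure
    extends outside the grid or the CTV mask comes out empty.
    """
    config = config or ProstatePhantomConfig()
    grid = VoxelGrid(shape=tuple(config.shape), spacing=tuple(config.spacing))
    rng = np.random.default_rng(seed)

    centers = {
        "CTV": np.asarray(config.ctv_center, float),
        "bladder": np.asarray(config.bladder_center, float),
        "rectum": np.asarray(config.rectum_center, float),
    }
    if config.jitter_mm > 0:
        for name in centers:
            centers[name] = centers[name] + rng.uniform(
                -config.jitter_mm, config.jitter_mm, size=3
            )
    semiaxes = {
        "CTV": np.asarray(config.ctv_semiaxes, float),
        "bladder": np.asarray(config.bladder_semiaxes, float),
        "rectum": np.asarray(config.rectum_semiaxes, float),
    }

    body = _ellipsoid_mask(grid, np.zeros(3), np.asarray(config.body_semiaxes, float))
    structures = {"body": body}
    for name in ("CTV", "bladder", "rectum"):
        _check_inside_grid(grid, name, centers[name], semiaxes[name])
        structures[name] = _ellipsoid_mask(grid, centers[name], semiaxes[name]) & body

    if not structures["CTV"].any():
        raise ValueError("CTV empty")
    for oar in ("bladder", "rectum"):
        if (structures["CTV"] & structures[oar]).any():
            raise ValueError(f"CTV overlaps {oar}; adjust phantom geometry")
    return VoxelPhantom(grid=grid, structures=structures)


def _margin_offsets(margins: MarginSpec, grid: VoxelGrid):
    """Integer voxel offsets inside the AP-asymmetric margin ellipsoid."""
    sx, sy, sz = grid.spacing
    rx = int(np.floor(margins.lr_mm / sx))
    ry = int(np.floor(max(margins.ant_mm, margins.post_mm) / sy))
    rz = int(np.floor(margins.is_mm / sz))
    offsets = []
    for ox in range(-rx, rx + 1):
        for oy in range(-ry, ry + 1):
            for oz in range(-rz, rz + 1):
                dx, dy, dz = ox * sx, oy * sy, oz * sz
                my = margins.ant_mm if dy >= 0 else margins.post_mm
                q = 0.0
                ok = True
                for d, m in ((dx, margins.lr_mm), (dy, my), (dz, margins.is_mm)):
                    if m == 0:
                        if d != 0:
                            ok = False
                            break
                    else:
                        q += (d / m) ** 2
                if ok and q <= 1.0:
                    offsets.append((ox, oy, oz))
    return offsets


def expand_margin(mask: np.ndarray, margins: MarginSpec, grid: VoxelGrid) -> np.ndarray:
    """Expand a mask by anisotropic, AP-asymmetric ellipsoidal margins.

    The result is the union, over source voxels, of an ellipsoid with
    semi-axes (lr, ant-or-post by the sign of the AP displacement, is),
    clipped to the grid.  With all margins zero this is the identity.
    """
    if not mask.any():
        raise ValueError("cannot expand an empty mask")
    out = np.zeros_like(mask)
    nx, ny, nz = mask.shape
    for ox, oy, oz in _margin_offsets(margins, grid):
        src = [slice(max(0, -o), min(s, s - o)) for o, s in zip((ox, oy, oz), mask.shape)]
        dst = [slice(max(0, o), min(s, s + o)) for o, s in zip((ox, oy, oz), mask.shape)]
        out[tuple(dst)] |= mask[tuple(src)]
    return out


def make_ring(
    target: np.ndarray,
    inner_mm: float,
    outer_mm: float,
    grid: VoxelGrid,
    body: np.ndarray | None = None,
) -> np.ndarray:
    """Ring of voxels outside ``target`` at surface distance in [inner, outer) mm.

    Distances are Euclidean distances (voxel-center to nearest target
    voxel-center, anisotropic spacing respected); the ring is intersected
    with ``body`` when given.
    """
    if not (0 <= inner_mm < outer_mm):
        raise ValueError("require 0 <= inner_mm < outer_mm")
    if not target.any():
        raise ValueError("cannot ring an empty target")
    dist = ndimage.distance_transform_edt(~target, sampling=grid.spacing)
    ring = (~target) & (dist >= inner_mm) & (dist < outer_mm)
    if body is not None:
        ring &= body
    return ring


def add_derived_structures(
    phantom: VoxelPhantom,
    margins: MarginSpec | None = None,
    ring_anchor: str = "CTV",
) -> VoxelPhantom:
    """Attach PTV (margin-expanded CTV) and the 0-20 / 20-50 mm rings.

    ``ring_anchor`` selects the structure the rings are grown from (CTV
    for nominal/minimax/interval plans, PTV for the margin-based plan).
    """
    margins = margins or MarginSpec()
    ptv = expand_margin(phantom.mask("CTV"), margins, phantom.grid) & phantom.mask("body")
    structures = dict(phantom.structures)
    structures["PTV"] = ptv
    anchor = structures[ring_anchor] if ring_anchor in structures else structures["CTV"]
    body = phantom.mask("body")
    structures["ring_0_20"] = make_ring(anchor, 0.0, 20.0, phantom.grid, body=body)
    structures["ring_20_50"] = make_ring(anchor, 20.0, 50.0, phantom.grid, body=body)
    return VoxelPhantom(grid=phantom.grid, structures=structures)
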