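"""HDF5 container for phantoms, dose-influence matrices and plan bundles."""

from __future__ import annotations

import numpy as np
import h5py
from scipy import sparse

from .phantom import VoxelGrid, VoxelPhantom


def _write_sparse(group: h5py.Group, name: str, M: sparse.spmatrix):
    M = sparse.csr_matrix(M).tocoo()
    g = group.create_group(name)
    g.attrs["shape"] = M.shape
    g.create_dataset("row", data=M.row, compression="gzip")
    g.create_dataset("col", data=M.col, compression="gzip")
    g.create_dataset("value", data=M.data, compression="gzip")


def _read_sparse(group: h5py.Group, name: str) -> sparse.csr_matrix:
    g = group[name]
    shape = tuple(g.attrs["shape"])
    return sparse.csr_matrix(
        (g["value"][:], (g["row"][:], g["col"][:])), shape=shape
    )


def save_phantom(path, phantom: VoxelPhantom):
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.attrs["shape"] = phantom.grid.shape
        g.attrs["spacing_mm"] = phantom.grid.spacing
        g.attrs["origin_mm"] = phantom.grid.origin
        sg = g.create_group("structures")
        for name, mask in phantom.structures.items():
            sg.create_dataset(
                name, data=np.packbits(mask.astype(np.uint8)), compression="gzip"
            )
            sg[name].attrs["n_voxels"] = mask.size


def load_phantom(path) -> VoxelPhantom:
    with h5py.File(path, "r") as f:
        g = f["phantom"]
        grid = VoxelGrid(
            shape=tuple(int(v) for v in g.attrs["shape"]),
            spacing=tuple(float(v) for v in g.attrs["spacing_mm"]),
            origin=tuple(float(v) for v in g.attrs["origin_mm"]),
        )
        structures = {}
        for name, ds in g["structures"].items():
            n = int(ds.attrs["n_voxels"])
            bits = np.unpackbits(ds[:])[:n].astype(bool)
            structures[name] = bits.reshape(grid.shape)
    return VoxelPhantom(grid=grid, structures=structures)


def save_dij_set(path, Dks, scenario_set):
    """Per-scenario dose-influence matrices in sparse triplet layout."""
    with h5py.File(path, "w") as f:
        g = f.create_group("dij")
        g.attrs["n_scenarios"] = len(Dks)
        g.create_dataset("shifts_mm", data=np.asarray(scenario_set.shifts_mm))
        g.create_dataset("weights", data=np.asarray(scenario_set.weights))
        g.attrs["nominal_index"] = scenario_set.nominal_index
        g.attrs["tag"] = scenario_set.tag
        for k, D in enumerate(Dks):
            _write_sparse(g, f"scenario_{k:03d}", getattr(D, "matrix", D))


def load_dij_matrices(path) -> list[sparse.csr_matrix]:
    with h5py.File(path, "r") as f:
        g = f["dij"]
        K = int(g.attrs["n_scenarios"])
        return [_read_sparse(g, f"scenario_{k:03d}") for k in range(K)]


def save_interval_model(path, model):
    with h5py.File(path, "w") as f:
        g = f.create_group("interval_model")
        _write_sparse(g, "center", model.center)
        g.create_dataset("sigmas", data=model.comp.sigmas)
        g.attrs["variance_explained"] = model.comp.variance_explained
        g.attrs["n_scenarios"] = model.comp.n_scenarios
        if model.scenario_shifts_mm is not None:
            g.create_dataset("scenario_shifts_mm", data=model.scenario_shifts_mm)
        mg = g.create_group("modes")
        for r, phi in enumerate(model.comp.modes):
            _write_sparse(mg, f"mode_{r:03d}", phi)


def load_interval_model(path):
    from .interval_model import CompressedRadius, IntervalDoseModel

    with h5py.File(path, "r") as f:
        g = f["interval_model"]
        center = _read_sparse(g, "center")
        sigmas = g["sigmas"][:]
        modes = [_read_sparse(g["modes"], f"mode_{r:03d}") for r in range(len(sigmas))]
        comp = CompressedRadius(
            sigmas=sigmas,
            modes=modes,
            variance_explained=float(g.attrs["variance_explained"]),
            n_scenarios=int(g.attrs["n_scenarios"]),
            _n_voxels=center.shape[0],
        )
        shifts = g["scenario_shifts_mm"][:] if "scenario_shifts_mm" in g else None
    return IntervalDoseModel(center=center, comp=comp, scenario_shifts_mm=shifts)
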