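"""File formats and run manifests.

One HDF5 container family serves rasters, model checkpoints, and simulator
ground truth; CSV/JSON is used only for reports.  Checkpoints store named
arrays "W", "bv", "bh" (plus "U", "binit" for an RTRBM) with a metadata
group recording the model kind and layer sizes; any checkpoint whose W
matches the data's visible side can donate W for transfer learning.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .model_core import RBMParams, RTRBMParams, SpikeRaster

__all__ = [
    "read_raster", "write_raster",
    "read_checkpoint", "write_checkpoint",
    "write_ground_truth", "read_ground_truth",
    "RunManifest", "write_manifest",
]


def write_raster(raster: SpikeRaster, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=raster.values, compression="gzip")
        meta = f.create_group("meta")
        meta.attrs["kind"] = "spike_raster"
        if raster.dt is not None:
            meta.attrs["dt"] = float(raster.dt)
        if raster.unit_ids is not None:
            meta.create_dataset("unit_ids",
                                data=np.asarray(raster.unit_ids, dtype="S"))


def read_raster(path) -> SpikeRaster:
    """Read a raster container; plain matrix files (a lone "values" or single
    dataset, no metadata) are accepted with dt=1 and a warning."""
    import warnings
    with h5py.File(path, "r") as f:
        if "values" in f:
            values = f["values"][()]
        else:
            dsets = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
            if len(dsets) != 1:
                raise ValueError(f"{path}: no 'values' array found")
            values = f[dsets[0]][()]
        dt, unit_ids = None, None
        if "meta" in f:
            meta = f["meta"]
            dt = float(meta.attrs["dt"]) if "dt" in meta.attrs else None
            if "unit_ids" in meta:
                unit_ids = [u.decode() if isinstance(u, bytes) else str(u)
                            for u in meta["unit_ids"][()]]
        else:
            warnings.warn(f"{path}: no metadata group; assuming dt=1")
            dt = 1.0
    return SpikeRaster(values, dt=dt, unit_ids=unit_ids)


def write_checkpoint(params: RBMParams | RTRBMParams, path, seed=None):
    kind = "rtrbm" if isinstance(params, RTRBMParams) else "rbm"
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=params.W)
        f.create_dataset("bv", data=params.bv)
        f.create_dataset("bh", data=params.bh)
        if kind == "rtrbm":
            f.create_dataset("U", data=params.U)
            f.create_dataset("binit", data=params.binit)
        meta = f.create_group("meta")
        meta.attrs["kind"] = kind
        meta.attrs["n_visible"] = params.n_visible
        meta.attrs["n_hidden"] = params.n_hidden
        # W is stored hidden-major (Nh × Nv): the energy interaction is hᵀWv
        meta.attrs["w_layout"] = "hidden_major"
        if seed is not None:
            meta.attrs["seed"] = int(seed)


def read_checkpoint(path, expect: str | None = None):
    with h5py.File(path, "r") as f:
        if "W" not in f:
            raise ValueError(f"{path}: missing array 'W'")
        kind = f["meta"].attrs["kind"] if "meta" in f and "kind" in f["meta"].attrs \
            else ("rtrbm" if "U" in f else "rbm")
        if expect is not None and kind != expect:
            raise ValueError(f"{path}: checkpoint kind is '{kind}', expected '{expect}'")
        W = f["W"][()]
        bv = f["bv"][()] if "bv" in f else np.zeros(W.shape[1])
        bh = f["bh"][()] if "bh" in f else np.zeros(W.shape[0])
        if kind == "rtrbm":
            if "U" not in f or "binit" not in f:
                raise ValueError(f"{path}: RTRBM checkpoint missing 'U' or 'binit'")
            return RTRBMParams(W, f["U"][()], bv, bh, f["binit"][()])
        return RBMParams(W, bv, bh)


def write_ground_truth(sim_output, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=sim_output.rates)
        f.create_dataset("intrinsic_rates", data=sim_output.intrinsic_rates)
        f.create_dataset("membership", data=sim_output.membership)
        f.create_dataset("scales", data=sim_output.scales)
        f.create_dataset("U_true", data=sim_output.U_true)


def read_ground_truth(path) -> dict:
    with h5py.File(path, "r") as f:
        return {k: f[k][()] for k in ("rates", "intrinsic_rates", "membership",
                                      "scales", "U_true") if k in f}


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict
    inputs: list
    outputs: list
    package_version: str = "0.1.0"
    wall_time_s: float = 0.0


def write_manifest(manifest: RunManifest, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as f:
        json.dump({
            "command": manifest.command,
            "config": manifest.config,
            "seeds": manifest.seeds,
            "inputs": [str(p) for p in manifest.inputs],
            "outputs": [str(p) for p in manifest.outputs],
            "package_version": manifest.package_version,
            "wall_time_s": manifest.wall_time_s,
        }, f, indent=2, default=str)
    return path
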