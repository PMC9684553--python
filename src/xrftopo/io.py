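"""File formats: the HDF5 map container, grid HDF5, float TIFF maps
and YAML specs.

Container layout:

    /xrf/<detector>/<element_line>   2D float count maps
    /stxm                            2D transmission map
    /meta                            attrs: beam, geometry, version, seed

Grids are stored as ``occupancy``, ``density`` and
``fractions/<element>`` datasets.  All maps are written (y, x) with
pixel (0, 0) at the North-West corner.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .forward import XRFMapSet
from .grid import VoxelGrid
from .phantom import PhantomSpec

__all__ = [
    "write_map_container", "read_map_container",
    "write_grid", "read_grid",
    "write_tiff", "read_tiff",
    "write_phantom_spec", "read_phantom_spec",
    "ContainerError",
]


class ContainerError(ValueError):
    """Malformed or incomplete map container."""


def write_map_container(mapset: XRFMapSet, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("xrf")
        for det, dmaps in mapset.maps.items():
            gd = g.create_group(det)
            for key, arr in dmaps.items():
                gd.create_dataset(key, data=np.asarray(arr, dtype=np.float64))
        f.create_dataset("stxm", data=np.asarray(mapset.stxm, dtype=np.float64))
        meta = f.create_group("meta")
        meta.attrs["version"] = __version__
        for k, v in mapset.meta.items():
            if v is None:
                continue
            meta.attrs[k] = json.dumps(v) if isinstance(v, (list, dict)) else v
    return path


def read_map_container(path) -> XRFMapSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "stxm" not in f:
            raise ContainerError(f"{path}: missing dataset /stxm")
        if "xrf" not in f:
            raise ContainerError(f"{path}: missing group /xrf")
        stxm = f["stxm"][()]
        maps = {}
        for det in f["xrf"]:
            maps[det] = {}
            for key in f["xrf"][det]:
                arr = f["xrf"][det][key][()]
                if arr.shape != stxm.shape:
                    raise ContainerError(
                        f"{path}: /xrf/{det}/{key} shape {arr.shape} "
                        f"inconsistent with /stxm {stxm.shape}"
                    )
                maps[det][key] = arr
        meta = {}
        if "meta" in f:
            for k, v in f["meta"].attrs.items():
                if isinstance(v, str) and v[:1] in "[{":
                    try:
                        v = json.loads(v)
                    except json.JSONDecodeError:
                        pass
                meta[k] = v
    return XRFMapSet(maps=maps, stxm=stxm, meta=meta)


def write_grid(grid: VoxelGrid, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("occupancy", data=grid.occupancy)
        f.create_dataset("density", data=grid.density)
        g = f.create_group("fractions")
        for sym, w in grid.fractions.items():
            g.create_dataset(sym, data=w)
        f.attrs["voxel_size"] = grid.voxel_size
        f.attrs["version"] = __version__
    return path


def read_grid(path) -> VoxelGrid:
    with h5py.File(path, "r") as f:
        return VoxelGrid(
            voxel_size=float(f.attrs["voxel_size"]),
            occupancy=f["occupancy"][()].astype(bool),
            density=f["density"][()],
            fractions={s: f["fractions"][s][()] for s in f.get("fractions", [])},
        )


def write_tiff(array: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_phantom_spec(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    doc = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size": spec.voxel_size,
        "hemispheres": [list(h) for h in spec.hemispheres],
        "base_fractions": dict(spec.base_fractions),
        "density": spec.density,
        "mg_rois": [list(r) for r in spec.mg_rois],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_phantom_spec(path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return PhantomSpec(
        grid_shape=tuple(doc["grid_shape"]),
        voxel_size=float(doc.get("voxel_size", 1.0)),
        hemispheres=tuple(tuple(h) for h in doc.get("hemispheres", [])),
        base_fractions=dict(doc["base_fractions"]),
        density=float(doc["density"]),
        mg_rois=tuple(tuple(r) for r in doc.get("mg_rois", [])),
    )
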