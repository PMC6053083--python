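"""File formats: TIFF stacks with YAML/JSON sidecars, map output, HDF5.

Stacks are stored as multi-page TIFF (pages = frames, axis order
(frame, y, x)) next to a sidecar file carrying the scan geometry, PSF,
seed and ground truth; maps are written as 32-bit float TIFF with NaN
for undefined pixels plus a JSON metadata file. Lengths are µm and
times seconds throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
import yaml

from .calibration import DiffusionMap
from .geometry import PSFModel, ScanGeometry
from .phasor import PhaseMap
from .sim import RasterStack

__all__ = ["write_stack", "read_stack", "write_map", "read_map",
           "write_stack_hdf5", "read_stack_hdf5"]

_REQUIRED_META = ("nx", "ny", "dx", "dwell")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _geometry_to_dict(g: ScanGeometry) -> dict:
    dwell = g.dwell_profile
    return {
        "nx": int(g.nx), "ny": int(g.ny), "dx": float(g.dx),
        "dwell": float(dwell[0]) if g.has_constant_dwell else dwell.tolist(),
        "line_retrace": float(g.line_retrace),
        "frame_retrace": float(g.frame_retrace),
    }


def _geometry_from_dict(d: dict) -> ScanGeometry:
    missing = [k for k in _REQUIRED_META if k not in d]
    if missing:
        raise ValueError(f"sidecar metadata missing required fields: {missing}")
    dwell = d["dwell"]
    return ScanGeometry(
        nx=int(d["nx"]), ny=int(d["ny"]), dx=float(d["dx"]),
        dwell=np.asarray(dwell, dtype=float) if isinstance(dwell, list) else float(dwell),
        line_retrace=float(d.get("line_retrace", 0.0)),
        frame_retrace=float(d.get("frame_retrace", 0.0)),
    )


def write_stack(stack: RasterStack, path) -> Path:
    """Write a stack as multi-page float32 TIFF plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32),
                     photometric="minisblack")
    meta: dict = {"geometry": _geometry_to_dict(stack.geometry)}
    if stack.psf is not None:
        meta["psf"] = {"w0": stack.psf.w0, "wz_ratio": stack.psf.wz_ratio}
    if stack.meta:
        meta["sim"] = stack.meta
    gt = stack.ground_truth
    if gt is not None:
        if np.ndim(gt) == 0:
            meta["ground_truth_d"] = float(gt)
        else:
            gt_path = path.with_suffix(".groundtruth.tif")
            tifffile.imwrite(gt_path, np.asarray(gt, dtype=np.float32),
                             photometric="minisblack")
            meta["ground_truth_map"] = gt_path.name
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_stack(path, sidecar=None) -> RasterStack:
    """Read a multi-page TIFF stack and its sidecar metadata.

    Accepts any integer or float pixel type. Raises when the sidecar is
    missing, lists missing fields, or disagrees with the data shape.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar} not found; stack metadata "
            f"({', '.join(_REQUIRED_META)}) is required"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    geometry = _geometry_from_dict(meta["geometry"])
    if data.shape[1:] != (geometry.ny, geometry.nx):
        raise ValueError(
            f"stack shape {data.shape[1:]} does not match sidecar geometry "
            f"({geometry.ny}, {geometry.nx})"
        )
    psf = None
    if "psf" in meta:
        psf = PSFModel(float(meta["psf"]["w0"]), float(meta["psf"].get("wz_ratio", 3.0)))
    gt = meta.get("ground_truth_d")
    if "ground_truth_map" in meta:
        gt = tifffile.imread(path.parent / meta["ground_truth_map"]).astype(float)
    return RasterStack(np.asarray(data, dtype=np.float64), geometry, psf, gt,
                       meta.get("sim", {}))


def write_map(map_obj: Union[DiffusionMap, PhaseMap], path) -> Path:
    """Write a phase or diffusion map: float32 TIFF + JSON metadata.

    Undefined pixels are NaN. A diffusion map without calibration
    provenance refuses to serialize as "diffusion" — an uncalibrated
    quantity must go through a :class:`PhaseMap` instead.
    """
    path = Path(path)
    if isinstance(map_obj, DiffusionMap):
        if not map_obj.provenance.get("calibration"):
            raise ValueError(
                "refusing to write a diffusion map without a calibration id; "
                "write the phase map instead"
            )
        values = map_obj.d
        meta = {
            "kind": "diffusion", "units": "um^2/s", "m": int(map_obj.m),
            "calibration": map_obj.provenance.get("calibration"),
            "provenance": _jsonable(map_obj.provenance),
        }
    elif isinstance(map_obj, PhaseMap):
        values = map_obj.phi
        meta = {
            "kind": "phase", "units": "rad", "m": int(map_obj.m),
            "mask_kind": map_obj.mask_kind,
        }
    else:
        raise TypeError("write_map accepts DiffusionMap or PhaseMap")
    out = np.where(np.isfinite(values), values, np.nan).astype(np.float32)
    tifffile.imwrite(path, out, photometric="minisblack")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_map(path):
    """Read a map written by :func:`write_map`: (values, metadata)."""
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    return values, meta


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def write_stack_hdf5(stack: RasterStack, path) -> Path:
    """HDF5 container mirroring the TIFF + sidecar layout."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=np.asarray(stack.data, dtype=np.float32))
        geo = fh.create_group("geometry")
        for k, v in _geometry_to_dict(stack.geometry).items():
            geo.attrs[k] = v
        if stack.psf is not None:
            psf = fh.create_group("psf")
            psf.attrs["w0"] = stack.psf.w0
            psf.attrs["wz_ratio"] = stack.psf.wz_ratio
        if stack.ground_truth is not None:
            fh.create_dataset("ground_truth", data=np.asarray(stack.ground_truth))
        sim = fh.create_group("sim")
        for k, v in (stack.meta or {}).items():
            try:
                sim.attrs[k] = v
            except TypeError:
                sim.attrs[k] = json.dumps(v)
    return path


def read_stack_hdf5(path) -> RasterStack:
    import h5py

    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        geometry = _geometry_from_dict(dict(fh["geometry"].attrs))
        psf = None
        if "psf" in fh:
            psf = PSFModel(float(fh["psf"].attrs["w0"]),
                           float(fh["psf"].attrs.get("wz_ratio", 3.0)))
        gt = fh["ground_truth"][()] if "ground_truth" in fh else None
        if gt is not None and np.ndim(gt) == 0:
            gt = float(gt)
        meta = dict(fh["sim"].attrs) if "sim" in fh else {}
    return RasterStack(np.asarray(data, dtype=np.float64), geometry, psf, gt, meta)
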