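"""HDF5 container I/O for 4D datasets.

Layout (format ``sedlab-4d``, version 1)::

    /counts                4D array (scan_y, scan_x, k_y, k_x)
    /counts attrs          units = "electrons"
    /axes attrs            scan_step_nm, detector_cal_invA,
                           rotation_offset_deg, beam_center_xy (optional)
    /acquisition attrs     kv, alpha_mrad, current_pa, dwell_ms (optional)
    root attrs             format, version, flags (JSON list)

A plain-array import path is provided for fixtures: a ``.npy`` 4D array with
an optional YAML sidecar (same stem, ``.yaml``) carrying the axis metadata.
Missing calibrations load with documented defaults and an ``uncalibrated-*``
flag rather than failing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .datamodel import Dataset4D
from .errors import DataError, FormatError
from .optics import AcquisitionGeometry

__all__ = ["save_dataset", "load_dataset"]

_FORMAT = "sedlab-4d"
_VERSION = 1


def save_dataset(ds: Dataset4D, path) -> Path:
    """Write a :class:`Dataset4D` to the documented HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["version"] = _VERSION
        f.attrs["flags"] = json.dumps(list(ds.flags))
        d = f.create_dataset("counts", data=ds.counts)
        d.attrs["units"] = "electrons"
        ax = f.create_group("axes")
        ax.attrs["scan_step_nm"] = ds.scan_step
        ax.attrs["detector_cal_invA"] = ds.detector_cal
        ax.attrs["rotation_offset_deg"] = ds.rotation_offset
        if ds.beam_center is not None:
            ax.attrs["beam_center_xy"] = np.asarray(ds.beam_center, dtype=float)
        if ds.geometry is not None:
            g = f.create_group("acquisition")
            g.attrs["kv"] = ds.geometry.kv
            g.attrs["alpha_mrad"] = ds.geometry.alpha_mrad
            g.attrs["current_pa"] = ds.geometry.current_pa
            g.attrs["dwell_ms"] = ds.geometry.dwell_ms
    return path


def _load_hdf5(path: Path) -> Dataset4D:
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError(f"{path}: no /counts dataset (4D signal missing)")
        counts = f["counts"][...]
        if counts.ndim != 4:
            raise FormatError(f"{path}: /counts has ndim={counts.ndim}, expected 4")
        flags = json.loads(f.attrs.get("flags", "[]"))
        meta = dict(f["axes"].attrs) if "axes" in f else {}
        geometry = None
        if "acquisition" in f:
            a = f["acquisition"].attrs
            geometry = AcquisitionGeometry(
                kv=float(a["kv"]),
                alpha_mrad=float(a["alpha_mrad"]),
                current_pa=float(a["current_pa"]),
                dwell_ms=float(a["dwell_ms"]),
            )
    return _assemble(counts, meta, flags, geometry, path)


def _assemble(counts, meta, flags, geometry, path) -> Dataset4D:
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer) and not np.all(np.isfinite(counts)):
        raise DataError(f"{path}: counts contain non-finite values")
    flags = list(flags)
    if "scan_step_nm" not in meta:
        flags.append("uncalibrated-scan")
    if "detector_cal_invA" not in meta:
        flags.append("uncalibrated-detector")
    bc = meta.get("beam_center_xy")
    return Dataset4D(
        counts,
        scan_step=float(meta.get("scan_step_nm", 1.0)),
        detector_cal=float(meta.get("detector_cal_invA", 1.0)),
        rotation_offset=float(meta.get("rotation_offset_deg", 0.0)),
        beam_center=None if bc is None else (float(bc[0]), float(bc[1])),
        geometry=geometry,
        flags=flags,
    )


def _load_raw(path: Path) -> Dataset4D:
    counts = np.load(path)
    if counts.ndim != 4:
        raise FormatError(f"{path}: raw array has ndim={counts.ndim}, expected 4")
    sidecar = path.with_suffix(".yaml")
    meta, flags, geometry = {}, [], None
    if sidecar.exists():
        cfg = yaml.safe_load(sidecar.read_text()) or {}
        meta = {k: cfg[k] for k in
                ("scan_step_nm", "detector_cal_invA", "rotation_offset_deg",
                 "beam_center_xy") if k in cfg}
        flags = cfg.get("flags", [])
        if "acquisition" in cfg:
            geometry = AcquisitionGeometry(**cfg["acquisition"])
    return _assemble(counts, meta, flags, geometry, path)


def load_dataset(path) -> Dataset4D:
    """Load a 4D dataset from HDF5 (or a raw ``.npy`` + YAML sidecar)."""
    path = Path(path)
    if path.suffix == ".npy":
        return _load_raw(path)
    if not h5py.is_hdf5(path):
        raise FormatError(f"{path} is not an HDF5 container or .npy array")
    return _load_hdf5(path)
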