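"""Time-series readers and writers for detector records.

The interchange default is delimited text with header columns
``time,X,Y,SUM`` and ``# key: value`` provenance comments; an HDF5
container with the same schema is available for long records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import QPDRecord

__all__ = ["read_timeseries", "write_timeseries"]

_REQUIRED = ("time", "X", "Y", "SUM")
_UNIFORMITY_RTOL = 1e-6


def _infer_sampling_rate(times: np.ndarray) -> float:
    if len(times) < 2:
        raise ValueError("need at least 2 samples to infer the sampling rate")
    dt = np.diff(times)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.any(np.abs(dt - dt_med) > _UNIFORMITY_RTOL * dt_med):
        raise ValueError("time grid is not uniform to 1 part in 1e6")
    return 1.0 / dt_med


def read_timeseries(path: str | Path, fmt: str = "auto",
                    particle_id: str | None = None) -> QPDRecord:
    """Load a detector record, validating schema, grid uniformity and SUM.

    ``fmt`` is ``csv``, ``hdf5`` or ``auto`` (by file extension).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            data = {c: fh[c][:] for c in _REQUIRED if c in fh}
            missing = set(_REQUIRED) - set(data)
            if missing:
                raise ValueError(f"{path}: missing dataset(s) {sorted(missing)}")
            fs = float(fh.attrs.get("sampling_rate", 0)) or _infer_sampling_rate(data["time"])
            pid = particle_id or str(fh.attrs.get("particle_id", path.stem))
    else:
        df = pd.read_csv(path, comment="#")
        missing = set(_REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        data = {c: df[c].to_numpy(dtype=float) for c in _REQUIRED}
        fs = _infer_sampling_rate(data["time"])
        pid = particle_id or path.stem
    if np.any(data["SUM"] <= 0):
        idx = int(np.argmax(data["SUM"] <= 0))
        raise ValueError(f"{path}: non-positive SUM at sample {idx}")
    _infer_sampling_rate(data["time"])  # uniformity check for hdf5 path too
    return QPDRecord(times=data["time"], X=data["X"], Y=data["Y"], SUM=data["SUM"],
                     sampling_rate=fs, particle_id=pid)


def write_timeseries(qpd: QPDRecord, path: str | Path, fmt: str = "auto",
                     header: dict | None = None) -> Path:
    """Write a record as delimited text (default) or HDF5.

    ``header`` entries become ``# key: value`` comment lines (csv) or file
    attributes (hdf5); sampling rate and particle id are always recorded.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    meta = {"sampling_rate": qpd.sampling_rate, "particle_id": qpd.particle_id}
    meta.update(header or {})
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time", data=qpd.times)
            fh.create_dataset("X", data=qpd.X)
            fh.create_dataset("Y", data=qpd.Y)
            fh.create_dataset("SUM", data=qpd.SUM)
            for k, v in meta.items():
                fh.attrs[k] = v
    else:
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("time,X,Y,SUM\n")
            for row in zip(qpd.times, qpd.X, qpd.Y, qpd.SUM):
                fh.write(",".join(f"{v:.12g}" for v in row) + "\n")
    return path
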