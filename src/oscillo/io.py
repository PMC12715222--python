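"""Reading and writing the on-disk containers.

SignalTrace lives in HDF5 (``/signal`` float32 dataset with
``sampling_rate_hz``, ``units`` and ``t0`` attributes), or alternatively a
flat float32 binary with a JSON sidecar.  Schedules, motion traces and
trajectories use the CSV dialects defined on their classes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import SignalTrace, ValidationError


def write_signal_h5(trace: SignalTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=trace.samples.astype(np.float32))
        ds.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
        ds.attrs["units"] = "uV"
        ds.attrs["t0"] = trace.t0
        ds.attrs["provenance"] = json.dumps(list(trace.provenance))


def read_signal_h5(path: str | Path) -> SignalTrace:
    with h5py.File(path, "r") as f:
        ds = f["signal"]
        prov = tuple(json.loads(ds.attrs.get("provenance", "[]")))
        return SignalTrace(
            ds[...].astype(np.float64),
            float(ds.attrs["sampling_rate_hz"]),
            t0=float(ds.attrs.get("t0", 0.0)),
            provenance=prov,
        )


def write_signal_binary(trace: SignalTrace, path: str | Path) -> None:
    """Flat float32 little-endian binary plus a ``.json`` sidecar."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    sidecar = {
        "dtype": "<f4",
        "sampling_rate_hz": trace.sampling_rate_hz,
        "units": "uV",
        "t0": trace.t0,
        "n_samples": trace.n_samples,
        "provenance": list(trace.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_signal_binary(path: str | Path) -> SignalTrace:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.fromfile(path, dtype=meta["dtype"]).astype(np.float64)
    if len(data) != meta["n_samples"]:
        raise ValidationError("binary length disagrees with sidecar n_samples")
    return SignalTrace(
        data,
        meta["sampling_rate_hz"],
        t0=meta.get("t0", 0.0),
        provenance=tuple(meta.get("provenance", [])),
    )


def read_signal_csv(path: str | Path, column: str = "value") -> SignalTrace:
    """Small-fixture CSV reader: columns ``t`` (seconds) and a value column."""
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=np.float64)
    dt = np.diff(t)
    if len(dt) == 0 or np.ptp(dt) > 1e-9 * dt.mean():
        raise ValidationError("CSV trace must be uniformly sampled")
    return SignalTrace(df[column].to_numpy(dtype=np.float64), 1.0 / dt.mean(), t0=t[0])
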