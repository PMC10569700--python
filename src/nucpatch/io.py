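"""Trace I/O: CSV and HDF5 round-trips with mandatory units metadata."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .traces import Trace

__all__ = ["read_trace", "write_trace"]

_META_PREFIX = "# "


def write_trace(trace: Trace, path) -> None:
    """Write a trace to ``path``; format chosen by extension (.csv / .h5)."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, "w") as fh:
            header = {
                "dt_ms": trace.dt,
                "t0_ms": trace.t0,
                "units": trace.units,
                **{k: v for k, v in trace.meta.items()
                   if isinstance(v, (str, int, float, bool))},
            }
            fh.write(_META_PREFIX + json.dumps(header) + "\n")
            pd.DataFrame({"t_ms": trace.t, "value": trace.values}).to_csv(
                fh, index=False
            )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("values", data=trace.values)
            ds.attrs["dt_ms"] = trace.dt
            ds.attrs["t0_ms"] = trace.t0
            ds.attrs["units"] = trace.units
            for k, v in trace.meta.items():
                if isinstance(v, (str, int, float, bool)):
                    ds.attrs[f"meta_{k}"] = v
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")


def read_trace(path, format: str | None = None) -> Trace:
    """Read a trace; format auto-detected from the extension.

    CSV files must carry a JSON metadata header line (written by
    :func:`write_trace`) or a ``sampling_khz`` column-free header; units
    are mandatory — a unit-less file is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt == "csv":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith(_META_PREFIX):
                raise ValueError(
                    "CSV trace lacks the metadata header (units are mandatory)"
                )
            try:
                header = json.loads(first[len(_META_PREFIX):])
            except json.JSONDecodeError as e:
                raise ValueError(f"malformed trace metadata header: {e}") from e
            df = pd.read_csv(fh)
        if "units" not in header:
            raise ValueError("trace file does not declare units")
        if "dt_ms" in header:
            dt = float(header["dt_ms"])
        elif "sampling_khz" in header:
            dt = 1.0 / float(header["sampling_khz"])
        else:
            raise ValueError("trace file declares neither dt_ms nor sampling_khz")
        meta = {
            k: v for k, v in header.items()
            if k not in ("dt_ms", "t0_ms", "units", "sampling_khz")
        }
        return Trace(
            df["value"].to_numpy(), dt, t0=float(header.get("t0_ms", 0.0)),
            units=str(header["units"]), meta=meta,
        )
    if fmt in ("h5", "hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["values"]
            attrs = dict(ds.attrs)
            if "units" not in attrs:
                raise ValueError("trace file does not declare units")
            meta = {
                k[len("meta_"):]: (v.item() if isinstance(v, np.generic) else v)
                for k, v in attrs.items() if k.startswith("meta_")
            }
            return Trace(
                ds[()], float(attrs["dt_ms"]), t0=float(attrs.get("t0_ms", 0.0)),
                units=str(attrs["units"]), meta=meta,
            )
    raise ValueError(f"unsupported trace format {fmt!r}")
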