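"""File formats: HDF5/raw traces, CSV tables, JSON config and results.

All CSVs are UTF-8 with a header row and units embedded in the column names
(``duration_s``, ``concentration_uM`` ...).  Traces travel as HDF5 (dataset
``/current`` in pA with ``fs``/``fc`` attributes and a provenance JSON
attribute) or, for interoperability, as raw little-endian float32 with a
JSON sidecar carrying the same metadata.  Readers validate schema and
invariants and report the offending fields or rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dwells import DwellSequence, Trace

__all__ = [
    "write_trace_h5",
    "read_trace_h5",
    "write_trace_raw",
    "read_trace_raw",
    "write_dwells_csv",
    "read_dwells_csv",
    "write_clusters_csv",
    "read_clusters_csv",
    "write_crc_csv",
    "read_crc_csv",
    "load_config",
    "save_config",
    "save_results",
    "read_write_formats",
]

DWELL_COLUMNS = ["start_s", "duration_s", "state_class", "conductance_class"]
CLUSTER_COLUMNS = [
    "patch_id", "agonist", "concentration_uM", "start_s", "end_s",
    "duration_s", "open_time_s", "popen", "n_openings",
]
CRC_COLUMNS = [
    "cell_id", "order", "agonist", "concentration_uM", "peak_current_nA",
    "is_standard",
]


class SchemaError(ValueError):
    """A file violated the declared schema or an invariant."""


def _require_columns(frame: pd.DataFrame, columns: list[str], kind: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{kind}: missing columns {missing}")


# --- traces ---------------------------------------------------------------

def write_trace_h5(path, trace: Trace) -> None:
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("current", data=trace.samples.astype(np.float32))
        ds.attrs["units"] = "pA"
        h5.attrs["fs"] = float(trace.fs)
        if trace.fc is not None:
            h5.attrs["fc"] = float(trace.fc)
        h5.attrs["provenance"] = json.dumps(trace.metadata, default=str)


def read_trace_h5(path) -> Trace:
    with h5py.File(path, "r") as h5:
        if "current" not in h5:
            raise SchemaError("trace container: missing /current dataset")
        if "fs" not in h5.attrs:
            raise SchemaError("trace container: missing required attribute 'fs'")
        samples = h5["current"][...]
        fs = float(h5.attrs["fs"])
        fc = float(h5.attrs["fc"]) if "fc" in h5.attrs else None
        meta = json.loads(h5.attrs.get("provenance", "{}"))
    return Trace(samples=samples, fs=fs, fc=fc, metadata=meta)


def write_trace_raw(path, trace: Trace) -> None:
    """Raw float32 samples plus a ``.json`` sidecar with the metadata."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    sidecar = {
        "fs": trace.fs,
        "fc": trace.fc,
        "dtype": "<f4",
        "units": "pA",
        "metadata": trace.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def read_trace_raw(path) -> Trace:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"raw trace: missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "fs" not in sidecar:
        raise SchemaError("raw trace sidecar: missing required field 'fs'")
    samples = np.fromfile(path, dtype=sidecar.get("dtype", "<f4"))
    return Trace(
        samples=samples,
        fs=float(sidecar["fs"]),
        fc=sidecar.get("fc"),
        metadata=sidecar.get("metadata", {}),
    )


# --- dwell tables ---------------------------------------------------------

def write_dwells_csv(path, dwells: DwellSequence) -> None:
    dwells.to_frame().to_csv(path, index=False)


def read_dwells_csv(path) -> DwellSequence:
    frame = pd.read_csv(path)
    _require_columns(frame, DWELL_COLUMNS, "dwell CSV")
    bad = frame.index[frame["duration_s"] <= 0]
    if len(bad):
        raise SchemaError(f"dwell CSV: non-positive duration_s at rows {list(bad[:5])}")
    return DwellSequence.from_frame(frame)


# --- cluster tables -------------------------------------------------------

def write_clusters_csv(path, table: pd.DataFrame) -> None:
    _require_columns(table, CLUSTER_COLUMNS, "cluster table")
    table.to_csv(path, index=False)


def read_clusters_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, CLUSTER_COLUMNS, "cluster CSV")
    bad = frame.index[(frame["popen"] < 0) | (frame["popen"] > 1)]
    if len(bad):
        raise SchemaError(f"cluster CSV: popen outside [0, 1] at rows {list(bad[:5])}")
    bad = frame.index[frame["duration_s"] <= 0]
    if len(bad):
        raise SchemaError(f"cluster CSV: non-positive duration_s at rows {list(bad[:5])}")
    return frame


# --- whole-cell CRC tables ------------------------------------------------

def write_crc_csv(path, table: pd.DataFrame) -> None:
    _require_columns(table, CRC_COLUMNS, "CRC table")
    table.to_csv(path, index=False)


def read_crc_csv(path) -> pd.DataFrame:
    """Read a concentration–response CSV; a ``concentration_mM`` column is
    converted to µM on load."""
    frame = pd.read_csv(path)
    if "concentration_mM" in frame.columns and "concentration_uM" not in frame.columns:
        frame["concentration_uM"] = frame.pop("concentration_mM") * 1000.0
    _require_columns(frame, CRC_COLUMNS, "CRC CSV")
    bad = frame.index[frame["concentration_uM"] <= 0]
    if len(bad):
        raise SchemaError(
            f"CRC CSV: non-positive concentration_uM at rows {list(bad[:5])}"
        )
    frame["is_standard"] = frame["is_standard"].astype(bool)
    return frame


# --- config & results -----------------------------------------------------

def load_config(path) -> dict:
    config = json.loads(Path(path).read_text())
    if not isinstance(config, dict):
        raise SchemaError("config JSON must contain an object at the top level")
    return config


def save_config(path, config: dict) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True, default=str))


def save_results(path, results: dict) -> None:
    Path(path).write_text(json.dumps(results, indent=2, default=str))


_READERS = {
    "trace_h5": read_trace_h5,
    "trace_raw": read_trace_raw,
    "dwells_csv": read_dwells_csv,
    "clusters_csv": read_clusters_csv,
    "crc_csv": read_crc_csv,
    "config_json": load_config,
}
_WRITERS = {
    "trace_h5": write_trace_h5,
    "trace_raw": write_trace_raw,
    "dwells_csv": write_dwells_csv,
    "clusters_csv": write_clusters_csv,
    "crc_csv": write_crc_csv,
    "config_json": save_config,
    "results_json": save_results,
}


def read_write_formats(path, kind: str, obj=None):
    """Dispatch load (``obj is None``) or save for a declared format kind."""
    if obj is None:
        if kind not in _READERS:
            raise ValueError(f"unknown or write-only format kind {kind!r}")
        return _READERS[kind](path)
    if kind not in _WRITERS:
        raise ValueError(f"unknown format kind {kind!r}")
    _WRITERS[kind](path, obj)
    return None
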