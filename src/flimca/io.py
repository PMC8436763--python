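"""Container I/O: HDF5 scan cubes, calibration JSON, CSV tables."""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .decode import CaTimeline
from .errors import ConfigurationError
from .simulate import ScanCube

__all__ = [
    "save_cube",
    "load_cube",
    "save_records",
    "load_records",
    "load_timeline",
]

RECORD_COLUMNS = [
    "bouton_id",
    "cell_id",
    "animal_id",
    "branch_order",
    "distance_um",
    "condition",
    "ca0_nM",
    "delta_nM",
    "qc_flags",
]


def save_cube(cube: ScanCube, path) -> None:
    """Write a ScanCube to an HDF5 container.

    Layout: datasets ``/counts`` (t, x, y, T), ``/bin_edges`` (ns) and
    scalar ``/cycle_period_ms``; ids and the stimulus time are root
    attributes.
    """
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=cube.counts, compression="gzip")
        fh.create_dataset("bin_edges", data=cube.bin_edges)
        fh.create_dataset("cycle_period_ms", data=cube.cycle_period_ms)
        if cube.ap_time_ms is not None:
            fh.attrs["ap_time_ms"] = cube.ap_time_ms
        for key, val in cube.meta.items():
            if val is not None:
                fh.attrs[key] = val


def load_cube(path) -> ScanCube:
    with h5py.File(path, "r") as fh:
        ap = fh.attrs.get("ap_time_ms")
        meta = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in fh.attrs.items()
            if k != "ap_time_ms"
        }
        return ScanCube(
            counts=fh["counts"][()],
            bin_edges=fh["bin_edges"][()],
            cycle_period_ms=float(fh["cycle_period_ms"][()]),
            ap_time_ms=None if ap is None else float(ap),
            meta=meta,
        )


def save_records(records: pd.DataFrame, path) -> None:
    """Write a bouton-record table as CSV (stable column order)."""
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    records[cols].to_csv(path, index=False)


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"bouton_id", "cell_id", "condition"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"record table missing columns: {missing}")
    return df


def load_timeline(path) -> pd.DataFrame:
    """Read a decoded-timeline CSV (written by CaTimeline.to_csv)."""
    df = pd.read_csv(path)
    missing = {"time_ms", "ca_nM", "flag"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"timeline missing columns: {missing}")
    return df
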