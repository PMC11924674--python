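"""Delimited-text persistence for spectra datasets.

Layout: one directory per dataset containing ``metadata.json`` (sidecar with
acquisition metadata and provenance) plus one CSV per record.  Processed
records are long-format ``shift_cm1,intensity`` tables; raw records are
``pixel,dark,frame_0..frame_{k-1}`` tables.  Floats are written with 17
significant digits so a write -> read round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, StructuralError
from .types import (
    AcquisitionMeta,
    ProcessedSpectrum,
    RawAcquisition,
    SpectralAxis,
    SpectraDataset,
)

__all__ = ["read_dataset", "write_dataset"]

_SIDECAR = "metadata.json"
_FLOAT_FMT = "%.17g"
_META_FIELDS = ("head_id", "tissue", "prep_method", "exposure_time_s", "laser_power_mw")


def _record_filename(meta: AcquisitionMeta) -> str:
    return (
        f"head{meta.head_id:02d}_{meta.tissue}_{meta.prep_method}_"
        f"rep{meta.replicate:03d}.csv"
    )


def write_dataset(ds: SpectraDataset, path: str | Path) -> None:
    """Write a dataset to ``path`` (created if needed), deterministically.

    Records are written in sorted key order with a fixed column order, so two
    writes of the same dataset are byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records_meta = []
    for rec in sorted(ds.records, key=lambda r: r.meta.key):
        fname = _record_filename(rec.meta)
        entry = {
            "file": fname,
            "head_id": rec.meta.head_id,
            "tissue": rec.meta.tissue,
            "prep_method": rec.meta.prep_method,
            "exposure_time_s": rec.meta.exposure_time_s,
            "laser_power_mw": rec.meta.laser_power_mw,
            "replicate": rec.meta.replicate,
        }
        if isinstance(rec, ProcessedSpectrum):
            entry["qf"] = rec.qf
            df = pd.DataFrame(
                {"shift_cm1": rec.axis.shifts, "intensity": rec.intensities}
            )
        elif isinstance(rec, RawAcquisition):
            cols = {"pixel": np.arange(rec.axis_pixels), "dark": rec.dark_frame}
            for i in range(rec.n_accumulations):
                cols[f"frame_{i}"] = rec.frames[i]
            df = pd.DataFrame(cols)
        else:  # pragma: no cover - guarded by SpectraDataset construction
            raise StructuralError(f"unknown record type {type(rec).__name__}")
        df.to_csv(path / fname, index=False, float_format=_FLOAT_FMT)
        records_meta.append(entry)

    schema = "processed" if ds.is_processed else "raw"
    if not ds.records:
        schema = ds.provenance.get("schema", "processed")
    sidecar = {
        "schema": schema,
        "provenance": ds.provenance,
        "records": records_meta,
    }
    (path / _SIDECAR).write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_dataset(path: str | Path, schema: str | None = None) -> SpectraDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Parameters
    ----------
    path : directory containing ``metadata.json`` and one CSV per record.
    schema : "raw", "processed", or None to accept whatever the sidecar says.
    """
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise SchemaError(f"no {_SIDECAR} sidecar found in {path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    file_schema = sidecar.get("schema")
    if file_schema not in ("raw", "processed"):
        raise SchemaError(f"sidecar 'schema' must be raw|processed, got {file_schema!r}")
    if schema is not None and schema != file_schema:
        raise SchemaError(f"requested schema {schema!r} but sidecar says {file_schema!r}")

    records = []
    # Replicate indices, when absent from the sidecar, are assigned in
    # file-name order within each (head, tissue, prep) group.
    counters: dict[tuple, int] = {}
    entries = sorted(sidecar.get("records", []), key=lambda e: e.get("file", ""))
    for entry in entries:
        for f in _META_FIELDS:
            if f not in entry:
                raise SchemaError(f"sidecar record missing field {f!r}: {entry}")
        group = (entry["head_id"], entry["tissue"], entry["prep_method"])
        replicate = entry.get("replicate")
        if replicate is None:
            replicate = counters.get(group, 0)
        counters[group] = max(counters.get(group, 0), int(replicate) + 1)
        meta = AcquisitionMeta(
            head_id=int(entry["head_id"]),
            tissue=entry["tissue"],
            prep_method=entry["prep_method"],
            exposure_time_s=float(entry["exposure_time_s"]),
            laser_power_mw=float(entry["laser_power_mw"]),
            replicate=int(replicate),
        )
        fpath = path / entry["file"]
        if not fpath.exists():
            raise SchemaError(f"sidecar references missing file {entry['file']!r}")
        # round_trip parsing restores the exact float64 written by %.17g
        df = pd.read_csv(fpath, float_precision="round_trip")
        if file_schema == "processed":
            if not {"shift_cm1", "intensity"} <= set(df.columns):
                raise StructuralError(
                    f"{entry['file']}: processed table needs shift_cm1,intensity"
                )
            axis = SpectralAxis(df["shift_cm1"].to_numpy())
            records.append(
                ProcessedSpectrum(
                    axis=axis,
                    intensities=df["intensity"].to_numpy(),
                    meta=meta,
                    qf=entry.get("qf"),
                )
            )
        else:
            frame_cols = sorted(
                (c for c in df.columns if c.startswith("frame_")),
                key=lambda c: int(c.split("_")[1]),
            )
            if "dark" not in df.columns or not frame_cols:
                raise StructuralError(
                    f"{entry['file']}: raw table needs dark and frame_* columns"
                )
            frames = df[frame_cols].to_numpy().T
            records.append(
                RawAcquisition(frames=frames, dark_frame=df["dark"].to_numpy(), meta=meta)
            )
    return SpectraDataset(records=records, provenance=sidecar.get("provenance", {}))
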