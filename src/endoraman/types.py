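"""Domain types for fiber-optic Raman acquisitions of intracranial tissue.

The containers mirror the acquisition protocol: a CCD records a handful of
accumulation frames plus a laser-off dark frame per probed site; conditioning
turns that into a single SNV-normalized fingerprint on the 800-1800 cm^-1
grid, tagged with the subject (head), tissue label and preparation method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import StructuralError, VocabularyError

__all__ = [
    "TISSUES",
    "PREP_METHODS",
    "SATURATION_CEILING",
    "FINGERPRINT_LO",
    "FINGERPRINT_HI",
    "DEFAULT_RESOLUTION",
    "SpectralAxis",
    "AcquisitionMeta",
    "RawAcquisition",
    "ProcessedSpectrum",
    "SpectraDataset",
]

#: Closed set of probed anatomical structures.
TISSUES = (
    "pituitary_gland",
    "optic_chiasm",
    "st_bone",
    "st_dura",
    "sphenoid_bone",
    "nasal_septum",
    "nasal_mucosa",
    "white_matter",
    "gray_matter",
)

#: Gland preparation methods; non-gland tissues are measured in place only.
PREP_METHODS = ("in_situ", "ex_situ", "in_section")

#: 16-bit CCD full-well ceiling used as the saturation bound on raw counts.
SATURATION_CEILING = 65535.0

#: Fingerprint window retained after truncation, cm^-1.
FINGERPRINT_LO = 800.0
FINGERPRINT_HI = 1800.0

#: Nominal spectral resolution of the instrument, cm^-1.
DEFAULT_RESOLUTION = 8.7

_SNV_TOL = 1e-8


@dataclass(frozen=True)
class SpectralAxis:
    """Wavenumber grid (cm^-1) shared by every spectrum of a dataset."""

    shifts: np.ndarray
    nominal_resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        if shifts.ndim != 1 or shifts.size < 2:
            raise StructuralError("spectral axis must be a 1-D array of >= 2 shifts")
        if not np.all(np.isfinite(shifts)):
            raise StructuralError("spectral axis contains non-finite values")
        if not np.all(np.diff(shifts) > 0):
            raise StructuralError("spectral axis must be strictly increasing")

    def __len__(self) -> int:
        return self.shifts.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return (
            self.shifts.shape == other.shifts.shape
            and bool(np.array_equal(self.shifts, other.shifts))
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.shifts.size, float(self.shifts[0]), float(self.shifts[-1])))


@dataclass(frozen=True)
class AcquisitionMeta:
    """Provenance of a single probed site."""

    head_id: int
    tissue: str
    prep_method: str = "in_situ"
    exposure_time_s: float = 5.0
    laser_power_mw: float = 40.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise VocabularyError(
                f"unknown tissue label {self.tissue!r}; expected one of {TISSUES}"
            )
        if self.prep_method not in PREP_METHODS:
            raise VocabularyError(
                f"unknown prep_method {self.prep_method!r}; expected one of {PREP_METHODS}"
            )
        if self.prep_method != "in_situ" and self.tissue != "pituitary_gland":
            raise VocabularyError(
                "ex_situ/in_section preparations exist only for the pituitary gland"
            )
        if int(self.head_id) < 1:
            raise VocabularyError("head_id must be a positive integer")
        if self.exposure_time_s <= 0 or self.laser_power_mw <= 0:
            raise VocabularyError("exposure time and laser power must be positive")

    @property
    def key(self) -> tuple[int, str, str, int]:
        return (self.head_id, self.tissue, self.prep_method, self.replicate)


@dataclass
class RawAcquisition:
    """Accumulation frames plus the matching laser-off dark frame."""

    frames: np.ndarray  # (n_accumulations, n_pixels) counts
    dark_frame: np.ndarray  # (n_pixels,) counts
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.dark_frame = np.asarray(self.dark_frame, dtype=float)
        if self.dark_frame.ndim != 1:
            raise StructuralError("dark frame must be 1-D")
        if self.frames.shape[1] != self.dark_frame.size:
            raise StructuralError(
                f"frame width {self.frames.shape[1]} != dark frame length "
                f"{self.dark_frame.size}"
            )
        if np.any(self.frames < 0) or np.any(self.dark_frame < 0):
            raise StructuralError("raw counts must be non-negative")
        if np.any(self.frames > SATURATION_CEILING):
            raise StructuralError(
                f"raw counts exceed the saturation ceiling {SATURATION_CEILING}"
            )

    @property
    def axis_pixels(self) -> int:
        return self.frames.shape[1]

    @property
    def n_accumulations(self) -> int:
        return self.frames.shape[0]


@dataclass
class ProcessedSpectrum:
    """SNV-normalized fingerprint restricted to the 800-1800 cm^-1 window."""

    axis: SpectralAxis
    intensities: np.ndarray
    meta: AcquisitionMeta
    qf: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.axis),):
            raise StructuralError("intensity vector does not match its axis")
        s = self.axis.shifts
        if s[0] < FINGERPRINT_LO - 1e-9 or s[-1] > FINGERPRINT_HI + 1e-9:
            raise StructuralError(
                "processed axis must lie within the "
                f"[{FINGERPRINT_LO}, {FINGERPRINT_HI}] cm^-1 fingerprint window"
            )
        m = float(self.intensities.mean())
        sd = float(self.intensities.std())  # population convention
        if abs(m) > _SNV_TOL or abs(sd - 1.0) > _SNV_TOL:
            raise StructuralError(
                f"intensities are not SNV-normalized (mean={m:.3g}, sd={sd:.6g})"
            )


@dataclass
class SpectraDataset:
    """Ordered collection of raw or processed records plus provenance.

    Record keys ``(head_id, tissue, prep_method, replicate)`` are unique.
    """

    records: list  # list[RawAcquisition] or list[ProcessedSpectrum]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.meta.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise StructuralError(f"duplicate record keys: {dupes[:3]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    @property
    def is_processed(self) -> bool:
        return bool(self.records) and isinstance(self.records[0], ProcessedSpectrum)

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted({r.meta.tissue for r in self.records}))

    @property
    def heads(self) -> tuple[int, ...]:
        return tuple(sorted({r.meta.head_id for r in self.records}))

    def subset(
        self,
        tissue: str | Sequence[str] | None = None,
        prep_method: str | Sequence[str] | None = None,
        heads: Sequence[int] | None = None,
    ) -> "SpectraDataset":
        """Filtered view (new dataset, shared record objects)."""

        def _as_set(v):
            if v is None:
                return None
            return {v} if isinstance(v, str) else set(v)

        tset, pset = _as_set(tissue), _as_set(prep_method)
        hset = set(heads) if heads is not None else None
        recs = [
            r
            for r in self.records
            if (tset is None or r.meta.tissue in tset)
            and (pset is None or r.meta.prep_method in pset)
            and (hset is None or r.meta.head_id in hset)
        ]
        return SpectraDataset(records=recs, provenance=dict(self.provenance))

    def to_matrix(self) -> tuple[np.ndarray, SpectralAxis, pd.DataFrame]:
        """Stack processed records into (X, axis, metadata frame).

        All records must share one axis; rows of the metadata frame align
        with rows of X.
        """
        if not self.records:
            raise StructuralError("cannot build a matrix from an empty dataset")
        if not self.is_processed:
            raise StructuralError("to_matrix requires processed records")
        axis = self.records[0].axis
        for r in self.records:
            if r.axis != axis:
                raise StructuralError("records do not share a common spectral axis")
        X = np.vstack([r.intensities for r in self.records])
        meta = pd.DataFrame(
            {
                "head_id": [r.meta.head_id for r in self.records],
                "tissue": [r.meta.tissue for r in self.records],
                "prep_method": [r.meta.prep_method for r in self.records],
                "replicate": [r.meta.replicate for r in self.records],
                "qf": [r.qf for r in self.records],
            }
        )
        return X, axis, meta

    def with_records(self, records: list) -> "SpectraDataset":
        return SpectraDataset(records=records, provenance=dict(self.provenance))


def renumber_replicates(records: list) -> list:
    """Assign replicate indices in order within each (head, tissue, prep)."""
    counters: dict[tuple, int] = {}
    out = []
    for r in records:
        k = (r.meta.head_id, r.meta.tissue, r.meta.prep_method)
        idx = counters.get(k, 0)
        counters[k] = idx + 1
        out.append(replace_meta(r, replicate=idx))
    return out


def replace_meta(record, **changes):
    """Return a copy of a record with meta fields replaced."""
    new_meta = replace(record.meta, **changes)
    if isinstance(record, RawAcquisition):
        return RawAcquisition(record.frames, record.dark_frame, new_meta)
    return ProcessedSpectrum(record.axis, record.intensities, new_meta, record.qf)
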