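"""Spectral quality factor (QF) and dataset gating.

The QF of an SNV-normalized fingerprint r is the average signed squared
intensity, (1/N) sum sgn(r_i) r_i^2.  Because SNV fixes sum r_i^2 = N, the
statistic is bounded in (-1, 1]: pure stochastic noise scores ~0, a few
large narrow peaks score close to 1.  Records below a cutoff (default 0.3)
are discarded before similarity analysis and model training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .types import ProcessedSpectrum, SpectraDataset

__all__ = ["quality_factor", "gate", "QualityReport", "DEFAULT_QF_THRESHOLD"]

DEFAULT_QF_THRESHOLD = 0.3
_NORM_TOL = 1e-6


def quality_factor(r: np.ndarray) -> float:
    """QF = (1/N) sum sgn(r_i) * r_i^2 of an SNV-normalized spectrum.

    Raises :class:`ContractError` if the input is not SNV-normalized
    (|mean| or |sd - 1| beyond 1e-6, population convention).
    """
    r = np.asarray(r, float)
    if r.ndim != 1 or r.size < 2:
        raise ContractError("QF expects a 1-D spectrum of >= 2 bins")
    if abs(float(r.mean())) > _NORM_TOL or abs(float(r.std()) - 1.0) > _NORM_TOL:
        raise ContractError(
            "QF is defined on SNV-normalized input (mean 0, population sd 1)"
        )
    return float(np.mean(np.sign(r) * r**2))


@dataclass
class QualityReport:
    """Outcome of gating a dataset at a QF threshold."""

    threshold: float
    qf_by_key: dict = field(default_factory=dict)
    kept_keys: list = field(default_factory=list)
    eliminated_keys: list = field(default_factory=list)
    counts_before: dict = field(default_factory=dict)
    counts_after: dict = field(default_factory=dict)

    @property
    def n_eliminated(self) -> int:
        return len(self.eliminated_keys)

    @property
    def eliminated_fraction(self) -> float:
        total = len(self.kept_keys) + len(self.eliminated_keys)
        return self.n_eliminated / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Per-tissue counts before/after gating."""
        tissues = sorted(self.counts_before)
        return pd.DataFrame(
            {
                "tissue": tissues,
                "before": [self.counts_before[t] for t in tissues],
                "after": [self.counts_after.get(t, 0) for t in tissues],
            }
        )


def gate(
    ds: SpectraDataset, threshold: float = DEFAULT_QF_THRESHOLD
) -> tuple[SpectraDataset, QualityReport]:
    """Eliminate records with QF below ``threshold`` (inclusive keep).

    QF values are computed where missing and stamped onto the kept records.
    Returns the filtered dataset and a :class:`QualityReport`.
    """
    report = QualityReport(threshold=threshold)
    kept_records = []
    for rec in ds.records:
        if not isinstance(rec, ProcessedSpectrum):
            raise ContractError("gate requires a processed dataset")
        qf = rec.qf if rec.qf is not None else quality_factor(rec.intensities)
        report.qf_by_key[rec.meta.key] = qf
        report.counts_before[rec.meta.tissue] = (
            report.counts_before.get(rec.meta.tissue, 0) + 1
        )
        if qf >= threshold:
            report.kept_keys.append(rec.meta.key)
            report.counts_after[rec.meta.tissue] = (
                report.counts_after.get(rec.meta.tissue, 0) + 1
            )
            kept_records.append(
                ProcessedSpectrum(rec.axis, rec.intensities, rec.meta, qf=qf)
            )
        else:
            report.eliminated_keys.append(rec.meta.key)
    if ds.records and not kept_records:
        warnings.warn(
            f"QF gate at {threshold} eliminated every record", stacklevel=2
        )
    prov = dict(ds.provenance)
    prov["qf_threshold"] = threshold
    return SpectraDataset(records=kept_records, provenance=prov), report
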