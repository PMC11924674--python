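"""Spectral angle mapper (SAM) and descriptive dataset comparisons.

SAM treats two spectra as vectors in bin space and reports the angle between
them in degrees: 0 for identical shapes, 90 for orthogonal ones.  It is
invariant to positive scaling, which makes it a convenient shape-similarity
summary for mean fingerprints; on SNV-normalized spectra negative components
are allowed and the arccos argument is clipped for numerical safety.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError, StructuralError
from .types import SpectraDataset

__all__ = [
    "sam",
    "SamMatrix",
    "mean_spectrum",
    "pairwise_sam",
    "within_between_sam",
    "prep_method_comparison",
]


def sam(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral angle between two equal-length vectors, in degrees."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise StructuralError("SAM expects two matching 1-D vectors of >= 2 bins")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("SAM is undefined for an all-zero vector")
    cos = np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


@dataclass
class SamMatrix:
    """Symmetric matrix of pairwise spectral angles (degrees)."""

    labels: tuple[str, ...]
    angles: np.ndarray

    @property
    def mean_offdiagonal(self) -> float:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(self.angles[iu].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.angles, index=self.labels, columns=self.labels)

    def pair(self, a: str, b: str) -> float:
        return float(self.angles[self.labels.index(a), self.labels.index(b)])


def mean_spectrum(
    ds: SpectraDataset, tissue: str, prep_method: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise mean and population variance across a tissue's records."""
    sub = ds.subset(tissue=tissue, prep_method=prep_method)
    if len(sub) < 2:
        raise InsufficientDataError(
            f"need >= 2 records of {tissue!r} (have {len(sub)})"
        )
    X, _, _ = sub.to_matrix()
    return X.mean(axis=0), X.var(axis=0)


def pairwise_sam(ds: SpectraDataset, tissues: tuple[str, ...] | None = None) -> SamMatrix:
    """SAM between every pair of tissue mean fingerprints."""
    tissues = tissues or ds.tissues
    if len(tissues) < 2:
        raise InsufficientDataError("pairwise SAM needs >= 2 tissues")
    means = {t: mean_spectrum(ds, t)[0] for t in tissues}
    n = len(tissues)
    angles = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        angles[i, j] = angles[j, i] = sam(means[tissues[i]], means[tissues[j]])
    return SamMatrix(labels=tuple(tissues), angles=angles)


def within_between_sam(ds: SpectraDataset) -> pd.DataFrame:
    """All record-level pairwise angles, tagged within- vs between-class.

    Returns a long frame with columns tissue_a, tissue_b, angle, kind.
    Quantile summaries can be derived by grouping on (tissue_a, kind).
    """
    if not ds.records:
        raise InsufficientDataError("empty dataset")
    X, _, meta = ds.to_matrix()
    rows = []
    for i, j in combinations(range(len(ds)), 2):
        ti, tj = meta.loc[i, "tissue"], meta.loc[j, "tissue"]
        rows.append(
            {
                "tissue_a": min(ti, tj),
                "tissue_b": max(ti, tj),
                "angle": sam(X[i], X[j]),
                "kind": "within" if ti == tj else "between",
            }
        )
    return pd.DataFrame(rows, columns=["tissue_a", "tissue_b", "angle", "kind"])


def prep_method_comparison(ds: SpectraDataset) -> dict[str, pd.DataFrame]:
    """Summed variances and method-mean SAM for gland preparation methods.

    Restricted to pituitary gland records.  Returns two frames:

    - ``variance``: rows = each head plus "pooled", columns = preparation
      methods, entries = per-bin population variance summed over the axis;
    - ``sam``: rows = head/pooled, columns = the three method pairs,
      entries = SAM between the method mean fingerprints.
    """
    gland = ds.subset(tissue="pituitary_gland")
    methods = sorted(
        {r.meta.prep_method for r in gland.records},
        key=["in_situ", "ex_situ", "in_section"].index,
    )
    if len(methods) < 2:
        raise InsufficientDataError("need gland records for >= 2 preparation methods")
    heads_with_all = sorted(
        h
        for h in gland.heads
        if all(
            len(gland.subset(prep_method=m, heads=[h])) >= 2 for m in methods
        )
    )
    if not heads_with_all:
        raise InsufficientDataError(
            "no head carries >= 2 gland records for every preparation method"
        )
    var_rows, sam_rows = [], []
    # the pooled row is a paired comparison: only heads measured with every
    # method contribute, so method contrasts are not confounded with
    # between-head differences
    groups = [(str(h), [h]) for h in heads_with_all] + [("pooled", heads_with_all)]
    pairs = list(combinations(methods, 2))
    for name, heads in groups:
        sub = gland.subset(heads=heads)
        vrow: dict = {"group": name}
        means = {}
        for m in methods:
            mean, var = mean_spectrum(sub, "pituitary_gland", prep_method=m)
            vrow[m] = float(var.sum())
            means[m] = mean
        var_rows.append(vrow)
        srow: dict = {"group": name}
        for a, b in pairs:
            srow[f"{a}|{b}"] = sam(means[a], means[b])
        sam_rows.append(srow)
    return {
        "variance": pd.DataFrame(var_rows).set_index("group"),
        "sam": pd.DataFrame(sam_rows).set_index("group"),
    }
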