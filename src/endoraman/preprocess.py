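"""Six-step conditioning chain from raw CCD frames to SNV fingerprints.

Order is fixed: dark subtraction, cosmic-ray removal, axis calibration and
instrument-response correction, accumulation averaging, BubbleFill baseline
removal, Savitzky-Golay smoothing, truncation to 800-1800 cm^-1, SNV.

BubbleFill estimates the autofluorescence background as the upper envelope of
circular "bubbles" grown from below the spectrum: the largest arc that fits
under the current interval is lifted until it touches the signal, the
interval is split at the touch point, and the procedure recurses until an
interval is narrower than the minimum bubble width.  Peaks narrower than that
width survive subtraction; broader structure is absorbed into the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    CalibrationError,
    DegenerateInputError,
    EndoRamanError,
    ParameterError,
    RangeError,
    StructuralError,
)
from .types import (
    FINGERPRINT_HI,
    FINGERPRINT_LO,
    ProcessedSpectrum,
    RawAcquisition,
    SpectralAxis,
    SpectraDataset,
)

__all__ = [
    "PreprocessParams",
    "CalibrationSet",
    "subtract_dark",
    "remove_cosmic_rays",
    "calibrate_axis",
    "correct_response",
    "bubblefill_baseline",
    "smooth_sg",
    "truncate",
    "snv",
    "preprocess",
    "preprocess_dataset",
    "SNVNormalizer",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables of the conditioning chain (defaults follow the protocol)."""

    bubble_min_width: float = 50.0  # cm^-1, narrowest structure kept as baseline
    sg_order: int = 3
    sg_window: int = 1  # window 1 is an exact no-op
    truncate_lo: float = FINGERPRINT_LO
    truncate_hi: float = FINGERPRINT_HI
    despike_threshold: float = 8.0  # MAD multiples
    calib_poly_degree: int = 2

    def __post_init__(self) -> None:
        if self.bubble_min_width <= 0:
            raise ParameterError("bubble_min_width must be positive")
        if self.truncate_lo >= self.truncate_hi:
            raise ParameterError("truncate_lo must be below truncate_hi")
        if self.sg_window % 2 == 0:
            raise ParameterError("sg_window must be odd")
        if self.sg_window != 1 and self.sg_window <= self.sg_order:
            raise ParameterError("sg_window must be 1 or greater than sg_order")
        if self.despike_threshold <= 0:
            raise ParameterError("despike_threshold must be positive")
        if self.calib_poly_degree < 1:
            raise ParameterError("calib_poly_degree must be >= 1")


@dataclass
class CalibrationSet:
    """Reference material measurements used for axis/response calibration.

    ``reference_peak_pixels`` are the detected (sub)pixel positions of
    acetaminophen reference peaks, ``reference_peak_shifts`` their published
    Raman shifts, and ``response_curve`` the relative spectral response of
    the instrument sampled on the pixel axis.
    """

    reference_peak_pixels: np.ndarray
    reference_peak_shifts: np.ndarray
    response_curve: np.ndarray

    def __post_init__(self) -> None:
        self.reference_peak_pixels = np.asarray(self.reference_peak_pixels, float)
        self.reference_peak_shifts = np.asarray(self.reference_peak_shifts, float)
        self.response_curve = np.asarray(self.response_curve, float)
        if self.reference_peak_pixels.shape != self.reference_peak_shifts.shape:
            raise CalibrationError("reference pixels and shifts must align")
        if self.reference_peak_pixels.size < 2:
            raise CalibrationError("need at least two reference peaks")


def subtract_dark(raw: RawAcquisition) -> np.ndarray:
    """Subtract the laser-off dark frame from every accumulation frame.

    Negative results are permitted (they are noise around zero signal).
    """
    if raw.frames.shape[1] != raw.dark_frame.size:  # pragma: no cover
        raise StructuralError("dark frame length mismatch")
    return raw.frames - raw.dark_frame[None, :]


def remove_cosmic_rays(frames: np.ndarray, threshold: float = 8.0) -> np.ndarray:
    """Replace cosmic-ray spikes with the across-accumulation median.

    For each pixel, values exceeding the across-frame median by more than
    ``threshold`` scaled MADs are replaced by that median.  Cosmic rays are
    strictly positive transients, so only upward excursions are touched.
    With a single frame, falls back to a within-spectrum rolling-median
    despiker.  A spike present in the majority of frames at the same pixel
    equals the median and is (by design) not removed.
    """
    frames = np.atleast_2d(np.asarray(frames, float))
    if frames.shape[0] < 2:
        return _despike_single(frames[0], threshold)[None, :]
    med = np.median(frames, axis=0)
    mad = np.median(np.abs(frames - med), axis=0) * 1.4826
    spikes = frames > med + threshold * mad
    out = frames.copy()
    out[spikes] = np.broadcast_to(med, frames.shape)[spikes]
    return out


def _despike_single(spectrum: np.ndarray, threshold: float) -> np.ndarray:
    rolled = median_filter(spectrum, size=5, mode="nearest")
    resid = spectrum - rolled
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    if mad == 0:
        return spectrum.copy()
    out = spectrum.copy()
    out[resid > threshold * mad] = rolled[resid > threshold * mad]
    return out


def calibrate_axis(
    calib: CalibrationSet, n_pixels: int, degree: int = 2
) -> SpectralAxis:
    """Least-squares pixel -> cm^-1 polynomial from reference peaks.

    The fitted mapping must be strictly increasing over the pixel range.
    """
    px = calib.reference_peak_pixels
    sh = calib.reference_peak_shifts
    if px.size < degree + 1:
        raise CalibrationError(
            f"{px.size} reference peaks cannot determine a degree-{degree} fit"
        )
    coeffs = npoly.polyfit(px, sh, degree)
    shifts = npoly.polyval(np.arange(n_pixels, dtype=float), coeffs)
    if not np.all(np.diff(shifts) > 0):
        raise CalibrationError("fitted pixel->shift mapping is not monotonic")
    return SpectralAxis(shifts)


def correct_response(spectrum: np.ndarray, calib: CalibrationSet) -> np.ndarray:
    """Divide by the instrument relative response, normalized to unit mean.

    Mean-normalization removes the arbitrary scale of the response standard
    without changing spectral shape; a uniform response is a no-op.
    """
    resp = calib.response_curve
    spectrum = np.asarray(spectrum, float)
    if resp.shape[-1] != spectrum.shape[-1]:
        raise StructuralError("response curve does not match the pixel axis")
    if np.any(resp <= 0):
        raise CalibrationError("response curve must be strictly positive")
    return spectrum / (resp / resp.mean())


def bubblefill_baseline(
    shifts: np.ndarray,
    intensities: np.ndarray,
    bubble_min_width: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-bubble baseline estimation.

    Returns ``(raman, baseline)`` with ``baseline <= intensities`` and
    ``raman >= 0`` everywhere.  Bubbles are circular arcs grown in a
    coordinate frame where the axis span and the intensity range are both
    rescaled to the unit interval, so bubble geometry is comparable across
    axes; the ``bubble_min_width`` stop criterion is applied in cm^-1.
    Intervals touching the data edges use half-bubbles anchored at the edge
    so the baseline can follow rising ends.
    """
    x = np.asarray(shifts, float)
    y = np.asarray(intensities, float)
    if x.shape != y.shape or x.ndim != 1:
        raise StructuralError("shifts and intensities must be matching 1-D arrays")
    if bubble_min_width <= 0:
        raise ParameterError("bubble_min_width must be positive")
    n = x.size
    if n < 2:
        raise StructuralError("need at least two bins")
    if n == 2:
        return np.zeros(2), y.copy()  # chord through both points

    # Remove the straight chord through the endpoints; it is restored below,
    # making the method invariant to linear trends and offsets.
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    yw = y - chord
    yr = float(yw.max() - yw.min())
    if yr == 0.0:
        return np.zeros(n), y.copy()
    xs = (x - x[0]) / (x[-1] - x[0])
    ys = (yw - yw.min()) / yr
    min_w = bubble_min_width / (x[-1] - x[0])

    baseline_s = np.full(n, -np.inf)
    # (lo, hi, is_initial); the initial full-range bubble is always grown.
    stack: list[tuple[int, int, bool]] = [(0, n - 1, True)]
    while stack:
        i, j, initial = stack.pop()
        if j - i < 2:
            continue
        width = xs[j] - xs[i]
        if width < min_w and not initial:
            continue
        seg_x = xs[i : j + 1]
        seg_y = ys[i : j + 1]
        if i == 0 and j == n - 1:
            mid, radius = 0.5 * (seg_x[0] + seg_x[-1]), 0.5 * width
        elif i == 0:  # half-bubble anchored at the left data edge
            mid, radius = seg_x[0], width
        elif j == n - 1:  # half-bubble anchored at the right data edge
            mid, radius = seg_x[-1], width
        else:
            mid, radius = 0.5 * (seg_x[0] + seg_x[-1]), 0.5 * width
        arc = np.sqrt(np.maximum(radius**2 - (seg_x - mid) ** 2, 0.0))
        lift = seg_y - arc
        t_local = int(np.argmin(lift))
        bubble = arc + lift[t_local]
        np.maximum(baseline_s[i : j + 1], bubble, out=baseline_s[i : j + 1])
        t = i + t_local
        if i < t < j:
            stack.append((i, t, False))
            stack.append((t, j, False))
        elif t == i:
            # touched at the left end: keep rolling over the remainder
            stack.append((i + 1, j, False))
        else:  # touched at the right end
            stack.append((i, j - 1, False))

    baseline = baseline_s * yr + yw.min() + chord
    raman = np.maximum(y - baseline, 0.0)
    return raman, baseline


def smooth_sg(spectrum: np.ndarray, order: int = 3, window: int = 1) -> np.ndarray:
    """Savitzky-Golay smoothing; window 1 is an exact no-op."""
    if window % 2 == 0:
        raise ParameterError("Savitzky-Golay window must be odd")
    spectrum = np.asarray(spectrum, float)
    if window == 1:
        return spectrum.copy()
    if window <= order:
        raise ParameterError("Savitzky-Golay window must exceed the polynomial order")
    return savgol_filter(spectrum, window_length=window, polyorder=order)


def truncate(
    axis: SpectralAxis,
    spectrum: np.ndarray,
    lo: float = FINGERPRINT_LO,
    hi: float = FINGERPRINT_HI,
) -> tuple[SpectralAxis, np.ndarray]:
    """Keep bins with ``lo <= shift <= hi``, order preserved."""
    spectrum = np.asarray(spectrum, float)
    # tolerance absorbs float dust on gridded axes (e.g. linspace endpoints)
    eps = 1e-8 * (axis.shifts[-1] - axis.shifts[0])
    keep = (axis.shifts >= lo - eps) & (axis.shifts <= hi + eps)
    if not np.any(keep):
        raise RangeError(f"[{lo}, {hi}] cm^-1 does not intersect the axis")
    if keep.sum() == 1:
        # A single-bin "spectrum" has no SpectralAxis (needs >= 2 bins);
        # return the raw pair for callers that asked for a point.
        return axis.shifts[keep], spectrum[keep]  # type: ignore[return-value]
    return (
        SpectralAxis(axis.shifts[keep], axis.nominal_resolution),
        spectrum[keep],
    )


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd.

    Uses the population (1/N) standard deviation, the same convention as the
    quality factor's normalization.
    """
    spectrum = np.asarray(spectrum, float)
    sd = spectrum.std()
    if sd == 0:
        raise DegenerateInputError("constant spectrum cannot be SNV-normalized")
    return (spectrum - spectrum.mean()) / sd


def _stage(name: str):
    """Context that tags component errors with the failing stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, EndoRamanError):
                exc.args = (f"[stage: {name}] {exc}",)
            return False

    return _Ctx()


def preprocess(
    raw: RawAcquisition,
    calib: CalibrationSet,
    params: PreprocessParams | None = None,
) -> ProcessedSpectrum:
    """Run the full fixed-order conditioning chain on one acquisition."""
    params = params or PreprocessParams()
    with _stage("dark_subtraction"):
        frames = subtract_dark(raw)
    with _stage("cosmic_ray_removal"):
        frames = remove_cosmic_rays(frames, params.despike_threshold)
    with _stage("axis_calibration"):
        axis = calibrate_axis(calib, raw.axis_pixels, params.calib_poly_degree)
    with _stage("response_correction"):
        frames = correct_response(frames, calib)
    spectrum = frames.mean(axis=0)
    with _stage("baseline_removal"):
        raman, _ = bubblefill_baseline(axis.shifts, spectrum, params.bubble_min_width)
    with _stage("smoothing"):
        smoothed = smooth_sg(raman, params.sg_order, params.sg_window)
    with _stage("truncation"):
        axis_t, y_t = truncate(axis, smoothed, params.truncate_lo, params.truncate_hi)
    with _stage("snv"):
        y_n = snv(y_t)
    return ProcessedSpectrum(axis=axis_t, intensities=y_n, meta=raw.meta, qf=None)


def preprocess_dataset(
    ds: SpectraDataset,
    calib: CalibrationSet,
    params: PreprocessParams | None = None,
) -> SpectraDataset:
    """Condition every raw record; provenance is carried through."""
    records = []
    for raw in ds.records:
        try:
            records.append(preprocess(raw, calib, params))
        except EndoRamanError as err:
            warnings.warn(f"record {raw.meta.key} dropped: {err}", stacklevel=2)
    prov = dict(ds.provenance)
    prov["preprocess"] = (params or PreprocessParams()).__dict__.copy()
    return SpectraDataset(records=records, provenance=prov)


class SNVNormalizer(TransformerMixin, BaseEstimator):
    """Row-wise SNV transformer for feature matrices (sklearn-compatible)."""

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise StructuralError("expected a 2-D matrix of spectra")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateInputError("constant row cannot be SNV-normalized")
        return (X - X.mean(axis=1, keepdims=True)) / sd
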