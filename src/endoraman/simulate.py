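"""Synthetic nine-tissue Raman acquisition generator.

Emulates the statistical structure of a fiber-optic probe survey of lamb
intracranial tissues: per-tissue band registries on an ordinal 1-5 intensity
scale, a dominant smooth autofluorescence baseline, dark counts, shot-like
heteroscedastic noise, sporadic cosmic-ray spikes, per-head multiplicative
band effects, bone bleed-through under the thin sellar dura, and three gland
preparation methods whose spectral variability is ordered
in_situ > ex_situ > in_section.

The generator is the study-conditions oracle for the rest of the pipeline:
:func:`mean_frame` exposes the exact noise-free expectation of every frame so
conditioning stages can be tested against closed-form truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .preprocess import CalibrationSet
from .types import (
    PREP_METHODS,
    SATURATION_CEILING,
    TISSUES,
    AcquisitionMeta,
    RawAcquisition,
    SpectraDataset,
)

__all__ = [
    "BandSpec",
    "TissueProfile",
    "GeneratorConfig",
    "default_profiles",
    "default_calibration",
    "generate_raw",
    "mean_frame",
    "ACETAMINOPHEN_SHIFTS",
]

#: Published acetaminophen reference lines within the instrument range, cm^-1.
ACETAMINOPHEN_SHIFTS = (
    465.1, 651.6, 797.2, 857.9, 968.7, 1105.5,
    1168.5, 1236.8, 1323.9, 1371.5, 1561.6, 1648.4,
)


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: center, linewidth, ordinal 1-5 intensity."""

    center: float  # cm^-1
    relative_intensity: int  # asterisk scale, 1 (weakest) .. 5 (strongest)
    fwhm: float = 15.0  # cm^-1; condensed-phase linewidth, below the 50 bubble floor

    def __post_init__(self) -> None:
        if not (800.0 <= self.center <= 1800.0):
            raise ConfigError(f"band center {self.center} outside fingerprint window")
        if not (0 < self.fwhm < 50):
            raise ConfigError("band fwhm must be in (0, 50) cm^-1")
        if not (1 <= self.relative_intensity <= 5):
            raise ConfigError("relative_intensity uses the 1..5 ordinal scale")


@dataclass(frozen=True)
class TissueProfile:
    """Synthetic class definition for one anatomical structure."""

    tissue: str
    bands: tuple[BandSpec, ...]
    baseline_amplitude: float  # counts at the autofluorescence envelope scale
    baseline_shape: tuple[float, ...]  # polynomial coefficients on u in [0,1]
    noise_scale: float = 1.0
    contamination: tuple[str, float] | None = None  # (other tissue, mix fraction)


# Band registry: (center, {tissue: ordinal intensity}); tissues absent from a
# row do not carry that band.  Group columns (ST bone+dura, nasal septum+
# mucosa, cerebral matter) are expanded per tissue, including the rows where
# the groups split (961, 1437-1439, 1446-1452, 1298, 1649-1652).
_REGISTRY: tuple[tuple[float, dict[str, int]], ...] = (
    (823.5, {"pituitary_gland": 1, "nasal_septum": 1, "nasal_mucosa": 1}),
    (856.0, {"pituitary_gland": 1, "st_bone": 1, "st_dura": 1,
             "sphenoid_bone": 1, "nasal_septum": 1, "nasal_mucosa": 1}),
    (940.0, {"pituitary_gland": 1, "nasal_septum": 2, "nasal_mucosa": 2}),
    (961.0, {"pituitary_gland": 1, "optic_chiasm": 1, "st_bone": 5, "st_dura": 4,
             "sphenoid_bone": 4, "nasal_septum": 4, "nasal_mucosa": 2,
             "white_matter": 1, "gray_matter": 1}),
    (1004.0, {"pituitary_gland": 2, "optic_chiasm": 1, "st_bone": 1, "st_dura": 1,
              "nasal_septum": 2, "nasal_mucosa": 2,
              "white_matter": 1, "gray_matter": 1}),
    (1064.0, {"pituitary_gland": 2, "optic_chiasm": 2, "sphenoid_bone": 1,
              "white_matter": 1, "gray_matter": 1}),
    (1078.0, {"pituitary_gland": 2, "optic_chiasm": 1, "st_bone": 1, "st_dura": 1,
              "sphenoid_bone": 1, "white_matter": 1, "gray_matter": 1}),
    (1128.0, {"pituitary_gland": 1, "optic_chiasm": 1, "sphenoid_bone": 1,
              "nasal_septum": 1, "nasal_mucosa": 1,
              "white_matter": 2, "gray_matter": 2}),
    (1298.0, {"pituitary_gland": 1, "optic_chiasm": 2, "sphenoid_bone": 2,
              "white_matter": 2, "gray_matter": 1}),
    (1438.0, {"pituitary_gland": 3, "optic_chiasm": 4, "st_bone": 1, "st_dura": 2,
              "sphenoid_bone": 3, "nasal_septum": 2, "nasal_mucosa": 3,
              "white_matter": 4, "gray_matter": 4}),
    (1449.0, {"pituitary_gland": 4, "optic_chiasm": 3, "st_bone": 1, "st_dura": 2,
              "sphenoid_bone": 3, "nasal_septum": 3, "nasal_mucosa": 4,
              "white_matter": 3, "gray_matter": 3}),
    (1650.5, {"pituitary_gland": 3, "optic_chiasm": 2, "st_bone": 1, "st_dura": 1,
              "sphenoid_bone": 2, "nasal_septum": 2, "nasal_mucosa": 3,
              "white_matter": 2, "gray_matter": 3}),
)

# Autofluorescence envelope scale in counts; brain tissues fluoresce more
# while yielding weaker Raman signal (hence their longer exposures).
_BASELINE_AMPLITUDE = {
    "pituitary_gland": 6000.0, "optic_chiasm": 5500.0, "st_bone": 4500.0,
    "st_dura": 5000.0, "sphenoid_bone": 5200.0, "nasal_septum": 4800.0,
    "nasal_mucosa": 5600.0, "white_matter": 7000.0, "gray_matter": 7500.0,
}

# Mild per-tissue variation of the (positive) baseline polynomial on u=[0,1].
_BASELINE_SHAPE = {
    "pituitary_gland": (1.0, -0.55, 0.28, -0.05, 0.02),
    "optic_chiasm": (1.0, -0.50, 0.22, -0.04, 0.01),
    "st_bone": (1.0, -0.60, 0.30, -0.06, 0.02),
    "st_dura": (1.0, -0.58, 0.27, -0.05, 0.02),
    "sphenoid_bone": (1.0, -0.52, 0.24, -0.05, 0.02),
    "nasal_septum": (1.0, -0.56, 0.26, -0.04, 0.01),
    "nasal_mucosa": (1.0, -0.48, 0.20, -0.04, 0.02),
    "white_matter": (1.0, -0.45, 0.18, -0.03, 0.01),
    "gray_matter": (1.0, -0.42, 0.16, -0.03, 0.01),
}

_EXPOSURE_MEAN = {"white_matter": 8.9, "gray_matter": 10.1}


def default_profiles() -> dict[str, TissueProfile]:
    """Band registry expanded into one profile per tissue.

    Asterisk counts map linearly onto amplitudes (k asterisks -> k units);
    the sellar dura additionally mixes in the underlying sellar cortical
    bone signal (bleed-through of the thin membrane).
    """
    profiles: dict[str, TissueProfile] = {}
    for tissue in TISSUES:
        bands = tuple(
            BandSpec(center=c, relative_intensity=row[tissue])
            for c, row in _REGISTRY
            if tissue in row
        )
        profiles[tissue] = TissueProfile(
            tissue=tissue,
            bands=bands,
            baseline_amplitude=_BASELINE_AMPLITUDE[tissue],
            baseline_shape=_BASELINE_SHAPE[tissue],
            contamination=("st_bone", 0.35) if tissue == "st_dura" else None,
        )
    return profiles


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic survey."""

    seed: int = 0
    n_heads: int = 6
    records_per_tissue_per_head: int = 5
    tissues: tuple[str, ...] = TISSUES
    # Per-(head, band) multiplicative log-normal effect: between-individual
    # variation that the head-disjoint split is designed to stress.
    head_effect_sd: float = 0.06
    # Per-(record, band) jitter; scaled by the prep multiplier below.
    record_effect_sd: float = 0.04
    baseline_jitter_sd: float = 0.10
    cosmic_ray_rate: float = 0.1  # expected spikes per frame
    noise_scale: float = 0.7  # sd = noise_scale * sqrt(expected counts)
    dark_level: float = 100.0
    n_accumulations: int = 10
    n_pixels: int = 1601
    axis_lo: float = 400.0
    axis_hi: float = 2000.0
    amplitude_unit: float = 120.0  # counts per asterisk (A0)
    # Shape-level variability multipliers by preparation method (drives the
    # in_situ > ex_situ > in_section total-variance ordering).
    prep_variance_multipliers: dict = field(
        default_factory=lambda: {"in_situ": 1.6, "ex_situ": 1.0, "in_section": 0.55}
    )
    # Mean fraction of neighboring-tissue (sellar dura) signal contaminating
    # gland records; largest in place, smallest for sectioned glands.
    prep_contamination: dict = field(
        default_factory=lambda: {"in_situ": 0.12, "ex_situ": 0.05, "in_section": 0.01}
    )
    contamination_jitter_sd: float = 0.04  # sd of the dura->bone mix fraction
    # Relative shot-noise scale by preparation method: measuring the gland in
    # place through the nostril collects less light than bench measurement of
    # the excised (and especially the sectioned) gland, so in-place records
    # are the noisiest.  This is the dominant driver of the in_situ >
    # ex_situ > in_section total-variance ordering after normalization.
    prep_noise_multipliers: dict = field(
        default_factory=lambda: {"in_situ": 1.0, "ex_situ": 0.6, "in_section": 0.35}
    )
    prep_heads: tuple[int, ...] = (1, 2, 3)  # heads with ex_situ/in_section glands

    def __post_init__(self) -> None:
        m = self.prep_variance_multipliers
        if not (m["in_situ"] > m["ex_situ"] > m["in_section"] > 0):
            raise ConfigError(
                "prep_variance_multipliers must be strictly ordered "
                "in_situ > ex_situ > in_section > 0"
            )
        n = self.prep_noise_multipliers
        if not (n["in_situ"] > n["ex_situ"] > n["in_section"] > 0):
            raise ConfigError(
                "prep_noise_multipliers must be strictly ordered "
                "in_situ > ex_situ > in_section > 0"
            )
        unknown = set(self.tissues) - set(TISSUES)
        if unknown:
            raise ConfigError(f"unknown tissues in config: {sorted(unknown)}")
        if self.n_heads < 1 or self.records_per_tissue_per_head < 1:
            raise ConfigError("n_heads and records_per_tissue_per_head must be >= 1")


def _axis(config: GeneratorConfig) -> np.ndarray:
    return np.linspace(config.axis_lo, config.axis_hi, config.n_pixels)


def _response(shifts: np.ndarray) -> np.ndarray:
    """Smooth positive relative instrument response across the axis."""
    return 0.8 + 0.4 * np.exp(-(((shifts - 900.0) / 700.0) ** 2))


def default_calibration(config: GeneratorConfig | None = None) -> CalibrationSet:
    """Calibration set consistent with the generator's true pixel map."""
    config = config or GeneratorConfig()
    shifts = _axis(config)
    # True pixel->shift map is linear; invert it for the reference lines.
    slope = (config.axis_hi - config.axis_lo) / (config.n_pixels - 1)
    pixels = (np.array(ACETAMINOPHEN_SHIFTS) - config.axis_lo) / slope
    return CalibrationSet(
        reference_peak_pixels=pixels,
        reference_peak_shifts=np.array(ACETAMINOPHEN_SHIFTS),
        response_curve=_response(shifts),
    )


def _pseudo_voigt(shifts: np.ndarray, center: float, fwhm: float, eta: float = 0.5):
    """Unit-height pseudo-Voigt: eta Lorentzian + (1 - eta) Gaussian."""
    u = (shifts - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * u**2)
    gauss = np.exp(-4.0 * np.log(2.0) * u**2)
    return eta * lorentz + (1.0 - eta) * gauss


def _peak_sum(shifts, profile: TissueProfile, a0: float, factors=None) -> np.ndarray:
    out = np.zeros_like(shifts)
    for k, b in enumerate(profile.bands):
        amp = b.relative_intensity * a0
        if factors is not None:
            amp *= factors[k]
        out += amp * _pseudo_voigt(shifts, b.center, b.fwhm)
    return out


def _baseline(shifts, profile: TissueProfile, config: GeneratorConfig) -> np.ndarray:
    u = (shifts - config.axis_lo) / (config.axis_hi - config.axis_lo)
    poly = np.polynomial.polynomial.polyval(u, profile.baseline_shape)
    broad = 0.6 * np.exp(-4 * np.log(2) * ((shifts - 1100.0) / 600.0) ** 2)
    return profile.baseline_amplitude * (np.maximum(poly, 0.05) + broad)


def _clean_signal(
    shifts,
    profiles: dict[str, TissueProfile],
    tissue: str,
    config: GeneratorConfig,
    prep_method: str = "in_situ",
    band_factors=None,
    mix_fraction: float | None = None,
    prep_fraction: float | None = None,
) -> np.ndarray:
    """Raman peak component (counts) before baseline/response/noise."""
    profile = profiles[tissue]
    own = _peak_sum(shifts, profile, config.amplitude_unit, band_factors)
    if profile.contamination is not None:
        other, default_f = profile.contamination
        f = default_f if mix_fraction is None else mix_fraction
        own = (1.0 - f) * own + f * _peak_sum(
            shifts, profiles[other], config.amplitude_unit
        )
    if tissue == "pituitary_gland":
        g = (
            config.prep_contamination[prep_method]
            if prep_fraction is None
            else prep_fraction
        )
        if g > 0:
            own = (1.0 - g) * own + g * _peak_sum(
                shifts, profiles["st_dura"], config.amplitude_unit
            )
    return own


def mean_frame(
    config: GeneratorConfig,
    profiles: dict[str, TissueProfile],
    tissue: str,
    prep_method: str = "in_situ",
) -> np.ndarray:
    """Noise-free expected counts per pixel for one frame of a tissue.

    Equals dark level + (baseline + peak sum) x instrument response, with
    every random effect held at its central value.  This is the closed-form
    oracle the conditioning tests compare against.
    """
    shifts = _axis(config)
    peaks = _clean_signal(shifts, profiles, tissue, config, prep_method)
    optical = peaks + _baseline(shifts, profiles[tissue], config)
    return config.dark_level + optical * _response(shifts)


def generate_raw(
    config: GeneratorConfig | None = None,
    profiles: dict[str, TissueProfile] | None = None,
) -> SpectraDataset:
    """Generate a labelled raw dataset; bit-reproducible given (seed, config).

    The pituitary gland is additionally emitted under the ex_situ and
    in_section preparations for the heads listed in ``config.prep_heads``.
    """
    config = config or GeneratorConfig()
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(config.seed)
    shifts = _axis(config)
    response = _response(shifts)

    # One multiplicative log-normal factor per (head, tissue, band).
    head_factors: dict[tuple[int, str], np.ndarray] = {}
    for head in range(1, config.n_heads + 1):
        for tissue in config.tissues:
            nb = len(profiles[tissue].bands)
            head_factors[(head, tissue)] = np.exp(
                rng.normal(0.0, config.head_effect_sd, size=nb)
            )

    records = []
    for head in range(1, config.n_heads + 1):
        for tissue in config.tissues:
            profile = profiles[tissue]
            preps = ["in_situ"]
            if tissue == "pituitary_gland" and head in config.prep_heads:
                preps = list(PREP_METHODS)
            for prep in preps:
                mult = config.prep_variance_multipliers[prep]
                for rep in range(config.records_per_tissue_per_head):
                    nb = len(profile.bands)
                    band_factors = head_factors[(head, tissue)] * np.exp(
                        rng.normal(0.0, config.record_effect_sd * mult, size=nb)
                    )
                    mix = None
                    if profile.contamination is not None:
                        mix = float(
                            np.clip(
                                rng.normal(
                                    profile.contamination[1],
                                    config.contamination_jitter_sd,
                                ),
                                0.0,
                                0.9,
                            )
                        )
                    prep_frac = None
                    if tissue == "pituitary_gland":
                        g0 = config.prep_contamination[prep]
                        prep_frac = float(
                            np.clip(rng.normal(g0, 0.5 * g0 * mult), 0.0, 0.5)
                        )
                    peaks = _clean_signal(
                        shifts, profiles, tissue, config, prep,
                        band_factors=band_factors,
                        mix_fraction=mix,
                        prep_fraction=prep_frac,
                    )
                    base = _baseline(shifts, profile, config) * np.exp(
                        rng.normal(0.0, config.baseline_jitter_sd)
                    )
                    expected = config.dark_level + (peaks + base) * response
                    noise_sd = (
                        config.noise_scale
                        * config.prep_noise_multipliers[prep]
                        * np.sqrt(np.maximum(expected, 0.0))
                    )
                    frames = np.empty((config.n_accumulations, config.n_pixels))
                    for a in range(config.n_accumulations):
                        frame = expected + rng.normal(0.0, noise_sd)
                        n_rays = rng.poisson(config.cosmic_ray_rate)
                        for _ in range(n_rays):
                            px = int(rng.integers(0, config.n_pixels))
                            amp = rng.uniform(2000.0, 15000.0)
                            frame[px] += amp
                            if px + 1 < config.n_pixels:
                                frame[px + 1] += 0.3 * amp
                        frames[a] = frame
                    frames = np.clip(frames, 0.0, SATURATION_CEILING)
                    dark = np.clip(
                        config.dark_level
                        + rng.normal(
                            0.0,
                            config.noise_scale * np.sqrt(config.dark_level),
                            size=config.n_pixels,
                        ),
                        0.0,
                        SATURATION_CEILING,
                    )
                    exposure = float(
                        np.clip(
                            rng.normal(_EXPOSURE_MEAN.get(tissue, 5.0), 0.8), 3.0, 11.0
                        )
                    )
                    meta = AcquisitionMeta(
                        head_id=head,
                        tissue=tissue,
                        prep_method=prep,
                        exposure_time_s=exposure,
                        replicate=rep,
                    )
                    records.append(
                        RawAcquisition(frames=frames, dark_frame=dark, meta=meta)
                    )
    provenance = {
        "generator": "endoraman.simulate.generate_raw",
        "seed": config.seed,
        "config": _config_dict(config),
    }
    return SpectraDataset(records=records, provenance=provenance)


def _config_dict(config: GeneratorConfig) -> dict:
    d = dict(config.__dict__)
    d["tissues"] = list(config.tissues)
    d["prep_heads"] = list(config.prep_heads)
    return d
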