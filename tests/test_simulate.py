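"""Generator: band registry facts, closed-form oracle, reproducibility."""

import dataclasses

import numpy as np
import pytest

from endoraman import GeneratorConfig, default_profiles, generate_raw, mean_frame
from endoraman.errors import ConfigError
from endoraman.simulate import ACETAMINOPHEN_SHIFTS, BandSpec, _axis
from endoraman.types import PREP_METHODS, TISSUES


def _band(profile, center):
    hits = [b for b in profile.bands if abs(b.center - center) < 2.0]
    assert len(hits) == 1, f"{profile.tissue} should carry one band near {center}"
    return hits[0]


class TestRegistry:
    def test_every_tissue_has_a_profile_with_fingerprint_bands(self):
        profiles = default_profiles()
        assert set(profiles) == set(TISSUES)
        for p in profiles.values():
            assert len(p.bands) >= 4
            for b in p.bands:
                assert 800.0 <= b.center <= 1800.0
                assert 1 <= b.relative_intensity <= 5

    def test_phosphate_band_separates_bone_from_dura(self):
        # 961 cm^-1 hydroxyapatite: strongest in sellar cortical bone, one
        # step weaker through the thin dura covering it.
        profiles = default_profiles()
        assert _band(profiles["st_bone"], 961.0).relative_intensity == 5
        assert _band(profiles["st_dura"], 961.0).relative_intensity == 4

    def test_ch_deformation_bands_separate_bone_from_dura(self):
        profiles = default_profiles()
        for center in (1438.0, 1449.0):
            assert _band(profiles["st_bone"], center).relative_intensity == 1
            assert _band(profiles["st_dura"], center).relative_intensity == 2

    def test_lipid_protein_bands_separate_white_from_gray_matter(self):
        profiles = default_profiles()
        assert _band(profiles["white_matter"], 1298.0).relative_intensity == 2
        assert _band(profiles["gray_matter"], 1298.0).relative_intensity == 1
        assert _band(profiles["white_matter"], 1650.5).relative_intensity == 2
        assert _band(profiles["gray_matter"], 1650.5).relative_intensity == 3

    def test_dura_mixes_in_underlying_bone_signal(self):
        profiles = default_profiles()
        assert profiles["st_dura"].contamination == ("st_bone", 0.35)
        assert profiles["pituitary_gland"].contamination is None

    def test_band_spec_validation(self):
        with pytest.raises(ConfigError):
            BandSpec(center=700.0, relative_intensity=1)
        with pytest.raises(ConfigError):
            BandSpec(center=1000.0, relative_intensity=6)
        with pytest.raises(ConfigError):
            BandSpec(center=1000.0, relative_intensity=1, fwhm=60.0)


class TestConfigValidation:
    def test_prep_variance_ordering_enforced(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(
                prep_variance_multipliers={
                    "in_situ": 1.0, "ex_situ": 1.0, "in_section": 0.5
                }
            )

    def test_prep_noise_ordering_enforced(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(
                prep_noise_multipliers={
                    "in_situ": 0.3, "ex_situ": 0.6, "in_section": 0.2
                }
            )

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(tissues=("pituitary_gland", "cerebellum"))

    def test_positive_sizes_required(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_heads=0)


def _noise_free_config(**kw):
    return GeneratorConfig(
        seed=7,
        n_heads=2,
        records_per_tissue_per_head=1,
        head_effect_sd=0.0,
        record_effect_sd=0.0,
        baseline_jitter_sd=0.0,
        contamination_jitter_sd=0.0,
        cosmic_ray_rate=0.0,
        noise_scale=0.0,
        prep_heads=(),
        prep_contamination={"in_situ": 0.0, "ex_situ": 0.0, "in_section": 0.0},
        **kw,
    )


class TestClosedFormOracle:
    def test_zero_noise_frames_match_mean_frame(self):
        # With every random effect switched off, each accumulation frame must
        # equal the closed-form expectation exactly (up to float arithmetic).
        cfg = _noise_free_config()
        profiles = default_profiles()
        ds = generate_raw(cfg, profiles)
        for rec in ds.records:
            expected = mean_frame(cfg, profiles, rec.meta.tissue, rec.meta.prep_method)
            for frame in rec.frames:
                np.testing.assert_allclose(frame, expected, rtol=1e-12)
            np.testing.assert_allclose(rec.dark_frame, cfg.dark_level)

    def test_mean_frame_structure(self):
        cfg = _noise_free_config()
        profiles = default_profiles()
        frame = mean_frame(cfg, profiles, "st_bone")
        shifts = _axis(cfg)
        assert frame.shape == shifts.shape
        assert np.all(frame >= cfg.dark_level)
        # the strongest bone band (961, five units) must show as a local peak
        i = int(np.argmin(np.abs(shifts - 961.0)))
        window = frame[i - 10 : i + 11]
        assert frame[i] == window.max()

    def test_dura_mean_is_bone_gland_ordered_at_phosphate_band(self):
        # With the bone admixture, the dura's 961 peak (above its local
        # background) sits between pure bone and a phosphate-poor soft tissue.
        cfg = _noise_free_config()
        profiles = default_profiles()
        shifts = _axis(cfg)
        i = int(np.argmin(np.abs(shifts - 961.0)))
        k = 35  # off-peak flanks; nearest other bands are > 40 bins away

        def peak_height(tissue):
            f = mean_frame(cfg, profiles, tissue)
            return f[i] - 0.5 * (f[i - k] + f[i + k])

        assert peak_height("pituitary_gland") < peak_height("st_dura")
        assert peak_height("st_dura") < peak_height("st_bone")


class TestGenerateRaw:
    def test_reproducible_and_seed_sensitive(self):
        cfg = GeneratorConfig(seed=3, n_heads=2, records_per_tissue_per_head=1,
                              tissues=("st_bone", "st_dura"), prep_heads=())
        a = generate_raw(cfg)
        b = generate_raw(cfg)
        np.testing.assert_array_equal(a.records[0].frames, b.records[0].frames)
        c = generate_raw(dataclasses.replace(cfg, seed=4))
        assert not np.array_equal(a.records[0].frames, c.records[0].frames)

    def test_record_inventory(self, raw_ds, default_config):
        cfg = default_config
        base = cfg.n_heads * len(cfg.tissues) * cfg.records_per_tissue_per_head
        extra = len(cfg.prep_heads) * 2 * cfg.records_per_tissue_per_head
        assert len(raw_ds) == base + extra

    def test_prep_records_only_on_prep_heads(self, raw_ds, default_config):
        for rec in raw_ds.records:
            if rec.meta.prep_method != "in_situ":
                assert rec.meta.tissue == "pituitary_gland"
                assert rec.meta.head_id in default_config.prep_heads
        methods = {
            r.meta.prep_method
            for r in raw_ds.records
            if r.meta.tissue == "pituitary_gland"
            and r.meta.head_id in default_config.prep_heads
        }
        assert methods == set(PREP_METHODS)

    def test_provenance_records_config(self, raw_ds, default_config):
        prov = raw_ds.provenance
        assert prov["seed"] == default_config.seed
        assert prov["config"]["n_pixels"] == default_config.n_pixels

    def test_counts_within_physical_bounds(self, raw_ds):
        for rec in raw_ds.records[:20]:
            assert np.all(rec.frames >= 0)
            assert np.all(rec.frames <= 65535.0)
            assert 3.0 <= rec.meta.exposure_time_s <= 11.0


def test_acetaminophen_reference_lines_span_the_instrument_range():
    lines = np.array(ACETAMINOPHEN_SHIFTS)
    assert np.all(np.diff(lines) > 0)
    assert lines[0] < 800.0 and lines[-1] > 1600.0
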