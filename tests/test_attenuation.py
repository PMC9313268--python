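import math

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from clearquant import (
    ProtocolParams,
    RegionSpec,
    TransmittanceImagePair,
    load_image_pair,
    region_mu,
    run_protocol,
    sample_regions,
)
from clearquant.attenuation import region_side
from clearquant.errors import (
    DegenerateRegionError,
    InvalidInputError,
    ProtocolFailureError,
    RegionBoundsError,
)
from conftest import make_pairs


def uniform_pair(blank, sample, thickness_mm, shape=(40, 40), **labels):
    return TransmittanceImagePair(
        np.full(shape, float(blank)), np.full(shape, float(sample)),
        thickness_mm, **labels)


class TestRegionMu:
    def test_identical_images_give_zero(self):
        pair = uniform_pair(123.0, 123.0, 3.7)
        m = region_mu(pair, RegionSpec(5, 5, 10, 10))
        assert m.mu == 0.0

    def test_closed_form_inversion(self):
        pair = uniform_pair(200.0, 200.0 * math.exp(-3.0), 1.5)
        m = region_mu(pair, RegionSpec(0, 0, 40, 40))
        assert m.mu == pytest.approx(2.0, rel=1e-12)
        assert m.mean_blank == pytest.approx(200.0)
        assert m.mean_sample == pytest.approx(200.0 * math.exp(-3.0))

    def test_zero_mu_phantom_within_1e12(self):
        pair = uniform_pair(100.0, 100.0, 2.0)
        assert abs(region_mu(pair, RegionSpec(0, 0, 40, 40)).mu) < 1e-12

    def test_out_of_bounds_region(self):
        pair = uniform_pair(10.0, 5.0, 1.0)
        with pytest.raises(RegionBoundsError):
            region_mu(pair, RegionSpec(35, 35, 10, 10))

    def test_degenerate_region(self):
        pair = uniform_pair(10.0, 0.0, 1.0)
        with pytest.raises(DegenerateRegionError):
            region_mu(pair, RegionSpec(0, 0, 10, 10))

    def test_negative_mu_not_clipped(self):
        pair = uniform_pair(100.0, 110.0, 1.0)  # "brighter" sample
        assert region_mu(pair, RegionSpec(0, 0, 10, 10)).mu < 0

    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           mu=st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c, mu):
        blank, sample = 500.0, 500.0 * math.exp(-mu)
        base = region_mu(uniform_pair(blank, sample, 1.0),
                         RegionSpec(0, 0, 40, 40)).mu
        scaled = region_mu(uniform_pair(blank * c, sample * c, 1.0),
                           RegionSpec(0, 0, 40, 40)).mu
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    @given(mu=st.floats(min_value=0.05, max_value=4.0),
           L=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_doubling_thickness_halves_mu(self, mu, L):
        blank, sample = 500.0, 500.0 * math.exp(-mu * L)
        m1 = region_mu(uniform_pair(blank, sample, L),
                       RegionSpec(0, 0, 40, 40)).mu
        m2 = region_mu(uniform_pair(blank, sample, 2 * L),
                       RegionSpec(0, 0, 40, 40)).mu
        assert m2 == pytest.approx(m1 / 2.0, rel=1e-12)


class TestSampleRegions:
    def test_default_sizes_on_1000px_image(self):
        rng = np.random.default_rng(0)
        regions = sample_regions(1000, 1000, ProtocolParams(), rng)
        assert len(regions) == 3
        for r in regions:
            assert (r.height_px, r.width_px) == (150, 150)
            r.check_bounds((1000, 1000))

    def test_half_up_rounding_small_image(self):
        # round(0.15 * 10) = round(1.5) -> 2 with half-up rounding
        assert region_side(10, 0.15) == 2
        rng = np.random.default_rng(0)
        regions = sample_regions(10, 10, ProtocolParams(), rng)
        assert all((r.height_px, r.width_px) == (2, 2) for r in regions)

    def test_minimum_side_is_one(self):
        assert region_side(2, 0.15) == 1

    def test_area_mode_uses_sqrt_fraction(self):
        assert region_side(1000, 0.15, mode="area") == round(
            math.sqrt(0.15) * 1000)

    def test_fixed_seed_reproducible(self):
        a = sample_regions(500, 400, ProtocolParams(), np.random.default_rng(9))
        b = sample_regions(500, 400, ProtocolParams(), np.random.default_rng(9))
        assert a == b

    def test_origins_cover_valid_range(self):
        rng = np.random.default_rng(3)
        params = ProtocolParams(regions_per_run=200)
        regions = sample_regions(100, 100, params, rng)
        rows = {r.row_origin for r in regions}
        assert min(rows) >= 0 and max(rows) <= 100 - 15
        assert len(rows) > 20  # placements actually vary

    def test_invalid_image_dims(self):
        with pytest.raises(InvalidInputError):
            sample_regions(0, 100, ProtocolParams(), np.random.default_rng(0))


class TestRunProtocol:
    def test_count_invariant_defaults(self, noisefree_pairs):
        summary = run_protocol(noisefree_pairs)
        assert summary.n_measurements == 135
        assert len(summary.measurements) == 135

    @pytest.mark.parametrize("regions,runs,n_images", [(1, 1, 1), (2, 4, 2),
                                                       (5, 3, 4)])
    def test_count_invariant_general(self, regions, runs, n_images):
        pairs = make_pairs(1.0, n_images=n_images, size=(64, 64))
        params = ProtocolParams(regions_per_run=regions, runs_per_image=runs)
        summary = run_protocol(pairs, params)
        assert summary.n_measurements == regions * runs * n_images

    def test_single_measurement_sem_zero(self):
        pairs = make_pairs(1.0, n_images=1, size=(64, 64))
        summary = run_protocol(pairs, ProtocolParams(regions_per_run=1,
                                                     runs_per_image=1))
        assert summary.n_measurements == 1
        assert summary.mu_mean == summary.measurements[0].mu
        assert summary.mu_sem == 0.0

    def test_noisefree_recovery_exact_any_seed(self):
        pairs = make_pairs(2.0, thickness_mm=1.5, vignette=0.2)
        for seed in (0, 1, 99):
            summary = run_protocol(pairs, ProtocolParams(seed=seed))
            assert abs(summary.mu_mean - 2.0) / 2.0 <= 1e-9
            for m in summary.measurements:
                assert abs(m.mu - 2.0) / 2.0 <= 1e-9

    def test_mu_mean_is_arithmetic_mean(self):
        pairs = make_pairs(1.0, noise_sigma_frac=0.02, size=(128, 128))
        summary = run_protocol(pairs)
        mus = [m.mu for m in summary.measurements]
        assert summary.mu_mean == pytest.approx(np.mean(mus), rel=1e-12)
        assert summary.mu_sem == pytest.approx(
            np.std(mus, ddof=1) / math.sqrt(len(mus)), rel=1e-12)

    def test_seeded_end_to_end_reproducibility(self):
        pairs = make_pairs(1.0, noise_sigma_frac=0.02, size=(128, 128))
        a = run_protocol(pairs, ProtocolParams(seed=11))
        b = run_protocol(pairs, ProtocolParams(seed=11))
        assert [m.mu for m in a.measurements] == [m.mu for m in b.measurements]
        assert [m.region for m in a.measurements] == [m.region
                                                      for m in b.measurements]

    def test_adding_images_keeps_earlier_draws(self):
        pairs = make_pairs(1.0, noise_sigma_frac=0.02, size=(128, 128))
        two = run_protocol(pairs[:2], ProtocolParams(seed=4))
        three = run_protocol(pairs, ProtocolParams(seed=4))
        assert [m.mu for m in two.measurements] == \
            [m.mu for m in three.measurements[:two.n_measurements]]

    def test_noisy_recovery_within_5pct(self):
        # detector noise 2% of illumination; muL in the recoverable range
        for mu in (0.1, 0.5, 2.0, 4.0):
            pairs = make_pairs(mu, thickness_mm=1.0, noise_sigma_frac=0.02,
                               size=(512, 512), seed=int(mu * 10))
            summary = run_protocol(pairs)
            assert abs(summary.mu_mean - mu) / mu <= 0.05

    def test_ordering_of_noisefree_phantoms(self):
        lo = run_protocol(make_pairs(0.5, sample_id="lo"))
        hi = run_protocol(make_pairs(1.5, sample_id="hi"))
        assert hi.mu_mean > lo.mu_mean

    def test_mixed_labels_rejected(self):
        pairs = make_pairs(1.0, n_images=1) + make_pairs(1.0, n_images=1,
                                                         sample_id="other")
        with pytest.raises(InvalidInputError):
            run_protocol(pairs)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            run_protocol([])

    def test_all_degenerate_protocol_failure(self):
        pair = uniform_pair(100.0, 0.0, 1.0, shape=(64, 64))
        with pytest.raises(ProtocolFailureError, match="image 0"):
            run_protocol([pair])

    def test_partial_degeneracy_resampled(self):
        blank = np.full((100, 100), 100.0)
        sample = np.full((100, 100), 50.0)
        sample[:, 50:] = 0.0  # right half dead; left half fine
        pair = TransmittanceImagePair(blank, sample, 1.0)
        summary = run_protocol([pair], ProtocolParams(seed=2))
        assert summary.n_measurements == 45
        assert all(np.isfinite(m.mu) for m in summary.measurements)


class TestLoadImagePair:
    def test_identical_files_zero_mu(self, tmp_path):
        img = (np.ones((32, 32)) * 57).astype(np.uint8)
        p = tmp_path / "img.png"
        import imageio.v3 as iio

        iio.imwrite(p, img)
        pair = load_image_pair(p, p, thickness_mm=1.0)
        m = region_mu(pair, RegionSpec(0, 0, 32, 32))
        assert m.mu == 0.0

    def test_rgb_equal_channels_luminance(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.full((16, 16, 3), 120, dtype=np.uint8)
        p = tmp_path / "rgb.png"
        iio.imwrite(p, rgb)
        pair = load_image_pair(p, p, thickness_mm=1.0)
        np.testing.assert_allclose(pair.blank_image, 120.0, rtol=1e-9)

    def test_16bit_tiff_roundtrip_within_one_step(self, tmp_path):
        from clearquant.phantom import write_pair_tiff
        from conftest import make_pairs  # noqa: F401
        from clearquant import TransmittancePhantomSpec, NoiseModel
        from clearquant.phantom import generate_transmittance_pair

        spec = TransmittancePhantomSpec(
            image_height_px=64, image_width_px=64, mu_true=1.0,
            thickness_mm=1.0, illumination_level=20000.0,
            vignette_strength=0.2,
            noise_model=NoiseModel("gaussian", sigma=100.0), seed=3)
        ph = generate_transmittance_pair(spec)
        bp, sp = tmp_path / "b.tif", tmp_path / "s.tif"
        write_pair_tiff(ph, bp, sp)
        pair = load_image_pair(bp, sp, thickness_mm=1.0)
        assert np.abs(pair.blank_image - ph.pair.blank_image).max() <= 0.5 + 1e-9
        assert np.abs(pair.sample_image - ph.pair.sample_image).max() <= 0.5 + 1e-9

    def test_dimension_mismatch(self, tmp_path):
        a, b = tmp_path / "a.tif", tmp_path / "b.tif"
        tifffile.imwrite(a, np.zeros((10, 10), dtype=np.uint16))
        tifffile.imwrite(b, np.zeros((12, 10), dtype=np.uint16))
        with pytest.raises(InvalidInputError, match="mismatch"):
            load_image_pair(a, b, thickness_mm=1.0)

    def test_nonpositive_thickness(self, tmp_path):
        p = tmp_path / "a.tif"
        tifffile.imwrite(p, np.ones((10, 10), dtype=np.uint16))
        with pytest.raises(InvalidInputError):
            load_image_pair(p, p, thickness_mm=0.0)
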