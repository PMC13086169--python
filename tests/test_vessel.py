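"""Vessel-shadow detection chain: SVD, ILM, Radon reinforcement, masking."""

import numpy as np
import pytest

from rnflseg.phantom import PhantomSpec, generate_phantom
from rnflseg.vessel import (
    IlmDetectionFailure,
    RadonConfig,
    ShadowProfile,
    detect_ilm,
    gamma_correct,
    mirror_pad,
    prepare_contrast,
    radon_reinforce,
    remove_vessels,
    shadow_profile,
    svd_enhance,
    vessel_mask_from_profile,
)


class TestSvdEnhance:
    def test_rank_one_image_is_fixed_point(self, rng):
        u = rng.uniform(0.2, 1.0, 32)
        v = rng.uniform(0.2, 1.0, 40)
        img = np.outer(u, v)
        img /= img.max()
        assert np.abs(svd_enhance(img, 0.5) - img).max() < 1e-6

    def test_column_constant_stripes_unchanged(self, rng):
        img = np.tile(rng.uniform(0, 1, 48)[None, :], (32, 1))
        assert np.linalg.matrix_rank(img) == 1
        assert np.abs(svd_enhance(img, 0.9) - img).max() < 1e-6

    def test_truncation_contracts_energy(self, rng):
        img = rng.random((32, 32))
        out = svd_enhance(img, 0.5)
        assert np.sum(out**2) <= np.sum(img**2) + 1e-9

    def test_all_zero_image_returned_unchanged(self):
        img = np.zeros((8, 8))
        assert np.array_equal(svd_enhance(img, 0.9), img)


class TestDetectIlm:
    def test_flat_ilm_recovered_exactly(self):
        rec = generate_phantom(PhantomSpec(
            seed=0, n_vessels=0, speckle_sigma=0.0,
            ilm_waviness_amplitude=0.0, ilm_baseline=20,
        ))
        assert np.all(detect_ilm(rec.image) == 20)

    def test_sinusoidal_ilm_within_one_pixel(self):
        rec = generate_phantom(PhantomSpec(
            seed=0, n_vessels=0, speckle_sigma=0.0, ilm_waviness_amplitude=5.0,
        ))
        err = np.abs(detect_ilm(rec.image) - rec.boundaries.upper)
        assert err.max() <= 1

    def test_dark_image_raises(self):
        with pytest.raises(IlmDetectionFailure):
            detect_ilm(np.zeros((64, 64)))


class TestContrastSteps:
    def test_above_ilm_maps_to_zero_and_shadows_brighten(self, rng):
        img = rng.random((32, 32))
        ilm = np.full(32, 10)
        out = prepare_contrast(img, ilm)
        assert np.all(out[:10] == 0.0)
        assert np.allclose(out[10:], 1.0 - img[10:])

    def test_double_application_is_not_identity(self, rng):
        img = rng.random((32, 32))
        ilm = np.full(32, 8)
        twice = prepare_contrast(prepare_contrast(img, ilm), ilm)
        assert not np.allclose(twice, img)

    def test_mirror_pad_reflection_definition(self, rng):
        img = rng.random((8, 12))
        width = 5
        out = mirror_pad(img, width)
        assert out.shape == (8, 12 + 2 * width)
        for j in range(width):
            assert np.array_equal(out[:, width - 1 - j], img[:, j])
        assert np.array_equal(out[:, width:-width], img)

    def test_mirror_pad_zero_is_identity_and_overwide_rejected(self, rng):
        img = rng.random((8, 12))
        assert np.array_equal(mirror_pad(img, 0), img)
        with pytest.raises(ValueError):
            mirror_pad(img, 13)

    def test_gamma_fixed_points_and_scalar_value(self):
        img = np.array([[0.0, 0.5, 1.0]])
        out = gamma_correct(img, 2.2)
        assert out[0, 0] == 0.0 and out[0, 2] == 1.0
        assert out[0, 1] == pytest.approx(0.5**2.2)
        assert np.array_equal(gamma_correct(img, 1.0), img)


class TestRadonReinforce:
    def test_zero_angle_projection_equals_column_sums(self, rng):
        config = RadonConfig(attenuation_time_constant=1e9)  # no attenuation
        for _ in range(3):
            img = rng.random((24, 30))
            sino = radon_reinforce(img, config)
            zero = int(np.argmin(np.abs(config.angle_grid)))
            col = sino[:, zero]
            # undo the squaring reinforcement to recover the raw projection
            raw = np.sqrt(col / col.max()) * col.max() if col.max() > 0 else col
            sums = img.sum(axis=0)
            off = (len(raw) - img.shape[1]) // 2
            core = raw[off: off + img.shape[1]]
            assert np.abs(core - sums).max() < 1e-6 * max(1.0, sums.max())

    def test_vertical_line_concentrates_at_zero_degrees(self):
        img = np.zeros((32, 40))
        img[:, 17] = 1.0
        config = RadonConfig()
        sino = radon_reinforce(img, config)
        r, a = np.unravel_index(np.argmax(sino), sino.shape)
        zero = int(np.argmin(np.abs(config.angle_grid)))
        assert a == zero
        off = (sino.shape[0] - img.shape[1]) // 2
        assert abs(r - (17 + off)) <= 1

    def test_attenuation_is_one_at_zero_and_decreasing(self):
        config = RadonConfig()
        factors = np.exp(
            -np.abs(config.angle_grid) / config.attenuation_time_constant
        )
        zero = int(np.argmin(np.abs(config.angle_grid)))
        assert factors[zero] == 1.0
        assert np.all(np.diff(factors[zero:]) < 0)
        assert np.all(np.diff(factors[:zero + 1]) > 0)

    def test_angle_grid_without_zero_rejected(self):
        config = RadonConfig(angle_grid=np.array([-2.0, -1.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="0 degrees"):
            radon_reinforce(np.ones((16, 16)), config)


class TestShadowProfile:
    def test_constant_image_gives_negligible_profile(self):
        # a constant image has no vertical structure; residual profile
        # (finite-angle back-projection ripple) stays far below the
        # detection floor of min_response_fraction x height
        config = RadonConfig()
        img = np.full((64, 64), 0.5)
        mw = config.resolved_mirror_width(64)
        sino = radon_reinforce(mirror_pad(img, mw), config)
        profile = shadow_profile(sino, config, 64, mw)
        assert profile.values.max() < 0.5 * config.min_response_fraction * 64
        assert np.all(profile.values >= 0)

    def test_single_shadow_peak_inside_interval(self):
        spec = PhantomSpec(
            seed=5, n_vessels=1, vessel_width_range=(6, 6),
            vessel_contrast=0.6, speckle_sigma=0.0,
        )
        rec = generate_phantom(spec)
        config = RadonConfig()
        enhanced = svd_enhance(rec.image, config.svd_energy_fraction)
        ilm = detect_ilm(enhanced)
        mw = config.resolved_mirror_width(rec.image.shape[1])
        padded = mirror_pad(prepare_contrast(enhanced, ilm), mw)
        sino = radon_reinforce(gamma_correct(padded, config.gamma), config)
        profile = shadow_profile(sino, config, rec.image.shape[1], mw)
        peak = int(np.argmax(profile.values))
        assert rec.vessel_mask.any(axis=0)[peak]


class TestVesselMask:
    def test_quantile_threshold_matches_order_statistic(self):
        config = RadonConfig()
        values = np.arange(100, dtype=float)
        profile = ShadowProfile(values=values, trend=np.zeros(100))
        ilm = np.full(100, 5)
        mask = vessel_mask_from_profile(profile, ilm, config, (32, 100))
        expected = (values > np.quantile(values, 0.85)).sum()
        assert mask.any(axis=0).sum() == expected

    def test_constant_profile_flags_nothing(self):
        config = RadonConfig()
        profile = ShadowProfile(values=np.ones(50), trend=np.zeros(50))
        mask = vessel_mask_from_profile(profile, np.full(50, 3), config, (16, 50))
        assert not mask.any()

    def test_no_mask_pixels_above_ilm(self):
        config = RadonConfig()
        rec = generate_phantom(PhantomSpec(seed=11))
        _, mask = remove_vessels(rec.image, config)
        enhanced = svd_enhance(rec.image, config.svd_energy_fraction)
        ilm = detect_ilm(enhanced)
        for c in range(mask.shape[1]):
            assert not mask[: ilm[c], c].any()


class TestRemoveVessels:
    def test_vessel_free_phantom_yields_near_empty_mask(self):
        rec = generate_phantom(PhantomSpec(seed=0, n_vessels=0, speckle_sigma=0.0))
        out, mask = remove_vessels(rec.image)
        flagged = mask.any(axis=0).mean()
        assert flagged <= 0.01
        assert np.abs(out - rec.image).mean() < 0.01

    def test_planted_shadows_recovered(self):
        rec = generate_phantom(PhantomSpec(
            seed=4, n_vessels=3, vessel_width_range=(4, 8),
            vessel_contrast=0.5, speckle_sigma=0.05,
        ))
        _, mask = remove_vessels(rec.image)
        true_cols = rec.vessel_mask.any(axis=0)
        pred_cols = mask.any(axis=0)
        recall = (true_cols & pred_cols).sum() / true_cols.sum()
        assert recall >= 0.9

    def test_inpainting_brightens_shadow_interior(self):
        rec = generate_phantom(PhantomSpec(
            seed=4, n_vessels=3, vessel_contrast=0.6, speckle_sigma=0.0,
        ))
        out, mask = remove_vessels(rec.image)
        assert mask.any()
        assert out[mask].mean() > rec.image[mask].mean()
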