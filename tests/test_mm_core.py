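import json

import numpy as np
import pytest

from polarmm.mm_core import (
    EmptyForegroundError,
    MuellerImage,
    RankDeficientError,
    Rect,
    StokesSet,
    normalize_mm,
    read_mask,
    read_mueller_npz,
    read_mueller_tiff,
    reconstruct_mm,
    rotate_mm,
    rotation_matrix,
    validate_mm,
    write_mask_tiff,
    write_mueller_npz,
    write_mueller_tiff,
    write_rois_json,
)
from polarmm.phantom import (
    default_generator_states,
    generate_phantom,
    linear_retarder,
    PRESETS,
    simulate_measurement,
)


class TestMuellerImage:
    def test_single_matrix_promoted(self):
        img = MuellerImage(np.eye(4))
        assert img.elements.shape == (1, 1, 4, 4)
        assert img.height == img.width == 1

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            MuellerImage(np.zeros((4, 3)))

    def test_flat_round_trip(self, rng):
        el = rng.normal(size=(5, 7, 4, 4))
        img = MuellerImage(el)
        back = MuellerImage.from_flat(img.to_flat())
        np.testing.assert_array_equal(back.elements, el)

    def test_element_accessor_is_one_based(self):
        el = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        img = MuellerImage(el)
        assert img.element(1, 1) == 0.0
        assert img.element(3, 4) == 11.0
        with pytest.raises(ValueError):
            img.element(0, 1)


class TestStokesSet:
    def test_unphysical_state_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            StokesSet(np.array([[1.0, 1.2, 0, 0]] * 4)).validate()

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="S0 > 0"):
            StokesSet(np.array([[0.0, 0, 0, 0]] * 4)).validate()

    def test_rank_deficient_generator_rejected(self):
        states = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 1]], float)
        with pytest.raises(RankDeficientError):
            StokesSet(states).validate()


class TestNormalize:
    def test_scaled_identity(self):
        img = MuellerImage(np.broadcast_to(3.0 * np.eye(4), (4, 4, 4, 4)).copy())
        out, bg = normalize_mm(img)
        assert not bg.any()
        assert out.normalized
        np.testing.assert_allclose(out.elements, np.broadcast_to(np.eye(4), (4, 4, 4, 4)))

    def test_zero_m11_pixel_goes_to_background_untouched(self):
        el = np.stack([np.eye(4), np.zeros((4, 4))]).reshape(1, 2, 4, 4)
        out, bg = normalize_mm(MuellerImage(el))
        assert bg.tolist() == [[False, True]]
        np.testing.assert_array_equal(out.elements[0, 1], np.zeros((4, 4)))

    def test_all_background_raises(self):
        img = MuellerImage(np.zeros((3, 3, 4, 4)))
        with pytest.raises(EmptyForegroundError):
            normalize_mm(img, eps_air=0.1)

    def test_transmittance_field_divides_out(self, rng):
        # phantom scaled by a known tau(x, y): normalized elements must equal
        # the stored unscaled matrices element-wise
        img, gt = generate_phantom(
            PRESETS["normal"], 24, 24, seed=7, tau=0.7, tau_jitter=0.15
        )
        out, bg = normalize_mm(img)
        fg = ~bg
        unscaled = img.elements[fg] / gt.tau_map[fg][:, None, None]
        np.testing.assert_allclose(out.elements[fg], unscaled, atol=1e-12)


class TestReconstruct:
    def test_identity_when_s_out_equals_s_in(self):
        gen = default_generator_states()
        res = reconstruct_mm(gen, StokesSet(gen.states, role="analyzer"))
        np.testing.assert_allclose(res.image.elements[0, 0], np.eye(4), atol=1e-12)
        assert res.condition_number < 10

    def test_round_trip_six_states_exact(self):
        m = linear_retarder(0.8, 25.0)
        gen = default_generator_states(angles_deg=(-45, -15, 0, 20, 45, 70))
        s_out = gen.states @ m.T
        res = reconstruct_mm(gen, s_out)
        np.testing.assert_allclose(res.image.elements[0, 0], m, atol=1e-10)

    def test_noise_rmse_halves_with_noise(self, rng):
        # Monte Carlo over 150 draws: halving sigma halves the element RMSE
        m = linear_retarder(0.8, 25.0)
        img = MuellerImage.from_matrix(m)
        gen = default_generator_states(angles_deg=(-45, -15, 0, 20, 45, 70))
        errs = {}
        for sigma in (0.02, 0.01):
            sq = []
            for draw in range(150):
                s_out = simulate_measurement(img, gen, noise_sigma=sigma, seed=1000 + draw)
                rec = reconstruct_mm(gen, s_out).image.elements[0, 0]
                sq.append(np.mean((rec - m) ** 2))
            errs[sigma] = np.sqrt(np.mean(sq))
        ratio = errs[0.02] / errs[0.01]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_frame_averaging_scaling(self):
        # RMSE falls as 1/sqrt(frames averaged), within 20% over >= 100 draws
        m = linear_retarder(1.1, 10.0)
        img = MuellerImage.from_matrix(m)
        gen = default_generator_states()
        errs = {}
        for frames in (1, 4):
            sq = []
            for draw in range(120):
                s_out = simulate_measurement(
                    img, gen, noise_sigma=0.02, seed=2000 + draw, n_frames=frames
                )
                rec = reconstruct_mm(gen, s_out).image.elements[0, 0]
                sq.append(np.mean((rec - m) ** 2))
            errs[frames] = np.sqrt(np.mean(sq))
        assert errs[1] / errs[4] == pytest.approx(2.0, rel=0.2)

    def test_rank_deficient_reports_condition_number(self):
        states = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 1]], float)
        gen = StokesSet.__new__(StokesSet)  # bypass validate-on-use path
        gen.states = states
        gen.role = "generator"
        with pytest.raises(RankDeficientError, match="condition number"):
            reconstruct_mm(gen, states)

    def test_batch_matches_per_pixel(self, rng):
        img, _ = generate_phantom(PRESETS["model"], 6, 5, seed=3)
        gen = default_generator_states()
        s_out = simulate_measurement(img, gen)
        res = reconstruct_mm(gen, s_out)
        np.testing.assert_allclose(res.image.elements, img.elements, atol=1e-10)


class TestValidate:
    def test_identity_clean(self):
        diag = validate_mm(MuellerImage(np.broadcast_to(np.eye(4), (3, 3, 4, 4)).copy()))
        assert diag.flagged_fraction == 0.0

    def test_element_above_m11_flagged(self):
        el = np.eye(4)
        el[0, 1] = 1.5
        diag = validate_mm(MuellerImage.from_matrix(el))
        assert diag.flagged.all()
        frame = diag.as_frame()
        assert frame.loc[frame.check == "element_exceeds_m11", "count"].item() == 1

    def test_noise_free_phantom_clean(self, normal_phantom):
        img, _ = normal_phantom
        assert validate_mm(img).flagged_fraction == 0.0


class TestRotation:
    def test_rotation_matrix_is_orthogonal(self):
        r = rotation_matrix(33.0)
        np.testing.assert_allclose(r @ r.T, np.eye(4), atol=1e-12)

    def test_rotate_unrotate_is_identity(self, normal_phantom):
        img, _ = normal_phantom
        back = rotate_mm(rotate_mm(img, 17.0), -17.0)
        np.testing.assert_allclose(back.elements, img.elements, atol=1e-10)


class TestIO:
    def test_tiff_round_trip(self, tmp_path, normal_phantom):
        img, _ = normal_phantom
        path = write_mueller_tiff(img, tmp_path / "mm.tiff")
        back = read_mueller_tiff(path)
        assert back.wavelength_nm == img.wavelength_nm
        assert back.normalized == img.normalized
        np.testing.assert_allclose(back.elements, img.elements, atol=1e-6)
        header = json.loads((tmp_path / "mm.tiff.json").read_text())
        assert header["element_order"].startswith("m11,m12")

    def test_npz_round_trip(self, tmp_path, normal_phantom):
        img, _ = normal_phantom
        write_mueller_npz(img, tmp_path / "mm.npz")
        back = read_mueller_npz(tmp_path / "mm.npz")
        np.testing.assert_allclose(back.elements, img.elements, atol=1e-6)

    def test_mask_tiff_round_trip(self, tmp_path, rng):
        mask = rng.random((16, 16)) > 0.5
        path = write_mask_tiff(mask, tmp_path / "mask.tiff")
        np.testing.assert_array_equal(read_mask(path), mask)

    def test_json_roi_round_trip(self, tmp_path):
        rects = [Rect(1, 2, 4, 3), Rect(8, 8, 5, 5)]
        path = write_rois_json(rects, tmp_path / "rois.json")
        mask = read_mask(path, shape=(16, 16))
        expected = rects[0].to_mask(16, 16) | rects[1].to_mask(16, 16)
        np.testing.assert_array_equal(mask, expected)
        with pytest.raises(ValueError, match="shape"):
            read_mask(path)
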