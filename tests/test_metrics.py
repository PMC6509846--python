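"""Binarization, contour extraction and the three pattern metrics."""

import numpy as np
import pytest
from skimage import draw

from pigmentpattern import (binarize, colour_tone, extract_contours,
                            isoperimetric_quotient, pattern_simplicity_score,
                            red_fraction, score_image)
from pigmentpattern.synth import ShapeSpec, render_shapes


def _disc_mask(n, r, center=None):
    img = np.zeros((n, n), dtype=bool)
    rr, cc = draw.disk(center or (n / 2, n / 2), r, shape=img.shape)
    img[rr, cc] = True
    return img


class TestBinarize:
    def test_fixed_threshold_keeps_dark_pixels(self):
        img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        assert binarize(img, "fixed", 128).tolist() == [[True, False],
                                                        [False, True]]

    def test_all_white_has_no_foreground(self):
        assert not binarize(np.full((5, 5), 255, np.uint8), "fixed", 128).any()

    def test_constant_image_otsu_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = binarize(np.full((5, 5), 77, np.uint8), "otsu")
        assert not out.any()

    def test_disc_foreground_area_matches_analytic(self):
        res = render_shapes([ShapeSpec("disc", (16, 16), radius=10)],
                            canvas=(32, 32), resolution=8)
        count = binarize((~res.image).astype(np.uint8) * 255, "fixed", 128).sum()
        assert count == pytest.approx(np.pi * 10**2 * 8**2, rel=0.02)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((3, 3)), "adaptive")


class TestExtractContours:
    def test_two_disjoint_discs_give_two_contours(self):
        img = _disc_mask(128, 20, (40, 40)) | _disc_mask(128, 20, (90, 90))
        assert len(extract_contours(img)) == 2

    def test_annulus_geometry_within_two_percent(self):
        # disc r=100 with concentric hole r=50, measured at 256 px
        img = _disc_mask(256, 100) & ~_disc_mask(256, 50)
        (c,) = extract_contours(img)
        assert c.n_holes == 1
        assert c.area == pytest.approx(np.pi * (100**2 - 50**2), rel=0.02)
        assert c.perimeter == pytest.approx(2 * np.pi * (100 + 50), rel=0.02)

    def test_speckle_filtered_by_min_area(self):
        img = np.zeros((16, 16), dtype=bool)
        img[8, 8] = True
        assert extract_contours(img, min_area=5) == []
        assert len(extract_contours(img, min_area=1)) == 1

    def test_border_touching_component_retained(self):
        img = np.zeros((64, 64), dtype=bool)
        img[:10, :] = True  # band clipped by the border
        (c,) = extract_contours(img)
        assert c.area == pytest.approx(10 * 64, rel=0.05)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            extract_contours(np.zeros((4, 4, 3), dtype=bool))
        with pytest.raises(ValueError):
            extract_contours(np.zeros((4, 4), dtype=bool), connectivity=6)


class TestIsoperimetricQuotient:
    @pytest.mark.parametrize("S, L, expected", [
        (np.pi * 100, 2 * np.pi * 10, 1.0),
        (100, 40, np.pi / 4),
        (16, 20, 0.16 * np.pi),
    ])
    def test_closed_form_values(self, S, L, expected):
        assert isoperimetric_quotient(S, L) == pytest.approx(expected, abs=1e-12)

    def test_clamped_at_one(self):
        assert isoperimetric_quotient(1000, 10) == 1.0
        assert isoperimetric_quotient(1000, 10, clamp=False) > 1.0

    @pytest.mark.parametrize("S, L", [(0, 10), (-1, 10), (10, 0)])
    def test_nonpositive_rejected(self, S, L):
        with pytest.raises(ValueError):
            isoperimetric_quotient(S, L)

    def test_rectangle_q_decreases_with_aspect_ratio(self):
        # closed form: Q = pi*a*b/(a+b)^2, strictly decreasing in b/a >= 1
        qs = [isoperimetric_quotient(a * b, 2 * (a + b))
              for a, b in ((4, 4), (4, 8), (4, 16), (4, 32))]
        assert all(x > y for x, y in zip(qs, qs[1:]))


class TestPatternSimplicityScore:
    def test_hand_evaluated_weighted_mean(self):
        from pigmentpattern.metrics import Contour
        circle = Contour(np.zeros((1, 2)), area=300, perimeter=2 * np.sqrt(300 * np.pi))
        square = Contour(np.zeros((1, 2)), area=100, perimeter=40)
        pss, table = pattern_simplicity_score([circle, square])
        assert pss == pytest.approx(0.75 * 1.0 + 0.25 * np.pi / 4, abs=1e-12)
        assert table["w"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_order_independent(self):
        cs = extract_contours(_disc_mask(128, 15, (30, 30))
                              | _disc_mask(128, 25, (85, 85)))
        assert pattern_simplicity_score(cs)[0] == \
            pytest.approx(pattern_simplicity_score(cs[::-1])[0], abs=1e-14)

    def test_empty_contours_give_nan_not_zero(self):
        pss, table = pattern_simplicity_score([])
        assert np.isnan(pss)
        assert table.empty


class TestToneAndRed:
    def test_tone_trivial_fractions(self):
        assert colour_tone(np.zeros((4, 4), dtype=bool)) == 1.0
        half = np.zeros((4, 4), dtype=bool)
        half[:2] = True
        assert colour_tone(half) == 0.5

    def test_pure_red_and_pure_blue(self):
        red = np.zeros((4, 4, 3), np.uint8)
        red[..., 0] = 220
        blue = np.zeros((4, 4, 3), np.uint8)
        blue[..., 2] = 220
        assert red_fraction(red) == 1.0
        assert red_fraction(blue) == 0.0

    def test_grayscale_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="grayscale"):
            assert red_fraction(np.zeros((4, 4))) == 0.0


class TestScoreImageProperties:
    def test_weights_sum_to_one(self, disc_scene, equal_area_scene):
        for scene in (disc_scene, equal_area_scene):
            s = score_image(scene.image)
            assert s.per_contour["w"].sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 < s.pss <= 1.0

    def test_single_disc_scores_high_at_64px_diameter(self):
        s = score_image(_disc_mask(96, 32))
        assert s.pss >= 0.9

    def test_scale_invariance_within_tolerance(self):
        shapes = [ShapeSpec("disc", (10, 12), radius=4),
                  ShapeSpec("rectangle", (24, 20), width=8, height=3)]
        a = score_image(render_shapes(shapes, (32, 32), resolution=8).image)
        b = score_image(render_shapes(shapes, (32, 32), resolution=16).image)
        assert abs(a.pss - b.pss) <= 0.02

    def test_rotation_robustness_of_rectangle(self):
        axis = render_shapes([ShapeSpec("rectangle", (16, 16), width=12,
                                        height=4)], (32, 32), resolution=8)
        rot = render_shapes([ShapeSpec("rectangle", (16, 16), width=12,
                                       height=4, angle=45.0)],
                            (32, 32), resolution=8)
        assert abs(score_image(axis.image).pss
                   - score_image(rot.image).pss) <= 0.05

    def test_all_white_image_has_tone_one_and_missing_pss(self):
        s = score_image(np.full((32, 32), 255, np.uint8))
        assert s.tone == 1.0
        assert np.isnan(s.pss)
        assert s.n_contours == 0

    def test_file_roundtrip(self, tmp_path, disc_scene):
        from pigmentpattern.pipeline import save_image
        path = tmp_path / "disc.png"
        save_image(disc_scene.image, path)
        assert score_image(path).pss == pytest.approx(
            score_image(disc_scene.image).pss, abs=1e-12)
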