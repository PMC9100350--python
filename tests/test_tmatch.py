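import numpy as np
import pytest

import skincap as sc
from skincap.synth import TextureParams
from skincap.tmatch import Method

from conftest import random_grid
from oracles import oracle_match_surface

ALL_METHODS = list(Method)


def _plant(rng, image_shape, tpl_shape, bright=True):
    """Image with a distinctive template planted at a known offset.

    The planted patch is brighter than the background so it is the
    highest-energy window — the regime in which even the un-normalised
    correlation score peaks at the true location.
    """
    ih, iw = image_shape
    th, tw = tpl_shape
    img = random_grid(rng, image_shape, low=10, high=100).astype(np.float64)
    tpl = random_grid(rng, tpl_shape, low=150, high=256).astype(np.float64)
    x0 = int(rng.integers(0, iw - tw + 1))
    y0 = int(rng.integers(0, ih - th + 1))
    img[y0 : y0 + th, x0 : x0 + tw] = tpl
    return img.astype(np.uint8), tpl.astype(np.uint8), (x0, y0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("literal", [False, True], ids=["standard", "literal"])
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_matches_nested_loop_oracle(self, method, literal):
        """Vectorised surfaces equal direct nested-loop sums on random
        small instances, elementwise."""
        rng = np.random.default_rng(202)
        for _ in range(30):
            ih, iw = rng.integers(2, 9, size=2)
            th = int(rng.integers(1, min(ih, 3) + 1))
            tw = int(rng.integers(1, min(iw, 3) + 1))
            img = random_grid(rng, (ih, iw), low=1)
            tpl = random_grid(rng, (th, tw), low=1)
            try:
                got = sc.match_surface(img, tpl, method, literal).scores
            except sc.DegenerateTemplateError:
                with pytest.raises(ValueError):
                    oracle_match_surface(img, tpl, method.value, literal)
                continue
            want = oracle_match_surface(img, tpl, method.value, literal)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_surface_shape_and_self_match(self):
        rng = np.random.default_rng(5)
        img = random_grid(rng, (6, 7))
        surf = sc.match_surface(img, img, Method.SQDIFF)
        assert surf.scores.shape == (1, 1)
        assert surf.scores[0, 0] == 0.0

    def test_template_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            sc.match_surface(np.ones((3, 3)), np.ones((4, 4)), Method.SQDIFF)

    @pytest.mark.parametrize(
        "method,template",
        [
            (Method.SQDIFF_NORMED, np.zeros((2, 2))),
            (Method.CCORR_NORMED, np.zeros((2, 2))),
            (Method.CCOEFF_NORMED, np.full((2, 2), 7.0)),
        ],
    )
    def test_degenerate_templates_rejected(self, method, template):
        with pytest.raises(sc.DegenerateTemplateError):
            sc.match_surface(np.ones((4, 4)), template, method)


class TestScoreProperties:
    def test_normalised_score_bounds(self):
        """Standard-mode CCoeff_Normed lies in [-1, 1]; CCorr_Normed on
        non-negative images lies in [0, 1] (Cauchy-Schwarz)."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            img = random_grid(rng, (12, 14), low=1)
            tpl = random_grid(rng, (4, 5), low=1)
            cn = sc.match_surface(img, tpl, Method.CCORR_NORMED).scores
            assert np.all(cn >= -1e-9) and np.all(cn <= 1 + 1e-9)
            ccn = sc.match_surface(img, tpl, Method.CCOEFF_NORMED).scores
            assert np.all(np.abs(ccn) <= 1 + 1e-9)

    def test_sqdiff_zero_iff_window_equals_template(self, rng):
        img = random_grid(rng, (9, 9), low=0, high=200)
        tpl = img[3:6, 2:5].copy()
        scores = sc.match_surface(img, tpl, Method.SQDIFF).scores
        zero_mask = scores == 0.0
        for y in range(scores.shape[0]):
            for x in range(scores.shape[1]):
                assert zero_mask[y, x] == bool(
                    np.array_equal(img[y : y + 3, x : x + 3], tpl)
                )
        assert zero_mask[3, 2]

    def test_ccoeff_invariant_under_constant_offset(self, rng):
        """Adding a constant to image and template leaves the mean-subtracted
        (CCoeff-family) surfaces unchanged in standard mode."""
        img = random_grid(rng, (10, 11), low=0, high=100).astype(np.float64)
        tpl = random_grid(rng, (3, 4), low=0, high=100).astype(np.float64)
        for method in (Method.CCOEFF, Method.CCOEFF_NORMED):
            base = sc.match_surface(img, tpl, method).scores
            shifted = sc.match_surface(img + 50, tpl + 50, method).scores
            np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-7)

    def test_constant_window_under_ccoeff_normed_scores_zero(self):
        img = np.full((5, 5), 9.0)
        img[4, 4] = 10.0  # keep the template non-constant elsewhere
        tpl = np.array([[1.0, 2.0], [3.0, 4.0]])
        surf = sc.match_surface(img, tpl, Method.CCOEFF_NORMED)
        assert surf.scores[0, 0] == 0.0
        assert surf.degenerate[0, 0]


class TestBestMatch:
    def test_min_for_sqdiff_max_for_ccorr(self):
        surf = sc.MatchSurface(np.array([[0.0, 5.0], [5.0, 5.0]]), Method.SQDIFF)
        assert sc.best_match(surf) == ((0, 0), 0.0)
        surf = sc.MatchSurface(np.array([[1.0, 1.0], [1.0, 1.0]]), Method.CCORR)
        assert sc.best_match(surf) == ((0, 0), 1.0)  # tie -> smallest y, then x

    def test_tie_break_prefers_smaller_y_then_x(self):
        scores = np.array([[1.0, 7.0], [7.0, 7.0]])
        surf = sc.MatchSurface(scores, Method.CCOEFF)
        assert sc.best_match(surf)[0] == (1, 0)

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            sc.best_match(sc.MatchSurface(np.empty((0, 0)), Method.SQDIFF))


class TestTranslationRecovery:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_noiseless_planted_template_recovered(self, method):
        rng = np.random.default_rng(77)
        for _ in range(5):
            img, tpl, (x0, y0) = _plant(rng, (40, 48), (9, 11))
            surf = sc.match_surface(img, tpl, method)
            (x, y), _ = sc.best_match(surf)
            assert (x, y) == (x0, y0)

    def test_noisy_recovery_rate_ccorr_normed(self):
        """Normalised cross-correlation recovers the exact planted offset in
        >= 95/100 noisy trials (noise SD 5, 32x32 template)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = sc.generate_texture(
                (96, 96), TextureParams(seed=int(rng.integers(2**31)), noise_sd=0)
            )
            dx = int(rng.integers(-8, 9))
            dy = int(rng.integers(-8, 9))
            target = sc.shift_and_capture(
                base, dx, dy, noise_sd=5.0, seed=int(rng.integers(2**31))
            )
            roi = sc.RoiRect(32, 32, 32, 32)
            rects = sc.relocate_roi(base, roi, [target], Method.CCORR_NORMED)
            hits += rects[0].x - roi.x == dx and rects[0].y - roi.y == dy
        assert hits >= 95


class TestRelocateRoi:
    def test_identity_target_returns_same_roi(self, rng):
        ref = sc.CapacitiveImage(pixels=random_grid(rng, (30, 30)))
        roi = sc.RoiRect(5, 8, 10, 7)
        assert sc.relocate_roi(ref, roi, [ref]) == [roi]

    def test_known_shift_recovered_exactly(self):
        base = sc.generate_texture((64, 64), TextureParams(seed=4, noise_sd=0))
        roi = sc.RoiRect(20, 22, 16, 16)
        targets = [
            sc.shift_and_capture(base, dx, dy, noise_sd=0, seed=abs(dx * 10 + dy))
            for dx, dy in [(5, 2), (-3, 4), (0, -6)]
        ]
        rects = sc.relocate_roi(base, roi, targets)
        assert [(r.x - roi.x, r.y - roi.y) for r in rects] == [(5, 2), (-3, 4), (0, -6)]

    def test_rects_contained_in_targets(self, default_study, default_roi):
        site = "site1"
        ref = default_study.images[(site, "before")]
        targets = [default_study.images[(site, tp)] for tp in ("1h", "2h")]
        for rect, target in zip(sc.relocate_roi(ref, default_roi, targets), targets):
            assert rect.contained_in(target)

    def test_roi_outside_reference_rejected(self, rng):
        ref = sc.CapacitiveImage(pixels=random_grid(rng, (20, 20)))
        with pytest.raises(ValueError):
            sc.relocate_roi(ref, sc.RoiRect(15, 15, 10, 10), [ref])
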