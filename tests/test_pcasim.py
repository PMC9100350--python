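import numpy as np
import pytest

import skincap as sc

from conftest import random_grid
from oracles import oracle_pca_components, oracle_pca_distance


def _images(rng, n, shape=(3, 3)):
    return [sc.CapacitiveImage(pixels=random_grid(rng, shape)) for _ in range(n)]


class TestFitPca:
    def test_two_images_single_component_parallel_to_difference(self, rng):
        a, b = _images(rng, 2, (4, 4))
        model = sc.fit_pca([a, b], 1)
        diff = (a.as_float() - b.as_float()).ravel()
        diff /= np.linalg.norm(diff)
        dot = abs(float(model.components[0] @ diff))
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_explained_variance_non_increasing_components_orthonormal(self, rng):
        model = sc.fit_pca(_images(rng, 8, (5, 6)), 5)
        ev = model.explained_variance
        assert np.all(np.diff(ev) <= 1e-9)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_matches_dense_covariance_eigendecomposition(self, rng):
        """Components equal an explicit 9x9 covariance eigendecomposition on
        tiny 3x3 frames, up to sign."""
        imgs = _images(rng, 6, (3, 3))
        model = sc.fit_pca(imgs, 4)
        mean, comps = oracle_pca_components([im.pixels for im in imgs], 4)
        np.testing.assert_allclose(model.mean_vector, mean, atol=1e-8)
        for got, want in zip(model.components, comps):
            sign = np.sign(got @ want) or 1.0
            np.testing.assert_allclose(got, sign * want, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        imgs = _images(rng, 5, (4, 4))
        m1 = sc.fit_pca(imgs, 3)
        m2 = sc.fit_pca(imgs, 3)
        np.testing.assert_array_equal(m1.components, m2.components)
        for comp in m1.components:
            assert comp[int(np.argmax(np.abs(comp)))] > 0

    def test_errors(self, rng):
        imgs = _images(rng, 3, (3, 3))
        with pytest.raises(ValueError, match="at least 2"):
            sc.fit_pca(imgs[:1], 1)
        with pytest.raises(ValueError, match="rank"):
            sc.fit_pca(imgs, 5)  # rank <= n - 1 = 2
        mixed = imgs[:2] + _images(rng, 1, (4, 4))
        with pytest.raises(ValueError, match="mismatch"):
            sc.fit_pca(mixed, 1)


class TestProject:
    def test_mean_image_projects_to_zero(self, rng):
        imgs = _images(rng, 4, (4, 5))
        model = sc.fit_pca(imgs, 3)
        mean_img = sc.CapacitiveImage(
            pixels=np.round(model.mean_vector).astype(np.uint8).reshape(4, 5)
        )
        # project the exact mean vector (bypassing 8-bit rounding)
        scores = model.components @ (model.mean_vector - model.mean_vector)
        assert np.allclose(scores, 0)
        pc = sc.project(model, mean_img)
        assert pc.shape == (3, 20)

    def test_full_rank_reconstruction_of_training_image(self, rng):
        imgs = _images(rng, 5, (3, 4))
        model = sc.fit_pca(imgs, 4)  # full rank: n - 1
        for img in imgs:
            pc = sc.project(model, img)
            recon = model.mean_vector + pc.sum(axis=0)
            np.testing.assert_allclose(recon, img.as_float().ravel(), atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        model = sc.fit_pca(_images(rng, 3, (3, 3)), 2)
        with pytest.raises(ValueError, match="shape"):
            sc.project(model, _images(rng, 1, (4, 4))[0])


class TestPcaDistance:
    def test_zero_for_identical_representation(self, rng):
        model = sc.fit_pca(_images(rng, 5, (4, 4)), 3)
        pc = sc.project(model, _images(rng, 1, (4, 4))[0])
        assert sc.pca_distance(pc, pc) == 0.0

    def test_single_coordinate_literal_value(self):
        assert sc.pca_distance(np.array([[3.0]]), np.array([[1.0]])) == pytest.approx(4.0)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(20):
            N, P = int(rng.integers(1, 5)), int(rng.integers(1, 12))
            pc1 = rng.normal(size=(N, P))
            pc2 = rng.normal(size=(N, P))
            for rooted in (False, True):
                got = sc.pca_distance(pc1, pc2, rooted=rooted)
                want = oracle_pca_distance(pc1, pc2, rooted)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_symmetry_and_literal_rooted_consistency(self, rng):
        pc1 = rng.normal(size=(3, 7))
        pc2 = rng.normal(size=(3, 7))
        assert sc.pca_distance(pc1, pc2) == pytest.approx(sc.pca_distance(pc2, pc1))
        literal = sc.pca_distance(pc1, pc2, rooted=False)
        rooted = sc.pca_distance(pc1, pc2, rooted=True)
        assert literal == pytest.approx(rooted**2 / 3, rel=1e-12)

    def test_full_rank_rooted_distance_is_image_space_distance(self, rng):
        """Parseval: with all components kept, the rooted distance between two
        training frames equals the Euclidean norm of their difference."""
        imgs = _images(rng, 6, (4, 4))
        model = sc.fit_pca(imgs, 5)
        for a, b in [(0, 1), (2, 4)]:
            d = sc.pca_distance(
                sc.project(model, imgs[a]), sc.project(model, imgs[b]), rooted=True
            )
            want = np.linalg.norm(imgs[a].as_float() - imgs[b].as_float())
            assert d == pytest.approx(want, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            sc.pca_distance(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))


class TestRankSites:
    def test_reference_alone_ranks_zero(self, rng):
        imgs = _images(rng, 3, (4, 4))
        model = sc.fit_pca(imgs, 2)
        ranking = sc.rank_sites(imgs[0], {"ref": imgs[0]}, model)
        assert ranking == [("ref", 0.0)]

    def test_distances_sorted_non_negative_reference_first(self, rng):
        imgs = _images(rng, 6, (5, 5))
        model = sc.fit_pca(imgs, 4)
        labelled = {f"im{i}": im for i, im in enumerate(imgs)}
        ranking = sc.rank_sites(imgs[2], labelled, model)
        dists = [d for _, d in ranking]
        assert ranking[0] == ("im2", 0.0)
        assert all(d >= 0 for d in dists)
        assert dists == sorted(dists)

    def test_study_ranking_groups_control_and_baseline_first(
        self, default_study, default_roi
    ):
        """Frames nearest the control's 2 h capture are the other control
        captures and the before-application frames; every treated
        post-application frame ranks behind them."""
        labels = {f"{s}@{t}": img for (s, t), img in default_study.images.items()}
        model = sc.fit_pca(list(labels.values()), 8)
        ranking = sc.rank_sites(labels["site4@2h"], labels, model)
        near = {lab for lab, _ in ranking[:6]}
        expected_near = {
            "site4@2h", "site4@1h", "site4@before",
            "site1@before", "site2@before", "site3@before",
        }
        assert near == expected_near
        assert ranking[0][0] == "site4@2h" and ranking[0][1] == 0.0
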