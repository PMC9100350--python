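"""PCA-based image similarity and site ranking.

A PCA model is fit on a pooled collection of capacitive frames (flattened
row-major, centred by the collection mean); each frame is then represented by
its per-component contributions pc(i, j) = score_i * component_i[j], i.e. the
rank-N reconstruction split by component.  The distance between two frames is

    d = (1/N) * sum_i sum_j (pc1(i, j) - pc2(i, j))^2        (default)

a mean-over-components squared Euclidean distance; the ``rooted`` variant
drops the 1/N factor and takes the square root, giving the plain Euclidean
norm of the difference of the two rank-N reconstructions (in full rank, the
norm of the centred image difference).  Smaller d means more similar frames.
Ranking the study's frames by distance to a reference frame (e.g. the control
site's final capture) orders sites by how much the applied product changed
their appearance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataio import CapacitiveImage

__all__ = ["PcaModel", "fit_pca", "project", "transform", "pca_distance", "rank_sites"]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class PcaModel:
    """Fitted principal components of an image collection.

    ``mean_vector`` is the per-pixel mean over the training frames;
    ``components`` holds N orthonormal direction vectors as rows, ordered by
    decreasing explained variance, each with a deterministic sign (its
    largest-magnitude coordinate is positive).
    """

    mean_vector: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    image_shape: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.mean_vector.size

    def _flatten(self, img: CapacitiveImage) -> np.ndarray:
        if img.shape != self.image_shape:
            raise ValueError(
                f"image shape {img.shape} does not match model shape {self.image_shape}"
            )
        return img.as_float().ravel()


def fit_pca(images: Sequence[CapacitiveImage], n_components: int) -> PcaModel:
    """Fit a PCA model to >= 2 same-sized frames.

    Components are the top eigendirections of the sample covariance of the
    flattened, mean-centred frames (computed by SVD of the centred data
    matrix, which is exact and deterministic).  ``n_components`` must not
    exceed the rank of the centred collection.
    """
    if len(images) < 2:
        raise ValueError("PCA needs at least 2 images")
    shapes = {img.shape for img in images}
    if len(shapes) != 1:
        raise ValueError(f"images have mismatched shapes: {sorted(shapes)}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    shape = images[0].shape
    X = np.stack([img.as_float().ravel() for img in images])  # (n, P)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * _RANK_RTOL)) if S.size and S[0] > 0 else 0
    if n_components > min(len(images) - 1, X.shape[1]) or n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the collection rank ({rank})"
        )
    components = Vt[:n_components].copy()
    # deterministic sign: largest-magnitude coordinate of each component positive
    for comp in components:
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            comp *= -1.0
    explained = (S[:n_components] ** 2) / (len(images) - 1)
    return PcaModel(
        mean_vector=mean,
        components=components,
        explained_variance=explained,
        image_shape=shape,
    )


def transform(model: PcaModel, img: CapacitiveImage) -> np.ndarray:
    """Component scores of a frame: length-N projection of the centred image."""
    return model.components @ (model._flatten(img) - model.mean_vector)


def project(model: PcaModel, img: CapacitiveImage) -> np.ndarray:
    """Per-component contribution matrix pc of shape (N, n_pixels).

    Row i is score_i * component_i; summing the rows onto the mean vector
    reconstructs the best rank-N approximation of the frame.
    """
    scores = transform(model, img)
    return scores[:, None] * model.components


def pca_distance(pc1: np.ndarray, pc2: np.ndarray, rooted: bool = False) -> float:
    """Distance between two per-component representations.

    Default: mean over components of the squared coordinate differences,
    d = (1/N) * sum_ij (pc1 - pc2)^2.  With ``rooted=True``: the plain
    Euclidean norm sqrt(sum_ij (pc1 - pc2)^2).
    """
    pc1 = np.asarray(pc1, dtype=np.float64)
    pc2 = np.asarray(pc2, dtype=np.float64)
    if pc1.shape != pc2.shape or pc1.ndim != 2:
        raise ValueError(f"mismatched pc shapes {pc1.shape} vs {pc2.shape}")
    s = float(np.sum((pc1 - pc2) ** 2))
    if rooted:
        return float(np.sqrt(s))
    return s / pc1.shape[0]


def rank_sites(
    reference: CapacitiveImage,
    candidates: Mapping[str, CapacitiveImage],
    model: PcaModel,
    rooted: bool = False,
) -> list[tuple[str, float]]:
    """Rank labelled frames by ascending distance to the reference frame.

    Ties preserve the candidates' insertion order; if the reference itself is
    among the candidates it ranks first with distance 0.
    """
    pc_ref = project(model, reference)
    dists = [
        (label, pca_distance(pc_ref, project(model, img), rooted=rooted))
        for label, img in candidates.items()
    ]
    return sorted(dists, key=lambda t: t[1])
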