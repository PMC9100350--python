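"""Independent brute-force oracles for the scoring functions.

Everything here is written as plain nested Python loops directly from the
score definitions, deliberately sharing no code with the package, so the
vectorised implementations can be checked against it on tiny instances.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_match_surface(
    image, template, method: str, literal_mode: bool
) -> np.ndarray:
    """Nested-loop evaluation of one scoring function over all placements."""
    I = np.asarray(image, dtype=np.float64)
    T = np.asarray(template, dtype=np.float64)
    th, tw = T.shape
    ih, iw = I.shape
    n = th * tw

    t_mean = sum(T[b][a] for b in range(th) for a in range(tw)) / n
    sum_t2 = sum(T[b][a] ** 2 for b in range(th) for a in range(tw))
    sum_tc2 = sum((T[b][a] - t_mean) ** 2 for b in range(th) for a in range(tw))
    if method in ("sqdiff_normed", "ccorr_normed") and sum_t2 == 0.0:
        raise ValueError("degenerate template")
    if method == "ccoeff_normed" and sum_tc2 == 0.0:
        raise ValueError("degenerate template")

    R = np.zeros((ih - th + 1, iw - tw + 1))
    for y in range(ih - th + 1):
        for x in range(iw - tw + 1):
            win_mean = sum(I[y + b][x + a] for b in range(th) for a in range(tw)) / n
            num = 0.0
            sum_i2 = 0.0
            sum_ic2 = 0.0
            for b in range(th):
                for a in range(tw):
                    t = T[b][a]
                    i = I[y + b][x + a]
                    tc = t - t_mean
                    ic = i - win_mean
                    sum_i2 += i * i
                    sum_ic2 += ic * ic
                    if method in ("sqdiff", "sqdiff_normed"):
                        num += (t - i) ** 2
                    elif method in ("ccorr", "ccorr_normed"):
                        num += (t * i) ** 2 if literal_mode else t * i
                    else:  # ccoeff family
                        num += (tc * ic) ** 2 if literal_mode else tc * ic
            if method in ("sqdiff", "ccorr", "ccoeff"):
                R[y][x] = num
                continue
            if method == "sqdiff_normed":
                denom = sum_t2 * sum_i2
            elif method == "ccorr_normed":
                denom = sum_t2 * sum_i2
            else:
                denom = sum_tc2 * sum_ic2
            if not literal_mode:
                denom = math.sqrt(denom)
            if denom == 0.0:
                R[y][x] = math.inf if method == "sqdiff_normed" else 0.0
            else:
                R[y][x] = num / denom
    return R


def oracle_pca_distance(pc1, pc2, rooted: bool) -> float:
    """Double-sum distance between two (N, P) component representations."""
    pc1 = np.asarray(pc1, dtype=np.float64)
    pc2 = np.asarray(pc2, dtype=np.float64)
    N, P = pc1.shape
    total = 0.0
    for i in range(N):
        for j in range(P):
            total += (pc1[i][j] - pc2[i][j]) ** 2
    return math.sqrt(total) if rooted else total / N


def oracle_pca_components(images, n_components: int):
    """Eigendecomposition of the explicitly assembled pixel covariance matrix.

    Returns (mean_vector, components) with components as rows ordered by
    decreasing eigenvalue; signs are arbitrary.
    """
    X = np.stack([np.asarray(img, dtype=np.float64).ravel() for img in images])
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = np.zeros((X.shape[1], X.shape[1]))
    for r in range(X.shape[0]):
        cov += np.outer(Xc[r], Xc[r])
    cov /= X.shape[0] - 1
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return mean, evecs[:, order[:n_components]].T
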