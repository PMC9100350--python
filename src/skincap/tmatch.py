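"""Template-matching score surfaces and ROI relocation.

Six sliding-window scoring functions, the standard repertoire for locating a
region of interest (ROI) selected in one capacitive frame inside later frames
of the same skin site:

========================  =============================================================
method                    standard-mode score at placement (x, y)
========================  =============================================================
``sqdiff``                sum over the window of (T - I)^2
``sqdiff_normed``         sum (T - I)^2 / sqrt(sum T^2 * sum I^2)
``ccorr``                 sum (T * I)
``ccorr_normed``          sum (T * I) / sqrt(sum T^2 * sum I^2)
``ccoeff``                sum (T' * I')           with T', I' mean-subtracted
``ccoeff_normed``         sum (T' * I') / sqrt(sum T'^2 * sum I'^2)
========================  =============================================================

Here T is the template, I the image window at (x, y), and the primed
quantities subtract the template mean and the per-window image mean
(recomputed at every placement).  The difference family is minimised; the
correlation families are maximised.

``literal_mode=True`` switches every correlation-family product to its
squared form — sum (T * I)^2 and sum (T' * I')^2 — and drops the square root
from the normalising denominators (sum (T-I)^2 / (sum T^2 * sum I^2) for the
normalised difference score).  This variant mirrors formula transcriptions
that occasionally appear in the applied literature under the same method
names; both are exposed so either convention can be reproduced and compared.

Scores are computed at valid placements only (the template never leaves the
image), in double precision, by direct summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataio import CapacitiveImage

__all__ = [
    "Method",
    "RoiRect",
    "MatchSurface",
    "DegenerateTemplateError",
    "match_surface",
    "best_match",
    "relocate_roi",
]


class Method(str, Enum):
    """The six scoring functions; values double as CLI spellings."""

    SQDIFF = "sqdiff"
    SQDIFF_NORMED = "sqdiff_normed"
    CCORR = "ccorr"
    CCORR_NORMED = "ccorr_normed"
    CCOEFF = "ccoeff"
    CCOEFF_NORMED = "ccoeff_normed"

    @property
    def minimised(self) -> bool:
        """True when the best match is the score minimum."""
        return self in (Method.SQDIFF, Method.SQDIFF_NORMED)

    @property
    def normalised(self) -> bool:
        return self in (Method.SQDIFF_NORMED, Method.CCORR_NORMED, Method.CCOEFF_NORMED)


class DegenerateTemplateError(ValueError):
    """Raised when a normalised method receives a zero-energy template."""


@dataclass(frozen=True)
class RoiRect:
    """Rectangular region: 0-based top-left corner (x = column, y = row),
    half-open extent [x, x+w) x [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI corner must be non-negative")

    def contained_in(self, img: CapacitiveImage | np.ndarray) -> bool:
        h, w = np.asarray(getattr(img, "pixels", img)).shape
        return self.x + self.w <= w and self.y + self.h <= h

    def crop(self, img: CapacitiveImage) -> CapacitiveImage:
        if not self.contained_in(img):
            raise ValueError(f"{self} not contained in {img.shape[1]}x{img.shape[0]} image")
        return CapacitiveImage(
            pixels=img.pixels[self.y : self.y + self.h, self.x : self.x + self.w].copy(),
            pixel_pitch=img.pixel_pitch,
        )


@dataclass(frozen=True)
class MatchSurface:
    """Score grid R over all valid template placements.

    ``scores[y, x]`` is the score with the template's top-left corner at
    image position (x, y); the grid therefore has shape
    ``(H - h + 1, W - w + 1)``.  Placements whose normalising denominator
    vanished (featureless windows) are flagged in ``degenerate`` and assigned
    a worst-case score.
    """

    scores: np.ndarray
    method: Method
    literal_mode: bool = False
    degenerate: np.ndarray | None = None

    @property
    def minimised(self) -> bool:
        return self.method.minimised


def _as_float(img: CapacitiveImage | np.ndarray) -> np.ndarray:
    if isinstance(img, CapacitiveImage):
        return img.as_float()
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image array")
    return arr


def match_surface(
    image: CapacitiveImage | np.ndarray,
    template: CapacitiveImage | np.ndarray,
    method: Method | str = Method.CCORR_NORMED,
    literal_mode: bool = False,
) -> MatchSurface:
    """Score the template against every valid placement in the image.

    Raises :class:`DegenerateTemplateError` for an all-zero template under a
    normalised method, or a constant template under ``ccoeff_normed`` (its
    mean-subtracted energy is zero, so no placement can be scored).
    """
    method = Method(method)
    img = _as_float(image)
    tpl = _as_float(template)
    th, tw = tpl.shape
    ih, iw = img.shape
    if th > ih or tw > iw:
        raise ValueError(f"template {tw}x{th} larger than image {iw}x{ih}")

    sum_t2 = float(np.sum(tpl * tpl))
    tpl_c = tpl - tpl.mean()
    sum_tc2 = float(np.sum(tpl_c * tpl_c))
    if method in (Method.SQDIFF_NORMED, Method.CCORR_NORMED) and sum_t2 == 0.0:
        raise DegenerateTemplateError("all-zero template under a normalised method")
    if method is Method.CCOEFF_NORMED and sum_tc2 == 0.0:
        raise DegenerateTemplateError("constant template under ccoeff_normed")

    n_y, n_x = ih - th + 1, iw - tw + 1
    scores = np.empty((n_y, n_x), dtype=np.float64)
    degenerate = np.zeros((n_y, n_x), dtype=bool)
    windows = sliding_window_view(img, (th, tw))  # view, no copy

    # Row-by-row direct summation: exact sums without materialising all windows.
    for y in range(n_y):
        win = windows[y]  # (n_x, th, tw) strided view
        if method is Method.SQDIFF or method is Method.SQDIFF_NORMED:
            diff = win - tpl
            num = np.einsum("phw,phw->p", diff, diff)
            if method is Method.SQDIFF:
                scores[y] = num
                continue
            sum_i2 = np.einsum("phw,phw->p", win, win)
            denom = sum_t2 * sum_i2
            if not literal_mode:
                denom = np.sqrt(denom)
            bad = denom == 0.0
            degenerate[y] = bad
            with np.errstate(divide="ignore", invalid="ignore"):
                row = num / denom
            row[bad] = np.inf  # worst case for a minimised score
            scores[y] = row
            continue

        if method is Method.CCOEFF or method is Method.CCOEFF_NORMED:
            t_eff, win_eff = tpl_c, win - win.mean(axis=(1, 2), keepdims=True)
            sum_t_eff2 = sum_tc2
        else:
            t_eff, win_eff = tpl, win
            sum_t_eff2 = sum_t2

        if literal_mode:
            prod = win_eff * t_eff
            num = np.einsum("phw,phw->p", prod, prod)
        else:
            num = np.einsum("phw,hw->p", win_eff, t_eff)

        if method.normalised:
            sum_i_eff2 = np.einsum("phw,phw->p", win_eff, win_eff)
            denom = sum_t_eff2 * sum_i_eff2
            if not literal_mode:
                denom = np.sqrt(denom)
            bad = denom == 0.0
            degenerate[y] = bad
            with np.errstate(divide="ignore", invalid="ignore"):
                row = num / denom
            row[bad] = 0.0  # featureless window: worst case for a maximised score
            scores[y] = row
        else:
            scores[y] = num

    return MatchSurface(scores=scores, method=method, literal_mode=literal_mode,
                        degenerate=degenerate)


def best_match(surface: MatchSurface) -> tuple[tuple[int, int], float]:
    """Best placement of a score surface: ((x, y), score).

    Argmin for the difference family, argmax for the correlation families.
    Ties resolve to the smallest y, then the smallest x (row-major first hit).
    """
    scores = surface.scores
    if scores.size == 0:
        raise ValueError("empty match surface")
    flat = np.argmin(scores) if surface.minimised else np.argmax(scores)
    y, x = np.unravel_index(int(flat), scores.shape)
    return (int(x), int(y)), float(scores[y, x])


def relocate_roi(
    reference: CapacitiveImage,
    roi: RoiRect,
    targets: Sequence[CapacitiveImage],
    method: Method | str = Method.CCORR_NORMED,
    literal_mode: bool = False,
) -> list[RoiRect]:
    """Find the ROI selected in the reference frame inside each target frame.

    The ROI crop is used as the template; each returned rectangle has the
    ROI's size at the best-match placement in its target.
    """
    template = roi.crop(reference)
    out = []
    for target in targets:
        surface = match_surface(target, template, method, literal_mode)
        (x, y), _ = best_match(surface)
        out.append(RoiRect(x=x, y=y, w=roi.w, h=roi.h))
    return out
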