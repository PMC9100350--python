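"""Synthetic capacitive skin images and TEWL replicate series.

The generator emulates the statistical structure the downstream analysis
assumes, with known ground truth:

* skin micro-relief as two oriented, gently meandering families of thin dark
  lines over a hydration-dependent base grey level;
* hydration encoded purely as an additive mean-brightness shift (the sensor
  reports an 8-bit grey map of surface permittivity);
* inter-capture translation jitter, creating the ROI-relocation problem;
* instrument noise on replicate TEWL readings with a configurable
  coefficient of variation (CV), drawn from a zero-truncated normal law.

The default :func:`default_design` reproduces a four-site volar-forearm
sunscreen study: three sites treated with SPF 20 / 30 / 50+ products and one
control, imaged and measured before, 1 h after and 2 h after application.
Effect directions follow the study the package models: TEWL falls most under
SPF 50+ and least under SPF 20, while surface hydration (brightness) rises
most under SPF 20 and least under SPF 50+.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .dataio import CapacitiveImage, MeasurementSeries

__all__ = [
    "TextureParams",
    "StudyDesign",
    "SyntheticStudy",
    "generate_texture",
    "shift_and_capture",
    "simulate_series",
    "generate_study",
    "default_design",
    "DEFAULT_SHAPE",
]

#: Default frame size of the sensing die (rows, columns).
DEFAULT_SHAPE = (256, 300)

CONTROL = "control"


@dataclass(frozen=True)
class TextureParams:
    """Parameters of the synthetic micro-relief texture.

    base_level
        Mean grey level of the skin plateau (0–255).
    relief_contrast
        Depth of the dark micro-relief lines, grey levels.
    line_spacing
        Mean spacing between relief lines of one family, pixels (>= 2).
    line_angle_set
        Orientations of the line families, degrees.
    line_width
        Gaussian half-width of a relief line profile, pixels.
    noise_sd
        Additive per-pixel Gaussian noise SD, grey levels.
    seed
        Seed for the texture's random phases and meander.
    """

    base_level: float = 80.0
    relief_contrast: float = 35.0
    line_spacing: float = 24.0
    line_angle_set: tuple[float, ...] = (30.0, 115.0)
    line_width: float = 1.3
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.line_spacing < 2:
            raise ValueError("line_spacing must be >= 2 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.base_level <= 255):
            raise ValueError("base_level must lie in [0, 255]")
        if self.relief_contrast < 0:
            raise ValueError("relief_contrast must be >= 0")


def _relief_depth(
    shape: tuple[int, int], params: TextureParams, rng: np.random.Generator
) -> np.ndarray:
    """Fractional line-depth map in [0, 1]: 1 on a line centre, 0 on plateau."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    keep = np.ones((h, w), dtype=np.float64)  # product of (1 - family profile)
    for angle in params.line_angle_set:
        th = np.deg2rad(angle)
        t = xx * np.cos(th) + yy * np.sin(th)
        # low-frequency meander so lines are not perfectly straight/periodic
        warp = np.zeros_like(t)
        for _ in range(3):
            fx, fy = rng.uniform(-1.0, 1.0, size=2) / (6.0 * params.line_spacing)
            amp = rng.uniform(0.1, 0.35) * params.line_spacing
            phase = rng.uniform(0, 2 * np.pi)
            warp += amp * np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
        t = t + warp + rng.uniform(0, params.line_spacing)
        r = np.mod(t, params.line_spacing)
        dist = np.minimum(r, params.line_spacing - r)
        profile = np.exp(-0.5 * (dist / params.line_width) ** 2)
        keep *= 1.0 - profile
    return 1.0 - keep


def generate_texture(
    shape: tuple[int, int] = DEFAULT_SHAPE, params: TextureParams | None = None
) -> CapacitiveImage:
    """Generate one synthetic capacitive frame.

    Deterministic for a fixed ``params.seed``.  With zero contrast and zero
    noise the output is constant at ``base_level``.
    """
    params = params or TextureParams()
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ValueError(f"image shape must be positive, got {shape}")
    rng = np.random.default_rng(params.seed)
    field_ = np.full((h, w), params.base_level, dtype=np.float64)
    if params.relief_contrast > 0:
        field_ -= params.relief_contrast * _relief_depth((h, w), params, rng)
    if params.noise_sd > 0:
        field_ += rng.normal(0.0, params.noise_sd, size=(h, w))
    return CapacitiveImage(pixels=np.clip(np.round(field_), 0, 255).astype(np.uint8))


def shift_and_capture(
    base: CapacitiveImage,
    dx: int,
    dy: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    fill_params: TextureParams | None = None,
) -> CapacitiveImage:
    """Re-capture ``base`` translated by (dx, dy) pixels, as a later probe placement.

    Content moves right by ``dx`` and down by ``dy``; the strip uncovered at
    the border is refilled with fresh texture (``fill_params``, defaulting to
    the base image's mean level with standard relief), and independent
    Gaussian pixel noise of SD ``noise_sd`` is added.  ``dx = dy = 0`` with
    zero noise returns an identical frame.
    """
    h, w = base.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift ({dx}, {dy}) exceeds image size {w}x{h}")
    rng = np.random.default_rng(seed)
    if fill_params is None:
        fill_params = TextureParams(
            base_level=float(np.clip(base.as_float().mean(), 0, 255)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    else:
        fill_params = replace(fill_params, seed=int(rng.integers(0, 2**31 - 1)))
    if dx == 0 and dy == 0 and noise_sd == 0:
        return CapacitiveImage(pixels=base.pixels.copy(), pixel_pitch=base.pixel_pitch)
    out = generate_texture((h, w), fill_params).as_float()
    src = base.as_float()
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = src[ys_src, xs_src]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return CapacitiveImage(
        pixels=np.clip(np.round(out), 0, 255).astype(np.uint8),
        pixel_pitch=base.pixel_pitch,
    )


def simulate_series(
    site_id: str,
    timepoint: str,
    instrument: str,
    mean: float,
    cv_percent: float,
    n: int,
    rng: np.random.Generator,
) -> MeasurementSeries:
    """Draw ``n`` replicate readings from a zero-truncated normal law.

    SD = mean * cv_percent / 100; truncation at zero keeps readings physical
    (at realistic CVs the truncation is numerically irrelevant).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if n < 1:
        raise ValueError("need at least one replicate")
    sd = mean * cv_percent / 100.0
    if sd == 0:
        vals = np.full(n, mean)
    else:
        a = (0.0 - mean) / sd
        vals = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    return MeasurementSeries(site_id, timepoint, instrument, tuple(float(v) for v in vals))


@dataclass(frozen=True)
class StudyDesign:
    """Ground-truthed design of a synthetic sunscreen study.

    ``sites`` maps site label -> product label; the product named
    ``"control"`` must have zero hydration effect and unit TEWL effect.
    ``hydration_effect`` / ``tewl_effect`` map product -> timepoint -> additive
    grey-level shift / multiplicative TEWL factor (the baseline timepoint is
    implicitly 0 / 1).  ``instrument_cv`` maps instrument label -> CV in %.
    """

    sites: Mapping[str, str] = field(
        default_factory=lambda: {
            "site1": "SPF20",
            "site2": "SPF30",
            "site3": "SPF50+",
            "site4": CONTROL,
        }
    )
    timepoints: tuple[str, ...] = ("before", "1h", "2h")
    baseline_timepoint: str = "before"
    hydration_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "SPF20": {"1h": 60.0, "2h": 50.0},
            "SPF30": {"1h": 40.0, "2h": 35.0},
            "SPF50+": {"1h": 25.0, "2h": 20.0},
            CONTROL: {"1h": 0.0, "2h": 0.0},
        }
    )
    tewl_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "SPF20": {"1h": 0.90, "2h": 0.85},
            "SPF30": {"1h": 0.80, "2h": 0.72},
            "SPF50+": {"1h": 0.68, "2h": 0.58},
            CONTROL: {"1h": 1.0, "2h": 1.0},
        }
    )
    baseline_tewl: float = 12.0
    instrument_cv: Mapping[str, float] = field(
        default_factory=lambda: {"AquaFlux": 3.0, "VapoMeter": 15.0}
    )
    n_replicates: int = 5
    jitter_max: int = 10
    texture: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")
        if self.baseline_timepoint not in self.timepoints:
            raise ValueError("baseline_timepoint must be among timepoints")
        if any(cv < 0 for cv in self.instrument_cv.values()):
            raise ValueError("instrument_cv values must be >= 0")
        post = [t for t in self.timepoints if t != self.baseline_timepoint]
        for product in set(self.sites.values()):
            for table, name in (
                (self.hydration_effect, "hydration_effect"),
                (self.tewl_effect, "tewl_effect"),
            ):
                if product not in table:
                    raise ValueError(f"{name} missing product {product!r}")
                missing = [t for t in post if t not in table[product]]
                if missing:
                    raise ValueError(f"{name}[{product!r}] missing timepoint(s) {missing}")
        if CONTROL in self.sites.values():
            if any(v != 0 for v in self.hydration_effect[CONTROL].values()):
                raise ValueError("control product must have zero hydration_effect")
            if any(v != 1 for v in self.tewl_effect[CONTROL].values()):
                raise ValueError("control product must have unit tewl_effect")

    def hydration_shift(self, site: str, timepoint: str) -> float:
        if timepoint == self.baseline_timepoint:
            return 0.0
        return float(self.hydration_effect[self.sites[site]][timepoint])

    def tewl_factor(self, site: str, timepoint: str) -> float:
        if timepoint == self.baseline_timepoint:
            return 1.0
        return float(self.tewl_effect[self.sites[site]][timepoint])


def default_design(seed: int = 0) -> StudyDesign:
    """The package's paper-like four-site study design with the given seed."""
    return StudyDesign(seed=seed, texture=TextureParams(seed=seed))


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated study: frames, replicate series, and the ground truth."""

    design: StudyDesign
    images: Mapping[tuple[str, str], CapacitiveImage]
    series: tuple[MeasurementSeries, ...]
    #: (site, timepoint) -> true translation (dx, dy) relative to baseline frame
    true_offsets: Mapping[tuple[str, str], tuple[int, int]]
    #: (site, timepoint) -> true mean grey level before capture noise
    true_brightness: Mapping[tuple[str, str], float]
    #: (site, timepoint, instrument) -> true TEWL mean
    true_tewl_mean: Mapping[tuple[str, str, str], float]


def generate_study(
    design: StudyDesign, shape: tuple[int, int] = DEFAULT_SHAPE
) -> SyntheticStudy:
    """Generate all frames and TEWL series of one study, with ground truth.

    Per site: a fixed micro-relief base texture (hydration changes brightness,
    not relief); the baseline frame is an unshifted capture and later frames
    are jittered captures with integer offsets drawn uniformly from
    ``[-jitter_max, jitter_max]``.  Per site/timepoint/instrument: replicate
    TEWL readings with mean ``baseline_tewl * tewl_effect`` and the
    instrument's design CV.
    """
    ss = np.random.SeedSequence(design.seed)
    site_seqs = ss.spawn(len(design.sites))
    images: dict[tuple[str, str], CapacitiveImage] = {}
    offsets: dict[tuple[str, str], tuple[int, int]] = {}
    brightness: dict[tuple[str, str], float] = {}
    tewl_truth: dict[tuple[str, str, str], float] = {}
    series: list[MeasurementSeries] = []

    for (site, product), sseq in zip(design.sites.items(), site_seqs):
        img_rng = np.random.default_rng(sseq.spawn(1)[0])
        tewl_rng = np.random.default_rng(sseq.spawn(1)[0])
        site_tex = replace(design.texture, seed=int(img_rng.integers(0, 2**31 - 1)))
        base = generate_texture(shape, replace(site_tex, noise_sd=0.0))
        base_f = base.as_float()
        for tp in design.timepoints:
            shift = design.hydration_shift(site, tp)
            bright = CapacitiveImage(
                pixels=np.clip(np.round(base_f + shift), 0, 255).astype(np.uint8)
            )
            if tp == design.baseline_timepoint or design.jitter_max == 0:
                dx = dy = 0
            else:
                dx = int(img_rng.integers(-design.jitter_max, design.jitter_max + 1))
                dy = int(img_rng.integers(-design.jitter_max, design.jitter_max + 1))
            frame = shift_and_capture(
                bright,
                dx,
                dy,
                noise_sd=design.texture.noise_sd,
                seed=int(img_rng.integers(0, 2**31 - 1)),
                fill_params=replace(
                    site_tex, base_level=float(np.clip(site_tex.base_level + shift, 0, 255))
                ),
            )
            images[(site, tp)] = frame
            offsets[(site, tp)] = (dx, dy)
            brightness[(site, tp)] = float(base_f.mean() + shift)
            for instr, cv in design.instrument_cv.items():
                mean = design.baseline_tewl * design.tewl_factor(site, tp)
                tewl_truth[(site, tp, instr)] = mean
                series.append(
                    simulate_series(site, tp, instr, mean, cv, design.n_replicates, tewl_rng)
                )

    return SyntheticStudy(
        design=design,
        images=images,
        series=tuple(series),
        true_offsets=offsets,
        true_brightness=brightness,
        true_tewl_mean=tewl_truth,
    )
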