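"""End-to-end study pipeline: simulate -> relocate -> hydration -> TEWL -> PCA.

The pipeline reproduces the full analysis sequence of a four-site sunscreen
study on synthetic data with known ground truth: generate the frames and
replicate TEWL series, relocate the analysis ROI in the post-application
frames by template matching, compute permittivity statistics and
hydration/TEWL ratios, summarise the TEWL repeat measurements per
instrument, and rank all frames by PCA distance to the control site's final
capture.  The summary also records three qualitative ordering checks:

* TEWL change: all treated sites drop, magnitudes ordered by product
  strength, control smallest;
* hydration change: all treated sites brighten, magnitudes ordered
  inversely with product strength;
* PCA ranking: the frames nearest the control's final capture are the other
  control captures and the before-application frames, ahead of every
  treated post-application frame.

Every stochastic draw derives from the single top-level config seed through
numpy seed-sequence spawning inside the study generator, so a fixed config
yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import dataio, hydration, pcasim, tewl, tmatch
from .synth import CONTROL, StudyDesign, SyntheticStudy, TextureParams, generate_study

__all__ = [
    "PipelineConfig",
    "StudyAnalysis",
    "analyze_study",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger("skincap.pipeline")

_EFFECT_TOL = 1e-9


class RoiConfig(BaseModel):
    x: int = 118
    y: int = 96
    w: int = 64
    h: int = 64

    def to_rect(self) -> tmatch.RoiRect:
        return tmatch.RoiRect(self.x, self.y, self.w, self.h)


class TextureConfig(BaseModel):
    base_level: float = 80.0
    relief_contrast: float = 35.0
    line_spacing: float = 24.0
    line_angle_set: tuple[float, ...] = (30.0, 115.0)
    line_width: float = 1.3
    noise_sd: float = 4.0


class DesignConfig(BaseModel):
    """Mirrors :class:`skincap.synth.StudyDesign` (seed supplied separately)."""

    sites: dict[str, str] = Field(
        default_factory=lambda: {
            "site1": "SPF20",
            "site2": "SPF30",
            "site3": "SPF50+",
            "site4": CONTROL,
        }
    )
    timepoints: tuple[str, ...] = ("before", "1h", "2h")
    baseline_timepoint: str = "before"
    hydration_effect: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "SPF20": {"1h": 60.0, "2h": 50.0},
            "SPF30": {"1h": 40.0, "2h": 35.0},
            "SPF50+": {"1h": 25.0, "2h": 20.0},
            CONTROL: {"1h": 0.0, "2h": 0.0},
        }
    )
    tewl_effect: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "SPF20": {"1h": 0.90, "2h": 0.85},
            "SPF30": {"1h": 0.80, "2h": 0.72},
            "SPF50+": {"1h": 0.68, "2h": 0.58},
            CONTROL: {"1h": 1.0, "2h": 1.0},
        }
    )
    baseline_tewl: float = 12.0
    instrument_cv: dict[str, float] = Field(
        default_factory=lambda: {"AquaFlux": 3.0, "VapoMeter": 15.0}
    )
    n_replicates: int = 5
    jitter_max: int = 10
    texture: TextureConfig = Field(default_factory=TextureConfig)

    def to_design(self, seed: int) -> StudyDesign:
        return StudyDesign(
            sites=self.sites,
            timepoints=self.timepoints,
            baseline_timepoint=self.baseline_timepoint,
            hydration_effect=self.hydration_effect,
            tewl_effect=self.tewl_effect,
            baseline_tewl=self.baseline_tewl,
            instrument_cv=self.instrument_cv,
            n_replicates=self.n_replicates,
            jitter_max=self.jitter_max,
            texture=TextureParams(seed=seed, **self.texture.model_dump()),
            seed=seed,
        )


class CalibrationConfig(BaseModel):
    grey_low: float = 0.0
    grey_high: float = 255.0
    eps_low: float = 1.0
    eps_high: float = 81.0

    def to_calibration(self) -> hydration.Calibration:
        return hydration.Calibration(**self.model_dump())


class PipelineConfig(BaseModel):
    """Validated top-level study configuration (YAML/JSON)."""

    seed: int = 0
    image_shape: tuple[int, int] = (256, 300)
    design: DesignConfig = Field(default_factory=DesignConfig)
    roi: RoiConfig = Field(default_factory=RoiConfig)
    match_method: str = "ccorr_normed"
    literal_match: bool = False
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    n_bins: int = 32
    n_components: int = 8
    rooted_pca: bool = False
    ratio_instrument: str = "AquaFlux"

    @field_validator("match_method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        tmatch.Method(v)  # raises ValueError with the offending value
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)


class StudyAnalysis(dict):
    """Summary dict of one study run (JSON-serialisable)."""


def _true_drop(design: StudyDesign, product: str, tp: str) -> float:
    return 1.0 - design.tewl_effect[product][tp]


def _treated_sites(design: StudyDesign) -> list[str]:
    return [s for s, p in design.sites.items() if p != CONTROL]


def _control_sites(design: StudyDesign) -> list[str]:
    return [s for s, p in design.sites.items() if p == CONTROL]


def analyze_study(
    study: SyntheticStudy,
    roi: tmatch.RoiRect,
    method: tmatch.Method | str = tmatch.Method.CCORR_NORMED,
    cal: hydration.Calibration | None = None,
    n_bins: int = 32,
    n_components: int = 8,
    rooted_pca: bool = False,
    ratio_instrument: str | None = None,
) -> StudyAnalysis:
    """Run the relocation / hydration / TEWL / PCA analyses on one study.

    Returns a JSON-serialisable summary: relocated ROI rectangles, per-site
    hydration means and deltas (permittivity scale), the TEWL report rows,
    hydration/TEWL ratios, the PCA distance ranking, and the three ordering
    checks (each "pass", "fail" or "no separation").
    """
    design = study.design
    cal = cal or hydration.Calibration()
    method = tmatch.Method(method)
    baseline = design.baseline_timepoint
    post_tps = [t for t in design.timepoints if t != baseline]
    last_tp = design.timepoints[-1]

    # --- ROI relocation ------------------------------------------------
    rects: dict[tuple[str, str], tmatch.RoiRect] = {}
    for site in design.sites:
        rects[(site, baseline)] = roi
        reference = study.images[(site, baseline)]
        targets = [study.images[(site, tp)] for tp in post_tps]
        for tp, rect in zip(post_tps, tmatch.relocate_roi(reference, roi, targets, method)):
            rects[(site, tp)] = rect

    relocation = {
        f"{site}@{tp}": {
            "x": r.x, "y": r.y, "w": r.w, "h": r.h,
            "true_dx": study.true_offsets[(site, tp)][0],
            "true_dy": study.true_offsets[(site, tp)][1],
            "found_dx": r.x - roi.x,
            "found_dy": r.y - roi.y,
        }
        for (site, tp), r in rects.items()
    }

    # --- hydration statistics on the relocated ROI ---------------------
    eps_means: dict[str, dict[str, float]] = {}
    for site in design.sites:
        eps_means[site] = {
            tp: hydration.roi_stats(study.images[(site, tp)], rects[(site, tp)], cal, n_bins).mean
            for tp in design.timepoints
        }
    eps_deltas = {
        site: hydration.hydration_change(means, baseline) for site, means in eps_means.items()
    }

    # --- TEWL statistics ------------------------------------------------
    report = tewl.site_report(study.series, baseline=baseline)

    ratio_instr = ratio_instrument or next(iter(design.instrument_cv))
    ratios: dict[str, dict[str, float]] = {}
    for site in design.sites:
        ratios[site] = {}
        for tp in design.timepoints:
            row = report[
                (report.site_id == site)
                & (report.timepoint == tp)
                & (report.instrument == ratio_instr)
            ]
            if not row.empty:
                ratios[site][tp] = hydration.hydration_tewl_ratio(
                    eps_means[site][tp], float(row["mean"].iloc[0])
                )

    # --- PCA ranking -----------------------------------------------------
    labels = {f"{site}@{tp}": study.images[(site, tp)] for (site, tp) in study.images}
    model = pcasim.fit_pca(list(labels.values()), n_components)
    controls = _control_sites(design)
    ref_label = f"{controls[0]}@{last_tp}" if controls else next(iter(labels))
    ranking = pcasim.rank_sites(labels[ref_label], labels, model, rooted=rooted_pca)

    checks = {
        "tewl_ordering": _check_tewl(report, design, ratio_instr, last_tp),
        "hydration_ordering": _check_hydration(eps_deltas, design, post_tps),
        "pca_ranking": _check_pca(ranking, design, ref_label),
    }

    return StudyAnalysis(
        relocation=relocation,
        hydration_means=eps_means,
        hydration_deltas=eps_deltas,
        tewl_report=report.to_dict(orient="records"),
        hydration_tewl_ratio=ratios,
        pca_reference=ref_label,
        pca_ranking=[{"label": lab, "distance": d} for lab, d in ranking],
        ordering_checks=checks,
    )


def _check_tewl(
    report: pd.DataFrame, design: StudyDesign, instrument: str, tp: str
) -> dict[str, Any]:
    treated = _treated_sites(design)
    controls = _control_sites(design)
    true_drops = {s: _true_drop(design, design.sites[s], tp) for s in treated}
    if not treated or max(true_drops.values()) < _EFFECT_TOL:
        return {"status": "no separation"}
    sel = report[(report.instrument == instrument) & (report.timepoint == tp)]
    deltas = {r.site_id: r.delta for r in sel.itertuples()}
    order = sorted(treated, key=lambda s: true_drops[s], reverse=True)
    mags = [abs(deltas[s]) for s in order]
    ok = all(deltas[s] < 0 for s in treated)
    ok = ok and all(a > b for a, b in zip(mags, mags[1:]))
    for c in controls:
        ok = ok and abs(deltas[c]) < min(mags)
    return {
        "status": "pass" if ok else "fail",
        "instrument": instrument,
        "timepoint": tp,
        "deltas": {s: float(deltas[s]) for s in deltas},
        "expected_magnitude_order": order,
    }


def _check_hydration(
    eps_deltas: Mapping[str, Mapping[str, float]],
    design: StudyDesign,
    post_tps: list[str],
) -> dict[str, Any]:
    treated = _treated_sites(design)
    shifts = {
        tp: {s: design.hydration_shift(s, tp) for s in treated} for tp in post_tps
    }
    if not treated or max(max(v.values()) for v in shifts.values()) < _EFFECT_TOL:
        return {"status": "no separation"}
    ok = True
    for tp in post_tps:
        order = sorted(treated, key=lambda s: shifts[tp][s], reverse=True)
        vals = [eps_deltas[s][tp] for s in order]
        ok = ok and all(v > 0 for v in vals) and all(a > b for a, b in zip(vals, vals[1:]))
    return {
        "status": "pass" if ok else "fail",
        "deltas": {s: {tp: float(eps_deltas[s][tp]) for tp in post_tps} for s in eps_deltas},
    }


def _check_pca(
    ranking: list[tuple[str, float]], design: StudyDesign, ref_label: str
) -> dict[str, Any]:
    treated = _treated_sites(design)
    baseline = design.baseline_timepoint
    last_tp = design.timepoints[-1]
    true_shifts = [design.hydration_shift(s, t) for s in treated for t in design.timepoints]
    if not treated or max(true_shifts, default=0.0) < _EFFECT_TOL:
        return {"status": "no separation"}
    dist = dict(ranking)
    near = [lab for lab in dist if lab.split("@")[0] not in treated or lab.endswith(f"@{baseline}")]
    far = [lab for lab in dist if lab.split("@")[0] in treated and not lab.endswith(f"@{baseline}")]
    ok = bool(near and far) and max(dist[l] for l in near) < min(dist[l] for l in far)
    return {
        "status": "pass" if ok else "fail",
        "reference": ref_label,
        "nearest": ranking[0][0] if ranking else None,
    }


def _setup_logging(out_dir: Path) -> None:
    handlers: list[logging.Handler] = [
        logging.FileHandler(out_dir / "run.log"),
        logging.StreamHandler(sys.stderr),
    ]
    fmt = logging.Formatter("%(asctime)s [%(name)s] %(levelname)s: %(message)s")
    root = logging.getLogger("skincap")
    root.setLevel(logging.INFO)
    for h in list(root.handlers):  # avoid duplicate handlers on re-runs
        root.removeHandler(h)
        h.close()
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> StudyAnalysis:
    """Run the full pipeline and write its report bundle under ``out_dir``.

    Outputs: per-frame PNGs and the measurement CSV under ``study/``, CSV
    tables for relocation, hydration statistics, the TEWL report and the PCA
    ranking, a ``summary.json`` with the ordering checks, and ``run.log``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)

    logger.info("simulate: generating study (seed=%d)", config.seed)
    design = config.design.to_design(config.seed)
    study = generate_study(design, config.image_shape)
    study_dir = out_dir / "study"
    for (site, tp), img in study.images.items():
        dataio.write_image(img, study_dir / f"{site}_{tp}.png")
    dataio.write_measurements(study.series, study_dir / "measurements.csv")

    logger.info("analyze: method=%s roi=%s", config.match_method, config.roi)
    summary = analyze_study(
        study,
        roi=config.roi.to_rect(),
        method=config.match_method,
        cal=config.calibration.to_calibration(),
        n_bins=config.n_bins,
        n_components=config.n_components,
        rooted_pca=config.rooted_pca,
        ratio_instrument=config.ratio_instrument,
    )

    pd.DataFrame(
        [{"label": k, **v} for k, v in summary["relocation"].items()]
    ).to_csv(out_dir / "roi_relocation.csv", index=False)
    pd.DataFrame(
        [
            {"site_id": s, "timepoint": tp, "eps_mean": m, "eps_delta": summary["hydration_deltas"][s][tp]}
            for s, means in summary["hydration_means"].items()
            for tp, m in means.items()
        ]
    ).to_csv(out_dir / "hydration_stats.csv", index=False)
    pd.DataFrame(summary["tewl_report"]).to_csv(out_dir / "tewl_report.csv", index=False)
    pd.DataFrame(summary["pca_ranking"]).to_csv(out_dir / "pca_distances.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    for name, check in summary["ordering_checks"].items():
        logger.info("check %s: %s", name, check["status"])
    return summary
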