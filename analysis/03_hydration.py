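"""Permittivity (hydration) statistics on the relocated ROI.

Maps the ROI grey levels to the permittivity scale, computes per-site means
and the change versus the before-application frame, and the hydration/TEWL
ratio against the AquaFlux means.  The expected picture: all treated sites
brighten, most for SPF 20 and least for SPF 50+, control flat.

Reads scratch/study/; writes results/hydration_stats.csv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import skincap as sc

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"
OUT = ROOT / "results" / "hydration_stats.csv"
ROI = sc.RoiRect(118, 96, 64, 64)


def main() -> int:
    if not (STUDY_DIR / "truth.json").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    truth = json.loads((STUDY_DIR / "truth.json").read_text())
    cal = sc.Calibration()
    series = sc.read_measurements(STUDY_DIR / "measurements.csv")
    tewl_mean = {
        (s.site_id, s.timepoint): sc.summarize(s)[0]
        for s in series if s.instrument == "AquaFlux"
    }
    rows = []
    for site, product in truth["sites"].items():
        ref = sc.read_image(STUDY_DIR / f"{site}_before.png")
        post = [t for t in truth["timepoints"] if t != "before"]
        targets = [sc.read_image(STUDY_DIR / f"{site}_{tp}.png") for tp in post]
        rects = dict(zip(post, sc.relocate_roi(ref, ROI, targets)), before=ROI)
        means = {
            tp: sc.roi_stats(sc.read_image(STUDY_DIR / f"{site}_{tp}.png"),
                             rects[tp], cal).mean
            for tp in truth["timepoints"]
        }
        deltas = sc.hydration_change(means)
        for tp in truth["timepoints"]:
            rows.append(
                dict(site=site, product=product, timepoint=tp,
                     eps_mean=round(means[tp], 3), eps_delta=round(deltas[tp], 3),
                     hydration_tewl_ratio=round(
                         sc.hydration_tewl_ratio(means[tp], tewl_mean[(site, tp)]), 4))
            )
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    order = (
        df[df.timepoint == "1h"].sort_values("eps_delta", ascending=False)["product"].tolist()
    )
    print(f"\n1 h hydration gain ordering (largest first): {order}  -> {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
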