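"""Relocate the analysis ROI in the post-application frames.

For each site, the ROI selected in the before-application frame is searched
in the 1 h and 2 h frames with normalised cross-correlation; the found
offsets are compared against the generator's true capture jitter.

Reads scratch/study/ (run 01_simulate.py first); writes
results/roi_relocation.csv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import skincap as sc

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"
OUT = ROOT / "results" / "roi_relocation.csv"
ROI = sc.RoiRect(118, 96, 64, 64)


def main() -> int:
    if not (STUDY_DIR / "truth.json").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    truth = json.loads((STUDY_DIR / "truth.json").read_text())
    rows = []
    for site in truth["sites"]:
        ref = sc.read_image(STUDY_DIR / f"{site}_before.png")
        post = [t for t in truth["timepoints"] if t != "before"]
        targets = [sc.read_image(STUDY_DIR / f"{site}_{tp}.png") for tp in post]
        for tp, rect in zip(post, sc.relocate_roi(ref, ROI, targets)):
            tdx, tdy = truth["true_offsets"][f"{site}@{tp}"]
            rows.append(
                dict(site=site, timepoint=tp, found_dx=rect.x - ROI.x,
                     found_dy=rect.y - ROI.y, true_dx=tdx, true_dy=tdy,
                     exact=(rect.x - ROI.x == tdx and rect.y - ROI.y == tdy))
            )
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    print(f"\nexact relocations: {df['exact'].sum()}/{len(df)}  -> {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
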