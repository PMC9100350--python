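"""PCA distance ranking of all frames against the control site's 2 h capture.

Fits principal components on the pooled 12 frames and ranks every frame by
its component-space distance to the control's final capture.  The expected
picture: the control's other captures and the before-application frames rank
nearest; treated post-application frames rank by product strength.

Reads scratch/study/; writes results/pca_distances.csv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import skincap as sc

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"
OUT = ROOT / "results" / "pca_distances.csv"
N_COMPONENTS = 8


def main() -> int:
    if not (STUDY_DIR / "truth.json").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    truth = json.loads((STUDY_DIR / "truth.json").read_text())
    labels = {
        f"{site}@{tp}": sc.read_image(STUDY_DIR / f"{site}_{tp}.png")
        for site in truth["sites"] for tp in truth["timepoints"]
    }
    model = sc.fit_pca(list(labels.values()), N_COMPONENTS)
    control = next(s for s, p in truth["sites"].items() if p == "control")
    ranking = sc.rank_sites(labels[f"{control}@2h"], labels, model)
    df = pd.DataFrame(ranking, columns=["label", "distance"])
    df["product"] = [truth["sites"][lab.split("@")[0]] for lab in df["label"]]
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    print(f"\nnearest to {control}@2h (control): {df['label'][1]}  -> {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
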