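"""Generate the synthetic four-site sunscreen study.

Writes the 12 capacitive frames (4 sites x before/1h/2h), the replicate TEWL
measurement table, and the generator's ground truth (true capture offsets,
brightness and TEWL means) for the downstream analysis steps.

Frames go under scratch/study/ (bulky, regenerable); run this first.
"""

import json
import sys
from pathlib import Path

import skincap as sc

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"


def main() -> None:
    design = sc.default_design(SEED)
    study = sc.generate_study(design)
    for (site, tp), img in study.images.items():
        sc.write_image(img, STUDY_DIR / f"{site}_{tp}.png")
    sc.write_measurements(study.series, STUDY_DIR / "measurements.csv")
    truth = {
        "design_seed": SEED,
        "sites": dict(design.sites),
        "timepoints": list(design.timepoints),
        "true_offsets": {f"{s}@{t}": list(v) for (s, t), v in study.true_offsets.items()},
        "true_brightness": {f"{s}@{t}": v for (s, t), v in study.true_brightness.items()},
        "true_tewl_mean": {f"{s}@{t}@{i}": v for (s, t, i), v in study.true_tewl_mean.items()},
    }
    (STUDY_DIR / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    print(f"wrote {len(study.images)} frames + measurements + truth to {STUDY_DIR}")
    print("site -> product:", dict(design.sites))


if __name__ == "__main__":
    sys.exit(main())
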