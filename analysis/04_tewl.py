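"""TEWL repeat-measurement report and instrument CV contrast.

Summarises the replicate TEWL readings per site/timepoint/instrument (mean,
SD, CV, change versus before) and contrasts the two instruments' empirical
CVs.  The expected picture: on the low-CV instrument, all treated sites show
a TEWL drop ordered SPF 50+ > SPF 30 > SPF 20 with the control nearly flat;
on the high-CV instrument, the small changes drown in replicate noise.

Reads scratch/study/measurements.csv; writes results/tewl_report.csv.
"""

import sys
from pathlib import Path

import skincap as sc

ROOT = Path(__file__).resolve().parents[1]
STUDY_DIR = ROOT / "scratch" / "study"
OUT = ROOT / "results" / "tewl_report.csv"


def main() -> int:
    meas = STUDY_DIR / "measurements.csv"
    if not meas.exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    series = sc.read_measurements(meas)
    report = sc.site_report(series)
    OUT.parent.mkdir(exist_ok=True)
    report.round(4).to_csv(OUT, index=False)
    print(report.round(3).to_string(index=False))
    for instr, grp in report.groupby("instrument"):
        print(f"\n{instr}: mean empirical CV {grp['cv'].mean():.2f}%")
    two_h = report[(report.timepoint == "2h") & (report.instrument == "AquaFlux")]
    print("\nAquaFlux 2 h TEWL change per site (g/m^2/h):")
    print(two_h[["site_id", "delta", "delta_pct"]].round(3).to_string(index=False))
    print(f"-> {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
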