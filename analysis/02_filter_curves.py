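#!/usr/bin/env python
"""Apply the accept/reject rules to the simulated 37 C dataset.

Reads the manifest written by 01_simulate_dataset.py, corrects every curve
(baseline, contact point, tip-sample separation), detects rupture events and
applies the selection rules (>= 3 events, <= N+1 events, no large adhesion,
regular spacing).  Writes per-curve decisions to results/decisions_37C.csv
and prints the acceptance breakdown.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from unfoldkit.io import read_curve, read_manifest
from unfoldkit.pipeline import process_curves
from unfoldkit.study import i27_study_config

logging.basicConfig(level=logging.WARNING)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data_37C"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = i27_study_config(310.15)
    curves = [read_curve(p) for p in read_manifest(DATA / "manifest.json").curve_paths()]
    _, summary, decisions = process_curves(curves, cfg)
    RESULTS.mkdir(exist_ok=True)
    decisions.to_csv(RESULTS / "decisions_37C.csv", index=False)
    accepted = int(decisions["accepted"].sum())
    print(f"accepted {accepted}/{len(decisions)} curves")
    print(decisions["reason_code"].value_counts().to_string())
    print(f"wrote {RESULTS / 'decisions_37C.csv'}")


if __name__ == "__main__":
    main()
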