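#!/usr/bin/env python
"""Quantify unfolding events on the accepted 37 C curves.

Each rising segment of an accepted curve is fitted with the worm-like chain
(p fixed at 0.35 nm), yielding the contour length LC, its increment dLC, the
unfolding force FU and the loading rate at rupture.  Writes the event table
to results/events_37C.csv and the dLC summary (the analogue of a per-
temperature contour-length-increment table) to results/dlc_summary_37C.json.
"""

import json
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
    table, summary, _ = process_curves(curves, cfg)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "events_37C.csv", index=False, float_format="%.9g")
    with open(RESULTS / "dlc_summary_37C.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    print(f"{summary['n_included']} events included "
          f"(of {summary['n_total_quantified']} quantified)")
    print(f"mean dLC = {summary['mean_dlc_nm']:.2f} +/- {summary['sd_dlc_nm']:.2f} nm "
          f"(generator truth 27.7 nm)")
    print(f"wrote {RESULTS / 'events_37C.csv'}")


if __name__ == "__main__":
    main()
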