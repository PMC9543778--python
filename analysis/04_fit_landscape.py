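#!/usr/bin/env python
"""Bell-Evans energy-landscape fit of the 37 C event table.

Fits FU against ln(loading rate) by ordinary least squares over the included
events of all six pulling speeds and converts the line to the landscape
parameters: dx = kBT/S, alpha0 = 1/(S e^{c/S}), dG = kBT ln(A/alpha0) and
D = 2 dG/dx^2.  Writes results/landscape_37C.json and prints the recovered
parameters next to the generator truth.
"""

import json
import logging
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from unfoldkit import presets
from unfoldkit.landscape import fit_fu_vs_lnr

logging.basicConfig(level=logging.WARNING)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "events_37C.csv", comment="#")
    est = fit_fu_vs_lnr(table, 310.15, presets.ARRHENIUS_A_S)
    with open(RESULTS / "landscape_37C.json", "w", encoding="utf-8") as fh:
        json.dump(est.to_dict(), fh, indent=1)
    truth = presets.I27_TEMPERATURE_STUDY[310.15]
    print(f"n events: {est.n_events} across {est.n_speeds} speeds")
    print(f"dx     = {est.delta_x:.3f} +/- {est.delta_x_stderr:.3f} nm "
          f"(generator truth {truth['delta_x_nm']})")
    print(f"alpha0 = {est.alpha0:.3f} +/- {est.alpha0_stderr:.3f} 1/s "
          f"(generator truth {truth['alpha0_s']})")
    print(f"dG     = {est.delta_g:.2f} +/- {est.delta_g_stderr:.2f} kBT (A = {est.arrhenius_a:g} 1/s)")
    print(f"D      = {est.spring_d:.2f} +/- {est.spring_d_stderr:.2f} N/m")
    print(f"wrote {RESULTS / 'landscape_37C.json'}")


if __name__ == "__main__":
    main()
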