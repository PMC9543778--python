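#!/usr/bin/env python
"""Simulate the 37 C force-extension experiment.

Generates 50 retract curves per pulling speed (400..12800 nm/s) for the
9x I27 construct with the published 37 C Bell parameters as ground truth, and
writes the curve files, truth log and manifest under scratch/data_37C/
(large raw data stays out of results/).
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from unfoldkit.pipeline import simulate_to_dir
from unfoldkit.study import i27_study_config

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")
logging.getLogger("unfoldkit.simulate").setLevel(logging.ERROR)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data_37C"
SEED = 1


def main() -> None:
    cfg = i27_study_config(310.15)
    cfg.n_curves_per_speed = 50
    cfg.seed = SEED
    manifest = simulate_to_dir(cfg, OUT)
    cfg.to_yaml(OUT / "config.yaml")
    n = len(cfg.speeds) * cfg.n_curves_per_speed
    print(f"simulated {n} curves at {len(cfg.speeds)} speeds (seed {SEED})")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
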