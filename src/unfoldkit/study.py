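"""Canonical in-silico reproduction of the I27 temperature study.

One function builds the study configuration for a bath temperature (9x I27,
the six-speed ladder, published kinetic parameters as generator truth) and
one runs the full chain: simulate -> correct/filter -> quantify -> Bell-Evans
fit.  Both the acceptance script and the analysis drivers go through here so
the study conditions are defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import replace

from unfoldkit import presets
from unfoldkit.config import PipelineConfig
from unfoldkit.pipeline import fit_landscape_by_temperature, process_curves
from unfoldkit.simulate import simulate_dataset


def i27_study_config(temperature: float = 310.15) -> PipelineConfig:
    """Pipeline configuration reproducing the experiment at ``temperature`` (K).

    Generator kinetics are the published (delta_x, alpha0) for that
    temperature; raises ``KeyError`` for temperatures without published rows.
    """
    row = presets.I27_TEMPERATURE_STUDY[temperature]
    cfg = PipelineConfig()
    cfg.simulation = replace(
        cfg.simulation,
        n_domains=presets.I27_N_DOMAINS,
        delta_lc=presets.I27_DELTA_LC_NM,
        persistence_length=presets.I27_PERSISTENCE_NM,
        cantilever_k=presets.CANTILEVER_K_NM,
        piezo_range=presets.PIEZO_RANGE_NM,
        temperature=temperature,
        delta_x=row["delta_x_nm"],
        alpha0=row["alpha0_s"],
    )
    cfg.speeds = presets.PULLING_SPEEDS_NM_S
    cfg.arrhenius_a = presets.ARRHENIUS_A_S
    return cfg


def run_study(seed: int, n_curves_per_speed: int = 50, temperature: float = 310.15):
    """Simulate and analyse one temperature condition end to end.

    Returns ``(event_table, summary, decisions, estimate)`` where ``estimate``
    is the FU-vs-ln r Bell-Evans fit at the study temperature.
    """
    cfg = i27_study_config(temperature)
    cfg.n_curves_per_speed = n_curves_per_speed
    cfg.seed = seed
    curves, _ = simulate_dataset(cfg.simulation, cfg.speeds, n_curves_per_speed, seed)
    table, summary, decisions = process_curves(curves, cfg)
    estimate = fit_landscape_by_temperature(table, cfg)[temperature]
    return table, summary, decisions, estimate
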