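"""End-to-end composition: correct -> filter -> quantify -> Bell-Evans fit.

The pipeline is deterministic given the configuration (every stochastic
stage is seeded from the config's top-level seed) and resilient per curve:
any stage error is recorded in the decisions table with its reason and the
pipeline moves on.  An empty final event table is a hard error.  Every
output file embeds the configuration hash and package version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from unfoldkit.config import PipelineConfig
from unfoldkit.errors import (
    CorrectionError,
    FitError,
    InsufficientDataError,
    PipelineError,
)
from unfoldkit.events import EVENT_TABLE_COLUMNS, collect_event_table, quantify_events
from unfoldkit.io import read_curve, read_manifest, write_dataset
from unfoldkit.landscape import fit_fu_vs_lnr
from unfoldkit.processing import correct_curve, detect_events, filter_curve
from unfoldkit.simulate import simulate_dataset

logger = logging.getLogger(__name__)

DECISION_COLUMNS = ["curve_id", "accepted", "reason_code", "n_events"]


def _provenance_comment(config: PipelineConfig) -> str:
    from unfoldkit import __version__
    return f"# unfoldkit {__version__} config {config.config_hash()}\n"


def process_curves(curves, config: PipelineConfig):
    """Correct, detect and filter every curve; quantify the accepted ones.

    Returns ``(event_table, summary, decisions)`` where ``decisions`` is a
    DataFrame with one accept/reject row per curve.
    """
    config.validate()
    decisions = []
    all_events = []
    n_accepted = 0
    for curve in curves:
        try:
            corrected = correct_curve(curve, config=config.processing)
        except (CorrectionError, ValueError) as exc:
            decisions.append((curve.curve_id, False, "correction_error", 0))
            logger.info("curve %s unusable: %s", curve.curve_id, exc)
            continue
        ev_idx = detect_events(corrected, config.processing)
        decision = filter_curve(corrected, ev_idx, config.simulation.n_domains,
                                config.processing)
        decisions.append((curve.curve_id, decision.accepted, decision.reason_code,
                          decision.n_events_detected))
        if not decision.accepted:
            continue
        n_accepted += 1
        all_events.extend(quantify_events(
            corrected, ev_idx,
            config.simulation.persistence_length,
            curve.temperature,
            config.events,
        ))

    decisions_df = pd.DataFrame(decisions, columns=DECISION_COLUMNS)
    logger.info("pipeline: %d/%d curves accepted, %d events quantified",
                n_accepted, len(decisions_df), len(all_events))
    if not all_events:
        raise PipelineError("no events quantified from any accepted curve")
    table, summary = collect_event_table(all_events, config=config.events)
    logger.info("pipeline: %d events included; mean dLC = %.2f nm",
                summary["n_included"], summary["mean_dlc_nm"])
    return table, summary, decisions_df


def fit_landscape_by_temperature(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """One FU-vs-ln r Bell-Evans estimate per temperature present."""
    results = {}
    for temp, grp in table.groupby("temperature_K"):
        try:
            est = fit_fu_vs_lnr(grp, float(temp), config.arrhenius_a)
        except (FitError, InsufficientDataError) as exc:
            logger.warning("landscape fit failed at %s K: %s", temp, exc)
            continue
        results[float(temp)] = est
    if not results:
        raise PipelineError("no temperature produced a landscape fit")
    return results


def run_pipeline(manifest_path, config: PipelineConfig, outdir) -> dict:
    """Full file-based pipeline: manifest in, events/decisions/results out."""
    manifest = read_manifest(manifest_path)
    if not manifest.curves:
        raise PipelineError("manifest lists no curves")
    curves = [read_curve(p) for p in manifest.curve_paths()]
    table, summary, decisions = process_curves(curves, config)
    estimates = fit_landscape_by_temperature(table, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stamp = _provenance_comment(config)
    with open(outdir / "events.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(stamp)
        table.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")
    with open(outdir / "decisions.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(stamp)
        decisions.to_csv(fh, index=False, lineterminator="\n")

    from unfoldkit import __version__
    payload = {
        "unfoldkit_version": __version__,
        "config_hash": config.config_hash(),
        "summary": summary,
        "landscape": {f"{t:g}": est.to_dict() for t, est in estimates.items()},
    }
    with open(outdir / "landscape.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return payload


def simulate_to_dir(config: PipelineConfig, outdir) -> Path:
    """Generate the configured dataset and write it (curves+truth+manifest)."""
    config.validate()
    curves, truths = simulate_dataset(
        config.simulation, config.speeds, config.n_curves_per_speed, config.seed,
    )
    provenance = {
        "kind": "simulated",
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    write_dataset(outdir, curves, truths, provenance)
    return Path(outdir) / "manifest.json"
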