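"""Per-event quantification of accepted saw-tooth curves.

For each detected rupture the rising segment preceding it (from the end of
the previous rupture's relaxation to the force maximum) is fitted with the
WLC model at fixed persistence length, giving the contour length LC.  The
contour-length increment dLC of an event is LC minus the LC of the previous
event; the unfolding force FU is the force at the rupture maximum; the
loading rate r is the slope of force versus time just before rupture.

The first event of a curve (contaminated by tip-surface interactions) and
the last (the tether detachment) are flagged ``included_in_stats=False``.
Events whose dLC falls outside a plausibility window around the construct's
per-domain increment (default 27.7 +/- 9 nm) are additionally excluded by
:func:`collect_event_table` -- this catches composite ruptures and missed
events, for which dLC is a fingerprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from unfoldkit.errors import FitError, InsufficientDataError
from unfoldkit.processing import CorrectedCurve
from unfoldkit.wlc import fit_wlc_segment

logger = logging.getLogger(__name__)

#: pN -> N
PN_TO_N = 1e-12

EVENT_TABLE_COLUMNS = [
    "curve_id", "event_index", "fu_pN", "lc_nm", "dlc_nm",
    "loading_rate_Ns", "speed_nms", "temperature_K", "included",
]


@dataclass
class EventConfig:
    """Segmenting, fitting and loading-rate parameters."""

    refold_threshold: float = 10.0  # pN; start of a rising segment after a drop
    min_segment_points: int = 5
    lr_fraction: float = 0.1  # top fraction of the segment's force range
    lr_min_samples: int = 10
    delta_lc_center: float = 27.7  # nm, expected per-domain increment
    delta_lc_halfwidth: float = 9.0  # nm, plausibility half-window


@dataclass
class UnfoldingEvent:
    """One quantified rupture."""

    curve_id: str
    event_index: int  # 1-based within the curve
    fu: float  # pN
    lc: float  # nm
    dlc: Optional[float]  # nm; None for the first fitted event
    loading_rate: float  # N/s
    pulling_speed: float  # nm/s
    temperature: float  # K
    included_in_stats: bool


def _segment_start(curve: CorrectedCurve, prev_peak: Optional[int], peak: int,
                   config: EventConfig) -> int:
    """First sample of the rising segment before ``peak``.

    After the previous rupture the force relaxes to near zero; the segment
    starts where the smoothed force first re-crosses the refold threshold.
    """
    if prev_peak is None:
        return curve.contact_index
    s = curve.smoothed_force
    lo = prev_peak + 1
    if peak - lo < 2:
        return lo
    seg = s[lo:peak]
    bottom = int(np.argmin(seg))
    above = np.nonzero(seg[bottom:] >= config.refold_threshold)[0]
    # if the relaxation never falls below the threshold, start at its minimum
    return lo + bottom + (int(above[0]) if above.size else 0)


def loading_rate_at_rupture(
    curve: CorrectedCurve,
    peak_index: int,
    config: Optional[EventConfig] = None,
    start_index: Optional[int] = None,
) -> float:
    """Loading rate dF/dt (N/s) at the rupture at ``peak_index``.

    Ordinary least-squares slope of force vs time over the samples spanning
    the top ``lr_fraction`` of the segment's force range before the maximum
    (at least ``lr_min_samples`` samples).  Raises
    :class:`InsufficientDataError` when the segment is shorter than the
    window and :class:`FitError` for a non-positive slope (non-physical
    ramp).
    """
    config = config or EventConfig()
    if start_index is None:
        s = curve.smoothed_force
        below = np.nonzero(s[curve.contact_index:peak_index] < config.refold_threshold)[0]
        start_index = curve.contact_index + (int(below[-1]) + 1 if below.size else 0)

    if peak_index - start_index + 1 < config.lr_min_samples:
        raise InsufficientDataError(
            f"segment [{start_index}, {peak_index}] shorter than the "
            f"{config.lr_min_samples}-sample loading-rate window"
        )
    seg_f = curve.smoothed_force[start_index:peak_index + 1]
    fu = seg_f.max()
    span = fu - seg_f.min()
    threshold = fu - config.lr_fraction * span
    # Contiguous run ending at the peak: start just after the last sample
    # below the threshold (a noise spike far from the peak must not widen
    # the window).
    below = np.nonzero(seg_f[:-1] < threshold)[0]
    first = int(below[-1]) + 1 if below.size else 0
    first = max(0, min(first, seg_f.size - config.lr_min_samples))
    idx = np.arange(start_index + first, peak_index + 1)

    times = np.asarray(curve.source.time, dtype=float)[idx]
    # Raw (unsmoothed) force: the median filter is edge-contaminated by
    # post-rupture samples right at the peak, which flattens the ramp top.
    forces = curve.force[idx]
    slope = np.polyfit(times, forces, 1)[0]  # pN/s
    if slope <= 0:
        raise FitError("non-positive force ramp before rupture")
    return float(slope) * PN_TO_N


def quantify_events(
    curve: CorrectedCurve,
    events: Sequence[int],
    persistence_length: float,
    temperature: float,
    config: Optional[EventConfig] = None,
) -> list:
    """WLC-fit every rising segment of an accepted curve.

    Returns a list of :class:`UnfoldingEvent`; events whose segment cannot be
    fitted (too short, degenerate, or non-physical ramp) are dropped with a
    logged reason.  ``event_index`` keeps the detected 1-based position, so
    the first/last exclusion refers to the detected sequence even if an
    intermediate event was dropped.
    """
    config = config or EventConfig()
    events = sorted(int(e) for e in events)
    n_det = len(events)
    sep = curve.tip_sample_separation
    sm = curve.smoothed_force
    out: list = []
    prev_lc: Optional[float] = None

    for j, peak in enumerate(events):
        prev_peak = events[j - 1] if j > 0 else None
        start = _segment_start(curve, prev_peak, peak, config)
        seg_sep = sep[start:peak]
        seg_frc = sm[start:peak]
        # noise can push pre-contact separations slightly negative on the
        # first segment; those samples are outside the WLC domain
        valid = seg_sep >= 0.0
        seg_sep, seg_frc = seg_sep[valid], seg_frc[valid]
        if seg_sep.size < config.min_segment_points:
            logger.info("curve %s event %d dropped: %d-point segment too short",
                        curve.source.curve_id, j + 1, seg_sep.size)
            continue
        order = np.argsort(seg_sep, kind="stable")
        try:
            fit = fit_wlc_segment(seg_sep[order], seg_frc[order],
                                  persistence_length, temperature)
            rate = loading_rate_at_rupture(curve, peak, config, start_index=start)
        except (InsufficientDataError, FitError) as exc:
            logger.info("curve %s event %d dropped: %s", curve.source.curve_id, j + 1, exc)
            continue

        # FU from the raw force localized at the detected rupture maximum;
        # the segment-wide maximum would bleed in earlier, higher teeth when
        # a sub-threshold rupture was missed.
        half = 2
        lo = max(start, peak - half)
        hi = min(curve.force.size, peak + half + 1)
        fu = float(curve.force[lo:hi].max())
        dlc = fit.contour_length - prev_lc if prev_lc is not None else None
        prev_lc = fit.contour_length
        out.append(UnfoldingEvent(
            curve_id=curve.source.curve_id,
            event_index=j + 1,
            fu=fu,
            lc=fit.contour_length,
            dlc=dlc,
            loading_rate=rate,
            pulling_speed=curve.source.pulling_speed,
            temperature=curve.source.temperature,
            included_in_stats=(j != 0 and j != n_det - 1),
        ))
    return out


def collect_event_table(
    events: Sequence[UnfoldingEvent],
    delta_lc_window: Optional[tuple] = None,
    config: Optional[EventConfig] = None,
):
    """Assemble the event table and the dLC summary.

    ``delta_lc_window`` (nm, inclusive) defaults to center +/- halfwidth from
    the config; events outside it, without a dLC, or flagged by the
    first/last rule are marked ``included=False``.  The summary reports the
    total and included counts and mean +/- sd of included dLC per
    temperature.  Raises :class:`InsufficientDataError` if no event survives.
    """
    config = config or EventConfig()
    if delta_lc_window is None:
        delta_lc_window = (config.delta_lc_center - config.delta_lc_halfwidth,
                           config.delta_lc_center + config.delta_lc_halfwidth)
    lo, hi = delta_lc_window

    rows = []
    for ev in events:
        in_window = ev.dlc is not None and lo <= ev.dlc <= hi
        rows.append({
            "curve_id": ev.curve_id,
            "event_index": ev.event_index,
            "fu_pN": ev.fu,
            "lc_nm": ev.lc,
            "dlc_nm": ev.dlc if ev.dlc is not None else np.nan,
            "loading_rate_Ns": ev.loading_rate,
            "speed_nms": ev.pulling_speed,
            "temperature_K": ev.temperature,
            "included": bool(ev.included_in_stats and in_window),
        })
    table = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)

    if table.empty or not table["included"].any():
        raise InsufficientDataError("no events left after dLC filtering; cannot summarise")

    inc = table[table["included"]]
    by_temp = {}
    for temp, grp in inc.groupby("temperature_K"):
        by_temp[float(temp)] = {
            "n": int(len(grp)),
            "mean_dlc_nm": float(grp["dlc_nm"].mean()),
            "sd_dlc_nm": float(grp["dlc_nm"].std(ddof=1)) if len(grp) > 1 else 0.0,
        }
    summary = {
        "n_total_quantified": int(len(table)),
        "n_included": int(len(inc)),
        "mean_dlc_nm": float(inc["dlc_nm"].mean()),
        "sd_dlc_nm": float(inc["dlc_nm"].std(ddof=1)) if len(inc) > 1 else 0.0,
        "by_temperature": by_temp,
        "delta_lc_window_nm": [float(lo), float(hi)],
    }
    return table, summary
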