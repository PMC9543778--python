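"""Raw-curve correction and accept/reject filtering.

Correction of a retract trace proceeds in three steps: (1) a linear baseline,
fitted far from the surface (by default the final 20% of the piezo range,
where the tether has detached), is subtracted; (2) the contact point is
located as the last zero crossing of the median-smoothed force before the
trace first develops real tension; (3) tip-sample separation is computed as
piezo travel from contact minus the cantilever deflection F/k_c.

Filtering applies the standard selection rules for saw-tooth curves: at
least three unfolding events (the first and last are unusable, see
:mod:`unfoldkit.events`); at most n_domains + 1 peaks (the +1 admits the
detachment peak -- more indicates several tethers in parallel); no large
surface adhesion near contact; and regular peak-to-peak spacing (irregular
spacing indicates an ill-formed tether).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from unfoldkit.constants import NM_TO_PN_PER_NM
from unfoldkit.errors import ConfigError, CorrectionError
from unfoldkit.simulate import ForceExtensionCurve


@dataclass
class ProcessingConfig:
    """Correction, detection and filtering parameters."""

    baseline_fraction: float = 0.2  # final fraction of piezo range for baseline fit
    fit_baseline: bool = True  # disable only for traces with no force-free tail
    smooth_window: int = 5  # median-filter window (samples, odd)
    contact_threshold: float = 15.0  # pN; force level marking real tension onset
    drop_min: float = 30.0  # pN; minimum post-peak force drop of a rupture
    drop_window: int = 50  # samples after a peak in which the drop must occur
    min_events: int = 3
    adhesion_window: float = 20.0  # nm of separation near contact
    adhesion_max: float = 500.0  # pN; reject if force < -adhesion_max in window
    spacing_tol: float = 0.4  # relative deviation from median peak spacing

    def validate(self) -> None:
        if self.drop_min <= 0:
            raise ConfigError("drop_min must be positive")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be a positive odd integer")
        if not 0 < self.baseline_fraction < 1:
            raise ConfigError("baseline_fraction must be in (0, 1)")
        if self.drop_window < 1:
            raise ConfigError("drop_window must be >= 1")
        if self.spacing_tol <= 0:
            raise ConfigError("spacing_tol must be positive")
        if self.adhesion_max <= 0:
            raise ConfigError("adhesion_max must be positive")


@dataclass
class CorrectedCurve:
    """Baseline/contact-corrected curve in tip-sample-separation coordinates."""

    tip_sample_separation: np.ndarray  # nm, zero at contact
    force: np.ndarray  # pN, baseline-subtracted
    smoothed_force: np.ndarray  # pN, median-filtered copy used for detection
    contact_index: int
    baseline_slope: float  # pN/nm of piezo
    baseline_offset: float  # pN
    source: ForceExtensionCurve


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the accept/reject rules for one curve."""

    accepted: bool
    reason_code: str  # ok | too_few_events | too_many_events | irregular_spacing | large_adhesion
    n_events_detected: int

    def __post_init__(self) -> None:
        if self.accepted != (self.reason_code == "ok"):
            raise ValueError("reason_code must be 'ok' iff accepted")


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or force.size < window:
        return force.astype(float, copy=True)
    return signal.medfilt(force.astype(float), kernel_size=window)


def correct_curve(
    curve: ForceExtensionCurve,
    cantilever_k: Optional[float] = None,
    config: Optional[ProcessingConfig] = None,
) -> CorrectedCurve:
    """Baseline-subtract, locate contact, and convert to tip-sample separation.

    ``cantilever_k`` (N/m) defaults to the curve's own metadata.  Raises
    :class:`CorrectionError` when the trace never develops tension or shows
    no baseline zero crossing before it.
    """
    config = config or ProcessingConfig()
    config.validate()
    k = cantilever_k if cantilever_k is not None else curve.cantilever_k
    if k <= 0:
        raise ValueError("cantilever_k must be positive")

    piezo = np.asarray(curve.piezo_position, dtype=float)
    raw = np.asarray(curve.force, dtype=float)
    if piezo.size < 10:
        raise CorrectionError("curve too short to correct")

    # Baseline from the far-from-surface tail of the piezo range (the tether
    # has detached there on any real retract trace).
    if config.fit_baseline:
        cutoff = piezo.max() - config.baseline_fraction * (piezo.max() - piezo.min())
        tail = piezo >= cutoff
        slope, offset = np.polyfit(piezo[tail], raw[tail], 1)
    else:
        slope, offset = 0.0, 0.0
    force = raw - (slope * piezo + offset)

    smoothed = _smooth(force, config.smooth_window)

    above = np.nonzero(smoothed > config.contact_threshold)[0]
    if above.size == 0:
        raise CorrectionError(
            f"force never exceeds the contact threshold ({config.contact_threshold} pN); "
            "curve carries no tension"
        )
    first_tension = int(above[0])
    crossings = np.nonzero(
        (smoothed[:first_tension] <= 0.0) & (smoothed[1:first_tension + 1] > 0.0)
    )[0]
    if crossings.size:
        contact = int(crossings[-1])
    elif np.all(smoothed[:first_tension + 1] > 0.0):
        contact = 0  # already in tension at the first sample
    else:
        raise CorrectionError("no zero crossing found before tension onset")

    deflection = force / (k * NM_TO_PN_PER_NM)  # nm
    separation = (piezo - piezo[contact]) - (deflection - deflection[contact])

    return CorrectedCurve(
        tip_sample_separation=separation,
        force=force,
        smoothed_force=smoothed,
        contact_index=contact,
        baseline_slope=float(slope),
        baseline_offset=float(offset),
        source=curve,
    )


def detect_events(curve: CorrectedCurve, config: Optional[ProcessingConfig] = None) -> list:
    """Candidate rupture indices on the corrected curve.

    An event is a local maximum of the median-smoothed force (prominence at
    least ``drop_min``) that is followed within ``drop_window`` samples by a
    drop of at least ``drop_min`` below the maximum.  Indices are 0-based on
    the full trace, sorted and strictly increasing; an empty list is valid.
    """
    config = config or ProcessingConfig()
    config.validate()
    s = curve.smoothed_force
    start = curve.contact_index
    n = s.size
    # Candidate local maxima (plateau-aware) that satisfy the drop rule.
    cand, _ = signal.find_peaks(s[start:], plateau_size=(1, None))
    cand = cand + start
    keep = []
    for p in cand:
        lo, hi = p + 1, min(p + 1 + config.drop_window, n)
        if lo < n and s[p] - s[lo:hi].min() >= config.drop_min:
            keep.append(int(p))
    # Merge candidates on the same tooth: two maxima belong to the same event
    # unless the force actually ruptures (drops >= drop_min below the earlier
    # maximum) between them; the event index is the tooth's highest sample.
    out: list = []
    for p in keep:
        if out:
            q = out[-1]
            if s[q] - s[q + 1:p + 1].min() < config.drop_min:
                if s[p] > s[q]:
                    out[-1] = p
                continue
        out.append(p)
    return out


def filter_curve(
    curve: CorrectedCurve,
    events,
    n_domains: int,
    config: Optional[ProcessingConfig] = None,
) -> FilterDecision:
    """Accept/reject decision for one corrected curve.

    Rules, in order: fewer than ``min_events`` events -> ``too_few_events``;
    more than ``n_domains + 1`` (detachment peak allowed) ->
    ``too_many_events``; force below ``-adhesion_max`` within the first
    ``adhesion_window`` nm of separation -> ``large_adhesion``; peak-to-peak
    separation spacings deviating from their median by more than
    ``spacing_tol`` (final detachment gap excluded) -> ``irregular_spacing``.
    """
    config = config or ProcessingConfig()
    config.validate()
    n_ev = len(events)

    if n_ev < config.min_events:
        return FilterDecision(False, "too_few_events", n_ev)
    if n_ev > n_domains + 1:
        return FilterDecision(False, "too_many_events", n_ev)

    sep = curve.tip_sample_separation
    near = (sep >= 0.0) & (sep <= config.adhesion_window)
    if np.any(near) and curve.force[near].min() < -config.adhesion_max:
        return FilterDecision(False, "large_adhesion", n_ev)

    spacings = np.diff(sep[np.asarray(events, dtype=int)])
    if spacings.size >= 3:
        body = spacings[:-1]  # final gap to the detachment peak is longer by design
        med = np.median(body)
        if med <= 0 or np.any(np.abs(body - med) > config.spacing_tol * med):
            return FilterDecision(False, "irregular_spacing", n_ev)

    return FilterDecision(True, "ok", n_ev)
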