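"""Small shared helpers for constructing synthetic in-memory curves."""

import numpy as np
from scipy.signal import medfilt

from unfoldkit.processing import CorrectedCurve
from unfoldkit.simulate import ForceExtensionCurve


def fake_corrected(force, rate=2500.0, speed=400.0, k=0.06):
    """Wrap a force array as an already-corrected curve (synthetic)."""
    force = np.asarray(force, dtype=float)
    n = force.size
    t = np.arange(1, n + 1) / rate
    curve = ForceExtensionCurve(
        time=t, piezo_position=speed * t, force=force,
        pulling_speed=speed, temperature=296.15, cantilever_k=k,
        sampling_rate=rate, curve_id="fake",
    )
    sep = curve.piezo_position - force / (k * 1000.0)
    return CorrectedCurve(
        tip_sample_separation=sep, force=force,
        smoothed_force=medfilt(force, kernel_size=5) if n >= 5 else force.copy(),
        contact_index=0, baseline_slope=0.0, baseline_offset=0.0, source=curve,
    )
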