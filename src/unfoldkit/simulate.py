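"""Monte Carlo simulation of polyprotein force-extension curves.

A polyprotein of N identical domains is tethered between a surface moved by a
piezo at constant speed v and a Hookean cantilever of spring constant k_c.
At piezo displacement Z the chain extension z satisfies the series force
balance

    k_c * (Z - z) = F_wlc(z; p, Lc, T),

which has a unique root because the left side decreases and the right side
increases in z.  Each folded domain unfolds with the Bell force-activated
rate alpha(F) = alpha0 * exp(F*dx/kBT); an unfolding adds delta_lc to the
contour length, dropping the force and producing one saw-tooth.  Tether
detachment is modelled as a normally distributed force threshold (detachment
empirically needs a larger force than domain unfolding).

Time is integrated on the acquisition grid dt = 1/sampling_rate with the
force held at its step-start value inside each step (explicit scheme) and the
exact per-step rupture probability 1 - exp(-n_folded*alpha(F)*dt).  Within a
constant-contour-length stage this per-step Bernoulli cascade is sampled in
one shot by drawing E ~ Exp(1) and locating the first step where the
cumulative hazard reaches E -- distributionally identical, but vectorizable.

Gaussian instrument noise is added to the *recorded* force channel only; the
kinetics see the noiseless mechanical force.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from unfoldkit.constants import NM_TO_PN_PER_NM, kbt_pn_nm
from unfoldkit.errors import ConfigError
from unfoldkit.wlc import DIVERGENCE_GUARD, WLCParameters, wlc_force

logger = logging.getLogger(__name__)

#: Acquisition-rate rule of the experiment: 2500 Hz at 400 nm/s, scaled
#: proportionally with pulling speed and capped at 80 kHz.
_RATE_AT_400 = 2500.0
_RATE_MIN, _RATE_MAX = 2500.0, 80000.0

#: Folded I27 domain length (nm) used for the default initial contour length.
_FOLDED_DOMAIN_NM = 4.4
_LINKER_NM = 5.0

# Adhesion-artifact shape: a decaying negative spike with a small positive
# rebound, confined to the first ~20 nm of piezo travel.
_ADHESION_AMP_PN = 800.0
_ADHESION_DECAY_NM = 4.0


@dataclass
class SimulationConfig:
    """Generator parameters for one pulling condition.

    Defaults emulate the 9x titin I27 construct pulled at 37 C: per-domain
    contour-length gain 27.7 nm, persistence length 0.35 nm, Bell parameters
    delta_x = 0.17 nm and alpha0 = 0.67 1/s, cantilever 0.06 N/m, 400 nm of
    piezo travel, 5 pN force noise, and detachment at 400 +/- 80 pN.
    """

    n_domains: int = 9
    delta_lc: float = 27.7  # nm per unfolding
    initial_contour_length: Optional[float] = None  # nm; default N*4.4 + 5
    persistence_length: float = 0.35  # nm
    delta_x: float = 0.17  # nm
    alpha0: float = 0.67  # 1/s
    cantilever_k: float = 0.06  # N/m
    pulling_speed: float = 1600.0  # nm/s
    temperature: float = 310.15  # K
    sampling_rate: Optional[float] = None  # Hz; default scales with speed
    force_noise_sd: float = 5.0  # pN
    detachment_force_mean: Union[float, str, None] = 400.0  # pN, or "never"
    detachment_force_sd: float = 80.0  # pN
    adhesion_artifact: bool = False
    piezo_range: float = 400.0  # nm
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_domains < 1:
            raise ConfigError(f"n_domains must be >= 1, got {self.n_domains}")
        if self.delta_lc <= 0:
            raise ConfigError("delta_lc must be > 0")
        if self.alpha0 <= 0:
            raise ConfigError("alpha0 must be > 0")
        if self.delta_x <= 0:
            raise ConfigError("delta_x must be > 0")
        if self.pulling_speed <= 0:
            raise ConfigError("pulling_speed must be > 0")
        if self.persistence_length <= 0:
            raise ConfigError("persistence_length must be > 0")
        if self.cantilever_k <= 0:
            raise ConfigError("cantilever_k must be > 0")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")
        if self.piezo_range <= 0:
            raise ConfigError("piezo_range must be > 0")
        if self.effective_sampling_rate() <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.force_noise_sd < 0:
            raise ConfigError("force_noise_sd must be >= 0")
        if not self.detaches_never():
            if not (isinstance(self.detachment_force_mean, (int, float)) and self.detachment_force_mean > 0):
                raise ConfigError("detachment_force_mean must be positive or 'never'")
            if self.detachment_force_sd < 0:
                raise ConfigError("detachment_force_sd must be >= 0")

    def detaches_never(self) -> bool:
        return self.detachment_force_mean is None or (
            isinstance(self.detachment_force_mean, str)
            and self.detachment_force_mean.lower() == "never"
        )

    def effective_initial_contour_length(self) -> float:
        if self.initial_contour_length is not None:
            return float(self.initial_contour_length)
        return self.n_domains * _FOLDED_DOMAIN_NM + _LINKER_NM

    def effective_sampling_rate(self) -> float:
        if self.sampling_rate is not None:
            return float(self.sampling_rate)
        rate = _RATE_AT_400 * self.pulling_speed / 400.0
        return float(min(max(rate, _RATE_MIN), _RATE_MAX))


@dataclass
class ForceExtensionCurve:
    """One sampled retract trace: time (s), piezo position (nm), force (pN)."""

    time: np.ndarray
    piezo_position: np.ndarray
    force: np.ndarray
    pulling_speed: float  # nm/s
    temperature: float  # K
    cantilever_k: float  # N/m
    sampling_rate: float  # Hz
    curve_id: str = "curve-0"
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.piezo_position) == len(self.force)):
            raise ValueError("time, piezo_position and force must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth record of one simulated domain unfolding."""

    event_index: int  # 1-based within the curve
    sample_index: int  # 0-based position on the trace
    time: float  # s
    force: float  # pN, mechanical force at rupture
    extension: float  # nm, chain end-to-end length at rupture
    lc_before: float  # nm
    lc_after: float  # nm


@dataclass
class SimulationTruth:
    """Per-curve event log enabling parameter-recovery tests."""

    curve_id: str
    events: list = field(default_factory=list)
    detachment_time: Optional[float] = None
    detachment_force: Optional[float] = None
    detachment_index: Optional[int] = None


def bell_rate(force, delta_x: float, alpha0: float, temperature: float):
    """Bell unfolding rate alpha(F) = alpha0 * exp(F*delta_x / kBT), 1/s.

    ``force`` in pN (scalar or array), ``delta_x`` in nm.
    """
    if delta_x <= 0 or alpha0 <= 0:
        raise ValueError("delta_x and alpha0 must be positive")
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    out = alpha0 * np.exp(f * delta_x / kbt_pn_nm(temperature))
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(out)
    return out


def solve_force_balance(
    piezo_displacement: float,
    contour_length: float,
    cantilever_k: float,
    persistence_length: float,
    temperature: float,
) -> tuple:
    """Chain extension z (nm) and force F (pN) at piezo displacement Z (nm).

    Solves k_c*(Z - z) = F_wlc(z) by bracketed bisection on
    [0, min(Z, Lc*(1-guard))]; the balance residual is below 1e-4 pN.
    """
    if piezo_displacement < 0:
        raise ValueError("piezo_displacement must be >= 0")
    if piezo_displacement == 0:
        return 0.0, 0.0
    params = WLCParameters(persistence_length, contour_length, temperature)
    k_pn = cantilever_k * NM_TO_PN_PER_NM
    z_hi = min(piezo_displacement, contour_length * (1.0 - DIVERGENCE_GUARD))

    def g(z: float) -> float:
        return k_pn * (piezo_displacement - z) - wlc_force(z, params)

    if g(z_hi) >= 0.0:  # cantilever still relaxed at the guard: chain carries ~all travel
        z = z_hi
    else:
        z = float(optimize.brentq(g, 0.0, z_hi, xtol=1e-12, rtol=8.9e-16))
    return z, k_pn * (piezo_displacement - z)


def _balance_grid(piezo: np.ndarray, z_lo: np.ndarray, lc: float, k_pn: float,
                  c_pn: float, guard_frac: float) -> tuple:
    """Vectorized bisection for the force balance on a piezo grid.

    ``z_lo`` must be a valid lower bracket (e.g. the solution for a smaller
    contour length).  Returns (z, F) with F = k_c*(Z - z).
    """
    z_max = lc * guard_frac
    lo = np.minimum(z_lo, z_max)
    hi = np.minimum(piezo, z_max)
    lo = np.minimum(lo, hi)
    # 55 halvings of a <=400 nm bracket: z to ~1e-14 nm, residual << 1e-4 pN.
    for _ in range(55):
        mid = 0.5 * (lo + hi)
        u = mid / lc
        f_wlc = c_pn * (u + 0.25 / (1.0 - u) ** 2 - 0.25)
        g_pos = k_pn * (piezo - mid) - f_wlc > 0.0
        lo = np.where(g_pos, mid, lo)
        hi = np.where(g_pos, hi, mid)
    z = 0.5 * (lo + hi)
    return z, k_pn * (piezo - z)


def _adhesion_spike(piezo: np.ndarray) -> np.ndarray:
    spike = -_ADHESION_AMP_PN * np.exp(-piezo / _ADHESION_DECAY_NM)
    rebound = (_ADHESION_AMP_PN / 4.0) * np.exp(-((piezo - 8.0) ** 2) / 10.0)
    out = spike + rebound
    out[piezo > 20.0] = 0.0
    return out


def simulate_curve(
    config: SimulationConfig,
    rng=None,
    *,
    curve_id: str = "sim-0",
    record: bool = True,
):
    """Simulate one retract trace.

    Returns ``(ForceExtensionCurve, SimulationTruth)``; with ``record=False``
    the curve is ``None`` and only the ground-truth event log is produced
    (used by the Monte Carlo landscape search, which only needs rupture
    forces).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    v = config.pulling_speed
    rate = config.effective_sampling_rate()
    dt = 1.0 / rate
    n = max(int(round(config.piezo_range / (v * dt))), 2)
    t = np.arange(n) * dt  # recording starts at contact (piezo = 0)
    piezo = v * t
    k_pn = config.cantilever_k * NM_TO_PN_PER_NM
    kbt = kbt_pn_nm(config.temperature)
    c_pn = kbt / config.persistence_length
    guard_frac = 1.0 - DIVERGENCE_GUARD

    if config.detaches_never():
        detach_threshold = math.inf
    else:
        detach_threshold = max(
            rng.normal(float(config.detachment_force_mean), config.detachment_force_sd), 10.0
        )

    lc = config.effective_initial_contour_length()
    n_folded = config.n_domains
    force = np.zeros(n)
    z_warm = np.zeros(n)
    truth = SimulationTruth(curve_id=curve_id)
    coarse_warned = False

    i0 = 0
    while i0 < n:
        z, f = _balance_grid(piezo[i0:], z_warm[i0:], lc, k_pn, c_pn, guard_frac)
        z_warm[i0:] = z
        m = f.shape[0]

        over = np.nonzero(f >= detach_threshold)[0]
        i_detach = int(over[0]) if over.size else m

        if n_folded > 0 and i_detach > 0:
            # exponent clipped: beyond ~700 the rate is effectively infinite
            # (rupture certain within one step) and exp would overflow.
            lam = n_folded * config.alpha0 * np.exp(
                np.minimum(f[:i_detach] * config.delta_x / kbt, 700.0))
            step_haz = lam * dt
            cum = np.cumsum(step_haz)
            i_rupt = int(np.searchsorted(cum, rng.exponential()))
            # Coarseness check on the steps actually traversed this stage.
            last = min(i_rupt + 1, i_detach)
            if not coarse_warned and last > 0 and step_haz[:last].max() > 0.1:
                logger.warning(
                    "curve %s: per-step unfolding hazard exceeds 0.1 (max %.3f); "
                    "dt=%.2e s may be too coarse",
                    curve_id, float(step_haz[:last].max()), dt,
                )
                coarse_warned = True
        else:
            i_rupt = m

        if i_rupt < i_detach and i_rupt < m:
            stop = i_rupt + 1
            force[i0:i0 + stop] = f[:stop]
            truth.events.append(TruthEvent(
                event_index=len(truth.events) + 1,
                sample_index=i0 + i_rupt,
                time=float(t[i0 + i_rupt]),
                force=float(f[i_rupt]),
                extension=float(z[i_rupt]),
                lc_before=lc,
                lc_after=lc + config.delta_lc,
            ))
            lc += config.delta_lc
            n_folded -= 1
            i0 += stop
            continue

        if i_detach < m:
            force[i0:i0 + i_detach + 1] = f[:i_detach + 1]
            truth.detachment_index = i0 + i_detach
            truth.detachment_time = float(t[i0 + i_detach])
            truth.detachment_force = float(f[i_detach])
            force[i0 + i_detach + 1:] = 0.0
            break

        force[i0:] = f
        break

    if not record:
        return None, truth

    recorded = force.copy()
    if config.adhesion_artifact:
        recorded += _adhesion_spike(piezo)
    if config.force_noise_sd > 0:
        recorded += rng.normal(0.0, config.force_noise_sd, size=n)

    curve = ForceExtensionCurve(
        time=t,
        piezo_position=piezo,
        force=recorded,
        pulling_speed=v,
        temperature=config.temperature,
        cantilever_k=config.cantilever_k,
        sampling_rate=rate,
        curve_id=curve_id,
        provenance="simulated",
    )
    return curve, truth


def simulate_dataset(
    config: SimulationConfig,
    speeds: Sequence[float],
    n_curves_per_speed: int,
    seed: int,
):
    """Simulate ``n_curves_per_speed`` curves at each pulling speed.

    Child seeds are derived deterministically as
    ``SeedSequence(seed).spawn(len(speeds) * n_curves_per_speed)`` in
    speed-major order, so the same ``seed`` reproduces the dataset exactly.
    Returns ``(curves, truths)`` as parallel lists.
    """
    if n_curves_per_speed < 1:
        raise ConfigError("n_curves_per_speed must be >= 1")
    if len(speeds) == 0:
        raise ConfigError("speeds must be non-empty")
    config.validate()

    children = np.random.SeedSequence(seed).spawn(len(speeds) * n_curves_per_speed)
    curves, truths = [], []
    idx = 0
    for speed in speeds:
        cfg = replace(config, pulling_speed=float(speed), sampling_rate=config.sampling_rate)
        for j in range(n_curves_per_speed):
            rng = np.random.default_rng(children[idx])
            cid = f"sim-v{int(round(speed)):05d}-{j:04d}"
            curve, truth = simulate_curve(cfg, rng, curve_id=cid)
            curves.append(curve)
            truths.append(truth)
            idx += 1
    return curves, truths


def sample_unfolding_times_at_force(
    force: float,
    n_folded: int,
    delta_x: float,
    alpha0: float,
    temperature: float,
    dt: float,
    n_samples: int,
    rng,
) -> np.ndarray:
    """First-unfolding times under a clamped force (force-clamp harness).

    Uses the simulator's per-step rupture law (geometric over steps of the
    exact per-step probability 1-exp(-lam*dt)) and then places the event
    within its step by the conditional exponential density, so the returned
    times are exactly Exponential(rate = n_folded * alpha(F)).  Internal
    harness for survival-statistics validation, not a user-facing force-clamp
    mode.
    """
    if n_folded < 1 or dt <= 0 or n_samples < 1:
        raise ValueError("n_folded, dt and n_samples must be positive")
    lam = n_folded * bell_rate(force, delta_x, alpha0, temperature)
    p_step = -math.expm1(-lam * dt)
    steps = rng.geometric(p_step, size=n_samples)
    u = rng.uniform(size=n_samples)
    within = -np.log1p(-u * p_step) / lam
    return (steps - 1) * dt + within
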