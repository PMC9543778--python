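"""Worm-like-chain (WLC) entropic elasticity.

The interpolation form of the WLC relates the stretching force F to the
end-to-end extension z of a chain with persistence length p and contour
length Lc:

    F(z) = (kB*T/p) * [ z/Lc + 1/(4*(1 - z/Lc)^2) - 1/4 ]

F vanishes at z = 0, grows linearly in the entropic-spring limit
(F ~ 3kBT/(2p) * z/Lc for z << Lc) and diverges as z -> Lc.  For rising
segments of a saw-tooth unfolding curve only Lc is fitted; p is fixed at the
average length of an amino acid (0.35 nm) unless explicitly floated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from unfoldkit.constants import kbt_pn_nm
from unfoldkit.errors import FitError, InsufficientDataError

#: Relative distance from z = Lc beyond which the model is considered
#: divergent: the admissible domain is z/Lc <= 1 - DIVERGENCE_GUARD.
DIVERGENCE_GUARD = 1e-6


@dataclass(frozen=True)
class WLCParameters:
    """WLC parameter triple: p (nm), Lc (nm), T (K)."""

    persistence_length: float
    contour_length: float
    temperature: float

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError(f"persistence_length must be > 0, got {self.persistence_length}")
        if self.contour_length <= 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass(frozen=True)
class WLCFitResult:
    """Outcome of a single-segment contour-length fit."""

    contour_length: float  # nm
    contour_length_stderr: float  # nm
    persistence_length_used: float  # nm
    rms_residual: float  # pN
    n_points: int


def _check_extension(z, contour_length: float):
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("extension z must be non-negative")
    if np.any(z > contour_length * (1.0 - DIVERGENCE_GUARD)):
        raise ValueError(
            f"extension z must stay below Lc*(1-{DIVERGENCE_GUARD}); the WLC diverges at z = Lc"
        )
    return z


def wlc_force(z, params: WLCParameters):
    """WLC force (pN) at end-to-end extension ``z`` (nm; scalar or array).

    Raises ``ValueError`` if z < 0 or z is at/beyond the divergence guard.
    """
    zz = _check_extension(z, params.contour_length)
    u = zz / params.contour_length
    bracket = u + 0.25 / (1.0 - u) ** 2 - 0.25
    force = (kbt_pn_nm(params.temperature) / params.persistence_length) * bracket
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(force)
    return force


def wlc_stiffness(z, params: WLCParameters):
    """dF/dz in pN/nm, the local WLC stiffness at extension ``z`` (nm)."""
    zz = _check_extension(z, params.contour_length)
    u = zz / params.contour_length
    lc = params.contour_length
    dfdz = (kbt_pn_nm(params.temperature) / params.persistence_length) * (
        1.0 / lc + 0.5 / (lc * (1.0 - u) ** 3)
    )
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(dfdz)
    return dfdz


def wlc_extension(force: float, params: WLCParameters) -> float:
    """Invert the WLC: extension z (nm) at which the chain pulls with ``force`` (pN).

    Numeric inverse by bracketed root finding; satisfies
    ``wlc_force(wlc_extension(F)) == F`` to better than 1e-6 pN.
    """
    if force < 0:
        raise ValueError(f"force must be non-negative, got {force}")
    if force == 0:
        return 0.0
    z_max = params.contour_length * (1.0 - DIVERGENCE_GUARD)
    f_max = wlc_force(z_max, params)
    if force >= f_max:
        raise ValueError(f"force {force} pN exceeds the model's guarded range ({f_max:.3g} pN)")
    return float(optimize.brentq(
        lambda z: wlc_force(z, params) - force, 0.0, z_max, xtol=1e-12, rtol=8.9e-16,
    ))


def fit_wlc_segment(
    separations,
    forces,
    p_fixed: float,
    temperature: float,
    *,
    float_persistence: bool = False,
) -> WLCFitResult:
    """Least-squares WLC fit of one rising force segment.

    ``separations`` (nm) and ``forces`` (pN) are samples of a stretching ramp;
    the contour length Lc is the single free parameter (ordinary least squares
    on force residuals), with p fixed at ``p_fixed`` (nm).  Set
    ``float_persistence=True`` to fit p as well.

    Raises
    ------
    InsufficientDataError
        fewer than 5 points.
    FitError
        flat/degenerate segment or non-convergence.
    """
    sep = np.asarray(separations, dtype=float)
    frc = np.asarray(forces, dtype=float)
    if sep.shape != frc.shape or sep.ndim != 1:
        raise ValueError("separations and forces must be 1-D arrays of equal length")
    if sep.size < 5:
        raise InsufficientDataError(f"need >= 5 points for a WLC fit, got {sep.size}")
    if np.any(np.diff(sep) < 0):
        raise ValueError("separations must be non-decreasing (sort the segment first)")
    if p_fixed <= 0:
        raise ValueError("p_fixed must be positive")

    # Degeneracy guard: the segment must actually rise.
    force_span = float(np.ptp(frc))
    trend = np.polyfit(sep, frc, 1)[0] if sep[-1] > sep[0] else 0.0
    if not np.isfinite(trend) or trend <= 0 or force_span < 1e-9:
        raise FitError("segment has no rising force trend; WLC fit is degenerate")

    z_end = sep[-1]
    lc_floor = z_end / (1.0 - DIVERGENCE_GUARD) + 1e-9

    def initial_lc() -> float:
        # Invert the dimensionless WLC at the segment end for a starting Lc.
        f_end = max(float(np.median(frc[-5:])), 1e-3)
        g = f_end * p_fixed / kbt_pn_nm(temperature)
        u = optimize.brentq(
            lambda uu: uu + 0.25 / (1.0 - uu) ** 2 - 0.25 - g, 0.0, 1.0 - 1e-9
        )
        u = min(max(u, 1e-6), 1.0 - 1e-4)
        return max(z_end / u, lc_floor * 1.001)

    def model_fixed(z, lc):
        params = WLCParameters(p_fixed, float(lc), temperature)
        zz = np.minimum(z, lc * (1.0 - DIVERGENCE_GUARD))
        return wlc_force(zz, params)

    def model_float(z, lc, p):
        params = WLCParameters(float(p), float(lc), temperature)
        zz = np.minimum(z, lc * (1.0 - DIVERGENCE_GUARD))
        return wlc_force(zz, params)

    try:
        if float_persistence:
            popt, pcov = optimize.curve_fit(
                model_float, sep, frc, p0=[initial_lc(), p_fixed],
                bounds=([lc_floor, 1e-3], [np.inf, 100.0]), maxfev=10000,
            )
            lc_hat, p_used = float(popt[0]), float(popt[1])
            lc_var = pcov[0, 0]
            resid = frc - model_float(sep, *popt)
        else:
            popt, pcov = optimize.curve_fit(
                model_fixed, sep, frc, p0=[initial_lc()],
                bounds=([lc_floor], [np.inf]), maxfev=10000,
            )
            lc_hat, p_used = float(popt[0]), p_fixed
            lc_var = pcov[0, 0]
            resid = frc - model_fixed(sep, lc_hat)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"WLC fit did not converge: {exc}") from exc

    if not np.isfinite(lc_hat) or lc_hat <= z_end:
        raise FitError(f"WLC fit returned non-physical Lc={lc_hat}")
    stderr = float(np.sqrt(lc_var)) if np.isfinite(lc_var) and lc_var >= 0 else float("nan")
    return WLCFitResult(
        contour_length=lc_hat,
        contour_length_stderr=stderr,
        persistence_length_used=p_used,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=int(sep.size),
    )
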