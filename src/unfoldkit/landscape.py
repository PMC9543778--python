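"""Bell-Evans dynamic force spectroscopy and energy-landscape parameters.

Under Bell kinetics, alpha(F) = alpha0*exp(F*dx/kBT), rupture forces grow
linearly with the logarithm of the loading rate r = dF/dt:

    FU = (kBT/dx)*ln r + c,      S = kBT/dx,
    c  = (kBT/dx)*ln(dx/(alpha0*kBT))   =>   alpha0 = 1/(S*exp(c/S)),

with S and c in newtons and r in N/s (the unit convention is recorded in
every estimate because c absorbs it).  Two estimators are provided: the
per-event fit of FU against ln r over all pulling speeds pooled, and the
most-probable-force route, Fmp against ln v (v in m/s), whose intercept
additionally absorbs the effective stiffness k (r = k*v) and therefore only
yields alpha0 once an explicit k is supplied.

Derived quantities: barrier height dG = kBT*ln(A/alpha0) (Arrhenius
prefactor A ~ 1e7 1/s in proteins, configurable) and the folded-state spring
constant D = 2*dG/dx**2 under a parabolic-well assumption.  Uncertainties
propagate from the fit's slope/intercept covariance by the first-order delta
method; a bootstrap over events is available as a cross-check.  A Monte
Carlo grid search refines (dx, alpha0) by matching simulated to observed
rupture-force distributions via the Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from unfoldkit.constants import kbt_joule
from unfoldkit.errors import ConfigError, FitError, InsufficientDataError
from unfoldkit.simulate import SimulationConfig, simulate_curve

#: Default Arrhenius pre-factor (1/s).
DEFAULT_ARRHENIUS_A = 1.0e7

PN_TO_N = 1e-12
M_TO_NM = 1e9


@dataclass
class LandscapeEstimate:
    """One Bell-Evans fit and its derived landscape parameters."""

    method: str  # fmp_vs_lnv | fu_vs_lnr | mc_search
    temperature: float  # K
    slope: float  # N per ln-unit
    intercept: float  # N
    slope_stderr: float
    intercept_stderr: float
    delta_x: float  # nm
    delta_x_stderr: float
    alpha0: Optional[float]  # 1/s; None if the method cannot identify it
    alpha0_stderr: Optional[float]
    delta_g: Optional[float]  # kBT units
    delta_g_stderr: Optional[float]
    spring_d: Optional[float]  # N/m
    spring_d_stderr: Optional[float]
    arrhenius_a: float = DEFAULT_ARRHENIUS_A
    n_events: Optional[int] = None
    n_speeds: Optional[int] = None
    rate_unit: str = "N/s"
    speed_unit: str = "m/s"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "T_K": self.temperature,
            "S_N": self.slope,
            "c_N": self.intercept,
            "S_se_N": self.slope_stderr,
            "c_se_N": self.intercept_stderr,
            "dx_nm": self.delta_x,
            "dx_se": self.delta_x_stderr,
            "alpha0_s": self.alpha0,
            "alpha0_se": self.alpha0_stderr,
            "dG_kBT": self.delta_g,
            "dG_se": self.delta_g_stderr,
            "D_Nm": self.spring_d,
            "D_se": self.spring_d_stderr,
            "A_s": self.arrhenius_a,
            "n_events": self.n_events,
            "n_speeds": self.n_speeds,
            "rate_unit": self.rate_unit,
            "speed_unit": self.speed_unit,
        }


def delta_x_from_slope(slope: float, temperature: float) -> float:
    """Distance to the transition state dx (nm) from the slope S (N)."""
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    return kbt_joule(temperature) / slope * M_TO_NM


def alpha0_from_intercept(intercept: float, slope: float) -> float:
    """Zero-force unfolding rate alpha0 = 1/(S*exp(c/S)), 1/s.

    ``intercept`` and ``slope`` in newtons, under the N/s loading-rate
    convention.  Computed in log space to avoid overflow of exp(c/S).
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    return math.exp(-math.log(slope) - intercept / slope)


def barrier_height(alpha0: float, arrhenius_a: float = DEFAULT_ARRHENIUS_A) -> float:
    """Barrier height dG in kBT units via Arrhenius: ln(A/alpha0)."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    if arrhenius_a <= 0:
        raise ValueError("arrhenius_a must be positive")
    if alpha0 > arrhenius_a:
        raise ValueError("alpha0 exceeds the Arrhenius prefactor: negative barrier")
    return math.log(arrhenius_a / alpha0)


def protein_spring_constant(delta_g_kbt: float, delta_x_nm: float, temperature: float) -> float:
    """Folded-state spring constant D = 2*dG/dx**2 (N/m), parabolic well."""
    if delta_x_nm <= 0:
        raise ValueError("delta_x must be positive")
    if delta_g_kbt < 0:
        raise ValueError("delta_g must be non-negative")
    dg_joule = delta_g_kbt * kbt_joule(temperature)
    dx_m = delta_x_nm * 1e-9
    return 2.0 * dg_joule / dx_m**2


def propagate_uncertainties(
    slope: float,
    intercept: float,
    covariance,
    temperature: float,
    arrhenius_a: float = DEFAULT_ARRHENIUS_A,
) -> dict:
    """First-order (delta-method) standard errors of dx, alpha0, dG and D.

    ``covariance`` is the 2x2 slope/intercept covariance of the linear fit
    (N^2).  Closed-form Jacobians, with ln(alpha0) = -ln S - c/S and
    dG = ln A + ln S + c/S (kBT units), D = 2*dG*S^2/kBT:

        d(dx)/dS   = -kBT/S^2
        d(dG)/dS   = 1/S - c/S^2,            d(dG)/dc = 1/S
        d(ln a0)/dS = -d(dG)/dS,             d(ln a0)/dc = -1/S
        dD/dS      = 2*S^2/kBT*d(dG)/dS + 4*dG*S/kBT,   dD/dc = 2*S/kBT

    Returns NaN stderrs for a singular/invalid covariance.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (2, 2) or not np.all(np.isfinite(cov)):
        nan = float("nan")
        return {"delta_x": nan, "alpha0": nan, "delta_g": nan, "spring_d": nan}
    kbt = kbt_joule(temperature)
    s, c = slope, intercept
    alpha0 = alpha0_from_intercept(c, s)
    dg = barrier_height(alpha0, arrhenius_a) if alpha0 <= arrhenius_a else float("nan")

    def quad(jac: np.ndarray) -> float:
        v = float(jac @ cov @ jac)
        return math.sqrt(v) if v >= 0 else float("nan")

    j_dx = np.array([-kbt / s**2 * M_TO_NM, 0.0])
    ddg_ds = 1.0 / s - c / s**2
    ddg_dc = 1.0 / s
    j_dg = np.array([ddg_ds, ddg_dc])
    sd_ln_a0 = quad(j_dg)  # |d ln a0| = |d dG| component-wise
    j_d = np.array([
        2.0 * s**2 / kbt * ddg_ds + 4.0 * dg * s / kbt,
        2.0 * s / kbt,
    ])
    return {
        "delta_x": quad(j_dx),
        "alpha0": alpha0 * sd_ln_a0,
        "delta_g": sd_ln_a0,
        "spring_d": quad(j_d),
    }


def _ols_line(x: np.ndarray, y: np.ndarray):
    """OLS fit y = S*x + c with the (2x2) parameter covariance."""
    n = x.size
    design = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - 2
    xtx_inv = np.linalg.inv(design.T @ design)
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * xtx_inv
    return float(beta[0]), float(beta[1]), cov


def _assemble(method: str, slope: float, intercept: float, cov: np.ndarray,
              temperature: float, arrhenius_a: float, alpha0: Optional[float],
              n_events: Optional[int], n_speeds: Optional[int]) -> LandscapeEstimate:
    dx = delta_x_from_slope(slope, temperature)
    if alpha0 is not None:
        dg = barrier_height(alpha0, arrhenius_a)
        d = protein_spring_constant(dg, dx, temperature)
    else:
        dg = d = None
    sds = propagate_uncertainties(slope, intercept, cov, temperature, arrhenius_a)
    return LandscapeEstimate(
        method=method,
        temperature=temperature,
        slope=slope,
        intercept=intercept,
        slope_stderr=float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else float("nan"),
        intercept_stderr=float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else float("nan"),
        delta_x=dx,
        delta_x_stderr=sds["delta_x"],
        alpha0=alpha0,
        alpha0_stderr=sds["alpha0"] if alpha0 is not None else None,
        delta_g=dg,
        delta_g_stderr=sds["delta_g"] if alpha0 is not None else None,
        spring_d=d,
        spring_d_stderr=sds["spring_d"] if alpha0 is not None else None,
        arrhenius_a=arrhenius_a,
        n_events=n_events,
        n_speeds=n_speeds,
    )


def most_probable_force(forces, config=None) -> float:
    """Most probable rupture force Fmp (pN) from a force sample.

    Freedman-Diaconis histogram; a Gaussian is fitted to the modal bin +/- 2
    bins and its center returned, falling back to the modal bin center if the
    Gaussian fit fails.  Requires at least 30 forces.
    """
    f = np.asarray(forces, dtype=float)
    if f.size < 30:
        raise InsufficientDataError(f"need >= 30 forces for Fmp, got {f.size}")
    if np.ptp(f) == 0:
        return float(f[0])
    edges = np.histogram_bin_edges(f, bins="fd")
    counts, edges = np.histogram(f, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    m = int(np.argmax(counts))
    lo, hi = max(m - 2, 0), min(m + 3, counts.size)
    x, y = centers[lo:hi], counts[lo:hi].astype(float)
    modal_center = float(centers[m])
    if x.size < 3:
        return modal_center
    width = edges[1] - edges[0]

    def gauss(v, a, mu, sigma):
        return a * np.exp(-0.5 * ((v - mu) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gauss, x, y, p0=[y.max(), modal_center, 2.0 * width], maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return modal_center
    mu = float(popt[1])
    if not (x[0] - width <= mu <= x[-1] + width):
        return modal_center
    return mu


def fit_fmp_vs_lnv(
    fmp_per_speed: Sequence,
    temperature: float,
    effective_k: Optional[float] = None,
    arrhenius_a: float = DEFAULT_ARRHENIUS_A,
) -> LandscapeEstimate:
    """Bell-Evans fit of Fmp against ln(pulling speed).

    ``fmp_per_speed``: (pulling speed in nm/s, Fmp in pN) pairs, one per
    speed; the regression uses ln(v) with v in m/s.  The slope gives dx; the
    intercept only yields alpha0 given the effective stiffness
    ``effective_k`` (N/m) because c absorbs ln k (r = k*v).  Without it,
    alpha0 (and dG, D) are left as None.
    """
    pairs = [(float(v), float(f)) for v, f in fmp_per_speed]
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 speeds, got {len(pairs)}")
    v = np.array([p[0] for p in pairs]) * 1e-9  # nm/s -> m/s
    fmp = np.array([p[1] for p in pairs]) * PN_TO_N
    if np.any(v <= 0):
        raise ValueError("pulling speeds must be positive")
    x = np.log(v)
    if np.ptp(x) == 0:
        raise FitError("all speeds identical; ln v has zero range")
    slope, intercept, cov = _ols_line(x, fmp)
    if slope <= 0:
        raise FitError(f"non-positive slope {slope}; Fmp does not grow with speed")
    alpha0 = None
    if effective_k is not None:
        if effective_k <= 0:
            raise ValueError("effective_k must be positive")
        # c = S*ln(k*dx/(alpha0*kBT)) = S*ln k - S*ln S + S*ln(dx/kBT*S) ...
        # equivalently alpha0 = k/(S*exp(c/S)).
        alpha0 = effective_k * math.exp(-math.log(slope) - intercept / slope)
    est = _assemble("fmp_vs_lnv", slope, intercept, cov, temperature, arrhenius_a,
                    alpha0, None, len(pairs))
    return est


def fit_fu_vs_lnr(
    events,
    temperature: float,
    arrhenius_a: float = DEFAULT_ARRHENIUS_A,
) -> LandscapeEstimate:
    """Bell-Evans fit of per-event FU against ln(loading rate).

    ``events`` is the event table (DataFrame with columns ``fu_pN``,
    ``loading_rate_Ns``, ``speed_nms``, ``included``); only included events
    enter the ordinary least-squares fit of FU (N) on ln r (r in N/s).
    Requires events from at least 3 distinct pulling speeds.
    """
    table = events if isinstance(events, pd.DataFrame) else pd.DataFrame(events)
    if "included" in table.columns:
        table = table[table["included"]]
    if table.empty:
        raise InsufficientDataError("no included events")
    speeds = np.unique(table["speed_nms"].to_numpy(dtype=float))
    if speeds.size < 3:
        raise InsufficientDataError(
            f"events span only {speeds.size} pulling speed(s); need >= 3 for a "
            "usable ln r range"
        )
    r = table["loading_rate_Ns"].to_numpy(dtype=float)
    fu = table["fu_pN"].to_numpy(dtype=float) * PN_TO_N
    if np.any(r <= 0):
        raise ValueError("loading rates must be positive")
    x = np.log(r)
    if np.ptp(x) == 0:
        raise FitError("zero variance in ln r; cannot fit")
    slope, intercept, cov = _ols_line(x, fu)
    if slope <= 0:
        raise FitError(f"non-positive slope {slope} in FU vs ln r")
    alpha0 = alpha0_from_intercept(intercept, slope)
    return _assemble("fu_vs_lnr", slope, intercept, cov, temperature, arrhenius_a,
                     alpha0, int(len(table)), int(speeds.size))


def bootstrap_landscape(
    events: pd.DataFrame,
    temperature: float,
    n_boot: int = 200,
    seed: int = 0,
    arrhenius_a: float = DEFAULT_ARRHENIUS_A,
) -> dict:
    """Bootstrap (event-resampling) standard errors for the FU-vs-ln r fit."""
    table = events[events["included"]] if "included" in events.columns else events
    rng = np.random.default_rng(seed)
    n = len(table)
    dx, a0 = [], []
    for _ in range(n_boot):
        sample = table.iloc[rng.integers(0, n, size=n)]
        try:
            est = fit_fu_vs_lnr(sample.assign(included=True), temperature, arrhenius_a)
        except (FitError, InsufficientDataError):
            continue
        dx.append(est.delta_x)
        a0.append(est.alpha0)
    if len(dx) < 2:
        raise FitError("bootstrap produced too few successful fits")
    return {
        "delta_x": float(np.std(dx, ddof=1)),
        "alpha0": float(np.std(a0, ddof=1)),
        "n_successful": len(dx),
    }


def mc_landscape_search(
    observed_by_speed: dict,
    delta_x_grid: Sequence[float],
    alpha0_grid: Sequence[float],
    sim_config: SimulationConfig,
    seed: int,
    n_sim: int = 200,
):
    """Grid search of (dx, alpha0) by matching rupture-force distributions.

    ``observed_by_speed`` maps pulling speed (nm/s) to an array of observed
    rupture forces (pN).  For each grid point, ``n_sim`` curves per speed are
    simulated (truth-only, no recording), rupture forces pooled per speed,
    and the objective is the sum over speeds of the two-sample
    Kolmogorov-Smirnov statistic against the observations.  Returns
    ``((best_dx, best_alpha0), surface)`` with the full objective surface as
    a DataFrame.  Deterministic given ``seed``.
    """
    dxs = [float(d) for d in delta_x_grid]
    a0s = [float(a) for a in alpha0_grid]
    if not dxs or not a0s:
        raise ConfigError("delta_x_grid and alpha0_grid must be non-empty")
    if any(d <= 0 for d in dxs) or any(a <= 0 for a in a0s):
        raise ConfigError("grid values must be positive")
    if len(observed_by_speed) < 2:
        raise InsufficientDataError("need observed forces for >= 2 pulling speeds")
    speeds = sorted(observed_by_speed)
    for v in speeds:
        if len(np.atleast_1d(observed_by_speed[v])) == 0:
            raise InsufficientDataError(f"empty observed force group at {v} nm/s")

    children = np.random.SeedSequence(seed).spawn(len(dxs) * len(a0s))
    rows = []
    best = (math.inf, None)
    idx = 0
    for dx in dxs:
        for a0 in a0s:
            rng = np.random.default_rng(children[idx])
            idx += 1
            objective = 0.0
            for v in speeds:
                cfg = replace(sim_config, delta_x=dx, alpha0=a0, pulling_speed=float(v))
                forces = []
                for _ in range(n_sim):
                    _, truth = simulate_curve(cfg, rng, record=False)
                    forces.extend(ev.force for ev in truth.events)
                if not forces:
                    objective = math.inf
                    break
                ks = stats.ks_2samp(np.asarray(forces), np.asarray(observed_by_speed[v]))
                objective += float(ks.statistic)
            rows.append({"delta_x": dx, "alpha0": a0, "objective": objective})
            if objective < best[0]:
                best = (objective, (dx, a0))
    surface = pd.DataFrame(rows)
    return best[1], surface
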