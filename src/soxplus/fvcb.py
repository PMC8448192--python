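"""Farquhar-von Caemmerer-Berry photosynthesis with temperature kinetics and
non-stomatal limitations (NSL).

Net assimilation is the minimum of the Rubisco-limited (Avc) and
RuBP-regeneration-limited (Aj) rates minus dark respiration. Temperature
scaling: Arrhenius for Gamma*, Kc, Ko; peaked Arrhenius (Ea, Ed, S) for
Vcmax and Jmax; Q10 for Rd. NSL down-regulates the apparent Vcmax25/Jmax25
multiplicatively via a Tuzet-type sigmoid of dampened canopy water potential.

Reference kinetics (Scots pine / tobacco-derived constants) live in
``PhotoParams``; A/Ci curves measured at saturating light are fit for
Vcmax25 and Jmax25 by differential evolution with a Gaussian log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import differential_evolution

R_GAS = 8.314  # J mol-1 K-1
T_REF = 298.15  # K

# A/Ci fit prior support (uniform)
VCMAX_BOUNDS = (10.0, 80.0)
JMAX_BOUNDS = (30.0, 140.0)


@dataclass(frozen=True)
class PhotoParams:
    """FvCB kinetic parameters; defaults are the fixed model constants."""

    vcmax25: float = 33.3        # umol m-2 s-1
    jmax25: float = 51.0         # umol m-2 s-1
    rd25: float = 0.4995         # umol m-2 s-1 (0.015 * vcmax25)
    q10: float = 2.0
    gamma_star25: float = 42.2   # umol mol-1
    kc25: float = 404.0          # umol mol-1
    ko25: float = 278_000.0      # umol mol-1
    ea_vcmax: float = 52_750.0   # J mol-1
    ed_vcmax: float = 202_600.0
    s_vcmax: float = 669.0       # J mol-1 K-1
    ea_jmax: float = 61_750.0
    ed_jmax: float = 185_600.0
    s_jmax: float = 621.0
    ea_gamma: float = 37_830.0
    ea_kc: float = 84_200.0
    ea_ko: float = 15_200.0
    o2_mole_fraction: float = 210_000.0  # umol mol-1
    theta_j: float = 0.9         # light-response curvature
    alpha_j: float = 0.3         # mol e- mol photon-1

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "q10", "gamma_star25", "kc25", "ko25"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rd25 < 0:
            raise ValueError("rd25 must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.vcmax25, self.jmax25, self.rd25, self.q10,
                self.gamma_star25, self.kc25, self.ko25,
                self.ea_vcmax, self.ed_vcmax, self.s_vcmax,
                self.ea_jmax, self.ed_jmax, self.s_jmax,
                self.ea_gamma, self.ea_kc, self.ea_ko,
                self.o2_mole_fraction, self.theta_j, self.alpha_j,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class NSLParams:
    """Tuzet sigmoid for non-stomatal down-regulation of Vcmax/Jmax."""

    psi_ref_tuz: float = -1.72  # MPa
    a_tuz: float = 2.92         # unitless

    def __post_init__(self) -> None:
        if self.psi_ref_tuz >= 0:
            raise ValueError("psi_ref_tuz must be negative (MPa)")
        if self.a_tuz <= 0:
            raise ValueError("a_tuz must be positive")


@dataclass
class AciCurveObs:
    """One A/Ci curve at saturating light: (Ci umol mol-1, An umol m-2 s-1)."""

    ci: np.ndarray
    an: np.ndarray
    t_leaf: float = 25.0  # degC
    par: float = 1500.0   # umol m-2 s-1
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.an = np.asarray(self.an, dtype=float)
        if self.ci.shape != self.an.shape or self.ci.ndim != 1:
            raise ValueError("ci and an must be 1-D arrays of equal length")
        if self.ci.size < 5:
            raise ValueError("need at least 5 points per A/Ci curve")
        if self.par < 1200:
            raise ValueError("A/Ci curves must be measured at saturating PAR (>= 1200)")


# ----------------------------------------------------------------------------
# temperature kinetics (numba kernels shared with the hourly engine)
# ----------------------------------------------------------------------------

@njit(cache=True)
def _arrhenius(k25: float, ea: float, tk: float) -> float:
    return k25 * np.exp(ea * (tk - T_REF) / (T_REF * R_GAS * tk))


@njit(cache=True)
def _peaked(k25: float, ea: float, ed: float, s: float, tk: float) -> float:
    # normalized so k(25 degC) = k25 exactly
    num = 1.0 + np.exp((T_REF * s - ed) / (T_REF * R_GAS))
    den = 1.0 + np.exp((s * tk - ed) / (R_GAS * tk))
    return _arrhenius(k25, ea, tk) * num / den


@njit(cache=True)
def _kinetics(t_leaf: float, p: np.ndarray):
    """(vcmax, jmax, rd, gamma_star, kc, ko) at leaf temperature t_leaf (degC)."""
    tk = t_leaf + 273.15
    vcmax = _peaked(p[0], p[7], p[8], p[9], tk)
    jmax = _peaked(p[1], p[10], p[11], p[12], tk)
    rd = p[2] * p[3] ** ((t_leaf - 25.0) / 10.0)
    gamma = _arrhenius(p[4], p[13], tk)
    kc = _arrhenius(p[5], p[14], tk)
    ko = _arrhenius(p[6], p[15], tk)
    return vcmax, jmax, rd, gamma, kc, ko


@njit(cache=True)
def _j_light(par: float, jmax: float, theta: float, alpha: float) -> float:
    """Non-rectangular hyperbola electron transport, capped at jmax."""
    if jmax <= 0.0:
        return 0.0
    q = alpha * par
    s = q + jmax
    disc = s * s - 4.0 * theta * q * jmax
    if disc < 0.0:
        disc = 0.0
    return (s - np.sqrt(disc)) / (2.0 * theta)


@njit(cache=True)
def _an_kernel(
    ci: float, par: float, f_nsl: float,
    vcmax: float, jmax: float, rd: float,
    gamma: float, kc: float, ko: float,
    o2: float, theta: float, alpha: float,
):
    """Return (an, avc, aj, rd) at given Ci; NSL scales vcmax/jmax."""
    vc = vcmax * f_nsl
    jm = jmax * f_nsl
    kco = kc * (1.0 + o2 / ko)
    avc = vc * (ci - gamma) / (ci + kco)
    j = _j_light(par, jm, theta, alpha)
    aj = j * (ci - gamma) / (4.0 * ci + 8.0 * gamma) if (4.0 * ci + 8.0 * gamma) > 0 else 0.0
    a = min(avc, aj)
    return a - rd, avc, aj, rd


# ----------------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------------

_KINETIC_IDS = ("vcmax", "jmax", "rd", "gamma_star", "kc", "ko")


def kinetics_at_temp(param_id: str, t_leaf: float, params: PhotoParams | None = None) -> float:
    """Temperature-adjusted kinetic parameter value in its native units."""
    params = params or PhotoParams()
    if not -10.0 <= t_leaf <= 50.0:
        raise ValueError("t_leaf outside supported range [-10, 50] degC")
    if param_id not in _KINETIC_IDS:
        raise ValueError(f"unknown param_id {param_id!r}; one of {_KINETIC_IDS}")
    vals = _kinetics(float(t_leaf), params.to_array())
    return float(vals[_KINETIC_IDS.index(param_id)])


def nsl_factor(psi_canopy_m: float, nsl: NSLParams) -> float:
    """Tuzet stress factor in (0, 1]: f = (1+e^{a*psi_ref}) / (1+e^{a*(psi_ref-psi)})."""
    if psi_canopy_m > 0:
        raise ValueError("psi_canopy_m must be <= 0 MPa")
    a, pref = nsl.a_tuz, nsl.psi_ref_tuz
    num = 1.0 + np.exp(min(a * pref, 700.0))
    den = 1.0 + np.exp(min(a * (pref - psi_canopy_m), 700.0))
    return float(num / den)


def nsl_half_strength_psi(nsl: NSLParams) -> float:
    """Canopy potential (MPa) at which the NSL factor equals 0.5 (closed form)."""
    a, pref = nsl.a_tuz, nsl.psi_ref_tuz
    return float(pref - np.log(1.0 + 2.0 * np.exp(a * pref)) / a)


def apparent_kinetics(vcmax25: float, jmax25: float, f_nsl: float) -> tuple[float, float]:
    """Apparent (down-regulated) 25 degC reference Vcmax and Jmax."""
    if not 0.0 <= f_nsl <= 1.0:
        raise ValueError("f_nsl must lie in [0, 1]")
    return vcmax25 * f_nsl, jmax25 * f_nsl


def an_fvcb(
    ci: float,
    par: float,
    t_leaf: float,
    params: PhotoParams | None = None,
    f_nsl: float = 1.0,
) -> tuple[float, float, float, float]:
    """Net assimilation (an, avc, aj, rd), all in umol m-2 s-1, at given Ci."""
    params = params or PhotoParams()
    if ci < 0:
        raise ValueError("ci must be >= 0")
    p = params.to_array()
    vcmax, jmax, rd, gamma, kc, ko = _kinetics(float(t_leaf), p)
    out = _an_kernel(
        float(ci), float(par), float(f_nsl), vcmax, jmax, rd, gamma, kc, ko,
        params.o2_mole_fraction, params.theta_j, params.alpha_j,
    )
    return tuple(float(v) for v in out)


def rd_from_vcmax(vcmax25: float) -> float:
    """Dark respiration at 25 degC tied to carboxylation capacity: 0.015 * Vcmax25."""
    if vcmax25 < 0:
        raise ValueError("vcmax25 must be >= 0")
    return 0.015 * vcmax25


def _aci_smart_start(obs: AciCurveObs) -> tuple[float, float]:
    """Data-informed start: Vcmax from the lowest-Ci point assuming Rubisco
    limitation, Jmax from the most CO2-saturated point assuming RuBP
    limitation (J ~ Jmax at saturating light)."""
    p = PhotoParams()
    tk_terms = _kinetics(obs.t_leaf, p.to_array())
    _, _, _, gamma, kc, ko = tk_terms
    kco = kc * (1.0 + p.o2_mole_fraction / ko)
    i_lo, i_hi = int(np.argmin(obs.ci)), int(np.argmax(obs.ci))
    an_lo, ci_lo = obs.an[i_lo], obs.ci[i_lo]
    an_hi, ci_hi = obs.an[i_hi], obs.ci[i_hi]
    # rd ~ 0.5 as a starting guess; both estimates refined by the optimizer
    vc0 = (an_lo + 0.5) * (ci_lo + kco) / max(ci_lo - gamma, 1.0)
    jm0 = (an_hi + 0.5) * (4.0 * ci_hi + 8.0 * gamma) / max(ci_hi - gamma, 1.0)
    vc0 = float(np.clip(vc0, *VCMAX_BOUNDS))
    jm0 = float(np.clip(jm0, *JMAX_BOUNDS))
    return vc0, jm0


def fit_aci(obs: AciCurveObs, seed: int = 0, maxiter: int = 200) -> dict:
    """Maximum-likelihood (Vcmax25, Jmax25) for one A/Ci curve.

    Rd is tied to Vcmax (rd25 = 0.015 * vcmax25); the Gaussian likelihood
    reduces to least squares, minimized by differential evolution over the
    uniform prior support. Because the tied Rd opens a broad shallow
    compensation ridge at high Vcmax, a local polish from a data-informed
    start is run as well and the lower-SSE solution is kept.
    """
    from scipy.optimize import minimize

    base = PhotoParams()

    def sse(x: np.ndarray) -> float:
        vc, jm = x
        p = replace(base, vcmax25=vc, jmax25=jm, rd25=rd_from_vcmax(vc))
        pred = np.array(
            [an_fvcb(c, obs.par, obs.t_leaf, p)[0] for c in obs.ci]
        )
        return float(np.sum((obs.an - pred) ** 2))

    bounds = [VCMAX_BOUNDS, JMAX_BOUNDS]
    res = differential_evolution(
        sse,
        bounds=bounds,
        seed=seed,
        maxiter=maxiter,
        tol=1e-8,
        polish=True,
    )
    local = minimize(sse, _aci_smart_start(obs), method="L-BFGS-B", bounds=bounds)
    best = local if local.fun < res.fun else res
    vc, jm = best.x
    p = replace(base, vcmax25=vc, jmax25=jm, rd25=rd_from_vcmax(vc))
    pred = np.array([an_fvcb(c, obs.par, obs.t_leaf, p)[0] for c in obs.ci])
    rmse = float(np.sqrt(np.mean((obs.an - pred) ** 2)))
    return {
        "vcmax25": float(vc),
        "jmax25": float(jm),
        "rd25": rd_from_vcmax(float(vc)),
        "rmse": rmse,
        "converged": bool(res.success or local.success),
        "predicted": pred,
    }


def fit_aci_population(curves: list[AciCurveObs], seed: int = 0) -> dict:
    """Fit each curve independently; the population summary is the median."""
    fits = [fit_aci(c, seed=seed + i) for i, c in enumerate(curves)]
    vc = np.array([f["vcmax25"] for f in fits])
    jm = np.array([f["jmax25"] for f in fits])
    return {
        "vcmax25_median": float(np.median(vc)),
        "jmax25_median": float(np.median(jm)),
        "jv_ratio_median": float(np.median(jm / vc)),
        "vcmax25_ci": [float(np.percentile(vc, 2.5)), float(np.percentile(vc, 97.5))],
        "jmax25_ci": [float(np.percentile(jm, 2.5)), float(np.percentile(jm, 97.5))],
        "per_curve": fits,
    }
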