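"""Hourly stomatal-optimization gas-exchange / hydraulics engine.

The soil-to-atmosphere pathway is three conductance nodes: soil-to-root
(k_sr, Campbell scaling with soil water content), root-to-canopy (k_rc,
declining with canopy water potential following the fitted vulnerability
curve), and stomata (gs). Water potentials follow Darcy's law on an explicit
lagged scheme: time-t potentials use transpiration and conductances from
t-1. Stomatal conductance maximizes photosynthetic gain against the marginal
hydraulic cost xi, with a minimum-conductance floor g_min for cuticular
leakiness; assimilation and gs are solved together by damped fixed-point
iteration on Ci. Optional non-stomatal limitations (NSL) down-regulate
apparent Vcmax/Jmax via a Tuzet sigmoid of the dampened canopy potential.

Conventions
-----------
* All potentials are negative MPa; conductances are per unit leaf area
  (mol m-2 s-1 MPa-1); gs is a CO2 conductance (mol m-2 s-1).
* The cost term xi uses VPD in kPa (the form the gain/cost solution was
  derived with); the transpiration flux E = 1.6 * gs * VPD / P_atm uses the
  water-vapor mole fraction.
* Soil water content is either a prescribed hourly driver or prognostic
  ("bucket" mode: a sealed pot, depletion = transpired mass).

The hot loops are numba-compiled; the public operations are thin validated
wrappers around the same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .fvcb import NSLParams, PhotoParams, _an_kernel, _kinetics
from .vulnerability import VulnParams, knorm_eval

RHO_WATER = 997.0        # kg m-3
GRAVITY = 9.8            # m s-2
MOLAR_MASS_W = 0.018     # kg mol-1
DEFAULT_PATM = 93.0      # kPa (~708 m a.s.l.)
DEFAULT_CA = 400.0       # umol mol-1
XI_CAP = 100.0           # mol m-2 s-1, guards the |dk/dpsi| -> 0 limit
CI_TOL = 0.01            # umol mol-1 fixed-point tolerance
CI_MAX_ITER = 100
DPSI_FD = 0.01           # MPa, finite-difference step for dk/dpsi

_FORM_CODE = {"WB": 0, "SE": 1, "SOXf": 2}


@dataclass(frozen=True)
class SoilParams:
    """Campbell retention/conductivity parameters for the potting substrate."""

    swc_fc: float = 0.35          # m3 m-3 field capacity
    b: float = 3.0                # retention shape
    bulk_density: float = 1.3     # g cm-3
    psi_e: float = -0.35          # MPa air-entry (peaty substrate default, see docs)
    porosity: float = 0.5094      # 1 - bulk_density / 2.65
    pot_volume_l: float = 120.0   # sealed pot volume for bucket mode
    swc_min: float = 0.01         # bucket floor

    def __post_init__(self) -> None:
        if not (0 < self.swc_fc <= self.porosity < 1):
            raise ValueError("require 0 < swc_fc <= porosity < 1")
        if self.b <= 0 or self.psi_e >= 0:
            raise ValueError("b must be > 0 and psi_e < 0")


@dataclass(frozen=True)
class HydraulicParams:
    """Whole-plant hydraulic and stomatal parameters."""

    ksr_max: float = 0.77        # mol m-2 s-1 MPa-1 (soil-root, at field capacity)
    krc_max: float = 0.035       # mol m-2 s-1 MPa-1 (root-canopy maximum)
    rplant_min: float = 4.87     # MPa m2 s mol-1 minimum plant resistance
    g_min_mmol: float = 2.0      # mmol m-2 s-1 minimum leaf conductance
    height: float = 2.0          # m
    leaf_area: float = 1.35      # m2 tree-1 initial

    def __post_init__(self) -> None:
        if min(self.ksr_max, self.krc_max, self.rplant_min, self.g_min_mmol) <= 0:
            raise ValueError("conductances and resistances must be positive")

    @property
    def g_min(self) -> float:
        """Minimum conductance in mol m-2 s-1."""
        return self.g_min_mmol * 1e-3


@dataclass
class SoxParams:
    """Full parameter bundle for a simulation run."""

    hydraulic: HydraulicParams = field(default_factory=HydraulicParams)
    soil: SoilParams = field(default_factory=SoilParams)
    photo: PhotoParams = field(default_factory=PhotoParams)
    vuln: VulnParams = field(default_factory=lambda: VulnParams("WB", -3.01, 2.85))
    nsl: NSLParams | None = field(default_factory=NSLParams)
    patm: float = DEFAULT_PATM
    ca: float = DEFAULT_CA

    def to_hvec(self, nsl_on: bool, swc_mode: str, la_mode: int,
                shed_rule=(0.002, 0.0055, 50.0)) -> np.ndarray:
        h, s = self.hydraulic, self.soil
        nsl = self.nsl if (nsl_on and self.nsl is not None) else None
        return np.array(
            [
                h.ksr_max, h.krc_max, h.rplant_min, h.g_min, h.height, h.leaf_area,
                float(_FORM_CODE[self.vuln.formulation]),
                self.vuln.psi_ref_or_50, self.vuln.a_coef,
                1.0 if nsl is not None else 0.0,
                nsl.psi_ref_tuz if nsl is not None else -1.0,
                nsl.a_tuz if nsl is not None else 1.0,
                s.swc_fc, s.b, s.psi_e, s.porosity,
                self.patm, self.ca, XI_CAP, s.pot_volume_l,
                0.0 if swc_mode == "driver" else 1.0,
                float(la_mode),
                shed_rule[0], shed_rule[1], shed_rule[2],
                s.swc_min,
            ],
            dtype=np.float64,
        )


@dataclass
class HydraulicState:
    """Per-hour model state (lagged inputs for the next step)."""

    psi_soil: float = 0.0
    psi_root: float = 0.0
    psi_canopy_t: float = 0.0
    psi_canopy_pd: float = 0.0
    psi_canopy_m: float = 0.0
    ksr: float = 1.0
    krc: float = 1.0
    gs: float = 0.0
    e_leaf: float = 0.0
    an: float = 0.0
    ci: float = 280.0
    xi: float = 0.0


# ----------------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------------

@njit(cache=True)
def _knorm_j(psi: float, form: int, p: float, a: float) -> float:
    if form == 0:  # Weibull
        return np.exp(-((abs(psi) / abs(p)) ** a))
    if form == 1:  # sigmoid exponential
        z = a * (psi - p)
        if z > 700.0:
            z = 700.0
        elif z < -700.0:
            z = -700.0
        return 1.0 - 1.0 / (1.0 + np.exp(z))
    return 1.0 / (1.0 + (abs(psi) / abs(p)) ** a)


@njit(cache=True)
def _dknorm_j(psi: float, form: int, p: float, a: float) -> float:
    """|dk/dpsi| by central finite differences (one-sided near psi = 0)."""
    if psi > -DPSI_FD:
        d = (_knorm_j(psi, form, p, a) - _knorm_j(psi - DPSI_FD, form, p, a)) / DPSI_FD
    else:
        d = (
            _knorm_j(psi + DPSI_FD, form, p, a)
            - _knorm_j(psi - DPSI_FD, form, p, a)
        ) / (2.0 * DPSI_FD)
    return abs(d)


@njit(cache=True)
def _tuzet_j(psi: float, pref: float, a: float) -> float:
    zn = a * pref
    zd = a * (pref - psi)
    if zn > 700.0:
        zn = 700.0
    if zd > 700.0:
        zd = 700.0
    return (1.0 + np.exp(zn)) / (1.0 + np.exp(zd))


@njit(cache=True)
def _gs_opt_j(dan_dci: float, xi: float, gmin: float) -> float:
    if dan_dci <= 1e-12 or xi <= 0.0:
        return gmin
    gs = 0.5 * dan_dci * (np.sqrt(4.0 * xi / dan_dci + 1.0) - 1.0)
    return gs if gs > gmin else gmin


@njit(cache=True)
def _simulate(
    par: np.ndarray, tair: np.ndarray, vpd: np.ndarray, swc_driver: np.ndarray,
    la_series: np.ndarray, hv: np.ndarray, pv: np.ndarray,
    e0: float, psi_m0: float, ksr0: float, ci0: float, swc0: float,
):
    n = par.size
    n_days = (n + 23) // 24

    ksr_max, krc_max, rplant_min, gmin, height, la0 = hv[0], hv[1], hv[2], hv[3], hv[4], hv[5]
    form = int(hv[6]); vp = hv[7]; va = hv[8]
    nsl_on = hv[9] > 0.5; pref_tuz = hv[10]; a_tuz = hv[11]
    swc_fc, soil_b, psi_e, porosity = hv[12], hv[13], hv[14], hv[15]
    patm, ca, xi_cap, pot_l = hv[16], hv[17], hv[18], hv[19]
    bucket = hv[20] > 0.5
    la_mode = int(hv[21])
    shed_basal, shed_drought, shed_x = hv[22], hv[23], hv[24]
    swc_min = hv[25]

    grav = height * RHO_WATER * GRAVITY * 1e-6
    exp_camp = 2.0 + 3.0 * soil_b

    # hourly outputs
    o_psi_soil = np.empty(n); o_psi_root = np.empty(n); o_psi_t = np.empty(n)
    o_psi_pd = np.empty(n); o_psi_m = np.empty(n)
    o_ksr = np.empty(n); o_krc = np.empty(n)
    o_gs = np.empty(n); o_e = np.empty(n); o_an = np.empty(n)
    o_ci = np.empty(n); o_xi = np.empty(n); o_swc = np.empty(n)
    # daily outputs
    d_tr = np.zeros(n_days); d_pd = np.zeros(n_days); d_plk = np.zeros(n_days)
    d_gsmax = np.zeros(n_days); d_la = np.zeros(n_days); d_swc = np.zeros(n_days)

    e_prev = e0
    psi_m_prev = psi_m0
    ksr_prev = ksr0
    ci = ci0
    swc_state = swc0
    la = la0

    for h in range(n):
        day = h // 24
        if h % 24 == 0:
            if la_mode == 1:
                la = la_series[day]
            elif la_mode == 2 and day > 0:
                rate = shed_drought if d_plk[day - 1] >= shed_x else shed_basal
                la = la * (1.0 - rate)
            d_la[day] = la

        swc = swc_state if bucket else swc_driver[h]
        if swc < 1e-6:
            swc = 1e-6
        psi_soil = psi_e * (swc / porosity) ** (-soil_b)

        ratio = swc / swc_fc
        ksr_now = ksr_max if ratio >= 1.0 else ksr_max * ratio ** exp_camp
        if ksr_now < 1e-12:
            ksr_now = 1e-12

        krc_prev = krc_max * _knorm_j(psi_m_prev, form, vp, va)
        if krc_prev < 1e-12:
            krc_prev = 1e-12

        psi_root = psi_soil - e_prev / ksr_prev
        psi_t = psi_root - e_prev / krc_prev - grav
        psi_pd = psi_soil - grav
        psi_m = 0.5 * (psi_t + psi_pd)
        if psi_m > 0.0:
            psi_m = 0.0

        k_m = _knorm_j(psi_m, form, vp, va)
        f_nsl = _tuzet_j(psi_m, pref_tuz, a_tuz) if nsl_on else 1.0

        vcmax, jmax, rd, gamma, kc, ko = _kinetics(tair[h], pv)
        o2 = pv[16]; theta = pv[17]; alpha = pv[18]

        vpd_h = vpd[h]
        if vpd_h < 1e-3:
            vpd_h = 1e-3

        if par[h] < 1.0:
            # night: stomata at the leakiness floor
            gs = gmin
            an = -rd
            ci = ca + rd / gs
            xi = 0.0
        else:
            dk = _dknorm_j(psi_m, form, vp, va)
            if dk < 1e-12 or k_m < 1e-12:
                xi = xi_cap
            else:
                xi = 2.0 / ((dk / k_m) * (rplant_min / k_m) * 1.6 * vpd_h)
                if xi > xi_cap:
                    xi = xi_cap
            an = 0.0
            gs = gmin
            for _ in range(CI_MAX_ITER):
                a0 = _an_kernel(ci, par[h], f_nsl, vcmax, jmax, rd, gamma, kc, ko, o2, theta, alpha)[0]
                ap = _an_kernel(ci + 1.0, par[h], f_nsl, vcmax, jmax, rd, gamma, kc, ko, o2, theta, alpha)[0]
                am = _an_kernel(ci - 1.0 if ci >= 1.0 else 0.0, par[h], f_nsl, vcmax, jmax, rd, gamma, kc, ko, o2, theta, alpha)[0]
                g = 0.5 * (ap - am)
                if g < 0.0:
                    g = 0.0
                gs = _gs_opt_j(g, xi, gmin)
                an = a0
                ci_new = ca - an / gs
                if ci_new < 1.0:
                    ci_new = 1.0
                elif ci_new > 4.0 * ca:
                    ci_new = 4.0 * ca
                # Newton-style adaptive damping: the raw map has slope -g/gs,
                # so a fixed 0.5 factor diverges when gs sits near the floor
                delta = (ci_new - ci) / (1.0 + g / gs)
                ci = ci + delta
                if abs(delta) < CI_TOL:
                    break

        e_flux = 1.6 * gs * vpd_h / patm  # mol m-2(leaf) s-1

        if bucket:
            mass = e_flux * la * 3600.0 * MOLAR_MASS_W  # kg over the hour
            swc_state = swc_state - mass / pot_l
            if swc_state < swc_min:
                swc_state = swc_min

        o_psi_soil[h] = psi_soil; o_psi_root[h] = psi_root; o_psi_t[h] = psi_t
        o_psi_pd[h] = psi_pd; o_psi_m[h] = psi_m
        o_ksr[h] = ksr_now; o_krc[h] = krc_prev
        o_gs[h] = gs; o_e[h] = e_flux; o_an[h] = an; o_ci[h] = ci; o_xi[h] = xi
        o_swc[h] = swc

        d_tr[day] += e_flux * la * 3600.0 * MOLAR_MASS_W
        if h % 24 == 0:
            d_pd[day] = psi_pd
            d_plk[day] = 100.0 * (1.0 - _knorm_j(psi_pd, form, vp, va))
            d_swc[day] = swc
        if gs > d_gsmax[day]:
            d_gsmax[day] = gs

        e_prev = e_flux
        ksr_prev = ksr_now
        psi_m_prev = psi_m

    return (
        o_psi_soil, o_psi_root, o_psi_t, o_psi_pd, o_psi_m, o_ksr, o_krc,
        o_gs, o_e, o_an, o_ci, o_xi, o_swc,
        d_tr, d_pd, d_plk, d_gsmax, d_la, d_swc,
    )


# ----------------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------------

def soil_psi(swc: float, soil: SoilParams) -> float:
    """Campbell soil water potential (MPa): psi_e * (swc/porosity)^(-b)."""
    if np.any(np.asarray(swc) <= 0):
        raise ValueError("swc must be positive")
    return soil.psi_e * (np.asarray(swc, dtype=float) / soil.porosity) ** (-soil.b)


def ksr_campbell(swc: float, soil: SoilParams, ksr_max: float) -> float:
    """Soil-to-root conductance: ksr_max * (swc/swc_fc)^(2+3b), capped at ksr_max."""
    swc = np.asarray(swc, dtype=float)
    if np.any(swc < 0):
        raise ValueError("swc must be >= 0")
    out = ksr_max * np.minimum(swc / soil.swc_fc, 1.0) ** (2.0 + 3.0 * soil.b)
    return float(out) if out.ndim == 0 else out


def potential_cascade(
    psi_soil: float, e_prev: float, ksr_prev: float, krc_prev: float, height: float
) -> tuple[float, float, float, float]:
    """Lagged Darcy cascade: (psi_root, psi_canopy_t, psi_canopy_pd, psi_canopy_m).

    Predawn uses E ~ 0; the dampened potential is the mean of instantaneous
    and predawn canopy potentials.
    """
    if ksr_prev <= 0 or krc_prev <= 0:
        raise ValueError("conductances must be positive")
    grav = height * RHO_WATER * GRAVITY * 1e-6
    psi_root = psi_soil - e_prev / ksr_prev
    psi_t = psi_root - e_prev / krc_prev - grav
    psi_pd = psi_soil - grav
    psi_m = 0.5 * (psi_t + psi_pd)
    return psi_root, psi_t, psi_pd, psi_m


def xi_cost(
    knorm_rc: float,
    dknorm_dpsi: float,
    rplant_min: float,
    vpd: float,
    p_atm: float = DEFAULT_PATM,
) -> float:
    """Marginal hydraulic cost xi (mol m-2 s-1) of opening stomata.

    xi = 2 / [ (|dk/dpsi| / k) * (rplant_min / k) * 1.6 * VPD ], VPD in kPa;
    capped at XI_CAP as |dk/dpsi| -> 0 near psi = 0. ``p_atm`` is accepted for
    interface symmetry with the flux calculation but does not enter the cost.
    """
    if not 0.0 < knorm_rc <= 1.0:
        raise ValueError("knorm_rc must lie in (0, 1]")
    if vpd <= 0:
        raise ValueError("vpd must be positive")
    dk = abs(dknorm_dpsi)
    if dk < 1e-12:
        return XI_CAP
    xi = 2.0 / ((dk / knorm_rc) * (rplant_min / knorm_rc) * 1.6 * vpd)
    return min(xi, XI_CAP)


def gs_optimal(dan_dci: float, xi: float, g_min: float) -> float:
    """Analytic gain/cost optimum: gs = 0.5*g*(sqrt(4*xi/g + 1) - 1), floored at g_min."""
    if dan_dci < 0 or xi < 0:
        raise ValueError("dan_dci and xi must be >= 0")
    return float(_gs_opt_j(dan_dci, xi, g_min))


def plkrc(psi_canopy_pd, vuln: VulnParams):
    """Percent loss of root-to-canopy conductance at the predawn potential."""
    return 100.0 * (1.0 - knorm_eval(psi_canopy_pd, vuln))


def solve_hour(
    drivers_t: dict,
    prev: HydraulicState,
    params: SoxParams,
    nsl_on: bool = True,
) -> HydraulicState:
    """Advance the engine by one hour from a previous state.

    ``drivers_t`` needs keys par, t_air_c, vpd_kpa, swc. The same jitted
    kernel as the full run is used on a single-hour series.
    """
    hv = params.to_hvec(nsl_on=nsl_on, swc_mode="driver", la_mode=0)
    pv = params.photo.to_array()
    out = _simulate(
        np.array([float(drivers_t["par"])]),
        np.array([float(drivers_t["t_air_c"])]),
        np.array([float(drivers_t["vpd_kpa"])]),
        np.array([float(drivers_t["swc"])]),
        np.array([params.hydraulic.leaf_area]),
        hv, pv,
        prev.e_leaf, prev.psi_canopy_m, prev.ksr, prev.ci,
        float(drivers_t["swc"]),
    )
    return HydraulicState(
        psi_soil=out[0][0], psi_root=out[1][0], psi_canopy_t=out[2][0],
        psi_canopy_pd=out[3][0], psi_canopy_m=out[4][0],
        ksr=out[5][0], krc=out[6][0], gs=out[7][0], e_leaf=out[8][0],
        an=out[9][0], ci=out[10][0], xi=out[11][0],
    )


def initial_state(swc0: float, params: SoxParams) -> HydraulicState:
    """Predawn-equilibrium state (E = 0) used to start a run."""
    psi_s = float(soil_psi(swc0, params.soil))
    grav = params.hydraulic.height * RHO_WATER * GRAVITY * 1e-6
    return HydraulicState(
        psi_soil=psi_s, psi_root=psi_s, psi_canopy_t=psi_s - grav,
        psi_canopy_pd=psi_s - grav, psi_canopy_m=psi_s - grav,
        ksr=float(ksr_campbell(swc0, params.soil, params.hydraulic.ksr_max)),
        krc=params.hydraulic.krc_max, ci=0.7 * params.ca,
    )


def run_experiment(
    drivers: pd.DataFrame,
    params: SoxParams,
    la_series: np.ndarray | None = None,
    nsl_on: bool = True,
    swc_mode: str = "driver",
    shed_rule: tuple[float, float, float] | None = None,
    seed: int | None = None,
) -> dict:
    """Run the engine over an hourly driver series; return hourly + daily frames.

    ``la_series`` is a daily leaf-area series (m2); if ``shed_rule``
    (basal, drought, threshold %) is given, leaf area follows the rule-based
    daily decay instead. Daily transpiration is in kg tree-1 day-1.
    ``seed`` is accepted for interface uniformity; the engine is deterministic.
    """
    required = {"doy", "hour", "par", "t_air_c", "vpd_kpa", "swc"}
    missing = required - set(drivers.columns)
    if missing:
        raise ValueError(f"drivers missing columns: {sorted(missing)}")
    n = len(drivers)
    if n % 24 != 0:
        raise ValueError("drivers must cover whole days (multiple of 24 hours)")
    n_days = n // 24
    if la_series is not None and shed_rule is not None:
        raise ValueError("give either la_series or shed_rule, not both")
    if la_series is not None:
        la_series = np.asarray(la_series, dtype=float)
        if la_series.size != n_days:
            raise ValueError("la_series must have one value per simulated day")
        la_mode = 1
        rule = (0.002, 0.0055, 50.0)
    elif shed_rule is not None:
        la_mode = 2
        rule = shed_rule
        la_series = np.zeros(n_days)
    else:
        la_mode = 0
        rule = (0.002, 0.0055, 50.0)
        la_series = np.zeros(n_days)

    hv = params.to_hvec(nsl_on=nsl_on, swc_mode=swc_mode, la_mode=la_mode, shed_rule=rule)
    pv = params.photo.to_array()
    swc0 = float(drivers["swc"].iloc[0])
    init = initial_state(swc0, params)
    out = _simulate(
        drivers["par"].to_numpy(float),
        drivers["t_air_c"].to_numpy(float),
        drivers["vpd_kpa"].to_numpy(float),
        drivers["swc"].to_numpy(float),
        la_series, hv, pv,
        0.0, init.psi_canopy_m, init.ksr, init.ci, swc0,
    )
    hourly = pd.DataFrame(
        {
            "doy": drivers["doy"].to_numpy(), "hour": drivers["hour"].to_numpy(),
            "psi_soil": out[0], "psi_root": out[1], "psi_canopy_t": out[2],
            "psi_canopy_pd": out[3], "psi_canopy_m": out[4],
            "ksr": out[5], "krc": out[6], "gs": out[7], "e_leaf": out[8],
            "an": out[9], "ci": out[10], "xi": out[11], "swc": out[12],
        }
    )
    doys = drivers["doy"].to_numpy()[::24]
    daily = pd.DataFrame(
        {
            "doy": doys, "transpiration_kg": out[13], "psi_pd_mpa": out[14],
            "plkrc_pct": out[15], "gs_max": out[16], "leaf_area_m2": out[17],
            "swc": out[18],
        }
    )
    return {"hourly": hourly, "daily": daily}
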