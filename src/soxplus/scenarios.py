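"""Dry-down scenario engine: posterior-predictive ensembles of conductance
loss under three model configurations, leaf-shedding rule and benefit
statistic, and minimum-conductance (g_min) sensitivity.

Scenario runs use the prognostic soil-water bucket so that canopy leaf area
feeds back on soil-water depletion; this is how leaf shedding protects the
root-to-canopy conductance (per-leaf-area fluxes themselves are unchanged
by shedding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .calibration import McmcRun
from .soxcore import SoxParams, _simulate, initial_state


@dataclass(frozen=True)
class ShedRule:
    """Daily multiplicative leaf-shedding rule with a conductance-loss trigger.

    Below the PLk_rc threshold ``x_threshold`` leaf area decays at the basal
    turnover rate; at or above it, at the faster drought rate.
    """

    basal_ls: float = 0.002      # fraction day-1
    drought_ls: float = 0.0055   # fraction day-1
    x_threshold: float = 50.0    # percent PLk_rc

    def __post_init__(self) -> None:
        if not (0.0 <= self.basal_ls <= self.drought_ls < 1.0):
            raise ValueError("require 0 <= basal_ls <= drought_ls < 1")


@dataclass
class ScenarioResult:
    name: str
    doys: np.ndarray
    plkrc: np.ndarray          # (n_runs, n_days) percent
    transpiration: np.ndarray  # (n_runs, n_days) kg tree-1 day-1
    leaf_area: np.ndarray      # (n_runs, n_days) m2
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        q = np.percentile(self.plkrc, [2.5, 50, 97.5], axis=0)
        qt = np.percentile(self.transpiration, [2.5, 50, 97.5], axis=0)
        self.summary = pd.DataFrame(
            {
                "doy": self.doys,
                "plkrc_median": q[1], "plkrc_q2.5": q[0], "plkrc_q97.5": q[2],
                "transpiration_median": qt[1],
                "transpiration_q2.5": qt[0], "transpiration_q97.5": qt[2],
                "leaf_area_median": np.median(self.leaf_area, axis=0),
            }
        )

    @property
    def final_plkrc_median(self) -> float:
        return float(np.median(self.plkrc[:, -1]))


# ----------------------------------------------------------------------------
# leaf-area bookkeeping
# ----------------------------------------------------------------------------

def upscale_sapflow(j: float, la_below: float, la_above: float) -> float:
    """Whole-tree transpiration from sap flow measured above part of the canopy:
    Tr = J * (1 + LA_below / LA_above)."""
    if la_above <= 0:
        raise ValueError("la_above must be positive")
    if j < 0:
        raise ValueError("sap flow must be >= 0")
    return j * (1.0 + la_below / la_above)


def leaf_area_series(
    weekly_shed_mass: np.ndarray,
    campaign_days: np.ndarray,
    initial_biomass: float,
    sla: float,
    n_days: int,
) -> np.ndarray:
    """Daily leaf area (m2) from weekly shed-biomass collections.

    Cumulative shed mass is linearly interpolated between campaign days
    (zero at day 0), subtracted from the initial biomass, and converted to
    area with the specific leaf area (cm2 g-1). The result is non-increasing.
    """
    mass = np.asarray(weekly_shed_mass, dtype=float)
    days = np.asarray(campaign_days, dtype=float)
    if np.any(mass < 0):
        raise ValueError("shed masses must be non-negative")
    if mass.shape != days.shape:
        raise ValueError("one campaign day per shed-mass value")
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    xp = np.concatenate([[0.0], days])
    if cum[-1] > initial_biomass:
        raise ValueError("cumulative shed exceeds initial biomass")
    t = np.arange(n_days, dtype=float)
    cum_daily = np.interp(t, xp, cum)
    biomass = initial_biomass - cum_daily
    return biomass * sla * 1e-4  # cm2 g-1 * g -> m2


def shed_step(la_prev: float, plkrc: float, rule: ShedRule) -> float:
    """One day of the shedding rule; the drought branch applies at plkrc >= x."""
    if la_prev < 0:
        raise ValueError("leaf area must be >= 0")
    rate = rule.drought_ls if plkrc >= rule.x_threshold else rule.basal_ls
    return la_prev * (1.0 - rate)


# ----------------------------------------------------------------------------
# posterior-predictive ensembles
# ----------------------------------------------------------------------------

_SCENARIO_CONFIG = {
    "Hydraulic": "Hydraulic",
    "Hydraulic+NSL": "Hydraulic+NSL",
    "Hydraulic+NSL+shedding": "Hydraulic+NSL",
}

_HV = {"ksr_max": 0, "krc_max": 1, "rplant_min": 2, "gmin": 3, "psi_ref_tuz": 10, "a_tuz": 11}


def _ensemble(
    posterior: McmcRun,
    drivers: pd.DataFrame,
    base_params: SoxParams,
    la_input,
    n_runs: int,
    seed: int,
    gmin_mmol: float | None = None,
):
    """Run ``n_runs`` bucket-mode simulations over posterior draws."""
    nsl_on = posterior.config == "Hydraulic+NSL"
    par = drivers["par"].to_numpy(float)
    tair = drivers["t_air_c"].to_numpy(float)
    vpd = drivers["vpd_kpa"].to_numpy(float)
    swc = drivers["swc"].to_numpy(float)
    doys = drivers["doy"].to_numpy()[::24]
    n_days = par.size // 24

    kind, payload = la_input
    if kind == "observed":
        la_mode, la_arr, rule = 1, np.asarray(payload, dtype=float), (0.002, 0.0055, 50.0)
        if la_arr.size != n_days:
            raise ValueError("observed leaf-area series must match the run length")
    elif kind == "constant":
        la_mode, la_arr, rule = 0, np.zeros(n_days), (0.002, 0.0055, 50.0)
    elif kind == "rule":
        r: ShedRule = payload or ShedRule()
        la_mode, la_arr, rule = 2, np.zeros(n_days), (r.basal_ls, r.drought_ls, r.x_threshold)
    else:
        raise ValueError(f"unknown leaf-area input kind {kind!r}")

    hv0 = base_params.to_hvec(nsl_on=nsl_on, swc_mode="bucket", la_mode=la_mode, shed_rule=rule)
    if gmin_mmol is not None:
        hv0[_HV["gmin"]] = gmin_mmol * 1e-3
    pv = base_params.photo.to_array()
    swc0 = float(swc[0])
    init = initial_state(swc0, base_params)
    init_tuple = (0.0, init.psi_canopy_m, init.ksr, init.ci, swc0)

    rng = np.random.default_rng(seed)
    flat = posterior.flat
    idx = rng.integers(0, flat.shape[0], n_runs)
    names = [n for n in posterior.param_names if n != "sigma"]

    plk = np.empty((n_runs, n_days))
    tr = np.empty((n_runs, n_days))
    la_out = np.empty((n_runs, n_days))
    for k, i in enumerate(idx):
        hv = hv0.copy()
        for name, value in zip(names, flat[i, : len(names)]):
            hv[_HV[name]] = value
        out = _simulate(par, tair, vpd, swc, la_arr, hv, pv, *init_tuple)
        tr[k] = out[13]
        plk[k] = out[15]
        la_out[k] = out[17] if la_mode != 0 else np.full(n_days, hv[5])
    return doys, plk, tr, la_out, idx


def run_scenario(
    name: str,
    posterior: McmcRun,
    drivers: pd.DataFrame,
    base_params: SoxParams,
    la_input=("constant", None),
    n_runs: int = 500,
    seed: int = 0,
    gmin_mmol: float | None = None,
) -> ScenarioResult:
    """Posterior-predictive ensemble for one named scenario.

    Pairings are enforced: the "Hydraulic" scenario runs the Hydraulic
    posterior; the NSL scenarios run the Hydraulic+NSL posterior.
    """
    if name not in _SCENARIO_CONFIG:
        raise ValueError(f"unknown scenario {name!r}")
    if posterior.config != _SCENARIO_CONFIG[name]:
        raise ValueError(
            f"scenario {name!r} requires the {_SCENARIO_CONFIG[name]!r} posterior, "
            f"got {posterior.config!r}"
        )
    doys, plk, tr, la, _ = _ensemble(
        posterior, drivers, base_params, la_input, n_runs, seed, gmin_mmol
    )
    return ScenarioResult(name, doys, plk, tr, la)


def benefit_ls(plkrc_noshed: np.ndarray, plkrc_shed: np.ndarray) -> np.ndarray:
    """Daily cumulative-average reduction in PLk_rc attributable to shedding:
    Benefit_i = mean over days 1..i of (noshed_j - shed_j)."""
    a = np.asarray(plkrc_noshed, dtype=float)
    b = np.asarray(plkrc_shed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    diff = a - b
    i = np.arange(1, diff.shape[-1] + 1)
    return np.cumsum(diff, axis=-1) / i


def onset_day(benefit_ensemble: np.ndarray) -> int | None:
    """First day (0-based) whose ensemble 2.5th percentile exceeds 0; None if never."""
    q = np.percentile(np.asarray(benefit_ensemble, dtype=float), 2.5, axis=0)
    above = np.nonzero(q > 0)[0]
    return int(above[0]) if above.size else None


def gmin_sensitivity(
    posterior: McmcRun,
    drivers: pd.DataFrame,
    base_params: SoxParams,
    la_shed_input=("rule", None),
    gmin_values: tuple[float, ...] = (2.0, 3.0),
    n_runs: int = 500,
    seed: int = 0,
) -> dict:
    """Benefit-of-shedding ensembles for each g_min (mmol m-2 s-1).

    For each g_min, independent posterior-draw ensembles are run with and
    without leaf shedding (as in posterior-predictive sampling, so early-run
    benefit distributions straddle zero), yielding a daily Benefit_LS
    ensemble and its onset day; benefit distributions at different g_min are
    compared per day by a two-sample Kolmogorov-Smirnov test at alpha = 0.05.
    """
    results = {}
    for gi, gmin in enumerate(gmin_values):
        sub_seed = seed + 1000 * gi
        doys, plk_shed, _, _, _ = _ensemble(
            posterior, drivers, base_params, la_shed_input, n_runs, sub_seed, gmin
        )
        _, plk_noshed, _, _, _ = _ensemble(
            posterior, drivers, base_params, ("constant", None), n_runs, sub_seed + 500, gmin
        )
        ben = benefit_ls(plk_noshed, plk_shed)
        results[gmin] = {
            "doys": doys,
            "benefit": ben,
            "benefit_median": np.median(ben, axis=0),
            "benefit_q2.5": np.percentile(ben, 2.5, axis=0),
            "benefit_q97.5": np.percentile(ben, 97.5, axis=0),
            "onset_day": onset_day(ben),
        }
    gvals = sorted(results)
    if len(gvals) >= 2:
        a, b = results[gvals[0]]["benefit"], results[gvals[-1]]["benefit"]
        n_days = a.shape[1]
        pvals = np.array(
            [ks_2samp(a[:, d], b[:, d]).pvalue if (np.ptp(a[:, d]) or np.ptp(b[:, d])) else 1.0
             for d in range(n_days)]
        )
        results["ks_pvalues"] = pvals
        results["ks_significant_days"] = np.nonzero(pvals < 0.05)[0]
    return results
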