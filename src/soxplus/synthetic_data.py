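"""Synthetic study generator: greenhouse drivers, a pot dry-down, and
known-truth observations for every stage of the analysis.

The generator emulates a 54-day greenhouse dry-down of potted pine
saplings: hourly PAR / air-temperature / VPD envelopes with a 2-day cold,
low-VPD dip early in the series; soil water content declining monotonically
from field capacity (~0.35 m3 m-3), produced by the water-balance bucket of
a known-truth model run; daily whole-tree transpiration observations with
Gaussian noise, starting between 1 and 2.6 kg tree-1 day-1 and collapsing
to ~10% within about two weeks; weekly leaf-shedding collections; five
xylem vulnerability curves and nineteen A/Ci curves with known generating
parameters.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fvcb import AciCurveObs, PhotoParams, an_fvcb, rd_from_vcmax
from .scenarios import ShedRule
from .soxcore import SoxParams, run_experiment
from .vulnerability import VulnCurveObs, VulnParams, knorm_eval


@dataclass
class SynthConfig:
    """Study conditions for the synthetic bundle."""

    n_days: int = 54
    start_doy: int = 212
    seed: int = 0
    truth: SoxParams = field(default_factory=SoxParams)
    shed_rule: ShedRule = field(default_factory=ShedRule)
    # observation noise
    transpiration_sd: float = 0.1   # kg tree-1 day-1
    plc_sd: float = 3.0             # PLC points
    aci_sd: float = 0.3             # umol m-2 s-1
    shed_mass_cv: float = 0.1       # lognormal CV on weekly collections
    # driver envelope (greenhouse)
    par_peak: float = 900.0         # umol m-2 s-1 clear-day midday PAR
    t_min: float = 15.0             # degC typical nightly minimum
    t_max: float = 30.0             # degC typical daily maximum
    vpd_night: float = 0.4          # kPa
    vpd_peak: float = 2.0           # kPa typical midday maximum
    cold_dip_days: tuple[int, int] = (4, 5)  # day indices (DOY 216-217)
    swc0: float = 0.35              # m3 m-3 at field capacity
    # A/Ci protocol: five Ca steps 400 -> 1200; Ci/Ca rises along the curve
    # (~0.6 at ambient where draw-down is strongest, ~0.75 when CO2-saturated)
    aci_ci_steps: tuple[float, ...] = (240.0, 420.0, 600.0, 780.0, 900.0)
    n_vuln_curves: int = 5
    n_aci_curves: int = 19
    vuln_psi_grid: tuple[float, ...] = tuple(-0.5 * k for k in range(1, 10))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("transpiration_sd", "plc_sd", "aci_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ----------------------------------------------------------------------------
# drivers
# ----------------------------------------------------------------------------

def gen_drivers(config: SynthConfig) -> pd.DataFrame:
    """Hourly PAR / T / VPD series with day-to-day variability and a cold dip.

    PAR follows a half-sine between 06:00 and 20:00; temperature and VPD
    follow smooth diurnal cycles peaking mid-afternoon. The two cold-dip
    days have the lowest daily maximum VPD of the whole series.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_days * 24
    doy = np.repeat(config.start_doy + np.arange(config.n_days), 24)
    hour = np.tile(np.arange(24), config.n_days)

    par_peak_d = config.par_peak * rng.lognormal(0.0, 0.12, config.n_days)
    t_max_d = np.clip(config.t_max + rng.normal(0.0, 1.5, config.n_days), 10.0, 35.0)
    t_min_d = np.clip(config.t_min + rng.normal(0.0, 1.0, config.n_days), 10.0, 35.0)
    t_min_d = np.minimum(t_min_d, t_max_d - 2.0)
    vpd_peak_d = np.clip(config.vpd_peak + rng.normal(0.0, 0.25, config.n_days), 1.2, 3.0)

    for d in config.cold_dip_days:
        par_peak_d[d] = 120.0
        t_max_d[d] = 14.0
        t_min_d[d] = 11.0
        vpd_peak_d[d] = 0.25  # below every other day's clip floor

    par = np.zeros(n)
    t_air = np.zeros(n)
    vpd = np.zeros(n)
    for d in range(config.n_days):
        sl = slice(d * 24, (d + 1) * 24)
        h = np.arange(24)
        daylight = (h >= 6) & (h <= 19)
        phase = np.clip((h - 6) / 14.0, 0.0, 1.0)
        par[sl] = np.where(daylight, par_peak_d[d] * np.sin(np.pi * phase), 0.0)
        # temperature: cosine ramp with minimum at 05:00, maximum at ~15:00
        diurnal = 0.5 * (1.0 - np.cos(np.pi * np.clip((h - 5.0) / 10.0, 0.0, 2.0)))
        t_air[sl] = t_min_d[d] + (t_max_d[d] - t_min_d[d]) * diurnal
        vpd[sl] = config.vpd_night + (vpd_peak_d[d] - config.vpd_night) * diurnal
    vpd = np.maximum(vpd, 0.05)
    return pd.DataFrame(
        {"doy": doy, "hour": hour, "par": par, "t_air_c": t_air, "vpd_kpa": vpd}
    )


# ----------------------------------------------------------------------------
# truth run and soil-water dry-down
# ----------------------------------------------------------------------------

def run_truth(config: SynthConfig, drivers: pd.DataFrame | None = None) -> dict:
    """Known-truth coupled run: bucket soil water + rule-based leaf shedding.

    Returns the run's hourly/daily frames; the hourly SWC trajectory is the
    dry-down used as the prescribed-SWC driver everywhere else.
    """
    drivers = gen_drivers(config) if drivers is None else drivers.copy()
    drivers = drivers.assign(swc=config.swc0)
    rule = config.shed_rule
    return run_experiment(
        drivers, config.truth, nsl_on=config.truth.nsl is not None, swc_mode="bucket",
        shed_rule=(rule.basal_ls, rule.drought_ls, rule.x_threshold),
    )


def gen_swc_drydown(config: SynthConfig, truth_run: dict | None = None) -> np.ndarray:
    """Hourly SWC trajectory (m3 m-3), monotone non-increasing from swc0.

    Produced by the truth run's water-balance bucket so that the decline
    matches simulated extraction exactly.
    """
    truth_run = truth_run or run_truth(config)
    swc = truth_run["hourly"]["swc"].to_numpy(float)
    return np.minimum.accumulate(swc)


# ----------------------------------------------------------------------------
# observations
# ----------------------------------------------------------------------------

def gen_observations(config: SynthConfig, truth_run: dict | None = None) -> dict:
    """All observation sets with known truth.

    Returns a dict with keys ``transpiration`` (daily DataFrame),
    ``shedding`` (weekly cumulative shed fractions), ``vuln_curves`` (list of
    VulnCurveObs), ``aci_curves`` (list of AciCurveObs), ``truth_run``.
    """
    truth_run = truth_run or run_truth(config)
    daily = truth_run["daily"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    # daily whole-tree transpiration + iid Gaussian observation noise
    tr_true = daily["transpiration_kg"].to_numpy(float)
    tr_obs = np.clip(tr_true + rng.normal(0.0, config.transpiration_sd, tr_true.size), 0.0, None)
    transpiration = pd.DataFrame(
        {
            "doy": daily["doy"].to_numpy(),
            "transpiration_kg_mean": tr_obs,
            "transpiration_kg_sd": np.full(tr_true.size, config.transpiration_sd),
        }
    )

    # weekly shed collections: cumulative leaf-area loss fraction with noise
    la = daily["leaf_area_m2"].to_numpy(float)
    la0 = la[0]
    weeks = np.arange(7, config.n_days + 1, 7)
    shed_rows = []
    prev_cum = 0.0
    for w in weeks:
        cum_true = 1.0 - la[w - 1] / la0
        inc = max(cum_true - prev_cum, 0.0)
        inc_obs = inc * rng.lognormal(0.0, config.shed_mass_cv)
        shed_rows.append({"day": int(w), "doy": int(config.start_doy + w - 1), "shed_frac_inc": inc_obs})
        prev_cum = cum_true
    shedding = pd.DataFrame(shed_rows, columns=["day", "doy", "shed_frac_inc"])
    shedding["shed_frac_cum"] = shedding["shed_frac_inc"].cumsum()

    # five vulnerability curves: per-sample parameter variation + PLC noise
    vuln_truth = config.truth.vuln
    vuln_curves = []
    for i in range(config.n_vuln_curves):
        p = float(np.clip(vuln_truth.psi_ref_or_50 + rng.normal(0.0, 0.12), -3.45, -1.55))
        a = float(np.clip(vuln_truth.a_coef + rng.normal(0.0, 0.2), 1.1, 7.9))
        params_i = VulnParams(vuln_truth.formulation, p, a)
        psi = np.array(config.vuln_psi_grid)
        plc = 100.0 * (1.0 - knorm_eval(psi, params_i))
        plc = np.clip(plc + rng.normal(0.0, config.plc_sd, psi.size), 0.0, 100.0)
        vuln_curves.append(VulnCurveObs(psi, plc, sample_id=f"S{i + 1}"))

    # nineteen A/Ci curves: per-tree Vcmax/Jmax variation + assimilation noise
    photo_truth = config.truth.photo
    aci_curves = []
    aci_truth = []
    for i in range(config.n_aci_curves):
        vc = photo_truth.vcmax25 * rng.lognormal(0.0, 0.09)
        jm = photo_truth.jmax25 / photo_truth.vcmax25 * vc * rng.lognormal(0.0, 0.05)
        p_i = replace(photo_truth, vcmax25=vc, jmax25=jm, rd25=rd_from_vcmax(vc))
        ci = np.array(config.aci_ci_steps) * rng.lognormal(0.0, 0.02, len(config.aci_ci_steps))
        an = np.array([an_fvcb(c, 1500.0, 25.0, p_i)[0] for c in ci])
        an = an + rng.normal(0.0, config.aci_sd, an.size)
        aci_curves.append(AciCurveObs(ci, an, t_leaf=25.0, par=1500.0, sample_id=f"T{i + 1}"))
        aci_truth.append({"vcmax25": vc, "jmax25": jm})

    return {
        "transpiration": transpiration,
        "shedding": shedding,
        "vuln_curves": vuln_curves,
        "aci_curves": aci_curves,
        "aci_truth": aci_truth,
        "truth_run": truth_run,
    }


def make_bundle(config: SynthConfig) -> dict:
    """Full input bundle: drivers (with the coupled SWC dry-down) + observations."""
    drivers = gen_drivers(config)
    truth_run = run_truth(config, drivers)
    drivers = drivers.assign(swc=gen_swc_drydown(config, truth_run))
    obs = gen_observations(config, truth_run)
    la_series = truth_run["daily"]["leaf_area_m2"].to_numpy(float)
    return {
        "drivers": drivers,
        "observed_la": la_series,
        "config": config,
        **obs,
    }
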