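"""Bayesian inverse calibration of the gas-exchange engine against daily
transpiration, plus convergence diagnostics and posterior-predictive
evaluation.

Two model configurations are calibrated: "Hydraulic" (3 hydraulic
parameters) and "Hydraulic+NSL" (adds the two Tuzet NSL parameters). The
observation-error scale sigma is a nuisance parameter with a half-normal
prior and is marginalized in reporting. Sampling uses an affine-invariant
ensemble sampler; several independent runs play the role of chains for the
Gelman-Rubin diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .soxcore import SoxParams, _simulate, initial_state
from .vulnerability import gelman_rubin_chains

CONFIGS = ("Hydraulic", "Hydraulic+NSL")

# default calibration window: first 19 days, minus the two cold-front days
DEFAULT_WINDOW = tuple(d for d in range(212, 231) if d not in (216, 217))

# hv indices of the sampled hydraulic/NSL parameters
_HV_IDX = {"ksr_max": 0, "krc_max": 1, "rplant_min": 2, "psi_ref_tuz": 10, "a_tuz": 11}
_HV_NSL_FLAG = 9


@dataclass(frozen=True)
class PriorSpec:
    name: str
    kind: str            # "uniform" | "gaussian" | "halfnormal"
    args: tuple          # (lo, hi) | (mean, sd) | (scale,)
    lower: float = -np.inf  # truncation (physical positivity etc.)
    upper: float = np.inf

    def logpdf(self, x: float) -> float:
        if not (self.lower <= x <= self.upper):
            return -np.inf
        if self.kind == "uniform":
            lo, hi = self.args
            return 0.0 if lo <= x <= hi else -np.inf
        if self.kind == "gaussian":
            mu, sd = self.args
            return -0.5 * ((x - mu) / sd) ** 2
        if self.kind == "halfnormal":
            (scale,) = self.args
            return -0.5 * (x / scale) ** 2 if x > 0 else -np.inf
        raise ValueError(self.kind)

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            if self.kind == "uniform":
                x = rng.uniform(*self.args)
            elif self.kind == "gaussian":
                x = rng.normal(*self.args)
            else:
                x = abs(rng.normal(0.0, self.args[0]))
            if self.lower <= x <= self.upper and np.isfinite(self.logpdf(x)):
                return x
        raise RuntimeError(f"could not draw from prior {self.name}")


@dataclass
class PriorSet:
    """Ordered parameter priors for one model configuration."""

    specs: list[PriorSpec]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def log_prior(self, theta: np.ndarray) -> float:
        total = 0.0
        for s, x in zip(self.specs, theta):
            lp = s.logpdf(float(x))
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([s.sample(rng) for s in self.specs])


def default_priors(config: str, sigma_scale: float = 0.3) -> PriorSet:
    """Broad, biologically meaningful priors (gaussians truncated at 0)."""
    if config not in CONFIGS:
        raise ValueError(f"config must be one of {CONFIGS}")
    specs = [
        PriorSpec("ksr_max", "uniform", (0.01, 1.0)),
        PriorSpec("krc_max", "gaussian", (0.025, 0.01), lower=1e-4),
        PriorSpec("rplant_min", "gaussian", (10.0, 3.0), lower=1e-2),
    ]
    if config == "Hydraulic+NSL":
        specs += [
            PriorSpec("psi_ref_tuz", "gaussian", (-1.5, 0.5), upper=-1e-3),
            PriorSpec("a_tuz", "gaussian", (3.0, 0.5), lower=1e-2),
        ]
    specs.append(PriorSpec("sigma", "halfnormal", (sigma_scale,), lower=1e-4))
    return PriorSet(specs)


@dataclass
class McmcRun:
    """Labelled chains from one calibration."""

    config: str
    param_names: list[str]
    chains: np.ndarray            # (n_chains, n_draws, n_params), post burn-in
    grd: np.ndarray               # per-parameter Gelman-Rubin
    seed: int
    n_iterations: int
    n_burn: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    @property
    def converged(self) -> bool:
        return bool(np.all(self.grd < 1.1))

    def summary(self) -> dict:
        q = np.percentile(self.flat, [2.5, 50, 97.5], axis=0)
        return {
            name: {"q2.5": float(q[0, i]), "median": float(q[1, i]), "q97.5": float(q[2, i])}
            for i, name in enumerate(self.param_names)
        }

    def median_theta(self) -> np.ndarray:
        return np.median(self.flat, axis=0)


# ----------------------------------------------------------------------------
# likelihood machinery
# ----------------------------------------------------------------------------

def gaussian_loglik(
    obs_daily: np.ndarray, sim_daily: np.ndarray, sigma: float,
    mask: np.ndarray | None = None,
) -> float:
    """Sum of Normal log-densities of observed minus simulated daily values."""
    obs = np.asarray(obs_daily, dtype=float)
    sim = np.asarray(sim_daily, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("series must be aligned")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        obs, sim = obs[mask], sim[mask]
    if obs.size == 0:
        raise ValueError("empty mask: no days to compare")
    resid = obs - sim
    return float(
        -0.5 * np.sum((resid / sigma) ** 2)
        - obs.size * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi))
    )


class _SimCache:
    """Precompiled driver arrays + hv template for fast repeated simulation."""

    def __init__(self, drivers: pd.DataFrame, base: SoxParams, nsl_on: bool):
        self.par = drivers["par"].to_numpy(float)
        self.tair = drivers["t_air_c"].to_numpy(float)
        self.vpd = drivers["vpd_kpa"].to_numpy(float)
        self.swc = drivers["swc"].to_numpy(float)
        self.doys = drivers["doy"].to_numpy()[::24]
        self.n_days = self.par.size // 24
        self.la_dummy = np.zeros(self.n_days)
        self.hv = base.to_hvec(nsl_on=nsl_on, swc_mode="driver", la_mode=0)
        self.pv = base.photo.to_array()
        init = initial_state(float(self.swc[0]), base)
        self.init = (0.0, init.psi_canopy_m, init.ksr, init.ci, float(self.swc[0]))

    def daily_tr(self, theta_hv: dict[str, float]) -> np.ndarray:
        hv = self.hv.copy()
        for name, value in theta_hv.items():
            hv[_HV_IDX[name]] = value
        out = _simulate(
            self.par, self.tair, self.vpd, self.swc, self.la_dummy,
            hv, self.pv, *self.init,
        )
        return out[13]


def _make_log_prob(cache: _SimCache, priors: PriorSet, obs: np.ndarray, mask: np.ndarray):
    names = priors.names

    def log_prob(theta: np.ndarray) -> float:
        lp = priors.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        mapping = {n: float(v) for n, v in zip(names, theta) if n != "sigma"}
        sim = cache.daily_tr(mapping)
        sigma = float(theta[-1])
        return lp + gaussian_loglik(obs, sim, sigma, mask)

    return log_prob


# ----------------------------------------------------------------------------
# calibration and diagnostics
# ----------------------------------------------------------------------------

def calibrate(
    config: str,
    obs: pd.DataFrame,
    drivers: pd.DataFrame,
    base_params: SoxParams,
    priors: PriorSet | None = None,
    window: tuple[int, ...] = DEFAULT_WINDOW,
    n_iterations: int = 30_000,
    n_burn: int = 20_000,
    n_chains: int = 3,
    n_walkers: int = 16,
    seed: int = 0,
) -> McmcRun:
    """Calibrate one configuration against daily transpiration observations.

    ``obs`` needs columns doy, transpiration_kg_mean. Only days in ``window``
    enter the likelihood; drivers are truncated to the window's last day.
    ``n_iterations``/``n_burn`` count posterior draws per chain.
    """
    if config not in CONFIGS:
        raise ValueError(f"config must be one of {CONFIGS}")
    priors = priors or default_priors(config)
    nsl_on = config == "Hydraulic+NSL"

    last_doy = max(window)
    sub = drivers[drivers["doy"] <= last_doy].reset_index(drop=True)
    cache = _SimCache(sub, base_params, nsl_on)

    obs_map = dict(zip(obs["doy"].to_numpy(), obs["transpiration_kg_mean"].to_numpy(float)))
    obs_daily = np.array([obs_map.get(d, np.nan) for d in cache.doys])
    mask = np.array([(d in window) and np.isfinite(obs_map.get(d, np.nan)) for d in cache.doys])
    if not mask.any():
        raise ValueError("calibration window has no observed days")

    log_prob = _make_log_prob(cache, priors, obs_daily, mask)
    ndim = len(priors.specs)
    n_steps = max(int(np.ceil(n_iterations / n_walkers)), 10)
    burn_steps = min(int(np.ceil(n_burn / n_walkers)), n_steps - 1)

    rng = np.random.default_rng(seed)
    chains = []
    acc = []
    for _ in range(n_chains):
        p0 = np.array([priors.sample(rng) for _ in range(n_walkers)])
        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
        sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        chains.append(sampler.get_chain(discard=burn_steps, flat=True))
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    chains_arr = np.stack(chains)
    grd = gelman_rubin(chains_arr)
    return McmcRun(
        config=config, param_names=priors.names, chains=chains_arr, grd=grd,
        seed=seed, n_iterations=n_iterations, n_burn=n_burn,
        diagnostics={"acceptance_fraction": acc, "window": list(window)},
    )


def gelman_rubin(chains) -> np.ndarray:
    """Per-parameter potential-scale-reduction statistic R-hat.

    ``chains``: array (n_chains, n_draws, n_params) or list of (n_draws,
    n_params) arrays; requires >= 2 chains of equal length.
    """
    if isinstance(chains, np.ndarray) and chains.ndim == 3:
        chains = list(chains)
    return gelman_rubin_chains(list(chains))


def evaluate_fit(
    posterior: McmcRun,
    obs: pd.DataFrame,
    drivers: pd.DataFrame,
    base_params: SoxParams,
    n_draws: int = 500,
    seed: int = 0,
) -> dict:
    """Posterior-predictive evaluation over the full experiment window.

    The median daily prediction across ``n_draws`` posterior draws is
    compared with observations by an AR(1)-residual regression (observed on
    simulated), with RMSE, Cox-Snell pseudo-R2, and the relative daily error
    series (sim - obs) / obs (zero-transpiration days excluded).
    """
    nsl_on = posterior.config == "Hydraulic+NSL"
    cache = _SimCache(drivers.reset_index(drop=True), base_params, nsl_on)
    rng = np.random.default_rng(seed)
    flat = posterior.flat
    idx = rng.integers(0, flat.shape[0], n_draws)
    names = [n for n in posterior.param_names if n != "sigma"]
    sims = np.empty((n_draws, cache.n_days))
    for k, i in enumerate(idx):
        mapping = dict(zip(names, flat[i, : len(names)]))
        sims[k] = cache.daily_tr(mapping)
    sim_med = np.median(sims, axis=0)

    obs_map = dict(zip(obs["doy"].to_numpy(), obs["transpiration_kg_mean"].to_numpy(float)))
    obs_daily = np.array([obs_map.get(d, np.nan) for d in cache.doys])
    ok = np.isfinite(obs_daily)
    o, s = obs_daily[ok], sim_med[ok]

    rmse = float(np.sqrt(np.mean((o - s) ** 2)))
    model = sm.GLSAR(o, sm.add_constant(s), rho=1)
    res = model.iterative_fit(maxiter=10)
    null = sm.GLSAR(o, np.ones((o.size, 1)), rho=1).iterative_fit(maxiter=10)
    n = o.size
    pseudo_r2 = float(1.0 - np.exp(-(2.0 / n) * (res.llf - null.llf)))

    nz = o > 1e-9
    rel_err = np.full(o.size, np.nan)
    rel_err[nz] = (s[nz] - o[nz]) / o[nz]

    return {
        "rmse": rmse,
        "pseudo_r2_cs": pseudo_r2,
        "ar1_intercept": float(res.params[0]),
        "ar1_slope": float(res.params[1]),
        "daily_error_series": rel_err,
        "sim_median": sim_med,
        "obs": obs_daily,
        "doys": cache.doys,
    }
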