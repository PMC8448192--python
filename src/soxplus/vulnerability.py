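"""Xylem vulnerability curves: response functions, Bayesian fitting, posterior merging.

Three functional forms describe the decline of normalized xylem conductance
``k_norm`` (0-1) with increasingly negative xylem water potential:

* ``WB``   -- Weibull, ``k = exp(-(|psi|/|psi_ref|)**a)``; ``psi_ref`` is the
  potential at which ``k = exp(-1) ~ 0.37`` and ``k(0) = 1`` exactly.
* ``SE``   -- sigmoid exponential, ``k = 1 - 1/(1 + exp(a*(psi - psi50)))``.
* ``SOXf`` -- ``k = 1/(1 + (|psi|/|psi50|)**a)``.

Curves are fit per sample by ensemble MCMC with a Gaussian likelihood on
percent loss of conductivity (PLC) and the residual scale as a nuisance
parameter; per-sample posteriors are merged by with-replacement resampling
to obtain the population-average response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.stats import spearmanr

FORMULATIONS = ("WB", "SE", "SOXf")

# uniform prior supports (Table-2-style, biologically meaningful)
PSI_PRIOR = (-3.5, -1.5)   # MPa, psi_ref (WB) or psi50 (SE, SOXf)
ACOEF_PRIOR = (1.0, 8.0)   # unitless shape
SIGMA_PRIOR = (0.1, 20.0)  # PLC points, residual scale nuisance


@dataclass(frozen=True)
class VulnParams:
    """One parameterization of a vulnerability response function."""

    formulation: str
    psi_ref_or_50: float  # MPa, < 0
    a_coef: float         # unitless, > 0

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if not np.isfinite(self.psi_ref_or_50) or not np.isfinite(self.a_coef):
            raise ValueError("non-finite vulnerability parameters")
        if self.psi_ref_or_50 >= 0:
            raise ValueError("psi parameter must be negative (MPa)")
        if self.a_coef <= 0:
            raise ValueError("a_coef must be positive")


@dataclass
class VulnCurveObs:
    """One measured vulnerability curve: (psi_xylem MPa <= 0, PLC %) points."""

    psi: np.ndarray
    plc: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.plc = np.asarray(self.plc, dtype=float)
        if self.psi.shape != self.plc.shape or self.psi.ndim != 1:
            raise ValueError("psi and plc must be 1-D arrays of equal length")
        if self.psi.size < 4:
            raise ValueError("need at least 4 points per curve")
        if np.any(self.psi > 0):
            raise ValueError("psi_xylem must be <= 0 MPa")
        if np.any((self.plc < 0) | (self.plc > 100)):
            raise ValueError("PLC must lie in [0, 100]")
        order = np.argsort(self.psi)[::-1]  # 0 -> most negative
        self.psi = self.psi[order]
        self.plc = self.plc[order]


@dataclass
class VulnPosterior:
    """Posterior draws for one formulation (per-curve or merged)."""

    formulation: str
    samples: np.ndarray          # (n, 2): psi parameter, a_coef
    source: str = "per-curve"
    diagnostics: dict = field(default_factory=dict)

    @property
    def median_params(self) -> VulnParams:
        med = np.median(self.samples, axis=0)
        return VulnParams(self.formulation, float(med[0]), float(med[1]))

    def summary(self) -> dict:
        q = np.percentile(self.samples, [2.5, 50, 97.5], axis=0)
        names = ("psi_ref" if self.formulation == "WB" else "psi50", "a_coef")
        return {
            name: {"q2.5": float(q[0, i]), "median": float(q[1, i]), "q97.5": float(q[2, i])}
            for i, name in enumerate(names)
        }


# ----------------------------------------------------------------------------
# response functions and inverses
# ----------------------------------------------------------------------------

def _knorm_arr(psi: np.ndarray, formulation: str, p: float, a: float) -> np.ndarray:
    """Vectorized k_norm; |psi| ratios keep non-integer powers well defined."""
    psi = np.asarray(psi, dtype=float)
    if formulation == "WB":
        return np.exp(-((np.abs(psi) / abs(p)) ** a))
    if formulation == "SE":
        z = np.clip(a * (psi - p), -700.0, 700.0)
        return 1.0 - 1.0 / (1.0 + np.exp(z))
    # SOXf
    return 1.0 / (1.0 + (np.abs(psi) / abs(p)) ** a)


def knorm_eval(psi, params: VulnParams):
    """Normalized conductance k_norm in [0, 1] at xylem potential ``psi`` (MPa <= 0)."""
    psi_arr = np.asarray(psi, dtype=float)
    if np.any(psi_arr > 0):
        raise ValueError("psi must be <= 0 MPa")
    out = _knorm_arr(psi_arr, params.formulation, params.psi_ref_or_50, params.a_coef)
    return float(out) if np.isscalar(psi) or psi_arr.ndim == 0 else out


def psi_at_knorm(target: float, params: VulnParams) -> float:
    """Xylem potential (MPa) at which k_norm equals ``target`` (closed forms)."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    p, a = params.psi_ref_or_50, params.a_coef
    if params.formulation == "WB":
        return -abs(p) * (-np.log(target)) ** (1.0 / a)
    if params.formulation == "SE":
        # target = 1 - 1/(1+e^{a(psi-p)})  =>  psi = p + ln(t/(1-t))/a
        return p + np.log(target / (1.0 - target)) / a
    # SOXf: (|psi|/|p|)^a = 1/t - 1
    return -abs(p) * (1.0 / target - 1.0) ** (1.0 / a)


def plc_knorm_convert(x, direction: str = "to_knorm"):
    """Convert between PLC (percent, 0-100) and k_norm (fraction, 0-1).

    ``direction``: ``"to_knorm"`` (PLC -> k_norm) or ``"to_plc"`` (k_norm -> PLC).
    """
    arr = np.asarray(x, dtype=float)
    if direction == "to_knorm":
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError("PLC must lie in [0, 100]")
        out = 1.0 - arr / 100.0
    elif direction == "to_plc":
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("k_norm must lie in [0, 1]")
        out = 100.0 * (1.0 - arr)
    else:
        raise ValueError("direction must be 'to_knorm' or 'to_plc'")
    return float(out) if np.isscalar(x) else out


# ----------------------------------------------------------------------------
# Bayesian per-curve fitting
# ----------------------------------------------------------------------------

def _log_prob(theta: np.ndarray, psi: np.ndarray, plc: np.ndarray, formulation: str) -> float:
    p, a, sigma = theta
    if not (PSI_PRIOR[0] <= p <= PSI_PRIOR[1]):
        return -np.inf
    if not (ACOEF_PRIOR[0] <= a <= ACOEF_PRIOR[1]):
        return -np.inf
    if not (SIGMA_PRIOR[0] <= sigma <= SIGMA_PRIOR[1]):
        return -np.inf
    pred = 100.0 * (1.0 - _knorm_arr(psi, formulation, p, a))
    resid = plc - pred
    return float(-0.5 * np.sum((resid / sigma) ** 2) - resid.size * np.log(sigma))


def fit_vuln_curve(
    obs: VulnCurveObs,
    formulation: str = "WB",
    n_iterations: int = 50_000,
    n_burn: int = 30_000,
    n_chains: int = 2,
    n_walkers: int = 8,
    seed: int = 0,
) -> VulnPosterior:
    """Fit one vulnerability curve by ensemble MCMC.

    ``n_iterations`` counts total posterior draws per chain (walkers x steps);
    the first ``n_burn`` draws are discarded. Two independent chains are run by
    default and compared with the Gelman-Rubin statistic (flagged, not fatal,
    above 1.05).
    """
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    if np.ptp(obs.plc) == 0:
        raise ValueError("degenerate curve: all PLC values identical")
    n_steps = max(int(np.ceil(n_iterations / n_walkers)), 10)
    burn_steps = min(int(np.ceil(n_burn / n_walkers)), n_steps - 1)

    rng = np.random.default_rng(seed)
    chains = []
    for _ in range(n_chains):
        p0 = np.column_stack(
            [
                rng.uniform(*PSI_PRIOR, n_walkers),
                rng.uniform(*ACOEF_PRIOR, n_walkers),
                rng.uniform(0.5, 10.0, n_walkers),
            ]
        )
        sampler = emcee.EnsembleSampler(
            n_walkers, 3, _log_prob, args=(obs.psi, obs.plc, formulation)
        )
        sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        chains.append(sampler.get_chain(discard=burn_steps, flat=True))

    grd = gelman_rubin_chains([c[:, :2] for c in chains]) if n_chains >= 2 else None
    samples = np.vstack(chains)[:, :2]
    diagnostics = {"gelman_rubin": grd, "converged": bool(grd is None or np.all(grd < 1.05))}
    return VulnPosterior(formulation, samples, source=f"curve:{obs.sample_id}", diagnostics=diagnostics)


def gelman_rubin_chains(chains: list[np.ndarray]) -> np.ndarray:
    """Potential-scale-reduction statistic over a list of equal-length (n, d) chains."""
    arr = np.stack([np.atleast_2d(c) for c in chains])  # (m, n, d)
    m, n, _ = arr.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + (1 + 1 / m) * b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(np.where(w > 0, var_hat / w, 1.0))


def merge_posteriors(
    posteriors: list[VulnPosterior], n_per_curve: int = 1000, seed: int = 0
) -> VulnPosterior:
    """Merge per-curve posteriors by with-replacement resampling (n_per_curve each)."""
    if not posteriors:
        raise ValueError("no posteriors to merge")
    forms = {p.formulation for p in posteriors}
    if len(forms) > 1:
        raise ValueError(f"mixed formulations: {sorted(forms)}")
    rng = np.random.default_rng(seed)
    parts = [
        p.samples[rng.integers(0, p.samples.shape[0], n_per_curve)] for p in posteriors
    ]
    merged = np.vstack(parts)
    return VulnPosterior(posteriors[0].formulation, merged, source="combined")


def compare_formulations(
    curves: list[VulnCurveObs],
    n_iterations: int = 50_000,
    n_burn: int = 30_000,
    seed: int = 0,
) -> list[dict]:
    """Fit every formulation to every curve; rank by pooled RMSE (lower first).

    pseudo-R^2 is the squared Spearman correlation between observed and
    modelled PLC, pooled over curves, using each curve's posterior-median
    parameters for prediction.
    """
    if not curves:
        raise ValueError("need at least one curve")
    results = []
    for fi, form in enumerate(FORMULATIONS):
        obs_all, pred_all = [], []
        merged_fits = []
        for ci, curve in enumerate(curves):
            post = fit_vuln_curve(
                curve, form, n_iterations=n_iterations, n_burn=n_burn,
                seed=seed + 1000 * fi + ci,
            )
            merged_fits.append(post)
            pred = 100.0 * (1.0 - knorm_eval(curve.psi, post.median_params))
            obs_all.append(curve.plc)
            pred_all.append(pred)
        obs_arr = np.concatenate(obs_all)
        pred_arr = np.concatenate(pred_all)
        rmse = float(np.sqrt(np.mean((obs_arr - pred_arr) ** 2)))
        if np.ptp(pred_arr) == 0 or np.ptp(obs_arr) == 0:
            pseudo_r2 = 1.0 if rmse == 0 else 0.0
        else:
            rho = spearmanr(obs_arr, pred_arr).statistic
            pseudo_r2 = float(rho**2)
        merged = merge_posteriors(merged_fits, seed=seed + 7 * fi)
        results.append(
            {
                "formulation": form,
                "rmse": rmse,
                "pseudo_r2": pseudo_r2,
                "merged_posterior": merged,
            }
        )
    results.sort(key=lambda r: r["rmse"])
    return results
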