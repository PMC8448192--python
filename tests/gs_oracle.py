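"""Independent brute-force oracle for the stomatal gain-x-cost optimum.

Reimplements the photosynthesis response in plain numpy (deliberately not
using the package's kernels) and maximizes An(gs) * k_norm(psi_canopy(gs))
on a dense gs grid, for comparison against the analytic optimum.
"""

import numpy as np

from soxplus import knorm_eval


def an_numpy(ci, par, p):
    """FvCB net assimilation at 25 degC on the reference-kinetics branch."""
    vc = p.vcmax25
    jm = p.jmax25
    kco = p.kc25 * (1.0 + p.o2_mole_fraction / p.ko25)
    avc = vc * (ci - p.gamma_star25) / (ci + kco)
    q = p.alpha_j * par
    j = (q + jm - np.sqrt((q + jm) ** 2 - 4.0 * p.theta_j * q * jm)) / (2.0 * p.theta_j)
    aj = j * (ci - p.gamma_star25) / (4.0 * ci + 8.0 * p.gamma_star25)
    return np.minimum(avc, aj) - p.rd25


def ci_equilibrium(gs, par, params, n_iter=80):
    """Bisection on An(Ci) - gs*(Ca - Ci) = 0, vectorized over gs.

    The residual is strictly increasing in Ci (An rises, supply falls), so
    the root is unique; bisection is robust for arbitrarily small gs.
    """
    gs = np.atleast_1d(np.asarray(gs, dtype=float))
    lo = np.full_like(gs, 1.0)
    hi = np.full_like(gs, 4.0 * params.ca)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        resid = an_numpy(mid, par, params.photo) - gs * (params.ca - mid)
        hi = np.where(resid > 0.0, mid, hi)
        lo = np.where(resid > 0.0, lo, mid)
    return 0.5 * (lo + hi)


def grid_search_gs(psi_m, vpd, par, params, n_grid=2000):
    """gs maximizing An(gs) * k_norm(psi_canopy(gs)) on a log-spaced grid.

    The cost is evaluated at the dampened canopy potential, whose predawn
    component does not respond to stomatal opening, so the potential drop
    carries a factor 1/2 relative to the instantaneous canopy potential.
    """
    k_m = float(knorm_eval(psi_m, params.vuln))
    rplant_eff = params.hydraulic.rplant_min / k_m
    gs = np.logspace(-4, 0.5, n_grid)
    ci = ci_equilibrium(gs, par, params)
    an = an_numpy(ci, par, params.photo)
    psi_c = np.minimum(psi_m - 0.5 * 1.6 * gs * vpd * rplant_eff, 0.0)
    k = np.array([float(knorm_eval(x, params.vuln)) for x in psi_c])
    return float(gs[np.argmax(an * k)])


_FORM_CODE = {"WB": 0, "SE": 1, "SOXf": 2}


def run_oracle_comparison(params, n_conditions=120, seed=2024):
    """Compare analytic vs grid-search gs over randomized conditions.

    Returns (n_checked, n_failed, worst_case, rel_errors) where a failure
    exceeds max(10% relative, 0.005 mol m-2 s-1).
    """
    from soxplus import gs_optimal, xi_cost
    from soxplus.soxcore import XI_CAP, _dknorm_j

    form = _FORM_CODE[params.vuln.formulation]
    rng = np.random.default_rng(seed)
    checked = failed = 0
    worst = None
    rel_errors = []
    for _ in range(n_conditions):
        psi_m = float(rng.uniform(-3.0, -0.5))
        vpd = float(rng.uniform(0.5, 2.5))
        par = float(rng.uniform(600.0, 1500.0))
        k_m = float(knorm_eval(psi_m, params.vuln))
        dk = _dknorm_j(psi_m, form, params.vuln.psi_ref_or_50, params.vuln.a_coef)
        xi = xi_cost(k_m, dk, params.hydraulic.rplant_min, vpd)
        if xi >= XI_CAP:  # vanishing-cost limit is floored, not optimized
            continue
        gs_grid = grid_search_gs(psi_m, vpd, par, params)
        # analytic side solved self-consistently (gs and Ci together, as in
        # the hourly engine), with the gain from central differences
        gs_analytic = 0.05
        g = 0.0
        for _ in range(100):
            ci = float(ci_equilibrium(gs_analytic, par, params)[0])
            g = float(
                an_numpy(np.array([ci + 1.0]), par, params.photo)[0]
                - an_numpy(np.array([ci - 1.0]), par, params.photo)[0]
            ) / 2.0
            g = max(g, 0.0)
            gs_new = gs_optimal(g, xi, 1e-6)
            if abs(gs_new - gs_analytic) < 1e-7:
                gs_analytic = gs_new
                break
            gs_analytic = 0.5 * gs_analytic + 0.5 * gs_new
        if g <= 1e-6:
            continue
        tol = max(0.10 * gs_grid, 0.005)
        err = abs(gs_analytic - gs_grid)
        rel_errors.append(err / max(gs_grid, 1e-9))
        if err > tol:
            failed += 1
            if worst is None or err > worst[0]:
                worst = (err, psi_m, vpd, par, gs_grid, gs_analytic)
        checked += 1
    return checked, failed, worst, rel_errors
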