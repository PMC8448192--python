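"""Validated readers/writers, run configuration, and the three-step pipeline
(curve fits -> calibration -> scenarios).

All tabular I/O is CSV; summaries are JSON. Day-of-year (DOY, integer) is the
canonical time key; hours run 0-23; potentials are stored as negative MPa.
Relative humidity, if given instead of VPD, is converted via the Magnus
saturation vapor pressure at air temperature.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import DEFAULT_WINDOW, calibrate, evaluate_fit
from .fvcb import AciCurveObs, fit_aci_population
from .scenarios import gmin_sensitivity, run_scenario
from .soxcore import SoxParams
from .synthetic_data import SynthConfig, make_bundle
from .vulnerability import VulnCurveObs, compare_formulations

logger = logging.getLogger("soxplus")

# Magnus saturation vapor pressure constants (kPa, degC)
MAGNUS_A = 0.6108
MAGNUS_B = 17.27
MAGNUS_C = 237.3


def saturation_vpd(t_air_c, rh_pct):
    """VPD (kPa) from air temperature and relative humidity (Magnus formula)."""
    es = MAGNUS_A * np.exp(MAGNUS_B * np.asarray(t_air_c) / (np.asarray(t_air_c) + MAGNUS_C))
    return es * (1.0 - np.asarray(rh_pct) / 100.0)


DRIVER_SCHEMA = {
    "required": ("doy", "hour", "par", "t_air_c", "swc"),
    "either": ("vpd_kpa", "rh_pct"),
}
OBS_SCHEMA = {"required": ("doy", "transpiration_kg_mean")}
VULN_SCHEMA = {"required": ("sample_id", "psi_mpa", "plc_percent")}
ACI_SCHEMA = {"required": ("sample_id", "ci", "an")}


def read_timeseries(path, schema: dict = DRIVER_SCHEMA) -> pd.DataFrame:
    """Read and validate a CSV time series against a column schema.

    For the driver schema: DOY must be present, monotone non-decreasing and
    free of duplicate (doy, hour) rows; if only relative humidity is given,
    ``vpd_kpa`` is derived from the Magnus saturation pressure. Gaps in the
    DOY sequence are reported as warnings, not errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in schema.get("required", ()) if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    either = schema.get("either")
    if either and not any(c in df.columns for c in either):
        raise ValueError(f"{path.name}: need one of {either}")

    if "doy" in df.columns:
        doy = df["doy"].to_numpy()
        if np.any(np.diff(doy) < 0):
            raise ValueError(f"{path.name}: DOY must be monotone non-decreasing")
        if "hour" in df.columns:
            if df.duplicated(subset=["doy", "hour"]).any():
                raise ValueError(f"{path.name}: duplicate (doy, hour) rows")
        elif df.duplicated(subset=["doy"]).any():
            raise ValueError(f"{path.name}: duplicate DOY rows")
        gaps = np.setdiff1d(np.arange(doy.min(), doy.max() + 1), doy)
        if gaps.size:
            logger.warning("%s: gaps in DOY sequence: %s", path.name, gaps.tolist())

    if "vpd_kpa" not in df.columns and "rh_pct" in df.columns:
        if np.any((df["rh_pct"] < 0) | (df["rh_pct"] > 100)):
            raise ValueError(f"{path.name}: rh_pct outside [0, 100]")
        df["vpd_kpa"] = saturation_vpd(df["t_air_c"], df["rh_pct"])

    if "swc" in df.columns and np.any((df["swc"] <= 0) | (df["swc"] >= 1)):
        raise ValueError(f"{path.name}: swc must lie in (0, 1) m3 m-3")
    if "par" in df.columns and np.any(df["par"] < 0):
        raise ValueError(f"{path.name}: PAR must be >= 0")
    return df


def read_vuln_curves(path) -> list[VulnCurveObs]:
    df = read_timeseries(path, VULN_SCHEMA)
    return [
        VulnCurveObs(g["psi_mpa"].to_numpy(), g["plc_percent"].to_numpy(), sample_id=str(sid))
        for sid, g in df.groupby("sample_id", sort=True)
    ]


def read_aci_curves(path) -> list[AciCurveObs]:
    df = read_timeseries(path, ACI_SCHEMA)
    curves = []
    for sid, g in df.groupby("sample_id", sort=True):
        t_leaf = float(g["t_leaf"].iloc[0]) if "t_leaf" in g.columns else 25.0
        par = float(g["par"].iloc[0]) if "par" in g.columns else 1500.0
        curves.append(
            AciCurveObs(g["ci"].to_numpy(), g["an"].to_numpy(), t_leaf=t_leaf, par=par,
                        sample_id=str(sid))
        )
    return curves


def write_bundle(bundle: dict, outdir) -> dict:
    """Write a synthetic input bundle (drivers, observations, curves, truth) as CSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["drivers"].to_csv(outdir / "drivers.csv", index=False)
    bundle["transpiration"].to_csv(outdir / "observations.csv", index=False)
    bundle["shedding"].to_csv(outdir / "shedding.csv", index=False)
    pd.concat(
        [
            pd.DataFrame({"sample_id": c.sample_id, "psi_mpa": c.psi, "plc_percent": c.plc})
            for c in bundle["vuln_curves"]
        ]
    ).to_csv(outdir / "vuln_curves.csv", index=False)
    pd.concat(
        [
            pd.DataFrame(
                {"sample_id": c.sample_id, "ci": c.ci, "an": c.an,
                 "t_leaf": c.t_leaf, "par": c.par}
            )
            for c in bundle["aci_curves"]
        ]
    ).to_csv(outdir / "aci_curves.csv", index=False)
    pd.DataFrame({"day": np.arange(len(bundle["observed_la"])), "leaf_area_m2": bundle["observed_la"]}).to_csv(
        outdir / "leaf_area.csv", index=False
    )
    cfg = bundle["config"]
    truth = {
        "seed": cfg.seed,
        "hydraulic": asdict(cfg.truth.hydraulic),
        "soil": asdict(cfg.truth.soil),
        "vuln": asdict(cfg.truth.vuln),
        "nsl": asdict(cfg.truth.nsl) if cfg.truth.nsl else None,
        "photo": {"vcmax25": cfg.truth.photo.vcmax25, "jmax25": cfg.truth.photo.jmax25},
        "shed_rule": asdict(cfg.shed_rule),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return {"outdir": str(outdir)}


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (paths, flags, seeds, window)."""

    outdir: str = "soxplus_out"
    seed: int = 0
    n_days: int = 54
    gmin_values: tuple[float, ...] = (2.0, 3.0)
    n_runs: int = 500
    calib_iterations: int = 30_000
    calib_burn: int = 20_000
    calib_chains: int = 3
    vuln_iterations: int = 50_000
    vuln_burn: int = 30_000
    window: tuple[int, ...] = DEFAULT_WINDOW
    drivers_csv: str | None = None
    observations_csv: str | None = None
    vuln_csv: str | None = None
    aci_csv: str | None = None
    leaf_area_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.window, list):
            cfg.window = tuple(cfg.window)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def pipeline_run(config: RunConfig) -> dict:
    """Execute the three-step pipeline and write a machine-readable report.

    Stages: (1) vulnerability-curve fits and formulation comparison;
    (2) A/Ci fits (skipped, with a note, if no curves are given and defaults
    are used); (3) calibration of both configurations; (4) scenario ensembles
    with the benefit-of-shedding statistic and g_min sensitivity. Synthetic
    inputs are generated when no CSV paths are configured.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    base = SoxParams()
    if config.drivers_csv is None:
        synth = SynthConfig(seed=config.seed, n_days=config.n_days, truth=base)
        bundle = make_bundle(synth)
        write_bundle(bundle, outdir / "inputs")
        drivers = bundle["drivers"]
        obs = bundle["transpiration"]
        vuln_curves = bundle["vuln_curves"]
        aci_curves = bundle["aci_curves"]
        la_obs = bundle["observed_la"]
        report["stages"]["synth"] = {"n_days": config.n_days, "source": "synthetic"}
    else:
        drivers = read_timeseries(config.drivers_csv, DRIVER_SCHEMA)
        obs = read_timeseries(config.observations_csv, OBS_SCHEMA)
        vuln_curves = read_vuln_curves(config.vuln_csv) if config.vuln_csv else []
        aci_curves = read_aci_curves(config.aci_csv) if config.aci_csv else []
        la_obs = (
            pd.read_csv(config.leaf_area_csv)["leaf_area_m2"].to_numpy()
            if config.leaf_area_csv else None
        )

    try:
        ranking = compare_formulations(
            vuln_curves, n_iterations=config.vuln_iterations, n_burn=config.vuln_burn,
            seed=config.seed + 1,
        )
        best = ranking[0]
        report["stages"]["fit_vuln"] = {
            "ranking": [
                {"formulation": r["formulation"], "rmse": r["rmse"], "pseudo_r2": r["pseudo_r2"]}
                for r in ranking
            ],
            "best": best["formulation"],
            "posterior": best["merged_posterior"].summary(),
        }
        vuln_best = best["merged_posterior"].median_params
    except Exception as exc:  # noqa: BLE001 - stage-tagged failure
        raise RuntimeError(f"stage fit_vuln failed: {exc}") from exc

    if aci_curves:
        try:
            aci = fit_aci_population(aci_curves, seed=config.seed + 2)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage fit_aci failed: {exc}") from exc
        report["stages"]["fit_aci"] = {k: v for k, v in aci.items() if k != "per_curve"}
        photo = base.photo.__class__(
            vcmax25=aci["vcmax25_median"], jmax25=aci["jmax25_median"],
            rd25=0.015 * aci["vcmax25_median"],
        )
    else:
        report["stages"]["fit_aci"] = {"skipped": "no A/Ci curves supplied; default kinetics used"}
        photo = base.photo

    params = SoxParams(hydraulic=base.hydraulic, soil=base.soil, photo=photo,
                       vuln=vuln_best, nsl=base.nsl, patm=base.patm, ca=base.ca)

    posteriors = {}
    for i, conf in enumerate(("Hydraulic", "Hydraulic+NSL")):
        try:
            run = calibrate(
                conf, obs, drivers, params, window=config.window,
                n_iterations=config.calib_iterations, n_burn=config.calib_burn,
                n_chains=config.calib_chains, seed=config.seed + 10 + i,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage calibrate[{conf}] failed: {exc}") from exc
        posteriors[conf] = run
        ev = evaluate_fit(run, obs, drivers, params, n_draws=min(config.n_runs, 200),
                          seed=config.seed + 20 + i)
        report["stages"][f"calibrate_{conf}"] = {
            "summary": run.summary(),
            "gelman_rubin": run.grd.tolist(),
            "converged": run.converged,
            "rmse": ev["rmse"],
            "pseudo_r2_cs": ev["pseudo_r2_cs"],
            "ar1_slope": ev["ar1_slope"],
            "ar1_intercept": ev["ar1_intercept"],
        }

    try:
        la_input = ("observed", la_obs) if la_obs is not None else ("rule", None)
        s1 = run_scenario("Hydraulic", posteriors["Hydraulic"], drivers, params,
                          la_input, n_runs=config.n_runs, seed=config.seed + 31)
        s2 = run_scenario("Hydraulic+NSL", posteriors["Hydraulic+NSL"], drivers, params,
                          ("constant", None), n_runs=config.n_runs, seed=config.seed + 32)
        s3 = run_scenario("Hydraulic+NSL+shedding", posteriors["Hydraulic+NSL"], drivers,
                          params, la_input, n_runs=config.n_runs, seed=config.seed + 33)
        gmin = gmin_sensitivity(
            posteriors["Hydraulic+NSL"], drivers, params, la_shed_input=la_input,
            gmin_values=config.gmin_values, n_runs=config.n_runs, seed=config.seed + 40,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage scenarios failed: {exc}") from exc

    for s, tag in ((s1, "hydraulic"), (s2, "nsl"), (s3, "full")):
        s.summary.to_csv(outdir / f"scenario_{tag}.csv", index=False)
    report["stages"]["scenarios"] = {
        "end_plkrc": {
            "Hydraulic": s1.final_plkrc_median,
            "Hydraulic+NSL": s2.final_plkrc_median,
            "Hydraulic+NSL+shedding": s3.final_plkrc_median,
        },
        "delta_hyd_minus_nsl": s1.final_plkrc_median - s2.final_plkrc_median,
        "delta_hyd_minus_full": s1.final_plkrc_median - s3.final_plkrc_median,
        "onset_days": {str(g): gmin[g]["onset_day"] for g in config.gmin_values},
    }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
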