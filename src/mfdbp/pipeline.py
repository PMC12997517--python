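"""End-to-end orchestration of the breakpoint analysis.

Stages run in dependency order: correlation screening, LOESS initialisation,
frequentist segmented regression, Bayesian re-estimation, ROPE analysis,
Monte Carlo power, logistic age cut-offs and band-wise variance analysis.
The frequentist breakpoint propagates downstream (to the logistic stage and
as the power-simulation success reference), so the pipeline stays internally
consistent if the input data change.

All randomness derives from one master seed through named
``numpy.random.SeedSequence`` streams, so toggling one stage never shifts
another stage's draws.  The report bundle is JSON-serialisable, carries the
configuration hash on every stage, and is written atomically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np

from . import bands as bands_mod
from . import bayes as bayes_mod
from . import cutoffs as cutoffs_mod
from . import power as power_mod
from . import screening as screening_mod
from . import segmented as segmented_mod
from .cohort import Cohort, load_reference_cohort, parse_cohort_table, subset_by_age

logger = logging.getLogger("mfdbp")

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "write_bundle"]

DEFAULT_CONFIG: dict[str, Any] = {
    "input": None,          # path to a cohort CSV; None -> packaged reference cohort
    "max_age": 11.0,
    "seed": 0,
    "stages": ["screen", "segfit", "bayes", "rope", "power", "cutoffs", "bands"],
    "screen": {"variables": None},
    "segfit": {"psi0": 6.0},
    "bayes": {"chains": 4, "draws": 2500},
    "rope": {"halfwidth": bayes_mod.DEFAULT_ROPE_HALFWIDTH, "paired_diff_sd": 55.0,
             "multipliers": [1.0, 1.5, 2.0]},
    "power": {"n_grid": list(power_mod.DEFAULT_N_GRID),
              "tolerances": list(power_mod.DEFAULT_TOLERANCES),
              "reps": 10_000, "sigma_mode": "posterior", "reference": "point"},
    "cutoffs": {"probabilities": [0.8, 0.5, 0.2]},
    "bands": {"boundaries": list(bands_mod.DEFAULT_BAND_BOUNDARIES),
              "variables": ["mean_mfs_um2", "sd_mfs_um2", "cov_mfs",
                            "mfa_pct", "fat_pct", "cfa_pct"],
              "bootstrap_reps": 5000},
}

_STAGE_DEPS = {
    "screen": [],
    "segfit": [],
    "bayes": ["segfit"],
    "rope": ["bayes"],
    "power": ["bayes", "segfit"],
    "cutoffs": ["segfit"],
    "bands": [],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    """Independent per-stage seeds spawned from the master seed by name order."""
    order = ["screen", "segfit", "bayes", "rope", "power", "cutoffs", "bands"]
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(order))
    table = {nm: int(child.generate_state(1)[0] % (2**31)) for nm, child in zip(order, children)}
    return {nm: table[nm] for nm in names}


def run_pipeline(config: dict | None = None) -> dict:
    """Run the configured stages and return the report bundle.

    A stage whose dependency failed is marked ``"skipped"`` with the reason;
    the partial bundle is still returned (and written, if requested).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    cfg_hash = _config_hash(cfg)
    requested = list(cfg["stages"])
    seeds = _stage_seeds(int(cfg["seed"]), requested)

    if cfg["input"]:
        cohort = parse_cohort_table(cfg["input"])
    else:
        cohort = load_reference_cohort()
    analysis = subset_by_age(cohort, float(cfg["max_age"]))

    bundle: dict[str, Any] = {
        "meta": {
            "config": cfg,
            "config_hash": cfg_hash,
            "seed": int(cfg["seed"]),
            "stage_seeds": seeds,
            "n_total": len(cohort),
            "n_analysis": len(analysis),
        }
    }
    state: dict[str, Any] = {}
    status: dict[str, str] = {}

    for name in requested:
        bad_dep = next((d for d in _STAGE_DEPS[name] if status.get(d) != "ok"), None)
        if bad_dep is not None:
            bundle[name] = {"status": "skipped", "reason": f"dependency {bad_dep!r} unavailable",
                            "config_hash": cfg_hash}
            status[name] = "skipped"
            continue
        try:
            result = _STAGE_RUNNERS[name](cfg, seeds.get(name, 0), cohort, analysis, state)
            result["status"] = "ok"
            result["config_hash"] = cfg_hash
            bundle[name] = result
            status[name] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("stage %s failed", name)
            bundle[name] = {"status": "failed", "error": str(exc), "config_hash": cfg_hash}
            status[name] = "failed"
    return bundle


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def _run_screen(cfg, seed, cohort: Cohort, analysis: Cohort, state) -> dict:
    corr = screening_mod.spearman_screen(cohort, cfg["screen"]["variables"])
    curve = screening_mod.fit_loess_with_span_selection(analysis.ages, analysis.mfd)
    bp0 = screening_mod.candidate_breakpoint(curve)
    state["candidate_breakpoint"] = bp0
    return {
        "correlations": corr.table.reset_index().to_dict(orient="records"),
        "loess_span": curve.span_or_k,
        "loess_rmse_by_span": curve.rmse_by_span,
        "candidate_breakpoint": bp0,
    }


def _run_segfit(cfg, seed, cohort, analysis: Cohort, state) -> dict:
    x, y = analysis.ages, analysis.mfd
    fit = segmented_mod.fit_segmented(x, y, psi0=float(cfg["segfit"]["psi0"]))
    ftest = segmented_mod.linear_vs_segmented_test(x, y, fit)
    rmse = segmented_mod.loocv_rmse(x, y, psi0=float(cfg["segfit"]["psi0"]))
    scan = segmented_mod.seed_robustness_scan(x, y)
    state["segmented_fit"] = fit
    state["loocv_rmse"] = rmse
    out = fit.summary_dict()
    out.update(
        {
            "f_test": {"f": ftest.f_stat, "df1": ftest.df1, "df2": ftest.df2, "p": ftest.p_value},
            "loocv_rmse": rmse,
            "seed_scan_max_deviation": scan,
        }
    )
    return out


def _run_bayes(cfg, seed, cohort, analysis: Cohort, state) -> dict:
    x, y = analysis.ages, analysis.mfd
    bc = cfg["bayes"]
    fit = bayes_mod.fit_bayes_segmented(x, y, chains=int(bc["chains"]), draws=int(bc["draws"]), seed=seed)
    lin = bayes_mod.fit_bayes_linear(x, y, chains=int(bc["chains"]), draws=int(bc["draws"]), seed=seed + 1)
    elpd_diff, elpd_se = bayes_mod.loo_compare(fit, lin)
    state["bayes_fit"] = fit
    summary = fit.summary(force=True)
    return {
        "summary": summary.reset_index().to_dict(orient="records"),
        "rhat": fit.rhat,
        "ess": fit.ess,
        "converged": fit.converged,
        "mu_x": fit.mu_x,
        "posterior_mean_breakpoint": float(fit.psi_draws().mean()),
        "elpd_diff_segmented_minus_linear": elpd_diff,
        "elpd_diff_se": elpd_se,
    }


def _run_rope(cfg, seed, cohort, analysis, state) -> dict:
    fit = state["bayes_fit"]
    rc = cfg["rope"]
    res = bayes_mod.rope_analysis(fit, float(rc["halfwidth"]))
    sens = bayes_mod.rope_sensitivity(fit, float(rc["halfwidth"]), float(rc["paired_diff_sd"]),
                                      rc["multipliers"])
    return {
        "halfwidth": res.halfwidth,
        "fraction_inside_pre": res.fraction_inside_pre,
        "fraction_inside_post": res.fraction_inside_post,
        "sensitivity": sens.reset_index().to_dict(orient="records"),
    }


def _run_power(cfg, seed, cohort, analysis: Cohort, state) -> dict:
    pc = cfg["power"]
    bayes_fit = state["bayes_fit"]
    seg_fit = state["segmented_fit"]
    kwargs: dict[str, Any] = {}
    if pc["sigma_mode"] == "fixed":
        kwargs.update(sigma_mode="fixed", sigma_fixed=state["loocv_rmse"])
    table = power_mod.simulate_power(
        analysis.ages,
        bayes_fit.segmented_param_draws(),
        n_grid=pc["n_grid"],
        tolerances=pc["tolerances"],
        reps=int(pc["reps"]),
        seed=seed,
        reference=pc["reference"],
        psi_reference=seg_fit.psi,
        **kwargs,
    )
    return {
        "percent": {str(n): {str(t): float(v) for t, v in row.items()}
                    for n, row in table.percent().iterrows()},
        "reps": table.reps,
        "reference": table.reference,
        "sigma_mode": table.sigma_mode,
        "n_nonconverged": table.n_nonconverged,
    }


def _run_cutoffs(cfg, seed, cohort, analysis: Cohort, state) -> dict:
    seg_fit = state["segmented_fit"]
    # classify against the breakpoint at reporting precision (2 decimals) so
    # membership of a patient sitting exactly on the estimate cannot hinge
    # on sub-0.01-year floating-point noise in the optimiser
    lfit = cutoffs_mod.fit_age_logistic(analysis, round(seg_fit.psi, 2))
    probs = cfg["cutoffs"]["probabilities"]
    thresholds = {str(p): cutoffs_mod.invert_probability(lfit, float(p)) for p in probs}
    hi = max(thresholds.values())
    lo = min(thresholds.values())
    zones = cutoffs_mod.zone_counts(analysis, hi, lo)
    return {
        "breakpoint_age": lfit.breakpoint_age,
        "intercept": lfit.intercept,
        "slope": lfit.slope,
        "separation_flag": lfit.separation_flag,
        "thresholds": thresholds,
        "zone_counts": zones,
    }


def _run_bands(cfg, seed, cohort, analysis: Cohort, state) -> dict:
    bc = cfg["bands"]
    grouped = bands_mod.assign_bands(analysis, tuple(bc["boundaries"]))
    out: dict[str, Any] = {"boundaries": list(grouped.boundaries), "sizes": grouped.sizes(),
                           "variables": {}}
    for var in bc["variables"]:
        res = bands_mod.analyse_variable(grouped, var, bootstrap_reps=int(bc["bootstrap_reps"]),
                                         seed=seed)
        out["variables"][var] = {
            "route": res.route,
            "omnibus_stat": res.omnibus_stat,
            "omnibus_p": res.omnibus_p,
            "pairwise": res.pairwise.to_dict(orient="records"),
            "effects": res.effects.to_dict(orient="records"),
        }
    return out


_STAGE_RUNNERS = {
    "screen": _run_screen,
    "segfit": _run_segfit,
    "bayes": _run_bayes,
    "rope": _run_rope,
    "power": _run_power,
    "cutoffs": _run_cutoffs,
    "bands": _run_bands,
}


def write_bundle(bundle: dict, path: str | Path) -> None:
    """Atomically write the bundle as JSON (tmp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(bundle, fh, indent=2, default=_json_default)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
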