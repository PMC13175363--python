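"""Stage runner: executes analysis stages in dependency order and writes a
self-describing run directory (manifest, CSV/JSON tables, figures).

Stages and their prerequisites within a run:

    simulate    -> (none)          synthetic trial IPD
    reconstruct -> simulate        digitize + pseudo-IPD round trip
    fit         -> reconstruct     five-family refit + selection per curve
    calibrate   -> (none)          linear cost calibration
    base        -> calibrate       base-case totals and ICER
    owsa        -> calibrate       tornado analysis
    psa         -> calibrate       Monte Carlo + CEAC + plots
    scenarios   -> calibrate       horizon / family / price sweeps

Requesting a stage without its prerequisite in the same run raises
:class:`DependencyError`.  All randomness flows from the single run seed
through named substreams, so a manifest (config hash + seed) suffices to
re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import CaseStudyConfig, config_hash
from .km import reconstruct_ipd
from .model import calibrate_case, run_base_case
from .scenarios import distribution_sweep, horizon_sweep, price_sweep, sweep_table
from .sensitivity import (
    ceac,
    crossover_wtp,
    owsa,
    plot_ce_plane,
    plot_ceac,
    plot_tornado,
    run_psa,
)
from .simulate import TrialSimSpec, make_digitized_curve, simulate_trial
from .survival import fit_all_families, fit_report, select_best, write_ipd_csv

__all__ = ["STAGES", "DependencyError", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "reconstruct", "fit", "calibrate", "base", "owsa",
          "psa", "scenarios")
_DEPS = {
    "simulate": (),
    "reconstruct": ("simulate",),
    "fit": ("reconstruct",),
    "calibrate": (),
    "base": ("calibrate",),
    "owsa": ("calibrate",),
    "psa": ("calibrate",),
    "scenarios": ("calibrate",),
}


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream stage in the same run."""


def _substream_seed(seed: int, stage: str) -> int:
    """Named, stable substream per stage from the top-level seed."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: CaseStudyConfig,
    stages: Sequence[str],
    out_dir: str | Path,
    seed: int = 0,
    n_psa: int | None = None,
) -> dict:
    """Execute the requested stages; returns the manifest dictionary."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    requested = [s for s in STAGES if s in set(stages)]  # dependency order
    for s in requested:
        missing = [d for d in _DEPS[s] if d not in requested]
        if missing:
            raise DependencyError(
                f"stage {s!r} requires {missing} in the same run"
            )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case = config.to_case_study()
    manifest: dict = {
        "config_name": config.name,
        "config_hash": config_hash(config),
        "seed": seed,
        "stages": requested,
        "versions": {
            "psmcea": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "started_at": datetime.now(timezone.utc).isoformat(),
        "outputs": {},
    }
    log.info("run: config %s seed %d stages %s", manifest["config_hash"][:12],
             seed, requested)

    artifacts: dict = {}
    for stage in requested:
        if stage in ("simulate", "reconstruct", "fit", "calibrate"):
            artifacts.update(_run_stage(stage, case, out, seed, n_psa, manifest))
        else:
            artifacts.update(
                _run_stage_calibrated(
                    stage, artifacts["calibrated"], out, seed, n_psa, manifest,
                    pseudo_ipd=artifacts.get("pseudo_ipd"),
                )
            )

    manifest["finished_at"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _record(manifest: dict, stage: str, *paths: Path) -> None:
    manifest["outputs"].setdefault(stage, []).extend(p.name for p in paths)


def _run_stage(stage, case, out, seed, n_psa, manifest) -> dict:
    if stage == "simulate":
        sim_spec = TrialSimSpec(
            curves={a: dict(c) for a, c in case.curves.items()},
            seed=_substream_seed(seed, "simulate"),
        )
        ipd = simulate_trial(sim_spec)
        paths = []
        for arm, endpoints in ipd.items():
            for ep, records in endpoints.items():
                p = out / f"ipd_{arm}_{ep}.csv"
                write_ipd_csv(records, p)
                paths.append(p)
        _record(manifest, stage, *paths)
        return {"ipd": ipd}

    if stage == "reconstruct":
        return _stage_reconstruct(case, out, seed, manifest)

    if stage == "fit":
        return _stage_fit(out, manifest)

    if stage == "calibrate":
        calibrated, report = calibrate_case(case)
        p = out / "calibration.json"
        p.write_text(json.dumps(dataclasses.asdict(report), indent=2))
        _record(manifest, stage, p)
        return {"calibrated": calibrated, "calibration_report": report}

    raise RuntimeError(f"unhandled stage {stage!r}")  # pragma: no cover


def _stage_reconstruct(case, out, seed, manifest) -> dict:
    # consumes the simulate outputs written in this run
    rng = np.random.default_rng(_substream_seed(seed, "reconstruct"))
    from .survival import read_ipd_csv

    recon: dict = {}
    paths = []
    for arm in case.arms:
        recon[arm] = {}
        for ep in ("pfs", "os"):
            ipd = read_ipd_csv(out / f"ipd_{arm}_{ep}.csv")
            curve = make_digitized_curve(ipd, n_points=60, jitter=0.005, rng=rng)
            pseudo = reconstruct_ipd(curve)
            p = out / f"pseudo_ipd_{arm}_{ep}.csv"
            write_ipd_csv(pseudo, p)
            paths.append(p)
            recon[arm][ep] = pseudo
    _record(manifest, "reconstruct", *paths)
    return {"pseudo_ipd": recon}


def _stage_fit(out, manifest) -> dict:
    from .survival import read_ipd_csv

    reports = {}
    paths = []
    for p_in in sorted(out.glob("pseudo_ipd_*.csv")):
        label = p_in.stem.removeprefix("pseudo_ipd_")
        ipd = read_ipd_csv(p_in)
        selection = select_best(fit_all_families(ipd))
        reports[label] = fit_report(selection)
        p = out / f"fit_{label}.json"
        p.write_text(json.dumps(reports[label], indent=2))
        paths.append(p)
    _record(manifest, "fit", *paths)
    return {"fits": reports}


# base / owsa / psa / scenarios run on the calibrated case
def _run_stage_calibrated(stage, calibrated, out, seed, n_psa, manifest,
                          pseudo_ipd=None):
    if stage == "base":
        res = run_base_case(calibrated)
        rows = []
        for arm, r in res.arm_results.items():
            for comp, v in r.cost_breakdown.items():
                rows.append({"arm": arm, "component": f"cost_{comp}", "value": v})
            rows.append({"arm": arm, "component": "total_cost", "value": r.total_cost})
            rows.append({"arm": arm, "component": "total_qaly", "value": r.total_qaly})
        rows.append({"arm": "incremental", "component": "cost",
                     "value": res.comparison.incremental_cost})
        rows.append({"arm": "incremental", "component": "qaly",
                     "value": res.comparison.incremental_qaly})
        rows.append({"arm": "incremental", "component": "icer",
                     "value": res.comparison.icer})
        p = out / "base_case.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.2f")
        trace = res.arm_results[calibrated.reference_arm].trace
        p2 = out / "trace.csv"
        pd.DataFrame({
            "time_months": trace.time_months,
            "pfs_share": trace.pfs_share,
            "pd_share": trace.pd_share,
            "death_share": trace.death_share,
            "incident_deaths": trace.incident_deaths,
            "discount": trace.discount,
        }).to_csv(p2, index=False)
        _record(manifest, stage, p, p2)
        return {"base": res}

    if stage == "owsa":
        entries = owsa(calibrated)
        base = run_base_case(calibrated).comparison.icer
        p = out / "tornado.csv"
        pd.DataFrame([
            {"parameter": e.name, "icer_at_low": e.icer_at_low,
             "icer_at_high": e.icer_at_high, "spread": e.spread}
            for e in entries
        ]).to_csv(p, index=False)
        figs = [out / "tornado.png", out / "tornado.svg"]
        for f in figs:
            plot_tornado(entries, base, f)
        _record(manifest, stage, p, *figs)
        return {"owsa": entries}

    if stage == "psa":
        n = n_psa if n_psa is not None else calibrated.psa.n_iterations
        psa_res = run_psa(calibrated, n_iterations=n,
                          seed=_substream_seed(seed, "psa"))
        p = out / "psa_draws.csv"
        psa_res.draws.to_csv(p, index=False)
        grid = np.arange(0.0, calibrated.psa.wtp_grid_max + 1,
                         calibrated.psa.wtp_grid_step)
        curve = ceac(psa_res, grid)
        p2 = out / "ceac.csv"
        pd.DataFrame({
            "wtp": curve.wtp,
            f"p_{calibrated.reference_arm}": curve.p_reference,
            f"p_{calibrated.comparator_arm}": curve.p_comparator,
        }).to_csv(p2, index=False)
        cross = crossover_wtp(curve)
        figs = []
        for ext in ("png", "svg"):
            f1, f2 = out / f"ce_plane.{ext}", out / f"ceac.{ext}"
            plot_ce_plane(psa_res, calibrated.spec.wtp_threshold, f1)
            plot_ceac(curve, (calibrated.reference_arm,
                              calibrated.comparator_arm), f2)
            figs += [f1, f2]
        _record(manifest, stage, p, p2, *figs)
        return {"psa": psa_res, "ceac": curve, "crossover": cross}

    if stage == "scenarios":
        ref, comp = calibrated.reference_arm, calibrated.comparator_arm
        paths = []
        out_art = {}
        sweeps = [
            ("horizon", horizon_sweep(calibrated)),
            ("price", price_sweep(calibrated)),
        ]
        if pseudo_ipd is not None:
            sweeps.append(
                ("family", distribution_sweep(calibrated, ipd_by_curve=pseudo_ipd))
            )
        for name, results in sweeps:
            p = out / f"scenarios_{name}.csv"
            sweep_table(results, ref, comp).to_csv(p, index=False)
            paths.append(p)
            out_art[f"scenarios_{name}"] = results
        _record(manifest, "scenarios", *paths)
        return out_art

    raise RuntimeError(f"unhandled stage {stage!r}")  # pragma: no cover
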