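"""End-to-end orchestration: simulate, segment, fit, reconstruct.

``run_pipeline`` takes a validated configuration and, per construct,
runs the equilibrium (constant-force), ramp, and force-jump stages, then
assembles the free-energy landscape from the fitted rate laws.  All
randomness derives from the configured seed, so re-running a config
reproduces every number; results land as JSON and TSV with a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constructs import ConstructModel, default_construct
from .io import validate_config
from .kinetics import FOLD, UNFOLD, RateEstimate, fit_bell
from .landscape import build_landscape, delta_g0_from_rates
from .polymer import ElasticityParams
from .ramp import analyze_ramp_experiment, collect_ruptures
from .simulate import (ForceProtocol, SimulationConfig, simulate_constant_force,
                       simulate_force_jump, simulate_ramp)
from .trajectory import detect_steps, extract_dwells, hmm_segment, survival_fit

log = logging.getLogger("mtfold")

__all__ = ["run_pipeline", "equilibrium_rates", "jump_rates_and_steps"]


def _bell_to_dict(p, construct, regime, n_events=None, force_window=None):
    return {"construct": construct, "regime": regime, "k0": p.k0, "x": p.x,
            "k0_err": p.k0_err, "x_err": p.x_err, "n_events": n_events,
            "force_window": force_window}


def equilibrium_rates(model: ConstructModel, forces, duration: float,
                      seed: int, sampling_rate: float = 200.0,
                      noise_sigma: float = 6.0):
    """Simulate + analyze constant-force hopping at each force.

    Returns (unfold_rates, fold_rates, dwell_table) where the rates are
    ``RateEstimate`` lists from HMM-decoded dwell survival fits.
    """
    unfold, fold, rows = [], [], []
    for i, f in enumerate(forces):
        cfg = SimulationConfig(
            construct=model,
            protocol=ForceProtocol(kind="constant", constant_force=float(f)),
            duration=duration, seed=seed + i, sampling_rate=sampling_rate,
            noise_sigma=noise_sigma)
        traj = simulate_constant_force(cfg)
        path, _ = hmm_segment(traj)
        dwells = extract_dwells(path, traj.sampling_rate, float(f))
        rows += [{"state": d.state, "duration_s": d.duration,
                  "force_pN": d.force, "censored": d.censored}
                 for d in dwells]
        n_dwells = [d for d in dwells if d.state == "N"]
        u_dwells = [d for d in dwells if d.state == "U"]
        try:
            unfold.append(survival_fit(n_dwells))
        except Exception as exc:
            log.warning("no unfolding rate at %.2f pN: %s", f, exc)
        try:
            fold.append(survival_fit(u_dwells))
        except Exception as exc:
            log.warning("no folding rate at %.2f pN: %s", f, exc)
        log.info("equilibrium %.2f pN: %d dwells", f, len(dwells))
    return unfold, fold, pd.DataFrame(rows)


def jump_rates_and_steps(model: ConstructModel, forces, hold: float,
                         n_traces: int, seed: int,
                         sampling_rate: float = 200.0,
                         noise_sigma: float = 6.0,
                         hold_force: float = 1.0):
    """Force-jump stage: unfolding rates and step sizes at high forces.

    Each trace holds at ``hold_force`` (native state) then jumps to the
    target force; the unfolding time and step size come from change-point
    detection on the post-jump segment.
    """
    rates, steps = [], []
    trace_seed = seed
    for f in forces:
        waits, sizes = [], []
        for _ in range(n_traces):
            cfg = SimulationConfig(
                construct=model,
                protocol=ForceProtocol(kind="jump", jump_schedule=(
                    (hold_force, 2.0), (float(f), hold))),
                seed=trace_seed, sampling_rate=sampling_rate,
                noise_sigma=noise_sigma)
            trace_seed += 1
            traj = simulate_force_jump(cfg)
            for e in detect_steps(traj):
                if e.time > 2.0 and e.size > 0:
                    waits.append(e.time - 2.0)
                    sizes.append(e.size)
                    break
        if len(waits) >= 10:
            w = np.asarray(waits)
            k = len(w) / w.sum()
            rates.append(RateEstimate(force=float(f), rate=float(k),
                                      stderr=float(k / np.sqrt(len(w))),
                                      n_events=len(w)))
        if sizes:
            steps.append({"force_pN": float(f),
                          "step_nm": float(np.mean(sizes)),
                          "step_sd_nm": float(np.std(sizes)),
                          "n": len(sizes)})
        log.info("jump %.1f pN: %d unfolding events", f, len(sizes))
    return rates, steps


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every configured stage and write results under outdir."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    el_over = config.get("elasticity", {})
    analysis = config.get("analysis", {})
    report: dict = {"version": __version__, "seed": seed, "constructs": {}}
    stage = "setup"
    try:
        for entry in config.get("constructs", ["LE-CSP-GS"]):
            cid = entry if isinstance(entry, str) else entry["id"]
            elasticity = ElasticityParams(**el_over) if el_over else None
            model = default_construct(cid, elasticity=elasticity)
            cres: dict = {}
            # ---- equilibrium stage
            eq = config.get("equilibrium")
            unfold_fit = fold_fit = None
            if eq:
                stage = f"{cid}:equilibrium"
                u_rates, f_rates, dwells = equilibrium_rates(
                    model, eq["forces"], eq["duration_s"], seed,
                    sampling_rate=eq.get("sampling_rate", 200.0),
                    noise_sigma=eq.get("noise_sigma", 6.0))
                dwells.to_csv(outdir / f"{cid}_dwells.tsv", sep="\t",
                              index=False)
                if len(u_rates) >= 3:
                    unfold_fit = fit_bell(u_rates,
                                          model.elasticity.thermal_energy)
                if len(f_rates) >= 3:
                    fold_fit = fit_bell(f_rates,
                                        model.elasticity.thermal_energy)
                cres["equilibrium"] = {
                    "unfolding_rates": [asdict(r) for r in u_rates],
                    "folding_rates": [asdict(r) for r in f_rates],
                    "bell_unfold_low": _bell_to_dict(
                        unfold_fit, cid, "low", len(u_rates),
                        [min(eq["forces"]), max(eq["forces"])])
                    if unfold_fit else None,
                    "bell_fold": _bell_to_dict(
                        fold_fit, cid, "folding", len(f_rates),
                        [min(eq["forces"]), max(eq["forces"])])
                    if fold_fit else None,
                }
            # ---- ramp stage
            rp = config.get("ramp")
            if rp:
                stage = f"{cid}:ramp"
                trajs = []
                for i in range(rp["n_traces"]):
                    cfg = SimulationConfig(
                        construct=model,
                        protocol=ForceProtocol(
                            kind="ramp", ramp_start=rp.get("start", 2.0),
                            ramp_end=rp.get("end", 42.0),
                            ramp_rate=rp.get("rate", 1.0),
                            round_trip=rp.get("round_trip", False)),
                        seed=seed + 10_000 + i,
                        sampling_rate=rp.get("sampling_rate", 200.0),
                        noise_sigma=rp.get("noise_sigma", 6.0))
                    trajs.append(simulate_ramp(cfg))
                ruptures = collect_ruptures(
                    trajs, "unfold",
                    threshold_sigma=analysis.get("threshold_sigma", 4.5))
                log.info("%s: n=%d ruptures collected", cid, len(ruptures))
                pd.DataFrame({"force_pN": ruptures.forces}).to_csv(
                    outdir / f"{cid}_ruptures.tsv", sep="\t", index=False)
                fit = analyze_ramp_experiment(
                    ruptures, model.elasticity.thermal_energy,
                    n_bootstrap=analysis.get("n_bootstrap", 50), seed=seed)
                cres["ramp"] = {
                    "n_events": fit.n_events,
                    "most_probable_force_pN": fit.most_probable_force,
                    "bell_ramp": _bell_to_dict(fit.params, cid, "ramp",
                                               fit.n_events),
                }
            # ---- jump stage
            jp = config.get("jump")
            high_fit = None
            if jp:
                stage = f"{cid}:jump"
                rates, steps = jump_rates_and_steps(
                    model, jp["forces"], jp["hold_s"], jp["n_traces"],
                    seed + 20_000,
                    sampling_rate=jp.get("sampling_rate", 200.0),
                    noise_sigma=jp.get("noise_sigma", 6.0),
                    hold_force=analysis.get("hold_force", 1.0))
                if len(rates) >= 3:
                    high_fit = fit_bell(rates,
                                        model.elasticity.thermal_energy)
                cres["jump"] = {
                    "rates": [asdict(r) for r in rates],
                    "step_sizes": steps,
                    "bell_unfold_high": _bell_to_dict(
                        high_fit, cid, "high", len(rates),
                        [min(jp["forces"]), max(jp["forces"])])
                    if high_fit else None,
                }
            # ---- landscape stage
            stage = f"{cid}:landscape"
            fitted = model
            if unfold_fit and fold_fit:
                fits = model.regime_fits
                fitted = model.with_(regime_fits=type(fits)(
                    low_force=unfold_fit.with_(sign=UNFOLD),
                    high_force=(high_fit.with_(sign=UNFOLD)
                                if high_fit else fits.high_force),
                    folding=fold_fit.with_(sign=FOLD),
                    construct_id=cid))
            scape = build_landscape(fitted)
            cres["landscape"] = scape.as_dict()
            report["constructs"][cid] = cres
        stage = "write"
        out = outdir / "report.json"
        out.write_text(json.dumps(report, indent=1, default=float))
        log.info("report written to %s", out)
        return report
    except Exception:
        partial = outdir / "report.partial.json"
        partial.write_text(json.dumps(report, indent=1, default=float))
        log.error("pipeline failed during stage %r; partial results in %s",
                  stage, partial)
        raise
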