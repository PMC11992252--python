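"""End-to-end orchestration: simulate → maps → place cells → transitions →
decoding → population structure, with one config and one seed.

Each stage writes flat CSV tables through :func:`placecode.session.save_results`
so a full run leaves a diffable, manifest-stamped results directory. A failing
session is isolated (logged, skipped); the remaining sessions proceed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import classify_outcome, lick_histogram, relative_performance, spatial_information
from .corridor import CorridorConfig, phase_of_day
from .decoding import empirical_chance, cross_session_decode, fit_session_decoder, \
    decode_frames, decoder_metrics, loo_within_session, _session_true_bins
from .placecells import classify_place_cell, classify_stability, cross_session_stability, \
    detection_context, within_session_stability
from .population import pairwise_correlations, pvc_curve_stats, pvc_matrix, \
    sync_pool_composition
from .session import save_results
from .spatial import bin_activity
from .synthetic import PerturbationSpec, generate_experiment, generate_population
from .transitions import shuffled_delta_p

log = logging.getLogger("placecode.pipeline")

__all__ = ["RunConfig", "run_pipeline", "analyze_experiment"]


@dataclass
class RunConfig:
    """All analysis thresholds in one place, defaults as published.

    Simulation sizes are deliberately desk-scale; bootstrap and shuffle
    counts are scalable (tests and quick runs reduce them, full fidelity
    uses 1000 / 500).
    """

    corridor: CorridorConfig = field(default_factory=CorridorConfig)
    velocity_threshold_cm_s: float = 5.0
    smooth_sigma_cm: float = 5.0
    min_field_width_cm: float = 15.0
    in_out_ratio: float = 6.0
    min_transient_coverage: float = 0.20
    transient_sigmas: float = 3.0
    transient_min_s: float = 0.5
    chunk_frames: int = 50
    n_bootstrap: int = 1000
    alpha_pf: float = 0.05
    decoder_neurons: int = 100
    delta_t_s: float = 0.5
    n_chance_shuffles: int = 500
    sync_percentile: float = 95.0
    outcome_threshold_pct: float = 75.0
    n_transition_shuffles: int = 1000
    # synthetic experiment defaults
    n_neurons: int = 200
    n_trials: int = 20
    timeline: tuple = (-4, -1, 2, 5, 8, 11, 14)
    proportions: tuple = (0.2, 0.2, 0.6)
    perturbation: PerturbationSpec = field(default_factory=lambda: PerturbationSpec(
        onset_day=0, class_turnover_prob=0.3, rate_scale=0.8, stability_scale=0.5))
    stages: tuple = ("behavior", "placecells", "transitions", "decoder", "population")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corridor"] = asdict(self.corridor)
        d["perturbation"] = asdict(self.perturbation)
        return d


def analyze_experiment(experiment, config: RunConfig, seed: int = 0) -> dict:
    """Run every enabled analysis stage on a multi-session experiment.

    Returns a dict of result DataFrames keyed by stage name. The experiment
    can come from :func:`placecode.synthetic.generate_experiment` or be
    assembled from loaded sessions with a registry of tracked neurons.
    """
    rng = np.random.default_rng(seed)
    cc = config.corridor
    days = sorted(experiment.sessions)
    tables: dict[str, pd.DataFrame] = {}
    failed: list[tuple] = []

    # ---- per-session products shared by several stages -------------------
    maps, ctxs = {}, {}
    for day in days:
        try:
            s = experiment.sessions[day]
            maps[day] = bin_activity(s, cc, config.velocity_threshold_cm_s,
                                     config.smooth_sigma_cm)
            ctxs[day] = detection_context(s, cc, config.velocity_threshold_cm_s,
                                          config.smooth_sigma_cm)
        except Exception as e:          # noqa: BLE001 - session isolation contract
            log.warning("session day %s failed in map building: %s", day, e)
            failed.append((day, "maps", str(e)))
    days = [d for d in days if d in maps]

    # ---- behaviour -------------------------------------------------------
    if "behavior" in config.stages:
        t0 = time.time()
        si = {}
        for day in days:
            h = lick_histogram(experiment.sessions[day], cc)
            si[day] = spatial_information(h)
        healthy = [d for d in days if phase_of_day(d) == "healthy"]
        rel = relative_performance(si, healthy) if healthy else {d: np.nan for d in si}
        rows = [{"day": d, "phase": phase_of_day(d), "si_bits": si[d],
                 "relative_pct": rel[d]} for d in days]
        tables["behavior"] = pd.DataFrame(rows)
        phase_mean = tables["behavior"].groupby("phase")["relative_pct"].mean()
        if {"early_post", "late_post"} <= set(phase_mean.index):
            outcome = classify_outcome(phase_mean["early_post"],
                                       phase_mean["late_post"], injected=True)
            tables["behavior"].attrs["outcome_group"] = outcome
        log.info("behavior stage: %d sessions in %.1fs", len(days), time.time() - t0)

    # ---- place cells and stability --------------------------------------
    classes_by_day = {}
    if "placecells" in config.stages or "transitions" in config.stages \
            or "population" in config.stages:
        t0 = time.time()
        pc_rows = []
        is_pc = {}           # day -> bool per neuron
        for day in days:
            s = experiment.sessions[day]
            flags = np.zeros(s.n_neurons, dtype=bool)
            for j in range(s.n_neurons):
                ok, fields, p = classify_place_cell(
                    s.dff[j], ctxs[day], chunk_frames=config.chunk_frames,
                    n_shuffles=config.n_bootstrap,
                    seed=rng.integers(0, 2**31 - 1), alpha=config.alpha_pf)
                flags[j] = ok
                best = max(fields, key=lambda f: f.in_field_mean, default=None)
                pc_rows.append({
                    "day": day, "neuron": j, "is_pc": ok, "p_pf": p,
                    "field_start_bin": best.bin_start if best else -1,
                    "field_end_bin": best.bin_end if best else -1,
                    "within_r": within_session_stability(maps[day].smoothed_per_trial[:, j, :]),
                })
            is_pc[day] = flags
        pc_df = pd.DataFrame(pc_rows)

        # cross-session stability and the median split
        phases = {}
        for d in days:
            phases.setdefault(phase_of_day(d), []).append(d)
        n = experiment.sessions[days[0]].n_neurons
        scores = {ph: np.array([
            cross_session_stability(
                {d: maps[d].smoothed[j] for d in phases[ph]}, phases[ph])
            for j in range(n)]) for ph in phases}
        baseline = (float(np.nanmedian(scores["healthy"]))
                    if "healthy" in scores else np.nan)
        class_rows = []
        for ph, ds in phases.items():
            pc_in_phase = np.zeros(n, dtype=bool)
            for d in ds:
                pc_in_phase |= is_pc[d]
            for j in range(n):
                cls = classify_stability(
                    {ph: scores[ph][j]}, baseline, {ph: bool(pc_in_phase[j])})[ph]
                class_rows.append({"phase": ph, "neuron": j, "class": cls,
                                   "stability_score": scores[ph][j]})
        cls_df = pd.DataFrame(class_rows)
        tables["placecells"] = pc_df
        tables["stability"] = cls_df
        classes_by_phase = cls_df.pivot(index="neuron", columns="phase", values="class")
        for d in days:
            classes_by_day[d] = classes_by_phase[phase_of_day(d)].to_numpy()
        log.info("placecell stage in %.1fs", time.time() - t0)

    # ---- class transitions ----------------------------------------------
    if "transitions" in config.stages and "placecells" in tables:
        t0 = time.time()
        trans = []
        phase_order = [p for p in ("healthy", "early_post", "late_post")
                       if p in classes_by_phase.columns]
        for a, b in zip(phase_order[:-1], phase_order[1:]):
            la = classes_by_phase[a].to_numpy()
            lb = classes_by_phase[b].to_numpy()
            ok = (la != "absent") & (lb != "absent")   # exclude pairwise
            if ok.sum() < 2:
                continue
            stats_ab = shuffled_delta_p(
                la[ok], lb[ok],
                n_shuffles=config.n_transition_shuffles,
                seed=rng.integers(0, 2**31 - 1))
            frame = stats_ab.to_frame()
            frame.insert(0, "epoch", f"{a}->{b}")
            trans.append(frame)
        if trans:
            tables["transitions"] = pd.concat(trans, ignore_index=True)
        log.info("transition stage in %.1fs", time.time() - t0)

    # ---- decoder ---------------------------------------------------------
    if "decoder" in config.stages:
        t0 = time.time()
        rows = []
        for day in days:
            s = experiment.sessions[day]
            try:
                loo = loo_within_session(s, cc, max_neurons=config.decoder_neurons,
                                         delta_t_s=config.delta_t_s)
                rows.append({"day": day, "mode": "within", "accuracy": loo["accuracy"],
                             "sensitivity": loo["sensitivity"]})
            except Exception as e:      # noqa: BLE001
                log.warning("decoder failed on day %s: %s", day, e)
                failed.append((day, "decoder", str(e)))
        healthy = [d for d in days if phase_of_day(d) == "healthy"]
        if healthy:
            train_day = max(healthy)
            for day in days:
                if day == train_day:
                    continue
                m = cross_session_decode(experiment.sessions[train_day],
                                         experiment.sessions[day], cc,
                                         max_neurons=config.decoder_neurons,
                                         delta_t_s=config.delta_t_s)
                rows.append({"day": day, "mode": "cross", "accuracy": m["accuracy"],
                             "sensitivity": m["sensitivity"]})
            # empirical chance of the last healthy session
            s = experiment.sessions[train_day]
            model = fit_session_decoder(s, cc, max_neurons=config.decoder_neurons)
            frames = np.nonzero(s.trial_of_frame() >= 0)[0]
            chance = empirical_chance(
                model, s.dff[:, frames], _session_true_bins(s, cc, frames), cc,
                n_shuffles=config.n_chance_shuffles,
                seed=rng.integers(0, 2**31 - 1),
                frame_rate_hz=s.frame_rate_hz, delta_t_s=config.delta_t_s)
            rows.append({"day": train_day, "mode": "chance",
                         "accuracy": chance["accuracy"],
                         "sensitivity": chance["sensitivity"]})
        tables["decoder"] = pd.DataFrame(rows)
        log.info("decoder stage in %.1fs", time.time() - t0)

    # ---- population structure -------------------------------------------
    if "population" in config.stages:
        t0 = time.time()
        pvc_rows, sync_rows = [], []
        for d1, d2 in zip(days[:-1], days[1:]):
            if abs(d2 - d1) != 3:
                continue
            res = pvc_curve_stats(pvc_matrix(maps[d1].smoothed, maps[d2].smoothed), cc)
            pvc_rows.append({"day_a": d1, "day_b": d2,
                             "y_intercept": res.y_intercept,
                             "initial_slope": res.initial_slope,
                             "max_rpp": max(res.rpp) if res.rpp else np.nan})
        for day in days:
            if day not in classes_by_day:
                continue
            corr = pairwise_correlations(experiment.sessions[day].dff)
            pool = sync_pool_composition(corr, classes_by_day[day],
                                         config.sync_percentile)
            for t, frac in pool["composition"].items():
                sync_rows.append({"day": day, "pair_type": t,
                                  "pool_fraction": frac,
                                  "pool_share": pool["pool_share"][t]})
        if pvc_rows:
            tables["pvc"] = pd.DataFrame(pvc_rows)
        if sync_rows:
            tables["sync_pools"] = pd.DataFrame(sync_rows)
        log.info("population stage in %.1fs", time.time() - t0)

    if failed:
        tables["failures"] = pd.DataFrame(failed, columns=["day", "stage", "error"])
    return tables


def run_pipeline(config: RunConfig, out_dir, seed: int = 0,
                 experiment=None) -> dict:
    """Simulate (unless an experiment is given), analyze, and persist.

    Writes one CSV per stage plus a JSON manifest into ``out_dir`` and
    returns the result tables. Reruns with identical config and seed are
    byte-identical.
    """
    if experiment is None:
        pop = generate_population(config.n_neurons, config.proportions, seed=seed)
        experiment = generate_experiment(
            list(config.timeline), pop, config.perturbation,
            config=config.corridor, n_trials=config.n_trials, seed=seed + 1)
    tables = analyze_experiment(experiment, config, seed=seed + 2)
    save_results(tables, out_dir, config=config.to_dict(), seed=seed)
    return tables
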