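"""Synthetic virtual-corridor experiments with known ground truth.

Generates the statistical structure the downstream analyses assume: an agent
running a 400 cm corridor over repeated trials, licking either uniformly
("naive") or concentrated in/just before reward zones ("expert"); a neuronal
population split into stable place cells (same field every session), unstable
place cells (field centre resampled per session) and non-coding cells; GCaMP-
like ΔF/F traces built from Poisson transient events convolved with a fast-
rise / exponential-decay kernel plus Gaussian noise; and multi-session
timelines with a parameterised stroke-like perturbation (class turnover, rate
scaling, optional recovery).

All randomness flows through one seeded :class:`numpy.random.Generator` per
experiment; per-session substreams are spawned deterministically so adding a
session never perturbs the preceding ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corridor import CorridorConfig, phase_of_day
from .session import CellRegistry, SessionData

__all__ = [
    "GroundTruthPopulation",
    "PerturbationSpec",
    "generate_trajectory",
    "generate_population",
    "generate_dff",
    "generate_experiment",
    "SyntheticExperiment",
]

CLASSES = ("stable_pc", "unstable_pc", "noncoding")


@dataclass
class GroundTruthPopulation:
    """Per-neuron generative parameters and true functional class."""

    classes: np.ndarray            # str per neuron, in CLASSES
    field_center_cm: np.ndarray    # per neuron; resampled per session if unstable
    field_width_cm: np.ndarray     # Gaussian tuning sigma, cm
    peak_rate: np.ndarray          # transient events / s at field centre
    baseline_event_rate: np.ndarray  # events / s anywhere
    noise_sd: np.ndarray           # ΔF/F units

    @property
    def n_neurons(self) -> int:
        return len(self.classes)

    def is_place_coding(self) -> np.ndarray:
        return np.isin(self.classes, ("stable_pc", "unstable_pc"))


@dataclass(frozen=True)
class PerturbationSpec:
    """Stroke-like perturbation applied to sessions after ``onset_day``.

    ``class_turnover_prob`` is the per-neuron probability of switching to a
    uniformly drawn different class at onset; ``rate_scale`` multiplies
    transient rates; ``stability_scale`` < 1 makes formerly stable cells remap
    between sessions with probability ``1 - stability_scale``;
    ``recovery_halflife_days`` relaxes all three effects toward baseline with
    the given half-life (None = chronic deficit).
    """

    onset_day: int = 0
    class_turnover_prob: float = 0.0
    rate_scale: float = 1.0
    stability_scale: float = 1.0
    recovery_halflife_days: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.class_turnover_prob <= 1.0:
            raise ValueError("class_turnover_prob must be in [0, 1]")
        for name in ("rate_scale", "stability_scale"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def generate_trajectory(config: CorridorConfig, n_trials: int, agent: str = "expert",
                        seed=None, mean_speed_cm_s: float = 25.0,
                        rz_slowdown: float = 0.45,
                        licks_per_trial: float = 12.0,
                        inter_trial_blackout_s: float = 1.0):
    """Simulate running, licking and rewards for one session.

    Each trial traverses the corridor start-to-end with lognormal speed
    fluctuations and slowing inside/just before reward zones (where trained
    mice decelerate to lick). Expert agents place ~85% of their licks inside
    an RZ or in the 10 cm of anticipatory approach before it; naive agents
    lick uniformly along the track. Trials are separated by a short blackout
    whose frames carry no valid position and fall outside ``trial_bounds``.

    Returns a dict with keys ``position_cm``, ``velocity_cm_s``,
    ``lick_frames``, ``reward_frames``, ``trial_bounds``.
    """
    if agent not in ("expert", "naive"):
        raise ValueError(f"unknown agent {agent!r}; use 'expert' or 'naive'")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    fr = config.frame_rate_hz
    dt = 1.0 / fr
    blackout = int(round(inter_trial_blackout_s * fr))

    # anticipatory approach window before each RZ entry (cm)
    anticip_cm = 10.0
    approach = [(lo - anticip_cm, lo) for lo, _ in config.rz_edges_cm]

    pos_parts, vel_parts, bounds = [], [], []
    lick_frames, reward_frames = [], []
    cursor = 0
    for _ in range(n_trials):
        # integrate position with speed fluctuations + RZ slowdown
        p, pos, vel = 0.0, [], []
        speed_ou = 0.0
        while p < config.length_cm:
            speed_ou = 0.9 * speed_ou + 0.435 * rng.standard_normal()
            speed = mean_speed_cm_s * np.exp(0.25 * speed_ou)
            near_rz = config.in_reward_zone(p) or any(a <= p < b for a, b in approach)
            if near_rz:
                speed *= rz_slowdown
            speed = max(speed, 6.0)   # keep most frames above the 5 cm/s filter
            pos.append(p)
            vel.append(speed)
            p += speed * dt
        pos = np.array(pos)
        vel = np.array(vel)
        start = cursor
        end = cursor + len(pos)
        bounds.append((start, end))

        # licks: experts concentrate on RZs and their approach, naive agents
        # lick at positions uniform along the track (not per frame, which
        # would inherit the occupancy bias of RZ slowdowns)
        n_licks = rng.poisson(licks_per_trial)
        if n_licks:
            if agent == "expert":
                in_target = config.in_reward_zone(pos) | np.any(
                    [(pos >= a) & (pos < b) for a, b in approach], axis=0)
                weights = np.where(in_target, 1.0, 0.0) + 0.03
                weights = weights / weights.sum()
                lf = np.sort(rng.choice(len(pos), size=n_licks, p=weights))
            else:
                targets = rng.uniform(0, config.length_cm, size=n_licks)
                lf = np.sort(np.searchsorted(pos, targets).clip(0, len(pos) - 1))
            lick_frames.extend(start + lf)

        # one reward at first entry of each RZ
        for lo, hi in config.rz_edges_cm:
            inside = np.nonzero((pos >= lo) & (pos <= hi))[0]
            if inside.size:
                reward_frames.append(start + inside[0])

        pos_parts.append(pos)
        vel_parts.append(vel)
        cursor = end
        # blackout: frozen position at corridor end, zero velocity
        pos_parts.append(np.full(blackout, config.length_cm - 1e-6))
        vel_parts.append(np.zeros(blackout))
        cursor += blackout

    position = np.concatenate(pos_parts)
    velocity = np.concatenate(vel_parts)
    return {
        "position_cm": position,
        "velocity_cm_s": velocity,
        "lick_frames": np.array(sorted(lick_frames), dtype=np.int64),
        "reward_frames": np.array(sorted(reward_frames), dtype=np.int64),
        "trial_bounds": np.array(bounds, dtype=np.int64),
    }


# ---------------------------------------------------------------------------
# population and traces
# ---------------------------------------------------------------------------

def generate_population(n_neurons: int,
                        proportions=(0.2, 0.2, 0.6),
                        seed=None,
                        field_width_cm=(8.0, 14.0),
                        peak_rate=(0.8, 1.6),
                        baseline_event_rate: float = 0.02,
                        noise_sd: float = 0.10,
                        config: CorridorConfig | None = None) -> GroundTruthPopulation:
    """Draw a ground-truth population.

    ``proportions`` are (stable_pc, unstable_pc, noncoding) and must sum to 1.
    Field widths and peak transient rates are drawn uniformly from the given
    ranges; field centres uniformly along the track, kept one width away from
    the walls so fields are not truncated into unrecognisability.
    """
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    config = config or CorridorConfig()
    rng = np.random.default_rng(seed)
    classes = rng.choice(CLASSES, size=n_neurons, p=proportions)
    width = rng.uniform(*field_width_cm, size=n_neurons)
    margin = width
    centers = rng.uniform(margin, config.length_cm - margin)
    return GroundTruthPopulation(
        classes=classes,
        field_center_cm=centers,
        field_width_cm=width,
        peak_rate=rng.uniform(*peak_rate, size=n_neurons),
        baseline_event_rate=np.full(n_neurons, baseline_event_rate),
        noise_sd=np.full(n_neurons, noise_sd),
    )


def _transient_kernel(frame_rate_hz: float, decay_tau_s: float = 0.7,
                      amplitude: float = 1.0) -> np.ndarray:
    """GCaMP6f-like impulse response: 1-frame rise, exponential decay."""
    n = int(np.ceil(5 * decay_tau_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    return amplitude * np.exp(-t / decay_tau_s)


def generate_dff(population: GroundTruthPopulation, trajectory: dict,
                 config: CorridorConfig, seed=None,
                 field_centers_cm: np.ndarray | None = None,
                 rate_scale: float = 1.0,
                 drift_sd: float = 0.0) -> np.ndarray:
    """Render ΔF/F traces for one session.

    Place-coding neurons emit Poisson transient events at rate
    ``peak_rate * exp(-(x - centre)^2 / (2 width^2))`` plus a floor of
    ``baseline_event_rate``; non-coding neurons only at the baseline rate.
    Events are convolved with an exponential-decay kernel (amplitude ~1 ΔF/F,
    tau 0.7 s) and Gaussian noise of ``noise_sd`` is added. Tuning is
    truncated at the corridor walls (linear track, no wraparound). Blackout
    frames between trials carry baseline activity only. ``drift_sd`` > 0 adds
    a slow multiplicative gain drift (lognormal random walk).
    """
    rng = np.random.default_rng(seed)
    pos = trajectory["position_cm"]
    n_frames = len(pos)
    trial_mask = np.zeros(n_frames, dtype=bool)
    for a, b in trajectory["trial_bounds"]:
        trial_mask[a:b] = True
    centers = (population.field_center_cm if field_centers_cm is None
               else field_centers_cm)
    kernel = _transient_kernel(config.frame_rate_hz)
    dt = 1.0 / config.frame_rate_hz

    dff = np.empty((population.n_neurons, n_frames))
    coding = population.is_place_coding()
    for j in range(population.n_neurons):
        rate = np.full(n_frames, population.baseline_event_rate[j])
        if coding[j]:
            tuning = np.exp(-0.5 * ((pos - centers[j]) / population.field_width_cm[j]) ** 2)
            rate = rate + rate_scale * population.peak_rate[j] * tuning * trial_mask
        events = rng.poisson(rate * dt).astype(float)
        trace = np.convolve(events, kernel)[:n_frames]
        if drift_sd > 0:
            gain = np.exp(np.cumsum(rng.normal(0, drift_sd / np.sqrt(n_frames), n_frames)))
            trace = trace * gain
        noise = population.noise_sd[j]
        if noise > 0:
            trace = trace + rng.normal(0, noise, n_frames)
        dff[j] = trace
    return dff


# ---------------------------------------------------------------------------
# multi-session experiments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """Sessions plus ground truth for one simulated mouse."""

    sessions: dict[int, SessionData]          # day -> session
    registry: CellRegistry
    true_classes: pd.DataFrame                # day x neuron true class
    field_centers: pd.DataFrame               # day x neuron centre used
    population: GroundTruthPopulation

    @property
    def days(self) -> list[int]:
        return sorted(self.sessions)


def _perturbation_strength(day: int, spec: PerturbationSpec) -> float:
    """1 at onset, decaying toward 0 with the recovery half-life."""
    if day <= spec.onset_day:
        return 0.0
    if spec.recovery_halflife_days is None:
        return 1.0
    return float(2.0 ** (-(day - spec.onset_day) / spec.recovery_halflife_days))


def generate_experiment(timeline, population: GroundTruthPopulation,
                        perturbation: PerturbationSpec | None = None,
                        config: CorridorConfig | None = None,
                        n_trials: int = 20, seed=None,
                        agent_by_day=None) -> SyntheticExperiment:
    """Simulate a full multi-session experiment for one mouse.

    ``timeline`` is a sorted list of session days relative to the injection
    (e.g. ``[-4, -1, 2, 5, ...]``). After ``perturbation.onset_day`` each
    neuron independently switches functional class with
    ``class_turnover_prob``, transient rates are scaled by ``rate_scale``, and
    stable cells remap between consecutive sessions with probability
    ``1 - stability_scale``; a recovery half-life relaxes all three toward
    baseline. The registry tracks every neuron in every session (identity is
    known exactly in simulation) and records the true class per phase.

    ``agent_by_day`` optionally maps day -> 'expert' | 'naive' (default:
    expert pre-onset, naive while perturbed beyond half strength).
    """
    timeline = list(timeline)
    if timeline != sorted(timeline):
        raise ValueError("timeline must be sorted")
    config = config or CorridorConfig()
    perturbation = perturbation or PerturbationSpec()
    rng = np.random.default_rng(seed)
    if perturbation.onset_day >= max(timeline) and any(
            d > perturbation.onset_day for d in timeline) is False:
        if perturbation.class_turnover_prob or perturbation.rate_scale < 1 \
                or perturbation.stability_scale < 1:
            import warnings
            warnings.warn("perturbation onset is outside the timeline span; inert")

    n = population.n_neurons
    # class turnover decided once, applied after onset
    switch = rng.random(n) < perturbation.class_turnover_prob
    post_classes = population.classes.copy()
    for j in np.nonzero(switch)[0]:
        others = [c for c in CLASSES if c != population.classes[j]]
        post_classes[j] = rng.choice(others)

    sessions, class_rows, center_rows = {}, {}, {}
    current_centers = population.field_center_cm.copy()
    prev_day = None
    for day in timeline:
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        strength = _perturbation_strength(day, perturbation)
        eff_classes = np.where((strength > 0) & switch, post_classes,
                               population.classes)
        rate_scale = 1.0 - strength * (1.0 - perturbation.rate_scale)
        p_remap_stable = strength * (1.0 - perturbation.stability_scale)

        # remap field centres: unstable cells always; stable cells only when
        # the perturbation erodes stability
        if prev_day is not None:
            unstable = eff_classes == "unstable_pc"
            current_centers[unstable] = sub.uniform(
                population.field_width_cm[unstable],
                config.length_cm - population.field_width_cm[unstable])
            stable = eff_classes == "stable_pc"
            remap = stable & (sub.random(n) < p_remap_stable)
            current_centers[remap] = sub.uniform(
                population.field_width_cm[remap],
                config.length_cm - population.field_width_cm[remap])

        if agent_by_day and day in agent_by_day:
            agent = agent_by_day[day]
        else:
            agent = "naive" if strength > 0.5 else "expert"
        traj = generate_trajectory(config, n_trials, agent=agent,
                                   seed=sub.integers(0, 2**31 - 1))
        # non-coding cells keep only baseline events regardless of centre
        session_pop = replace_classes(population, eff_classes)
        dff = generate_dff(session_pop, traj, config,
                           seed=sub.integers(0, 2**31 - 1),
                           field_centers_cm=current_centers,
                           rate_scale=rate_scale)
        sessions[day] = SessionData(
            dff=dff, position_cm=traj["position_cm"],
            velocity_cm_s=traj["velocity_cm_s"],
            lick_frames=traj["lick_frames"],
            reward_frames=traj["reward_frames"],
            trial_bounds=traj["trial_bounds"],
            day=day, frame_rate_hz=config.frame_rate_hz,
        )
        class_rows[day] = eff_classes.copy()
        center_rows[day] = current_centers.copy()
        prev_day = day

    uids = np.arange(n)
    table = pd.DataFrame({d: uids for d in timeline}, index=uids)
    true_classes = pd.DataFrame(class_rows).T      # day x neuron
    # per-phase truth: the class the neuron held for the majority of the
    # phase's sessions (ties -> earlier session's class)
    phases = {}
    for d in timeline:
        phases.setdefault(phase_of_day(d), []).append(d)
    phase_class = {}
    for ph, days in phases.items():
        block = true_classes.loc[days]
        phase_class[ph] = block.apply(
            lambda col: col.value_counts().idxmax(), axis=0)
    registry = CellRegistry(table=table,
                            class_by_phase=pd.DataFrame(phase_class))
    return SyntheticExperiment(
        sessions=sessions, registry=registry, true_classes=true_classes,
        field_centers=pd.DataFrame(center_rows).T, population=population,
    )


def replace_classes(population: GroundTruthPopulation,
                    classes: np.ndarray) -> GroundTruthPopulation:
    """Population with the same tuning parameters but different class labels."""
    return GroundTruthPopulation(
        classes=np.asarray(classes),
        field_center_cm=population.field_center_cm,
        field_width_cm=population.field_width_cm,
        peak_rate=population.peak_rate,
        baseline_event_rate=population.baseline_event_rate,
        noise_sd=population.noise_sd,
    )
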