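"""Synthetic magnetic-tweezers trajectories with known ground truth.

Two-state (folded N / unfolded U) hopping is simulated exactly: constant
force segments use Gillespie alternation of exponential waiting times,
and force ramps use thinning against a piecewise-constant majorant of the
monotone Bell rate laws.  Bead height is the state-dependent polymer
extension plus optional linear drift and per-sample noise (i.i.d.
Gaussian by default, Ornstein-Uhlenbeck optionally).

Every simulation is deterministic given its seed; the ground-truth state
path and transition events are part of the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constructs import ConstructModel
from .polymer import InvalidParameterError, StepSizeTable, step_size

__all__ = [
    "ForceProtocol",
    "SimulationConfig",
    "Trajectory",
    "TransitionEvent",
    "STATE_N",
    "STATE_U",
    "simulate_constant_force",
    "simulate_force_jump",
    "simulate_ramp",
    "ramp_transition_forces",
]

STATE_N = 0
STATE_U = 1
STATE_LABELS = np.array(["N", "U"])

_FORCE_MIN, _FORCE_MAX = 0.1, 60.0


@dataclass(frozen=True)
class ForceProtocol:
    """Force schedule for one trajectory.

    kind="constant": hold ``constant_force`` for the config duration.
    kind="ramp": sweep from ``ramp_start`` to ``ramp_end`` at
        ``ramp_rate`` pN/s (sign must match the sweep direction);
        ``round_trip=True`` appends the reverse sweep.
    kind="jump": play ``jump_schedule``, a sequence of (force pN,
        duration s) holds with instantaneous force changes.
    """

    kind: str
    constant_force: float | None = None
    ramp_start: float | None = None
    ramp_end: float | None = None
    ramp_rate: float | None = None
    round_trip: bool = False
    jump_schedule: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ramp", "jump"):
            raise InvalidParameterError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "constant":
            _check_force(self.constant_force, "constant_force")
        elif self.kind == "ramp":
            _check_force(self.ramp_start, "ramp_start")
            _check_force(self.ramp_end, "ramp_end")
            if self.ramp_rate is None or self.ramp_rate == 0:
                raise InvalidParameterError("ramp_rate must be nonzero")
            if np.sign(self.ramp_end - self.ramp_start) != np.sign(self.ramp_rate):
                raise InvalidParameterError(
                    "ramp_rate sign must match the start->end direction")
        else:
            if not self.jump_schedule:
                raise InvalidParameterError("jump_schedule must be non-empty")
            object.__setattr__(self, "jump_schedule",
                               tuple((float(f), float(d))
                                     for f, d in self.jump_schedule))
            for f, d in self.jump_schedule:
                _check_force(f, "jump hold force")
                if d <= 0:
                    raise InvalidParameterError("hold durations must be > 0")


def _check_force(f, name: str) -> None:
    if f is None:
        raise InvalidParameterError(f"{name} is required")
    if not (_FORCE_MIN <= f <= _FORCE_MAX):
        raise InvalidParameterError(
            f"{name}={f} outside admissible range [{_FORCE_MIN}, {_FORCE_MAX}] pN")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated recording.

    ``seed`` is mandatory; identical configs reproduce byte-identical
    trajectories.  ``force_scale_sigma`` optionally perturbs the true
    force scale of the trace (fractional, e.g. 0.05), emulating the
    calibration uncertainty of the instrument; the recorded force column
    keeps the nominal values.
    """

    construct: ConstructModel
    protocol: ForceProtocol
    seed: int
    sampling_rate: float = 200.0
    noise_sigma: float = 6.0
    baseline_drift: float = 0.0
    duration: float | None = None
    initial_state: int = STATE_N
    force_scale_sigma: float = 0.0
    noise_model: str = "gaussian"
    ou_corner_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")
        if self.protocol.kind == "constant" and (
                self.duration is None or self.duration <= 0):
            raise InvalidParameterError(
                "constant-force protocols need duration > 0")
        if self.initial_state not in (STATE_N, STATE_U):
            raise InvalidParameterError("initial_state must be 0 (N) or 1 (U)")
        if self.noise_model not in ("gaussian", "ou"):
            raise InvalidParameterError("noise_model must be gaussian or ou")


@dataclass(frozen=True)
class TransitionEvent:
    """One ground-truth state change."""

    time: float
    force: float
    from_state: int
    to_state: int

    @property
    def kind(self) -> str:
        return "unfold" if self.to_state == STATE_U else "refold"


@dataclass
class Trajectory:
    """Time-stamped bead-height series with its force protocol."""

    time: np.ndarray
    force: np.ndarray
    height: np.ndarray
    true_state: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    events: list[TransitionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.force) != n or len(self.height) != n:
            raise InvalidParameterError("time/force/height lengths differ")
        if self.true_state is not None and len(self.true_state) != n:
            raise InvalidParameterError("true_state length differs")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise InvalidParameterError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise InvalidParameterError("time spacing must be uniform")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def state_labels(self) -> np.ndarray | None:
        if self.true_state is None:
            return None
        return STATE_LABELS[self.true_state]


# ----------------------------------------------------------------------
# state-path generation


def _gillespie_segments(segments, model: ConstructModel, rng,
                        initial_state: int):
    """Exact two-state alternation over piecewise-constant force segments.

    Returns (events, final_state); event times are absolute from 0.
    """
    events: list[TransitionEvent] = []
    state = initial_state
    t = 0.0
    for force, dur in segments:
        t_end = t + dur
        k_u = model.unfolding_rate(force)
        k_f = model.folding_rate(force)
        while True:
            rate = k_u if state == STATE_N else k_f
            if rate <= 0:
                t = t_end
                break
            wait = rng.exponential(1.0 / rate)
            if t + wait >= t_end:
                t = t_end
                break
            t += wait
            new = STATE_U if state == STATE_N else STATE_N
            events.append(TransitionEvent(t, force, state, new))
            state = new
    return events, state


def _ramp_legs(protocol: ForceProtocol):
    legs = [(protocol.ramp_start, protocol.ramp_end, protocol.ramp_rate)]
    if protocol.round_trip:
        legs.append((protocol.ramp_end, protocol.ramp_start,
                     -protocol.ramp_rate))
    return legs


def _thinning_ramp(legs, model: ConstructModel, rng, initial_state: int):
    """Time-inhomogeneous simulation along force ramps by thinning."""
    events: list[TransitionEvent] = []
    state = initial_state
    t0 = 0.0
    cross = model.regime_crossover
    for f_start, f_end, rate in legs:
        dur = (f_end - f_start) / rate
        t_end = t0 + dur
        t = t0

        def force_at(tt):
            return f_start + rate * (tt - t0)

        lookahead = 2.0 / abs(rate)  # majorant window: 2 pN of ramp
        while t < t_end:
            t_win = min(t + lookahead, t_end)
            f_now, f_win = force_at(t), force_at(t_win)
            # rate laws are monotone per regime branch, so the max over
            # the window is attained at {now, window end, crossover}
            candidates = [f_now, f_win]
            if min(f_now, f_win) < cross < max(f_now, f_win):
                candidates.append(cross)
            if state == STATE_N:
                lam = max(model.unfolding_rate(f) for f in candidates)
            else:
                lam = max(model.folding_rate(f) for f in candidates)
            lam *= 1.0 + 1e-9
            if lam <= 0 or not np.isfinite(lam):
                break
            wait = rng.exponential(1.0 / lam)
            if t + wait >= t_win:
                t = t_win
                continue
            t += wait
            f_now = force_at(t)
            k = (model.unfolding_rate(f_now) if state == STATE_N
                 else model.folding_rate(f_now))
            if rng.uniform() < k / lam:
                new = STATE_U if state == STATE_N else STATE_N
                events.append(TransitionEvent(t, f_now, state, new))
                state = new
        t0 = t_end
    return events, state


def _states_on_grid(times, events, initial_state: int) -> np.ndarray:
    if not events:
        return np.full(len(times), initial_state, dtype=np.int8)
    ev_t = np.array([e.time for e in events])
    n_before = np.searchsorted(ev_t, times, side="right")
    return ((initial_state + n_before) % 2).astype(np.int8)


def _noise(config: SimulationConfig, n: int, rng) -> np.ndarray:
    if config.noise_sigma == 0:
        return np.zeros(n)
    w = rng.normal(0.0, config.noise_sigma, size=n)
    if config.noise_model == "gaussian":
        return w
    dt = 1.0 / config.sampling_rate
    a = np.exp(-2.0 * np.pi * config.ou_corner_hz * dt)
    out = np.empty(n)
    scale = np.sqrt(1.0 - a * a)
    prev = w[0]
    out[0] = prev
    for i in range(1, n):  # short traces only; OU mode is off by default
        prev = a * prev + scale * w[i]
        out[i] = prev
    return out


def _finalize(config: SimulationConfig, times, forces, events, states,
              extensions, rng, protocol_meta) -> Trajectory:
    drift = config.baseline_drift * times
    height = drift + extensions + _noise(config, len(times), rng)
    meta = {
        "construct": config.construct.construct_id,
        "seed": config.seed,
        "sampling_rate": config.sampling_rate,
        "noise_sigma": config.noise_sigma,
        "baseline_drift": config.baseline_drift,
        **protocol_meta,
    }
    return Trajectory(time=times, force=forces, height=height,
                      true_state=states, metadata=meta, events=list(events))


def _force_scale(config: SimulationConfig, rng) -> float:
    if config.force_scale_sigma > 0:
        return 1.0 + config.force_scale_sigma * rng.normal()
    return 1.0


def _simulate_piecewise(config: SimulationConfig, segments,
                        protocol_meta) -> Trajectory:
    rng = np.random.default_rng(config.seed)
    scale = _force_scale(config, rng)
    true_segments = [(f * scale, d) for f, d in segments]
    model = config.construct
    for f, _ in true_segments:
        k_u, k_f = model.unfolding_rate(f), model.folding_rate(f)
        if max(k_u, k_f) > config.sampling_rate / 2.0:
            warnings.warn(
                f"mean dwell at {f:.3g} pN shorter than 2 samples: "
                "undersampled regime", RuntimeWarning, stacklevel=3)
    events, _ = _gillespie_segments(true_segments, model, rng,
                                    config.initial_state)
    total = sum(d for _, d in segments)
    n = int(round(total * config.sampling_rate))
    times = np.arange(n) / config.sampling_rate
    bounds = np.cumsum([d for _, d in segments])
    seg_idx = np.searchsorted(bounds, times, side="right")
    nominal = np.array([f for f, _ in segments])
    forces = nominal[seg_idx]
    states = _states_on_grid(times, events, config.initial_state)
    dx = np.array([step_size(f * scale, model.elasticity) for f, _ in segments])
    extensions = np.where(states == STATE_U, dx[seg_idx], 0.0)
    return _finalize(config, times, forces, events, states, extensions, rng,
                     protocol_meta)


# ----------------------------------------------------------------------
# public entry points


def simulate_constant_force(config: SimulationConfig) -> Trajectory:
    """Equilibrium hopping at one constant force."""
    if config.protocol.kind != "constant":
        raise InvalidParameterError("protocol.kind must be 'constant'")
    f = config.protocol.constant_force
    return _simulate_piecewise(
        config, [(f, config.duration)],
        {"protocol": "constant", "force_pN": f, "duration_s": config.duration})


def simulate_force_jump(config: SimulationConfig) -> Trajectory:
    """Concatenated constant-force holds with instantaneous force jumps;
    the state carries over between holds."""
    if config.protocol.kind != "jump":
        raise InvalidParameterError("protocol.kind must be 'jump'")
    schedule = list(config.protocol.jump_schedule)
    return _simulate_piecewise(
        config, schedule,
        {"protocol": "jump", "schedule": schedule})


def simulate_ramp(config: SimulationConfig) -> Trajectory:
    """Constant-loading-rate sweep (optionally with the return leg).

    The ground-truth transition events, including every rupture/refold
    force, are attached to the returned trajectory.
    """
    if config.protocol.kind != "ramp":
        raise InvalidParameterError("protocol.kind must be 'ramp'")
    rng = np.random.default_rng(config.seed)
    scale = _force_scale(config, rng)
    model = config.construct
    legs = [(f0 * scale, f1 * scale, r * scale)
            for f0, f1, r in _ramp_legs(config.protocol)]
    events, _ = _thinning_ramp(legs, model, rng, config.initial_state)
    total = sum(abs(f1 - f0) / abs(r) for f0, f1, r in legs)
    n = int(round(total * config.sampling_rate))
    times = np.arange(n) / config.sampling_rate
    # nominal force trace
    nom_legs = _ramp_legs(config.protocol)
    forces = np.empty(n)
    t_off = 0.0
    for f0, f1, r in nom_legs:
        dur = (f1 - f0) / r
        mask = (times >= t_off) & (times < t_off + dur + 1e-12)
        forces[mask] = f0 + r * (times[mask] - t_off)
        t_off += dur
    states = _states_on_grid(times, events, config.initial_state)
    table = StepSizeTable(model.elasticity)
    extensions = np.where(states == STATE_U, table(forces * scale), 0.0)
    meta = {"protocol": "ramp",
            "loading_rate_pN_s": config.protocol.ramp_rate,
            "ramp_start_pN": config.protocol.ramp_start,
            "ramp_end_pN": config.protocol.ramp_end,
            "round_trip": config.protocol.round_trip}
    return _finalize(config, times, forces, events, states, extensions, rng,
                     meta)


def ramp_transition_forces(config: SimulationConfig, n_traces: int,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth first-unfolding and first-refolding forces over many
    independent ramp traces (event-level fast path: no height arrays).

    Trace i uses seed ``config.seed + i``.  Refold forces are taken from
    the unloading leg and are NaN for traces without one.
    """
    if config.protocol.kind != "ramp":
        raise InvalidParameterError("protocol.kind must be 'ramp'")
    model = config.construct
    unfold = np.full(n_traces, np.nan)
    refold = np.full(n_traces, np.nan)
    legs = _ramp_legs(config.protocol)
    t_load_end = abs(legs[0][1] - legs[0][0]) / abs(legs[0][2])
    for i in range(n_traces):
        rng = np.random.default_rng(config.seed + i)
        scale = _force_scale(config, rng)
        s_legs = [(f0 * scale, f1 * scale, r * scale) for f0, f1, r in legs]
        events, _ = _thinning_ramp(s_legs, model, rng, config.initial_state)
        for e in events:
            if (e.to_state == STATE_U and e.time <= t_load_end
                    and np.isnan(unfold[i])):
                unfold[i] = e.force / scale
            if (e.to_state == STATE_N and e.time > t_load_end
                    and np.isnan(refold[i])):
                refold[i] = e.force / scale
    return unfold, refold
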