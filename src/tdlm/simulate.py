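"""Synthetic MEG-like and rodent-like data generators.

These generators provide the statistical structure the sequence GLM assumes,
so the whole pipeline is testable without any recorded data:

* task data — per-state ground-truth sensor patterns plus i.i.d. Gaussian
  noise, used to train state decoders;
* rest data — a multivariate AR(1) background with spatially correlated
  innovations (the temporal-smoothness / spatial-correlation confound),
  optionally a background oscillation with per-sensor phase offsets (a
  travelling-wave analogue), and optionally injected state sequences whose
  state-to-state gaps are gamma distributed;
* a linear-track session — place-cell-like Gaussian tuning curves, Poisson
  spiking during running, and burst-like rest events whose latent decoded
  position advances at a controlled replay speed.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "OscillationSpec",
    "SimulationConfig",
    "SimulatedTaskSet",
    "TrackSessionConfig",
    "TrackSession",
    "exponential_sensor_covariance",
    "line_transition_matrix",
    "simulate_task_data",
    "simulate_rest_data",
    "simulate_linear_track_session",
]


def line_transition_matrix(n_states: int) -> np.ndarray:
    """Forward matrix of the line graph s0 -> s1 -> ... -> s{n-1}."""
    T = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        T[i, i + 1] = 1.0
    return T


def exponential_sensor_covariance(n_sensors: int, rho: float = 0.5) -> np.ndarray:
    """Sigma_ij = rho^|i-j|: nearby channels are more correlated."""
    idx = np.arange(n_sensors)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class OscillationSpec:
    """Background rhythm added to the rest data.

    ``phase_offsets`` defaults to a linear 0..2*pi gradient across sensors,
    so different sensors (and hence different decoded states) experience the
    wave at different times.
    """

    frequency: float = 10.0
    amplitude: float = 1.0
    phase_offsets: np.ndarray | None = None

    def phases(self, n_sensors: int) -> np.ndarray:
        if self.phase_offsets is not None:
            p = np.asarray(self.phase_offsets, dtype=float)
            if p.shape != (n_sensors,):
                raise ValueError("phase_offsets must have one entry per sensor")
            return p
        return np.linspace(0.0, 2.0 * np.pi, n_sensors, endpoint=False)


@dataclass
class SimulationConfig:
    """Study conditions for the MEG-like simulations.

    ``pattern_snr`` is the ratio of the per-sensor ground-truth pattern scale
    (unit) to the task-noise standard deviation.  ``lag_gamma`` is the
    (shape, scale) of the state-to-state onset gap distribution in samples;
    the default mean is shape*scale = 4 samples = 40 ms at 100 Hz, with
    shape 10 keeping the draws tight around that mean.
    """

    n_states: int = 8
    n_sensors: int = 64
    pattern_density: float = 0.25  # fraction of sensors carrying each pattern
    pattern_snr: float = 0.5
    ar_coefficient: float = 0.9
    sensor_covariance: np.ndarray | None = None  # default exponential, rho 0.5
    oscillation: OscillationSpec | None = None
    n_injected_sequences: int = 0
    injected_transition_matrix: np.ndarray | None = None  # default line graph
    injection_amplitude: float = 1.0
    lag_gamma: tuple[float, float] = (10.0, 0.4)
    duration: int = 3000  # rest samples (30 s at 100 Hz)
    sample_rate: float = 100.0
    n_task_obs_per_state: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        shape, scale = self.lag_gamma
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")

    def resolved_covariance(self) -> np.ndarray:
        if self.sensor_covariance is None:
            return exponential_sensor_covariance(self.n_sensors)
        S = np.asarray(self.sensor_covariance, dtype=float)
        if S.shape != (self.n_sensors, self.n_sensors):
            raise ValueError("sensor_covariance shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("sensor_covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(S).min()
        if eigmin < -1e-10:
            raise ValueError("sensor_covariance is not positive semi-definite")
        return S

    def resolved_transitions(self) -> np.ndarray:
        if self.injected_transition_matrix is None:
            return line_transition_matrix(self.n_states)
        T = np.asarray(self.injected_transition_matrix, dtype=float)
        if T.shape != (self.n_states, self.n_states):
            raise ValueError("injected_transition_matrix shape mismatch")
        return T

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class SimulatedTaskSet:
    """Labelled stimulus-evoked observations for classifier training."""

    data: np.ndarray  # (b, s)
    labels: np.ndarray  # (b,) state indices 0..n_states-1
    ground_truth_patterns: np.ndarray  # (n_states, s)
    null_data: np.ndarray  # (b_null, s) pure-noise rows


def _covariance_chol(cov: np.ndarray) -> np.ndarray:
    # semi-definite safe factor
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _ground_truth_patterns(config: SimulationConfig, rng) -> np.ndarray:
    """Focal sensor topographies: each state loads on a random subset of
    sensors (evoked fields are spatially localised, not whole-array)."""
    patterns = rng.standard_normal((config.n_states, config.n_sensors))
    if config.pattern_density < 1.0:
        k = max(2, int(round(config.pattern_density * config.n_sensors)))
        for s in range(config.n_states):
            off = rng.choice(config.n_sensors, config.n_sensors - k, replace=False)
            patterns[s, off] = 0.0
        # keep the overall pattern scale comparable across densities
        patterns *= np.sqrt(config.n_sensors / k)
    return patterns


def simulate_task_data(config: SimulationConfig) -> SimulatedTaskSet:
    """Per-state pattern + spatially correlated Gaussian noise.

    The noise shares the rest data's sensor covariance (scaled to unit
    variance per sensor, then by 1/pattern_snr); an equal-sized block of
    pure-noise null rows is returned for null-data mixing during training.
    """
    rng = np.random.default_rng(config.seed)
    patterns = _ground_truth_patterns(config, rng)
    n_obs = config.n_task_obs_per_state
    labels = np.repeat(np.arange(config.n_states), n_obs)
    noise_sd = 0.0 if np.isinf(config.pattern_snr) else 1.0 / config.pattern_snr
    chol = _covariance_chol(config.resolved_covariance())
    noise = rng.standard_normal((2 * labels.size, config.n_sensors)) @ chol.T
    data = patterns[labels] + noise_sd * noise[: labels.size]
    null = noise_sd * noise[labels.size :]
    return SimulatedTaskSet(
        data=data, labels=labels, ground_truth_patterns=patterns, null_data=null
    )


def _traverse(T: np.ndarray, rng: np.random.Generator) -> list[int]:
    """One sequence of states following T; starts at a source state."""
    out_deg = T.sum(axis=1)
    in_deg = T.sum(axis=0)
    starts = np.flatnonzero((out_deg > 0) & (in_deg == 0))
    if starts.size == 0:
        starts = np.flatnonzero(out_deg > 0)
    if starts.size == 0:
        raise ValueError("injected transition matrix has no successor for any state")
    state = int(rng.choice(starts))
    path = [state]
    for _ in range(T.shape[0] - 1):
        row = T[state]
        total = row.sum()
        if total == 0:
            break
        state = int(rng.choice(T.shape[0], p=row / total))
        path.append(state)
    if len(path) < 2:
        raise ValueError(
            f"injected transition matrix row for state {path[0]} is all zeros: "
            "no successor"
        )
    return path


def simulate_rest_data(
    config: SimulationConfig,
) -> tuple[np.ndarray, dict[int, list[int]]]:
    """AR(1) sensor background, optional oscillation, injected sequences.

    Returns the (samples, sensors) rest data and a ground-truth mapping
    state -> list of onset samples for every injected reactivation.
    """
    rng = np.random.default_rng(config.seed + 1)
    cov = config.resolved_covariance()
    chol = _covariance_chol(cov)
    T_dur = config.duration
    innov = rng.standard_normal((T_dur, config.n_sensors)) @ chol.T
    phi = config.ar_coefficient
    if phi > 0:
        R = signal.lfilter([1.0], [1.0, -phi], innov, axis=0)
    else:
        R = innov
    if config.oscillation is not None:
        osc = config.oscillation
        t = np.arange(T_dur) / config.sample_rate
        phases = osc.phases(config.n_sensors)
        R = R + osc.amplitude * np.sin(
            2.0 * np.pi * osc.frequency * t[:, None] + phases[None, :]
        )
    onsets: dict[int, list[int]] = {k: [] for k in range(config.n_states)}
    if config.n_injected_sequences > 0:
        T_mat = config.resolved_transitions()
        rng_pat = np.random.default_rng(config.seed)  # same patterns as task data
        patterns = _ground_truth_patterns(config, rng_pat)
        shape, scale = config.lag_gamma
        mean_gap = shape * scale
        max_len = int(np.ceil(config.n_states * (mean_gap + 4 * np.sqrt(shape) * scale)))
        for _ in range(config.n_injected_sequences):
            path = _traverse(T_mat, rng)
            start = int(rng.integers(0, max(1, T_dur - max_len)))
            t0 = start
            for k, state in enumerate(path):
                if k > 0:
                    gap = max(1, int(round(rng.gamma(shape, scale))))
                    t0 += gap
                if t0 >= T_dur:
                    break
                R[t0] += config.injection_amplitude * patterns[state]
                onsets[state].append(t0)
    return R, onsets


# ---------------------------------------------------------------------------
# Linear-track rodent-like session
# ---------------------------------------------------------------------------


@dataclass
class TrackSessionConfig:
    """Desk-scale linear-track session with burst-like replay events."""

    track_length: float = 600.0  # cm
    n_cells: int = 60
    n_events: int = 60
    replay_speed: float = 5.0  # m/s, negative for backward
    event_duration: float = 0.1  # s
    run_duration: float = 240.0  # s
    rest_duration: float = 120.0  # s
    run_speed: float = 20.0  # cm/s
    peak_rate: float = 20.0  # Hz at field centre during running
    field_sigma: float = 10.0  # cm
    burst_gain: float = 5.0  # rate multiplier inside events
    background_rate: float = 0.5  # Hz per cell during quiet rest
    pos_dt: float = 0.02  # position sampling (50 Hz)
    spike_dt: float = 0.001  # spike-train resolution (1 ms)
    noise: float = 1.0  # 1 = Poisson spiking; 0 = deterministic expected counts
    seed: int = 0


@dataclass
class TrackSession:
    """Positions, spikes and ground-truth replay events of one session."""

    position_t: np.ndarray  # (n_pos,) s, running phase
    position_x: np.ndarray  # (n_pos,) cm
    speed: np.ndarray  # (n_pos,) cm/s
    spike_cells: np.ndarray  # (n_spikes,) cell index (whole session)
    spike_times: np.ndarray  # (n_spikes,) s
    tuning_centers: np.ndarray  # (n_cells,) cm
    events: list[dict]  # start/end (s), direction, start_x
    run_end: float  # boundary between running and rest phases (s)
    config: TrackSessionConfig

    def spikes_by_cell(self) -> list[np.ndarray]:
        return [
            self.spike_times[self.spike_cells == c]
            for c in range(self.config.n_cells)
        ]

    def rest_spikes(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.spike_times >= self.run_end
        return self.spike_cells[m], self.spike_times[m]


def _tuning(x: np.ndarray, centers: np.ndarray, cfg: TrackSessionConfig) -> np.ndarray:
    """Rates (..., n_cells) at positions x (cm)."""
    d = np.asarray(x)[..., None] - centers
    return cfg.peak_rate * np.exp(-0.5 * (d / cfg.field_sigma) ** 2)


def _emit(rates_dt: np.ndarray, rng: np.random.Generator, noise: float) -> np.ndarray:
    """Spike counts from expected counts; deterministic when noise == 0."""
    if noise == 0:
        return rates_dt
    return rng.poisson(rates_dt * noise) / 1.0


def simulate_linear_track_session(
    config: TrackSessionConfig | None = None, **overrides
) -> TrackSession:
    """Gaussian tuning curves tiling the track; running then rest with bursts.

    Replay events advance a latent decoded position at ``replay_speed``
    (forward when positive, backward when negative).  A traversal that would
    exceed the track is truncated at the end of the track.
    """
    import warnings

    cfg = config or TrackSessionConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    if cfg.replay_speed == 0:
        raise ValueError("replay_speed must be non-zero")
    if cfg.n_cells < 10:
        raise ValueError("need at least 10 cells to tile the track")
    rng = np.random.default_rng(cfg.seed)
    centers = np.linspace(0.0, cfg.track_length, cfg.n_cells)

    # -- running phase: back and forth at run_speed
    t_pos = np.arange(0.0, cfg.run_duration, cfg.pos_dt)
    period = 2.0 * cfg.track_length / cfg.run_speed
    phase = (t_pos % period) / period
    x = np.where(
        phase < 0.5,
        2.0 * phase * cfg.track_length,
        2.0 * (1.0 - phase) * cfg.track_length,
    )
    v = np.gradient(x, t_pos)
    speed = np.abs(v)

    cells: list[np.ndarray] = []
    times: list[np.ndarray] = []
    rates = _tuning(x, centers, cfg)  # (n_pos, n_cells)
    counts = _emit(rates * cfg.pos_dt, rng, cfg.noise)
    if cfg.noise == 0:
        counts = np.round(counts * 0)  # no running spikes needed in noiseless mode
    nz_t, nz_c = np.nonzero(counts)
    for ti, ci in zip(nz_t, nz_c):
        k = int(counts[ti, ci])
        if k > 0:
            cells.append(np.full(k, ci))
            times.append(
                t_pos[ti] + rng.uniform(0.0, cfg.pos_dt, size=k)
                if cfg.noise > 0
                else np.full(k, t_pos[ti])
            )

    # -- rest phase: background + burst events
    run_end = cfg.run_duration
    rest_t0 = run_end
    n_bg_bins = int(round(cfg.rest_duration / cfg.spike_dt))
    if cfg.noise > 0 and cfg.background_rate > 0:
        bg_counts = rng.poisson(
            cfg.background_rate * cfg.spike_dt, size=(n_bg_bins, cfg.n_cells)
        )
        nz_t, nz_c = np.nonzero(bg_counts)
        for ti, ci in zip(nz_t, nz_c):
            k = int(bg_counts[ti, ci])
            cells.append(np.full(k, ci))
            times.append(rest_t0 + ti * cfg.spike_dt + rng.uniform(0, cfg.spike_dt, k))

    events: list[dict] = []
    if cfg.n_events > 0:
        gap = cfg.rest_duration / (cfg.n_events + 1)
        if gap <= cfg.event_duration:
            raise ValueError("rest_duration too short for the requested events")
        starts = rest_t0 + gap * np.arange(1, cfg.n_events + 1)
        starts = starts + rng.uniform(-0.25 * gap, 0.25 * gap, size=cfg.n_events)
        speed_cm = cfg.replay_speed * 100.0  # m/s -> cm/s
        span = abs(speed_cm) * cfg.event_duration
        for s0 in starts:
            if speed_cm > 0:
                x0 = rng.uniform(0.0, max(1e-9, cfg.track_length - span))
            else:
                x0 = rng.uniform(min(span, cfg.track_length), cfg.track_length)
            n_bins = int(round(cfg.event_duration / cfg.spike_dt))
            tt = np.arange(n_bins) * cfg.spike_dt
            xx = x0 + speed_cm * tt
            if xx.max() > cfg.track_length or xx.min() < 0:
                warnings.warn("replay traversal exceeds track length; truncated")
                keep = (xx >= 0) & (xx <= cfg.track_length)
                tt, xx = tt[keep], xx[keep]
            ev_rates = _tuning(xx, centers, cfg) * cfg.burst_gain
            ev_counts = _emit(ev_rates * cfg.spike_dt, rng, cfg.noise)
            if cfg.noise == 0:
                # deterministic: emit expected counts as unit spikes at bin centres
                ev_counts = np.where(ev_counts > 0.5 * ev_counts.max(), 1.0, 0.0)
            nz_t, nz_c = np.nonzero(ev_counts)
            for ti, ci in zip(nz_t, nz_c):
                k = int(ev_counts[ti, ci])
                cells.append(np.full(k, ci))
                if cfg.noise > 0:
                    times.append(s0 + tt[ti] + rng.uniform(0, cfg.spike_dt, k))
                else:
                    times.append(np.full(k, s0 + tt[ti]))
            events.append(
                {
                    "start": float(s0),
                    "end": float(s0 + (tt[-1] if tt.size else 0.0) + cfg.spike_dt),
                    "direction": "forward" if speed_cm > 0 else "backward",
                    "start_x": float(x0),
                    "speed_mps": cfg.replay_speed,
                }
            )

    if cells:
        cell_arr = np.concatenate(cells).astype(int)
        time_arr = np.concatenate(times)
        order = np.argsort(time_arr, kind="stable")
        cell_arr, time_arr = cell_arr[order], time_arr[order]
    else:
        cell_arr = np.empty(0, dtype=int)
        time_arr = np.empty(0)
    return TrackSession(
        position_t=t_pos,
        position_x=x,
        speed=speed,
        spike_cells=cell_arr,
        spike_times=time_arr,
        tuning_centers=centers,
        events=events,
        run_end=run_end,
        config=cfg,
    )
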