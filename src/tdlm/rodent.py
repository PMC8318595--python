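"""Spiking-data front-end: rate maps, candidate events, posterior decoding.

The path from spikes to a decoded state space:

1. linearised rate maps per cell and running direction (2 cm bins, Gaussian
   smoothing sigma = 5 bins, samples slower than 3 cm/s and masked track
   zones excluded; smoothing is applied identically to the spike-count
   numerator and the dwell-time denominator, so total spike mass is
   conserved);
2. place-cell selection (peak rate above 1 Hz, half-peak field width of at
   least 20 cm);
3. candidate replay events from multi-unit activity (1 ms bins, Gaussian
   sigma = 10 ms), spans exceeding mean + 3 SD extended to the mean
   crossing, then filtered to >= 40 ms duration and >= 15% ensemble
   participation;
4. per-event Poisson posterior decoding with a uniform prior
   (posterior(k) ∝ prod_c rate_c(k)^{n_c} * exp(-tau * sum_c rate_c(k)),
   rates floored at 0.01 Hz), giving a posterior-mode StateSpace with one
   segment per event; events are concatenated for the sequence GLM so that
   no lagged pair crosses an event boundary.

Two single-event line-search baselines are included for comparison: the
discrete Radon best-line integral and the posterior-weighted time-position
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import logsumexp

from .core import StateSpace

__all__ = [
    "RateMap",
    "CandidateEvent",
    "RateMapConfig",
    "EventConfig",
    "compute_rate_maps",
    "classify_place_cells",
    "detect_candidate_events",
    "decode_posterior",
    "concatenate_events",
    "radon_score",
    "weighted_correlation",
]

RATE_FLOOR_HZ = 0.01


@dataclass
class RateMapConfig:
    bin_width: float = 2.0  # cm
    smoothing_sigma: float = 5.0  # bins
    speed_threshold: float = 3.0  # cm/s
    masked_zones: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class RateMap:
    """Linearised firing-rate map of one cell in one running direction.

    Bins excluded by the behaviour mask carry NaN, not zero.
    """

    rates: np.ndarray  # (n_bins,) Hz, NaN where masked
    bin_width: float
    direction: str  # "outbound" | "inbound"
    cell: int = -1

    @property
    def n_bins(self) -> int:
        return self.rates.size

    @property
    def peak_rate(self) -> float:
        valid = self.rates[np.isfinite(self.rates)]
        return float(valid.max()) if valid.size else 0.0

    @property
    def field_width(self) -> float:
        """Contiguous span (cm) around the peak where rate >= half the peak."""
        r = self.rates
        finite = np.isfinite(r)
        if not finite.any() or self.peak_rate == 0:
            return 0.0
        peak_idx = int(np.nanargmax(r))
        half = 0.5 * self.peak_rate
        lo = peak_idx
        while lo - 1 >= 0 and finite[lo - 1] and r[lo - 1] >= half:
            lo -= 1
        hi = peak_idx
        while hi + 1 < r.size and finite[hi + 1] and r[hi + 1] >= half:
            hi += 1
        return float((hi - lo + 1) * self.bin_width)


@dataclass
class CandidateEvent:
    """A putative replay burst in the multi-unit activity."""

    start: float  # s
    end: float  # s
    participation: float  # fraction of ensemble spiking in the event
    posterior: StateSpace | None = None

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1e3


def _bin_positions(x: np.ndarray, track_length: float, bin_width: float) -> int:
    return int(np.ceil(track_length / bin_width))


def compute_rate_maps(
    spike_cells: np.ndarray,
    spike_times: np.ndarray,
    position_t: np.ndarray,
    position_x: np.ndarray,
    speed: np.ndarray,
    n_cells: int,
    track_length: float,
    config: RateMapConfig | None = None,
) -> dict[str, list[RateMap]]:
    """Smoothed occupancy-normalised rate maps per cell and direction.

    Rate = smooth(spike counts) / smooth(dwell time), both binned at
    ``bin_width`` cm.  Outbound is defined as motion toward increasing
    linearised position.  Samples below the speed threshold and samples in
    masked zones contribute neither spikes nor dwell; fully masked bins are
    NaN in the output.
    """
    cfg = config or RateMapConfig()
    position_t = np.asarray(position_t, dtype=float)
    position_x = np.asarray(position_x, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if position_x.min() < 0 or position_x.max() > track_length:
        raise ValueError("positions must lie within [0, track_length]")
    n_bins = _bin_positions(position_x, track_length, cfg.bin_width)
    dt = np.median(np.diff(position_t)) if position_t.size > 1 else 0.0
    velocity = np.gradient(position_x, position_t) if position_t.size > 1 else speed

    # per-sample inclusion and direction
    include = speed >= cfg.speed_threshold
    for lo, hi in cfg.masked_zones:
        include &= ~((position_x >= lo) & (position_x <= hi))
    outbound = velocity > 0

    spike_cells = np.asarray(spike_cells, dtype=int)
    spike_times = np.asarray(spike_times, dtype=float)
    in_range = (spike_times >= position_t[0]) & (spike_times <= position_t[-1])
    s_cells, s_times = spike_cells[in_range], spike_times[in_range]
    sample_of_spike = np.searchsorted(position_t, s_times).clip(0, position_t.size - 1)
    spike_x = position_x[sample_of_spike]
    spike_ok = include[sample_of_spike]
    spike_out = outbound[sample_of_spike]

    maps: dict[str, list[RateMap]] = {}
    for direction, dmask_samples, dmask_spikes in (
        ("outbound", outbound, spike_out),
        ("inbound", ~outbound, ~spike_out),
    ):
        sel = include & dmask_samples
        dwell = np.histogram(
            position_x[sel], bins=n_bins, range=(0, n_bins * cfg.bin_width)
        )[0].astype(float) * dt
        if dwell.sum() == 0:
            raise ValueError(f"zero dwell time everywhere for {direction} running")
        dwell_s = gaussian_filter1d(dwell, cfg.smoothing_sigma, mode="constant")
        visited = dwell > 0
        dir_maps = []
        for c in range(n_cells):
            m = spike_ok & dmask_spikes & (s_cells == c)
            counts = np.histogram(
                spike_x[m], bins=n_bins, range=(0, n_bins * cfg.bin_width)
            )[0].astype(float)
            counts_s = gaussian_filter1d(counts, cfg.smoothing_sigma, mode="constant")
            with np.errstate(invalid="ignore", divide="ignore"):
                rates = np.where(dwell_s > 0, counts_s / dwell_s, np.nan)
            rates[~np.isfinite(rates)] = np.nan
            # bins with no (unmasked, fast-enough) occupancy are undefined,
            # not zero — this is what marks the masked track zones
            rates[~visited] = np.nan
            dir_maps.append(
                RateMap(rates=rates, bin_width=cfg.bin_width, direction=direction, cell=c)
            )
        maps[direction] = dir_maps
    return maps


def classify_place_cells(
    maps: dict[str, list[RateMap]] | list[RateMap],
    min_peak_rate: float = 1.0,
    min_field_width: float = 20.0,
) -> np.ndarray:
    """Boolean per cell: peak above 1 Hz AND half-peak width >= 20 cm.

    With directional maps a cell qualifies if it passes in either direction.
    """
    if isinstance(maps, dict):
        groups = list(maps.values())
    else:
        groups = [maps]
    n_cells = len(groups[0])
    ok = np.zeros(n_cells, dtype=bool)
    for dir_maps in groups:
        for c, m in enumerate(dir_maps):
            if m.peak_rate > min_peak_rate and m.field_width >= min_field_width:
                ok[c] = True
    return ok


@dataclass
class EventConfig:
    mua_bin: float = 0.001  # s
    mua_sigma: float = 0.010  # s, Gaussian smoothing of the MUA trace
    threshold_sd: float = 3.0
    min_duration: float = 0.040  # s
    min_participation: float = 0.15


def detect_candidate_events(
    spike_cells: np.ndarray,
    spike_times: np.ndarray,
    n_cells: int,
    t_start: float,
    t_end: float,
    config: EventConfig | None = None,
) -> list[CandidateEvent]:
    """Bursts of multi-unit place-cell activity during rest.

    The summed spike train is binned at 1 ms, Gaussian smoothed (sigma
    10 ms); spans above mean + 3 SD are extended outward to where the trace
    falls back to the mean, merged if they touch, and filtered by the 40 ms
    duration and 15% participation rules.
    """
    cfg = config or EventConfig()
    spike_cells = np.asarray(spike_cells, dtype=int)
    spike_times = np.asarray(spike_times, dtype=float)
    m = (spike_times >= t_start) & (spike_times < t_end)
    if not m.any():
        return []
    cells, times = spike_cells[m], spike_times[m]
    n_bins = int(np.ceil((t_end - t_start) / cfg.mua_bin))
    mua = np.histogram(times, bins=n_bins, range=(t_start, t_start + n_bins * cfg.mua_bin))[0]
    smooth = gaussian_filter1d(mua.astype(float), cfg.mua_sigma / cfg.mua_bin)
    mu, sd = smooth.mean(), smooth.std()
    if sd == 0:
        return []
    hi = smooth > mu + cfg.threshold_sd * sd
    if not hi.any():
        return []
    # contiguous spans above threshold; the duration rule applies to this
    # core (a chance 3 SD excursion of smoothed Poisson noise rarely lasts
    # 40 ms), then the event boundaries extend to the mean crossing
    above_mean = smooth > mu
    starts = list(np.flatnonzero(np.diff(np.concatenate(([0], hi.astype(int)))) == 1))
    stops = list(np.flatnonzero(np.diff(np.concatenate((hi.astype(int), [0]))) == -1))
    spans = []
    for a, b in zip(starts, stops):
        if (b - a + 1) * cfg.mua_bin < cfg.min_duration:
            continue
        while a - 1 >= 0 and above_mean[a - 1]:
            a -= 1
        while b + 1 < n_bins and above_mean[b + 1]:
            b += 1
        spans.append((a, b))
    # merge overlapping extended spans
    merged = []
    for a, b in spans:
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    events = []
    for a, b in merged:
        s = t_start + a * cfg.mua_bin
        e = t_start + (b + 1) * cfg.mua_bin
        inside = (times >= s) & (times < e)
        participation = np.unique(cells[inside]).size / n_cells
        if participation < cfg.min_participation:
            continue
        events.append(CandidateEvent(start=s, end=e, participation=participation))
    return events


def _rate_matrix(maps: list[RateMap]) -> np.ndarray:
    """(n_cells, n_bins) with NaN-masked bins; error if nothing is valid."""
    R = np.stack([m.rates for m in maps])
    if not np.isfinite(R).any(axis=0).any():
        raise ValueError("all rate-map bins are missing")
    return R


def decode_posterior(
    event_cells: np.ndarray,
    event_times: np.ndarray,
    maps: list[RateMap],
    t_start: float,
    t_end: float,
    decode_bin: float = 0.010,
) -> StateSpace:
    """Poisson posterior over position bins, uniform prior, per decode bin.

    log P(k | n) = sum_c n_c log(rate_c(k)) - tau * sum_c rate_c(k) + const;
    rates are floored at 0.01 Hz so silent cells never zero out a state.
    Position bins masked in *any* cell's map are excluded from the state set.
    """
    R = _rate_matrix(maps)
    valid_bins = np.all(np.isfinite(R), axis=0)
    if not valid_bins.any():
        raise ValueError("no position bin is valid across all cells")
    R = np.clip(R[:, valid_bins], RATE_FLOOR_HZ, None)  # (n_cells, n_states)
    n_cells, n_states = R.shape
    n_t = max(1, int(np.ceil((t_end - t_start) / decode_bin)))
    counts = np.zeros((n_t, n_cells))
    cells = np.asarray(event_cells, dtype=int)
    times = np.asarray(event_times, dtype=float)
    inside = (times >= t_start) & (times < t_start + n_t * decode_bin)
    bin_idx = ((times[inside] - t_start) / decode_bin).astype(int)
    np.add.at(counts, (bin_idx, cells[inside]), 1.0)
    logR = np.log(R)
    loglik = counts @ logR - decode_bin * R.sum(axis=0)  # (n_t, n_states)
    post = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    return StateSpace(
        values=post,
        sample_interval=decode_bin,
        state_labels=[f"pos{b}" for b in np.flatnonzero(valid_bins)],
        mode="posterior",
    )


def concatenate_events(posteriors: list[StateSpace]) -> StateSpace:
    """Stack per-event posteriors; segment ids mark event boundaries."""
    if not posteriors:
        raise ValueError("no events to concatenate")
    k = posteriors[0].n_states
    interval = posteriors[0].sample_interval
    values, seg = [], []
    for e, p in enumerate(posteriors):
        if p.n_states != k:
            raise ValueError("events must share a state set")
        values.append(p.values)
        seg.append(np.full(p.n_samples, e))
    return StateSpace(
        values=np.vstack(values),
        sample_interval=interval,
        state_labels=posteriors[0].state_labels,
        segment_ids=np.concatenate(seg),
        mode="posterior",
    )


def radon_score(
    posterior: np.ndarray,
    n_slopes: int = 61,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[tuple[float, float], float, float]:
    """Discrete Radon line search over a single event's posterior.

    ``posterior`` is (n_time, n_positions).  Lines are position =
    slope * t + intercept over a slope grid spanning +/- the full posterior
    height per event; the score of a line is the mean posterior mass at the
    nearest position bin along it (bins off the matrix score 0).  Ties prefer
    the steepest line (vertical-most convention).  The permutation null
    shuffles position bins.  Returns ((slope, intercept), score, p).
    """
    P = np.asarray(posterior, dtype=float)
    n_t, n_pos = P.shape
    t_idx = np.arange(n_t)
    max_slope = float(n_pos) if n_t == 1 else n_pos / 1.0
    slopes = np.linspace(-max_slope, max_slope, n_slopes)
    intercepts = np.arange(n_pos, dtype=float)

    def best(Pm: np.ndarray) -> tuple[float, float, float]:
        best_val, best_line = -np.inf, (0.0, 0.0)
        for s in slopes:
            pos = np.rint(s * t_idx[None, :] + intercepts[:, None]).astype(int)
            ok = (pos >= 0) & (pos < n_pos)
            vals = np.where(ok, Pm[t_idx[None, :], pos.clip(0, n_pos - 1)], 0.0)
            scores = vals.mean(axis=1)
            k = int(np.argmax(scores))
            v = scores[k]
            if v > best_val + 1e-15 or (
                abs(v - best_val) <= 1e-15 and abs(s) > abs(best_line[0])
            ):
                best_val, best_line = v, (float(s), float(intercepts[k]))
        return best_line[0], best_line[1], float(best_val)

    s0, i0, score = best(P)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = best(P[:, rng.permutation(n_pos)])[2]
    p = float((1 + np.sum(null >= score)) / (1 + n_perm))
    return (s0, i0), score, p


def weighted_correlation(posterior: np.ndarray) -> float:
    """Posterior-weighted Pearson correlation between time and position."""
    P = np.asarray(posterior, dtype=float)
    n_t, n_pos = P.shape
    w = P / P.sum()
    t = np.arange(n_t, dtype=float)[:, None]
    x = np.arange(n_pos, dtype=float)[None, :]
    mt = (w * t).sum()
    mx = (w * x).sum()
    cov = (w * (t - mt) * (x - mx)).sum()
    vt = (w * (t - mt) ** 2).sum()
    vx = (w * (x - mx) ** 2).sum()
    if vt == 0 or vx == 0:
        return 0.0
    return float(cov / np.sqrt(vt * vx))
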