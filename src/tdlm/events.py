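"""Sequence-event projection and replay-onset detection.

Given a decoded state space X and a hypothesis matrix T with lag dt, the
sequence-event space has one column per directed edge (i -> j) of T:

    column(i -> j)[t] = X[t - dt, i] * X[t, j]

i.e. the joint evidence that state i was active dt ago and its successor j is
active now.  Summing over edge columns gives a per-sample replay score;
summing only the edges that share a successor j reproduces the equivalent
matrix form X(t) .* (X(t - dt) @ T) exactly.  Onsets are samples where the
score first exceeds a percentile threshold after a quiet window, and are used
to epoch independent data for replay-triggered averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StateSpace, TransitionTemplate

__all__ = [
    "SequenceEventSpace",
    "project_sequence_events",
    "sequence_event_matrix_form",
    "detect_replay_onsets",
    "epoch_around",
]


@dataclass
class SequenceEventSpace:
    """Per-edge sequence-completion evidence over time.

    The first ``lag`` samples of every segment are undefined and carry NaN.
    """

    values: np.ndarray  # (samples, n_edges)
    edges: list[tuple[int, int]]
    lag: int
    sample_interval: float

    @property
    def summed_score(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def valid(self) -> np.ndarray:
        return np.all(np.isfinite(self.values), axis=1)


def project_sequence_events(
    space: StateSpace, T: TransitionTemplate | np.ndarray, lag: int
) -> SequenceEventSpace:
    """One column per directed edge of T; masked for the first lag samples."""
    Tm = T.matrix if isinstance(T, TransitionTemplate) else np.asarray(T, float)
    lag = int(lag)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    edges = list(zip(*(np.nonzero(Tm))))
    edges = [(int(i), int(j)) for i, j in edges]
    if not edges:
        raise ValueError("transition matrix has no edges")
    X = space.values
    n = space.n_samples
    out = np.full((n, len(edges)), np.nan)
    for seg in space.segment_slices():
        a, b = seg.start, seg.stop
        if b - a <= lag:
            continue
        for k, (i, j) in enumerate(edges):
            out[a + lag : b, k] = X[a : b - lag, i] * X[a + lag : b, j]
    return SequenceEventSpace(
        values=out, edges=edges, lag=lag, sample_interval=space.sample_interval
    )


def sequence_event_matrix_form(
    space: StateSpace, T: TransitionTemplate | np.ndarray, lag: int
) -> np.ndarray:
    """Matrix form X(t) .* (X(t - dt) @ T): per-successor grouped columns.

    Column j equals the sum of the per-edge columns of
    :func:`project_sequence_events` whose successor is j (unit-test identity).
    """
    Tm = T.matrix if isinstance(T, TransitionTemplate) else np.asarray(T, float)
    X = space.values
    out = np.full_like(X, np.nan)
    for seg in space.segment_slices():
        a, b = seg.start, seg.stop
        if b - a <= lag:
            continue
        out[a + lag : b] = X[a + lag : b] * (X[a : b - lag] @ Tm)
    return out


def detect_replay_onsets(
    summed_score: np.ndarray,
    percentile: float = 95.0,
    quiet_window: int = 10,
) -> np.ndarray:
    """Samples where the replay score crosses its percentile threshold after
    being at or below it for the entire preceding quiet window.

    The threshold percentile is computed over the valid (finite) samples
    only.  Samples too early to have a full, fully valid quiet window are
    never onsets.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    if quiet_window < 1:
        raise ValueError("quiet_window must be >= 1 sample")
    score = np.asarray(summed_score, dtype=float)
    valid = np.isfinite(score)
    if not valid.any():
        return np.empty(0, dtype=int)
    thr = np.percentile(score[valid], percentile)
    above = valid & (score > thr)
    onsets = []
    for t in np.flatnonzero(above):
        if t < quiet_window:
            continue
        window = score[t - quiet_window : t]
        if np.all(np.isfinite(window)) and np.all(window <= thr):
            onsets.append(t)
    return np.asarray(onsets, dtype=int)


def epoch_around(
    raw: np.ndarray, onsets: np.ndarray, window: tuple[int, int]
) -> tuple[np.ndarray, int]:
    """Fixed-window epochs of ``raw`` around each onset.

    ``window`` is (before, after) in samples; onsets whose window would run
    off either edge of the recording are dropped and counted.  Returns
    (epochs, n_dropped) with epochs shaped (n_kept, before + after, ...).
    """
    raw = np.asarray(raw)
    before, after = int(window[0]), int(window[1])
    n = raw.shape[0]
    kept, dropped = [], 0
    for t in np.asarray(onsets, dtype=int):
        if t - before < 0 or t + after > n:
            dropped += 1
            continue
        kept.append(raw[t - before : t + after])
    if kept:
        return np.stack(kept), dropped
    shape = (0, before + after) + raw.shape[1:]
    return np.empty(shape, dtype=raw.dtype), dropped
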