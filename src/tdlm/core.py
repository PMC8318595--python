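"""Shared domain types for sequenceness analysis.

Everything downstream operates on a :class:`StateSpace` — a samples x states
matrix of decoded reactivation evidence (sigmoid classifier outputs in
classifier mode, row-normalised posterior probabilities in rodent posterior
mode).  Time lags are always integer sample counts; conversion to milliseconds
goes through ``sample_interval``.  Segment boundaries (e.g. concatenated
candidate replay events) are first-class so that no lagged regression pair is
ever formed across two different events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "TransitionTemplate",
    "EmpiricalTransitions",
    "SequencenessResult",
    "LagPairIndex",
    "LagTooLargeError",
    "build_lag_pairs",
    "save_statespace_hdf5",
    "load_statespace_hdf5",
    "statespace_to_csv",
    "statespace_from_csv",
]

_POSTERIOR_ROW_TOL = 1e-6


class LagTooLargeError(ValueError):
    """Raised when a requested lag exceeds every segment's length."""


@dataclass
class StateSpace:
    """Decoded evidence for each state over time.

    Parameters
    ----------
    values : (n_samples, n_states) array
        Decoded evidence.  In ``posterior`` mode each row must sum to 1.
    sample_interval : float
        Seconds per sample (e.g. 0.01 for 100 Hz).
    state_labels : sequence of str, optional
        One identifier per state; defaults to ``s0..s{n-1}``.
    segment_ids : (n_samples,) int array, optional
        Non-decreasing id marking which contiguous segment each sample
        belongs to.  Defaults to a single segment.
    mode : {"evidence", "posterior"}
        ``posterior`` enforces unit row sums.
    """

    values: np.ndarray
    sample_interval: float
    state_labels: list[str] = field(default_factory=list)
    segment_ids: np.ndarray | None = None
    mode: str = "evidence"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x states)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("StateSpace values contain non-finite entries")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")
        n, k = self.values.shape
        if not self.state_labels:
            self.state_labels = [f"s{i}" for i in range(k)]
        if len(self.state_labels) != k:
            raise ValueError("state_labels length does not match n_states")
        if self.segment_ids is None:
            self.segment_ids = np.zeros(n, dtype=int)
        else:
            self.segment_ids = np.asarray(self.segment_ids, dtype=int)
            if self.segment_ids.shape != (n,):
                raise ValueError("segment_ids must have one entry per sample")
            if np.any(np.diff(self.segment_ids) < 0):
                raise ValueError("segment_ids must be non-decreasing")
        if self.mode == "posterior":
            rows = self.values.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > _POSTERIOR_ROW_TOL):
                raise ValueError("posterior mode requires unit row sums")
        elif self.mode != "evidence":
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def segment_slices(self) -> list[slice]:
        """Contiguous row ranges, one per segment, in order."""
        ids = self.segment_ids
        if ids.size == 0:
            return []
        change = np.flatnonzero(np.diff(ids)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [ids.size]))
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]

    def lags_to_ms(self, lags: Sequence[int]) -> np.ndarray:
        return np.asarray(lags, dtype=float) * self.sample_interval * 1000.0


@dataclass
class TransitionTemplate:
    """An n x n hypothesis matrix (forward/backward/auto/const/permuted)."""

    matrix: np.ndarray
    name: str = "template"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("transition template must be square")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("transition template must be finite")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def transpose(self, name: str | None = None) -> "TransitionTemplate":
        return TransitionTemplate(self.matrix.T.copy(), name or f"{self.name}_T")

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(self.matrix)
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass
class EmpiricalTransitions:
    """First-level regression coefficients: one n x n matrix per lag.

    ``betas[L][i, j]`` is the coefficient of state ``i`` at time t predicting
    state ``j`` at time t + lags[L].  ``extra`` holds coefficient blocks of
    any control regressors (e.g. the time-interaction block), keyed by name.
    """

    betas: np.ndarray  # (n_lags, n, n)
    lags: list[int]
    intercepts: np.ndarray | None = None  # (n_lags, n)
    extra: dict = field(default_factory=dict)
    n_obs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (n_lags, n, n)")
        lags = list(int(v) for v in self.lags)
        if any(l < 1 for l in lags):
            raise ValueError("lags must all be >= 1")
        if any(b >= a for a, b in zip(lags[1:], lags[:-1])):
            raise ValueError("lags must be strictly increasing")
        if len(lags) != self.betas.shape[0]:
            raise ValueError("lags length must match betas")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")
        self.lags = lags


@dataclass
class SequencenessResult:
    """Second-level sequenceness per lag, plus optional permutation null.

    ``difference`` is always exactly ``z_forward - z_backward``.
    """

    lags: list[int]
    z_forward: np.ndarray
    z_backward: np.ndarray
    z_auto: np.ndarray | None = None
    z_const: np.ndarray | None = None
    variance: np.ndarray | None = None  # per-lag var of (z_forward, z_backward)
    null_distribution: np.ndarray | None = None  # (n_perm, n_lags)
    threshold: float | None = None
    sample_interval: float | None = None

    def __post_init__(self) -> None:
        self.z_forward = np.asarray(self.z_forward, dtype=float)
        self.z_backward = np.asarray(self.z_backward, dtype=float)

    @property
    def difference(self) -> np.ndarray:
        return self.z_forward - self.z_backward

    @property
    def lags_ms(self) -> np.ndarray | None:
        if self.sample_interval is None:
            return None
        return np.asarray(self.lags, dtype=float) * self.sample_interval * 1e3


@dataclass
class LagPairIndex:
    """Aligned (source, target) row indices with target = source + lag.

    No pair crosses a segment boundary.
    """

    source_rows: np.ndarray
    target_rows: np.ndarray
    lag: int

    def __post_init__(self) -> None:
        self.source_rows = np.asarray(self.source_rows, dtype=int)
        self.target_rows = np.asarray(self.target_rows, dtype=int)
        if self.source_rows.shape != self.target_rows.shape:
            raise ValueError("source and target rows must align")
        if self.source_rows.size and not np.all(
            self.target_rows - self.source_rows == self.lag
        ):
            raise ValueError("every pair must satisfy target - source = lag")

    def __len__(self) -> int:
        return int(self.source_rows.size)


def build_lag_pairs(space: StateSpace, lag: int) -> LagPairIndex:
    """All (t, t + lag) sample pairs that stay within one segment.

    The row-shift convention pairs X[t] (predictor) with X[t + lag]
    (outcome); there is no wraparound and the trailing ``lag`` rows of each
    segment are dropped.

    Raises
    ------
    LagTooLargeError
        If every segment is shorter than ``lag + 1`` samples.
    """
    lag = int(lag)
    if lag < 1:
        raise ValueError("lag must be >= 1 sample")
    sources: list[np.ndarray] = []
    for seg in space.segment_slices():
        length = seg.stop - seg.start
        if length > lag:
            sources.append(np.arange(seg.start, seg.stop - lag))
    if not sources:
        raise LagTooLargeError(
            f"lag {lag} is too large: no segment has more than {lag} samples"
        )
    src = np.concatenate(sources)
    return LagPairIndex(source_rows=src, target_rows=src + lag, lag=lag)


# ---------------------------------------------------------------------------
# Serialization: HDF5 group and wide CSV for small cases
# ---------------------------------------------------------------------------

def save_statespace_hdf5(space: StateSpace, path, group: str = "/") -> None:
    import h5py

    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for name in ("values", "labels", "segment_ids"):
            if name in g:
                del g[name]
        g.create_dataset("values", data=space.values)
        g.create_dataset(
            "labels", data=np.array(space.state_labels, dtype=h5py.string_dtype())
        )
        g.create_dataset("segment_ids", data=space.segment_ids)
        g.attrs["sample_interval"] = space.sample_interval
        g.attrs["mode"] = space.mode


def load_statespace_hdf5(path, group: str = "/") -> StateSpace:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in g["labels"][()]
        ]
        return StateSpace(
            values=g["values"][()],
            sample_interval=float(g.attrs["sample_interval"]),
            state_labels=labels,
            segment_ids=g["segment_ids"][()],
            mode=str(g.attrs.get("mode", "evidence")),
        )


def statespace_to_csv(space: StateSpace, path) -> None:
    import pandas as pd

    df = pd.DataFrame(space.values, columns=space.state_labels)
    df.insert(0, "segment_id", space.segment_ids)
    df.insert(0, "time_s", np.arange(space.n_samples) * space.sample_interval)
    df.to_csv(path, index=False)


def statespace_from_csv(path, mode: str = "evidence") -> StateSpace:
    import pandas as pd

    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    seg = df.pop("segment_id").to_numpy(dtype=int)
    if len(times) > 1:
        interval = float(np.median(np.diff(times)))
    else:
        interval = 1.0
    return StateSpace(
        values=df.to_numpy(dtype=float),
        sample_interval=interval,
        state_labels=list(df.columns),
        segment_ids=seg,
        mode=mode,
    )
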