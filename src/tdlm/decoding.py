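"""Train per-state decoders on task data and project test data to a StateSpace.

One-vs-rest binomial logistic models, one per state: the positives are that
state's task rows, the negatives are every other state's rows plus an
adjustable amount of "null" (baseline) rows.  The null:task ratio steers the
spatial correlation between the trained state decoders — no null data drives
the states negatively correlated, a large ratio drives them positive — and
sequence detection is most sensitive when that correlation is near zero, so
``tune_null_ratio`` searches a grid for the ratio whose mean off-diagonal
weight correlation is closest to zero.

L1 regularization (penalty b*lambda*||W||_1, with b the number of fitting
rows) additionally sparsifies the weight maps and is the recommended default:
it lowers inter-state weight correlation, which is what matters downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import StateSpace

__all__ = [
    "ClassifierSet",
    "select_training_time",
    "train_classifiers",
    "decode_states",
    "spatial_correlation",
    "tune_null_ratio",
    "save_classifiers_hdf5",
    "load_classifiers_hdf5",
]

_TOL = 1e-6
_MAX_ITER = 1000


@dataclass
class ClassifierSet:
    """Per-state decoding weights plus training metadata.

    ``weights`` is (n_sensors, n_states); ``bias`` is (n_states,).  Sensors
    are z-scored with the stored ``scale_mean`` / ``scale_sd`` before both
    training and decoding.
    """

    weights: np.ndarray
    bias: np.ndarray
    regularization: dict = field(default_factory=lambda: {"type": "l1", "strength": 0.01})
    null_ratio: float = 0.0
    training_time_point: float | None = None
    cv_accuracy_curve: np.ndarray | None = None
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("classifier weights must be finite")
        if self.weights.shape[1] != self.bias.shape[0]:
            raise ValueError("one bias per state required")

    @property
    def n_states(self) -> int:
        return self.weights.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.weights.shape[0]


def _zscore_params(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def select_training_time(
    epochs: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the post-stimulus time bin with peak cross-validated accuracy.

    Folds partition *trials* (never time points of one trial); ties between
    equal-accuracy bins resolve to the earliest bin.
    """
    epochs = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (trials, sensors, time)")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError(
            "at least 2 trials per state are required for cross-validation"
        )
    k = int(min(n_folds, counts.min()))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n_time = epochs.shape[2]
    curve = np.zeros(n_time)
    folds = list(cv.split(epochs[:, :, 0], labels))
    for t in range(n_time):
        M = epochs[:, :, t]
        correct = 0
        for train, test in folds:
            mean, sd = _zscore_params(M[train])
            clf = LogisticRegression(C=np.inf, max_iter=_MAX_ITER, tol=_TOL)
            clf.fit((M[train] - mean) / sd, labels[train])
            correct += int((clf.predict((M[test] - mean) / sd) == labels[test]).sum())
        curve[t] = correct / labels.size
    return int(np.argmax(curve)), curve


def train_classifiers(
    M: np.ndarray,
    Y: np.ndarray,
    regularization: tuple[str, float] | dict = ("l1", 0.01),
    null_ratio: float = 0.0,
    null_data: np.ndarray | None = None,
    seed: int = 0,
) -> ClassifierSet:
    """Fit one-vs-rest logistic decoders with null-data mixing.

    For each state, positives are that state's rows; negatives are all other
    states' rows plus round(null_ratio * b) null rows, b being the number of
    task rows.  The penalty is b*lambda*||W|| (so lambda is per-observation),
    and the intercept is unpenalized in spirit (large intercept scaling for
    the L1 solver).
    """
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y)
    if isinstance(regularization, dict):
        reg_type = regularization.get("type", "l1")
        lam = float(regularization.get("strength", 0.0))
    else:
        reg_type, lam = regularization
        lam = float(lam)
    reg_type = (reg_type or "none").lower()
    if lam < 0:
        raise ValueError("regularization strength must be >= 0")
    states = np.unique(Y)
    if states.size < 2:
        raise ValueError("degenerate single-class input: need >= 2 states")
    b = M.shape[0]
    n_null = int(round(null_ratio * b))
    if n_null > 0:
        if null_data is None:
            raise ValueError("null_ratio > 0 requires null_data")
        null_data = np.asarray(null_data, dtype=float)
        if null_data.shape[0] < n_null:
            raise ValueError(
                f"need {n_null} null rows for ratio {null_ratio}, "
                f"got {null_data.shape[0]}"
            )
        rng = np.random.default_rng(seed)
        pick = rng.choice(null_data.shape[0], size=n_null, replace=False)
        X_all = np.vstack([M, null_data[pick]])
    else:
        X_all = M
    mean, sd = _zscore_params(X_all)
    Xz = (X_all - mean) / sd
    n_fit = Xz.shape[0]

    if reg_type in ("none",) or lam == 0:
        base = dict(C=np.inf, solver="lbfgs")
    elif reg_type == "l1":
        base = dict(
            l1_ratio=1,
            solver="liblinear",
            C=1.0 / (n_fit * lam),
            intercept_scaling=100.0,
        )
    elif reg_type == "l2":
        base = dict(solver="lbfgs", C=1.0 / (n_fit * lam))
    else:
        raise ValueError(f"unknown regularization type {reg_type!r}")

    n_states = states.size
    W = np.zeros((M.shape[1], n_states))
    bias = np.zeros(n_states)
    for k, s in enumerate(states):
        y = np.zeros(n_fit, dtype=int)
        y[: b][Y == s] = 1  # null rows carry the all-negative label
        clf = LogisticRegression(
            max_iter=_MAX_ITER, tol=_TOL, random_state=seed, **base
        )
        clf.fit(Xz, y)
        W[:, k] = clf.coef_[0]
        bias[k] = clf.intercept_[0]
    return ClassifierSet(
        weights=W,
        bias=bias,
        regularization={"type": reg_type, "strength": lam},
        null_ratio=float(null_ratio),
        scale_mean=mean,
        scale_sd=sd,
    )


def decode_states(
    R: np.ndarray,
    cls: ClassifierSet,
    sample_interval: float = 0.01,
    segment_ids: np.ndarray | None = None,
) -> StateSpace:
    """X = sigmoid(R W + bias): per-state reactivation evidence in (0, 1)."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[1] != cls.n_sensors:
        raise ValueError(
            f"sensor mismatch: data has {R.shape[1] if R.ndim == 2 else '?'} "
            f"sensors, classifiers were trained on {cls.n_sensors}"
        )
    if cls.scale_mean is not None:
        R = (R - cls.scale_mean) / cls.scale_sd
    from scipy.special import expit

    logits = R @ cls.weights + cls.bias
    X = expit(logits)
    return StateSpace(
        values=X, sample_interval=sample_interval, segment_ids=segment_ids
    )


def spatial_correlation(cls: ClassifierSet) -> np.ndarray:
    """Pairwise Pearson correlation of the sensor-weight columns (bias excluded).

    Zero-variance columns yield NaN rows/columns (flagged, not silently 0).
    """
    W = cls.weights
    if W.shape[0] < 2:
        raise ValueError("need at least 2 sensors for spatial correlation")
    sd = W.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            "zero-variance weight column(s); their correlations are undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(W.T)
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    np.fill_diagonal(C, 1.0)
    return C


def mean_offdiag_correlation(cls: ClassifierSet, absolute: bool = False) -> float:
    C = spatial_correlation(cls)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        return np.nan
    return float(np.abs(off).mean() if absolute else off.mean())


def tune_null_ratio(
    M: np.ndarray,
    Y: np.ndarray,
    null_data: np.ndarray,
    grid: list[float] | np.ndarray,
    regularization: tuple[str, float] = ("l1", 0.01),
    seed: int = 0,
) -> float:
    """Grid value whose mean off-diagonal weight correlation is nearest zero."""
    grid = list(grid)
    if not grid:
        raise ValueError("null-ratio grid must be non-empty")
    scores = []
    for ratio in grid:
        cls = train_classifiers(
            M, Y, regularization, null_ratio=ratio, null_data=null_data, seed=seed
        )
        scores.append(abs(mean_offdiag_correlation(cls)))
    return float(grid[int(np.argmin(scores))])


def save_classifiers_hdf5(cls: ClassifierSet, path, group: str = "/") -> None:
    import h5py

    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for name in ("weights", "bias", "scale_mean", "scale_sd"):
            if name in g:
                del g[name]
        g.create_dataset("weights", data=cls.weights)
        g.create_dataset("bias", data=cls.bias)
        if cls.scale_mean is not None:
            g.create_dataset("scale_mean", data=cls.scale_mean)
            g.create_dataset("scale_sd", data=cls.scale_sd)
        g.attrs["reg_type"] = cls.regularization["type"]
        g.attrs["reg_strength"] = cls.regularization["strength"]
        g.attrs["null_ratio"] = cls.null_ratio


def load_classifiers_hdf5(path, group: str = "/") -> ClassifierSet:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        return ClassifierSet(
            weights=g["weights"][()],
            bias=g["bias"][()],
            regularization={
                "type": str(g.attrs["reg_type"]),
                "strength": float(g.attrs["reg_strength"]),
            },
            null_ratio=float(g.attrs["null_ratio"]),
            scale_mean=g["scale_mean"][()] if "scale_mean" in g else None,
            scale_sd=g["scale_sd"][()] if "scale_sd" in g else None,
        )
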