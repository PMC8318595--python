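"""Statistical inference on sequenceness.

Single-lag tests compare per-subject sequenceness against zero (t or
signed-rank) when the lag was chosen a priori.  When the lag is scanned, the
family-wise error over lags is controlled with a state-identity permutation
test: the hypothesis matrix is relabelled (never the data, whose temporal
structure must be preserved), the full second level is recomputed per
permutation, and the null is the per-permutation *maximum* over lags.  The
threshold is the nearest-rank (1 - alpha) quantile of those maxima.

Two permutation sets are supported: all state permutations, or only those
whose permuted transitions connect states from *different* sequences (a
stricter null that shares no edge with the hypothesis and is more sensitive
in the presence of signal).

A uniform time-shuffle test is included purely as a negative control: it
destroys temporal smoothness and is anticonservative on autocorrelated data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import EmpiricalTransitions, StateSpace, TransitionTemplate
from .glm import build_templates, sequenceness_curve

__all__ = [
    "PermutationScheme",
    "GroupResult",
    "single_lag_test",
    "generate_state_permutations",
    "max_stat_threshold",
    "permutation_pvalue",
    "time_permutation_test",
    "group_sequenceness",
]

_ENUM_LIMIT = 362_880  # 9!: enumerate exactly up to here


@dataclass
class PermutationScheme:
    """How to build the state-identity permutation null.

    ``cross_sequence_only`` requires ``sequence_membership`` (state index ->
    sequence id) and keeps only permutations whose permuted transition matrix
    contains no within-sequence edge.  The identity permutation is always
    excluded.
    """

    mode: str = "all_states"  # or "cross_sequence_only"
    sequence_membership: np.ndarray | None = None
    n_permutations: int = 500
    seed: int = 0
    use_abs_null: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("all_states", "cross_sequence_only"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.mode == "cross_sequence_only" and self.sequence_membership is None:
            raise ValueError("cross_sequence_only requires sequence_membership")


def single_lag_test(z_values: np.ndarray, test: str = "t") -> float:
    """Two-sided one-sample test of per-subject sequenceness against zero."""
    z = np.asarray(z_values, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 subjects")
    if z.size < 5:
        warnings.warn("fewer than 5 subjects: test is fragile")
    if np.allclose(z.std(), 0.0):
        if np.allclose(z.mean(), 0.0):
            return 1.0
        warnings.warn("degenerate zero-variance sample with nonzero mean")
        return 0.0
    if test == "t":
        return float(stats.ttest_1samp(z, 0.0).pvalue)
    if test == "signed_rank":
        return float(stats.wilcoxon(z).pvalue)
    raise ValueError(f"unknown test {test!r}")


def _permute_template(T: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """T_pi[i, j] = T[pi(i), pi(j)]."""
    return T[np.ix_(perm, perm)]


def _cross_sequence_ok(
    T_perm: np.ndarray, membership: np.ndarray
) -> bool:
    ii, jj = np.nonzero(T_perm)
    return bool(np.all(membership[ii] != membership[jj]))


def generate_state_permutations(
    scheme: PermutationScheme, t_f: TransitionTemplate | np.ndarray
) -> list[TransitionTemplate]:
    """Permuted hypothesis templates for the null distribution.

    Enumerates all n! - 1 non-identity permutations exactly when feasible and
    samples without replacement from them; raises if more permutations are
    requested than exist (the error reports the exact count).
    """
    T = t_f.matrix if isinstance(t_f, TransitionTemplate) else np.asarray(t_f, float)
    n = T.shape[0]
    membership = None
    if scheme.mode == "cross_sequence_only":
        membership = np.asarray(scheme.sequence_membership)
        if membership.shape != (n,):
            raise ValueError("sequence_membership needs one id per state")
    if math.factorial(n) <= _ENUM_LIMIT:
        perms = []
        identity = tuple(range(n))
        for p in itertools.permutations(range(n)):
            if p == identity:
                continue
            parr = np.array(p)
            if membership is not None and not _cross_sequence_ok(
                _permute_template(T, parr), membership
            ):
                continue
            perms.append(parr)
        available = len(perms)
        if scheme.n_permutations > available:
            raise ValueError(
                f"requested {scheme.n_permutations} permutations but only "
                f"{available} are available"
            )
        rng = np.random.default_rng(scheme.seed)
        if scheme.n_permutations < available:
            idx = rng.choice(available, size=scheme.n_permutations, replace=False)
            perms = [perms[i] for i in sorted(idx)]
    else:
        rng = np.random.default_rng(scheme.seed)
        seen: set[tuple] = {tuple(range(n))}
        perms = []
        while len(perms) < scheme.n_permutations:
            p = rng.permutation(n)
            key = tuple(p.tolist())
            if key in seen:
                continue
            if membership is not None and not _cross_sequence_ok(
                _permute_template(T, p), membership
            ):
                continue
            seen.add(key)
            perms.append(p)
    return [
        TransitionTemplate(_permute_template(T, p), name=f"perm_{k}")
        for k, p in enumerate(perms)
    ]


def max_stat_threshold(
    null_curves: np.ndarray, alpha: float = 0.05, use_abs: bool = False
) -> float:
    """Nearest-rank (1 - alpha) quantile of per-permutation maxima over lags."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    null_curves = np.asarray(null_curves, dtype=float)
    if null_curves.ndim == 1:
        null_curves = null_curves[:, None]
    n_perm = null_curves.shape[0]
    if n_perm < 20 and alpha <= 0.05:
        warnings.warn("fewer than 20 permutations for alpha <= 0.05")
    maxima = (
        np.abs(null_curves).max(axis=1) if use_abs else null_curves.max(axis=1)
    )
    rank = int(math.ceil((1.0 - alpha) * n_perm))  # 1-based nearest rank
    return float(np.sort(maxima)[rank - 1])


def permutation_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Valid permutation p-value (1 + #{null >= obs}) / (1 + n_perm)."""
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))


def time_permutation_test(
    space: StateSpace,
    t_f: TransitionTemplate | np.ndarray,
    lags: list[int],
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Uniform time-shuffle null — NEGATIVE CONTROL ONLY.

    Shuffling rows destroys the temporal smoothness of the data, so the null
    is artificially narrow and the test is anticonservative on autocorrelated
    signals.  Returns (p_value, observed max Z_F, null maxima).
    """
    warnings.warn(
        "time_permutation_test is anticonservative on autocorrelated data; "
        "use state-identity permutations for inference"
    )
    obs = sequenceness_curve(space, t_f, lags).z_forward.max()
    rng = np.random.default_rng(seed)
    n = space.n_samples
    null = np.empty(n_perm)
    identity = np.arange(n)
    for k in range(n_perm):
        while True:
            order = rng.permutation(n)
            if not np.array_equal(order, identity):
                break
        shuffled = StateSpace(
            values=space.values[order],
            sample_interval=space.sample_interval,
            state_labels=space.state_labels,
            segment_ids=space.segment_ids,
        )
        null[k] = sequenceness_curve(shuffled, t_f, lags).z_forward.max()
    return permutation_pvalue(float(obs), null), float(obs), null


@dataclass
class GroupResult:
    """Group-level sequenceness with its permutation null."""

    lags: list[int]
    group_forward: np.ndarray
    group_backward: np.ndarray
    null_forward: np.ndarray  # (n_perm, n_lags)
    threshold: float
    p_value: float
    alpha: float
    observed_max: float
    per_subject_forward: np.ndarray = field(default=None)  # (n_subj, n_lags)

    @property
    def significant(self) -> bool:
        return self.observed_max > self.threshold


def _vec_beta_stack(emp: EmpiricalTransitions) -> np.ndarray:
    """(n_cells, n_lags) vectorised betas."""
    n_lags, n, _ = emp.betas.shape
    return emp.betas.reshape(n_lags, n * n).T


def group_sequenceness(
    per_subject: list[EmpiricalTransitions],
    t_f: TransitionTemplate | np.ndarray,
    scheme: PermutationScheme,
    alpha: float = 0.05,
    statistic: str = "mean",
) -> GroupResult:
    """Group statistic per lag with a shared-permutation null.

    Within one null sample the *same* state permutation is applied to every
    subject.  The default group statistic is the subject mean (because the
    second level is linear in beta, the mean of per-subject Z equals Z of
    the mean beta, which is exploited for speed); ``statistic="t"`` uses the
    one-sample t statistic across subjects instead.
    """
    if not per_subject:
        raise ValueError("no subjects")
    lags = per_subject[0].lags
    n = per_subject[0].betas.shape[1]
    for emp in per_subject[1:]:
        if emp.lags != lags:
            raise ValueError("subjects must share the same lag grid")
        if emp.betas.shape[1] != n:
            raise ValueError("subjects must share the same state count")
    T = t_f.matrix if isinstance(t_f, TransitionTemplate) else np.asarray(t_f, float)

    if statistic not in ("mean", "t"):
        raise ValueError(f"unknown group statistic {statistic!r}")
    stacks = np.stack([_vec_beta_stack(e) for e in per_subject])  # (S, n², L)
    mean_stack = stacks.mean(axis=0)

    def z_curves(template: np.ndarray, vecs: np.ndarray) -> np.ndarray:
        """Rows (Z_F, Z_B) for every lag, given vec-beta columns."""
        D = np.column_stack(
            [t.matrix.ravel() for t in build_templates(template)]
        )
        return np.linalg.pinv(D) @ vecs  # (4, n_lags)

    def t_stat(fwd_per_subj: np.ndarray) -> np.ndarray:
        n = fwd_per_subj.shape[0]
        sd = fwd_per_subj.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return fwd_per_subj.mean(axis=0) / (sd / np.sqrt(n))

    obs = z_curves(T, mean_stack)
    per_subj_fwd = np.stack([z_curves(T, s)[0] for s in stacks])
    if statistic == "t":
        obs = np.stack(
            [
                t_stat(np.stack([z_curves(T, s)[row] for s in stacks]))
                for row in (0, 1)
            ]
        )

    permuted = generate_state_permutations(scheme, T)
    null = np.empty((len(permuted), len(lags)))
    for k, tpl in enumerate(permuted):
        if statistic == "mean":
            null[k] = z_curves(tpl.matrix, mean_stack)[0]
        else:
            null[k] = t_stat(
                np.stack([z_curves(tpl.matrix, s)[0] for s in stacks])
            )

    threshold = max_stat_threshold(null, alpha, use_abs=scheme.use_abs_null)
    observed_max = float(obs[0].max())
    maxima = np.abs(null).max(axis=1) if scheme.use_abs_null else null.max(axis=1)
    p = permutation_pvalue(observed_max, maxima)
    return GroupResult(
        lags=list(lags),
        group_forward=obs[0],
        group_backward=obs[1],
        null_forward=null,
        threshold=threshold,
        p_value=p,
        alpha=alpha,
        observed_max=observed_max,
        per_subject_forward=per_subj_fwd,
    )
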