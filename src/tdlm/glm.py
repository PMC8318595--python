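"""The sequence GLM core.

First level: for a given time lag dt, every state's dt-shifted time course is
regressed (OLS) on all states' unshifted time courses simultaneously.  Using
*all* states in one multiple regression — rather than one pairwise regression
per state pair — is what lets the method control for the interaction between
state correlations and temporal autocorrelation: any spurious path from
X_i(t) to X_j(t+dt) that is mediated by the decoded subspace at time t is
absorbed by the co-regressors.  The resulting n x n coefficient matrix is the
*empirical transition matrix* beta(dt).

Second level: vec(beta) is regressed on a small set of vectorised hypothesis
templates — the forward matrix T_F, its transpose T_B, the identity T_auto
(self-transitions / autocorrelation) and the all-ones T_const (mean
transition level).  The coefficients Z_F, Z_B are the forward and backward
"sequenceness" at that lag; D = Z_F - Z_B contrasts the two directions.

Optional nuisance blocks in the first level:

* oscillation controls — phase-shifted copies X(t + tau) of the state
  regressors, which absorb background rhythms (e.g. tau = 100 ms for a 10 Hz
  alpha rhythm) that would otherwise masquerade as lagged structure;
* a time interaction block X(t) .* z-scored time, which measures whether
  sequence strength drifts over the session (second-order inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    EmpiricalTransitions,
    LagPairIndex,
    SequencenessResult,
    StateSpace,
    TransitionTemplate,
    build_lag_pairs,
)

__all__ = [
    "FirstLevelDesign",
    "SingularDesignError",
    "empirical_transitions",
    "simple_pairwise_transitions",
    "build_templates",
    "sequenceness",
    "sequenceness_curve",
    "add_oscillation_controls",
]

_RCOND = 1e-10


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when a design matrix is rank deficient."""


@dataclass
class FirstLevelDesign:
    """Configuration of the first-level design matrix.

    All predictor blocks share the row indexing of one :class:`LagPairIndex`,
    so control columns never straddle a segment boundary either.
    """

    intercept: bool = True
    oscillation_taus: list[int] = field(default_factory=list)
    time_interaction: bool = False
    allow_pseudo_inverse: bool = False

    def copy(self) -> "FirstLevelDesign":
        return FirstLevelDesign(
            intercept=self.intercept,
            oscillation_taus=list(self.oscillation_taus),
            time_interaction=self.time_interaction,
            allow_pseudo_inverse=self.allow_pseudo_inverse,
        )


def add_oscillation_controls(
    design: FirstLevelDesign, taus: list[int] | int
) -> FirstLevelDesign:
    """Append phase-shifted nuisance blocks X(t + tau) to a design.

    Each tau is an integer sample shift; duplicates raise (they would make
    the design singular).  Validity against the outcome lag is checked when
    the design is materialised, since it depends on dt.
    """
    if np.isscalar(taus):
        taus = [int(taus)]
    new = design.copy()
    for tau in taus:
        tau = int(tau)
        if tau < 1:
            raise ValueError("oscillation control tau must be >= 1 sample")
        if tau in new.oscillation_taus:
            raise SingularDesignError(
                f"duplicate oscillation control tau={tau} would be singular"
            )
        new.oscillation_taus.append(tau)
    return new


def _valid_sources(space: StateSpace, lag: int, taus: list[int]) -> LagPairIndex:
    """Pairs whose source row t also has t + tau inside the segment for all taus."""
    pairs = build_lag_pairs(space, lag)
    if not taus:
        return pairs
    keep = np.ones(len(pairs), dtype=bool)
    seg = space.segment_ids
    for tau in taus:
        shifted = pairs.source_rows + tau
        ok = shifted < space.n_samples
        ok &= seg[np.minimum(shifted, space.n_samples - 1)] == seg[pairs.source_rows]
        keep &= ok
    src = pairs.source_rows[keep]
    if src.size == 0:
        raise ValueError("no valid rows remain after applying oscillation controls")
    return LagPairIndex(source_rows=src, target_rows=src + lag, lag=lag)


def _materialise_design(
    space: StateSpace, lag: int, design: FirstLevelDesign
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build (A, Y, column map) for one lag."""
    taus = [t for t in design.oscillation_taus]
    for tau in taus:
        if tau == lag:
            raise ValueError(
                f"oscillation control tau={tau} equals the outcome lag; "
                "the control column would duplicate the outcome"
            )
        if tau >= space.n_samples:
            raise ValueError(f"oscillation control tau={tau} out of range")
    pairs = _valid_sources(space, lag, taus)
    X = space.values
    blocks = [X[pairs.source_rows]]
    colmap: dict = {"main": (0, space.n_states)}
    col = space.n_states
    for tau in taus:
        blocks.append(X[pairs.source_rows + tau])
        colmap[f"osc_tau{tau}"] = (col, col + space.n_states)
        col += space.n_states
    if design.time_interaction:
        t_idx = np.arange(space.n_samples, dtype=float)
        sd = t_idx.std()
        if sd == 0:
            raise ValueError("time index is constant; interaction undefined")
        zt = (t_idx - t_idx.mean()) / sd
        blocks.append(X[pairs.source_rows] * zt[pairs.source_rows, None])
        colmap["time_interaction"] = (col, col + space.n_states)
        col += space.n_states
    if design.intercept:
        blocks.append(np.ones((len(pairs), 1)))
        colmap["intercept"] = (col, col + 1)
        col += 1
    A = np.hstack(blocks)
    Y = X[pairs.target_rows]
    return A, Y, colmap


def _describe_singularity(A: np.ndarray, labels: list[str]) -> str:
    """Name zero-variance or duplicated columns for the error message."""
    culprits = []
    sd = A.std(axis=0)
    mean = np.abs(A.mean(axis=0))
    for k, (s, m) in enumerate(zip(sd, mean)):
        # a constant non-intercept column collides with the intercept
        if s < 1e-12 and labels[k] != "intercept":
            culprits.append(f"constant column {labels[k]}")
    if not culprits:
        c = np.corrcoef(A.T)
        n = A.shape[1]
        for i in range(n):
            for j in range(i + 1, n):
                if np.isfinite(c[i, j]) and abs(c[i, j]) > 1 - 1e-10:
                    culprits.append(f"collinear columns {labels[i]}, {labels[j]}")
    return "; ".join(culprits) if culprits else "rank-deficient design"


def _solve_ols(
    A: np.ndarray, Y: np.ndarray, labels: list[str], allow_pinv: bool
) -> np.ndarray:
    # normal equations with a conditioning check: much cheaper than an SVD
    # per lag, and the Gram spectrum gives the same rank decision
    G = A.T @ A
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= eig[-1] * _RCOND or eig[-1] == 0:
        if allow_pinv:
            return np.linalg.pinv(A, rcond=_RCOND) @ Y
        raise SingularDesignError(
            "singular first-level design: " + _describe_singularity(A, labels)
        )
    return np.linalg.solve(G, A.T @ Y)


def empirical_transitions(
    space: StateSpace,
    lag: int,
    design: FirstLevelDesign | None = None,
) -> EmpiricalTransitions:
    """First-level GLM at one lag: beta = argmin ||X_dt - [X, controls] B||².

    Returns the n x n empirical transition matrix (main-block coefficients);
    control-block coefficients are stored under ``extra`` keyed by block name.
    """
    if design is None:
        design = FirstLevelDesign()
    A, Y, colmap = _materialise_design(space, int(lag), design)
    labels = [""] * A.shape[1]
    for name, (a, b) in colmap.items():
        for k in range(a, b):
            if name == "main":
                labels[k] = f"state {space.state_labels[k - a]}"
            elif name == "intercept":
                labels[k] = "intercept"
            else:
                labels[k] = f"{name}[{space.state_labels[k - a]}]"
    coef = _solve_ols(A, Y, labels, design.allow_pseudo_inverse)
    a, b = colmap["main"]
    betas = coef[a:b, :]
    extra = {}
    for name, (c, d) in colmap.items():
        if name in ("main", "intercept"):
            continue
        extra[name] = coef[c:d, :][None, :, :]
    intercepts = None
    if "intercept" in colmap:
        c, _ = colmap["intercept"]
        intercepts = coef[c, :][None, :]
    return EmpiricalTransitions(
        betas=betas[None, :, :],
        lags=[int(lag)],
        intercepts=intercepts,
        extra=extra,
        n_obs=[A.shape[0]],
    )


def simple_pairwise_transitions(space: StateSpace, lag: int) -> np.ndarray:
    """One-predictor regressions X_j(t+dt) ~ X_i(t), all (i, j) pairs.

    This is the naive estimator that multiple regression replaces: with
    correlated, autocorrelated states it reports spurious sequenceness.  It
    is provided as a negative control only.
    """
    pairs = build_lag_pairs(space, int(lag))
    X = space.values[pairs.source_rows]
    Y = space.values[pairs.target_rows]
    n = space.n_states
    out = np.empty((n, n))
    ones = np.ones((X.shape[0], 1))
    for i in range(n):
        A = np.hstack([X[:, [i]], ones])
        if np.linalg.matrix_rank(A) < 2:
            raise SingularDesignError(
                f"singular pairwise design: constant column state "
                f"{space.state_labels[i]}"
            )
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        out[i, :] = coef[0, :]
    return out


def build_templates(t_f: TransitionTemplate | np.ndarray) -> list[TransitionTemplate]:
    """Canonical second-level template set [T_F, T_B, T_auto, T_const]."""
    if not isinstance(t_f, TransitionTemplate):
        t_f = TransitionTemplate(np.asarray(t_f, dtype=float), "forward")
    n = t_f.n_states
    return [
        TransitionTemplate(t_f.matrix.copy(), "forward"),
        TransitionTemplate(t_f.matrix.T.copy(), "backward"),
        TransitionTemplate(np.eye(n), "auto"),
        TransitionTemplate(np.ones((n, n)), "const"),
    ]


def _template_design(
    templates: list[TransitionTemplate], include_diagonal: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(design matrix D, cell mask) for the vectorised second level."""
    n = templates[0].n_states
    mask = np.ones((n, n), dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    cols = []
    for t in templates:
        if t.n_states != n:
            raise ValueError("templates must share one state count")
        cols.append(t.matrix[mask].astype(float))
    return np.column_stack(cols), mask


def sequenceness(
    betas: EmpiricalTransitions,
    templates: list[TransitionTemplate] | TransitionTemplate | np.ndarray,
    include_diagonal: bool = True,
    sample_interval: float | None = None,
) -> SequencenessResult:
    """Second-level GLM: vec(beta) ~ [vec(T_F), vec(T_B), vec(T_auto), vec(T_const)].

    When ``include_diagonal`` is False the diagonal cells are dropped from
    the vectorisation; all-zero template columns (T_auto, whose support is
    exactly the diagonal) are then excluded and their Z reported as NaN.  For
    off-diagonal templates on full-rank designs the two conventions give
    identical Z_F / Z_B.

    ``variance`` holds the classical OLS sampling variance of (Z_F, Z_B),
    sigma² diag((D'D)^-1), per lag — the V_i of the multi-scale combination.
    """
    if isinstance(templates, (TransitionTemplate, np.ndarray)):
        templates = build_templates(templates)
    D_full, mask = _template_design(templates, include_diagonal)
    keep = np.linalg.norm(D_full, axis=0) > 0
    D = D_full[:, keep]
    if np.linalg.matrix_rank(D) < D.shape[1]:
        names = [t.name for t, k in zip(templates, keep) if k]
        raise SingularDesignError(
            "rank-deficient template set "
            f"{names}: drop the duplicate template (e.g. a symmetric T_F "
            "makes forward and backward identical)"
        )
    pinv = np.linalg.pinv(D)
    gram_inv_diag = np.diag(np.linalg.inv(D.T @ D))
    n_lags = betas.betas.shape[0]
    n_templates = len(templates)
    Z = np.full((n_lags, n_templates), np.nan)
    var = np.full((n_lags, n_templates), np.nan)
    dof = D.shape[0] - D.shape[1]
    for L in range(n_lags):
        y = betas.betas[L][mask]
        z = pinv @ y
        resid = y - D @ z
        sigma2 = (resid @ resid) / dof if dof > 0 else 0.0
        Z[L, keep] = z
        var[L, keep] = sigma2 * gram_inv_diag
    by_name = {t.name: k for k, t in enumerate(templates)}
    iF = by_name.get("forward", 0)
    iB = by_name.get("backward", 1 if n_templates > 1 else 0)
    return SequencenessResult(
        lags=list(betas.lags),
        z_forward=Z[:, iF],
        z_backward=Z[:, iB],
        z_auto=Z[:, by_name["auto"]] if "auto" in by_name else None,
        z_const=Z[:, by_name["const"]] if "const" in by_name else None,
        variance=var[:, [iF, iB]],
        sample_interval=sample_interval,
    )


def sequenceness_curve(
    space: StateSpace,
    t_f: TransitionTemplate | np.ndarray,
    lags: list[int] | np.ndarray,
    design: FirstLevelDesign | None = None,
    include_diagonal: bool = True,
    skip_conflicting_taus: bool = True,
) -> SequencenessResult:
    """First + second level at every lag in ``lags``.

    When an oscillation control tau coincides with the current outcome lag
    the control column would duplicate the outcome; with
    ``skip_conflicting_taus`` that tau is dropped for that lag only (the
    default), otherwise the conflict raises.
    """
    if design is None:
        design = FirstLevelDesign()
    templates = build_templates(t_f)
    lags = [int(v) for v in lags]
    beta_stack = []
    for lag in lags:
        d = design
        if lag in design.oscillation_taus:
            if not skip_conflicting_taus:
                raise ValueError(f"tau={lag} equals outcome lag {lag}")
            d = design.copy()
            d.oscillation_taus = [t for t in d.oscillation_taus if t != lag]
        beta_stack.append(empirical_transitions(space, lag, d).betas[0])
    emp = EmpiricalTransitions(betas=np.stack(beta_stack), lags=lags)
    return sequenceness(
        emp, templates, include_diagonal, sample_interval=space.sample_interval
    )
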