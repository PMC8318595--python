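"""Multi-scale sequence analysis on continuous (1D) spaces.

A continuous track is discretised at several bin widths (default 5, 10, 20,
40 cm).  A replay speed maps to an integer decode-bin lag at each scale
(lag = bin_width / (speed * decode_bin)); scales where the rounded lag is
below one bin or misrepresents the speed by more than 25% are excluded for
that speed.  Per speed, the sequence GLM runs at each valid scale's lag and
the per-scale estimates are combined by inverse-variance weighting,

    beta_M = sum_i(beta_i / V_i) / sum_i(1 / V_i),

with V_i the OLS sampling variance of the per-scale estimate.  Small scales
capture slow within-bin replay, large scales capture fast bin-skipping
replay; weighting the two together restores the Euclidean-geometry
sensitivity that a single graph discretisation lacks.  Outbound and inbound
maps are distinct state sets and are analysed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StateSpace, TransitionTemplate
from .glm import (
    FirstLevelDesign,
    build_templates,
    empirical_transitions,
    sequenceness,
)
from .inference import PermutationScheme, generate_state_permutations, max_stat_threshold

__all__ = [
    "ScaleSet",
    "MultiscaleResult",
    "speed_to_lag",
    "discretize_track",
    "n_track_states",
    "coarsen_posterior",
    "multiscale_sequenceness",
    "speed_curve_inference",
    "default_speed_grid",
]

ROUNDING_TOLERANCE = 0.25


@dataclass
class ScaleSet:
    """Discretisation scales for one track."""

    track_length: float
    bin_widths: list[float] = field(default_factory=lambda: [5.0, 10.0, 20.0, 40.0])

    def __post_init__(self) -> None:
        widths = [float(w) for w in self.bin_widths]
        if any(w <= 0 for w in widths):
            raise ValueError("bin widths must be positive")
        if any(b <= a for a, b in zip(widths[:-1], widths[1:])):
            raise ValueError("bin widths must be increasing")
        self.bin_widths = widths

    def state_counts(self) -> list[int]:
        return [n_track_states(self.track_length, w) for w in self.bin_widths]


def default_speed_grid(
    lo: float = 0.5, hi: float = 20.0, n: int = 30
) -> np.ndarray:
    """Logarithmic replay-speed grid in m/s."""
    return np.geomspace(lo, hi, n)


def speed_to_lag(
    speed_mps: float, bin_width_cm: float, decode_bin_s: float
) -> int | None:
    """Integer decode-bin lag for a replay speed at one scale.

    lag = bin_width / (speed * decode_bin); returns None ("invalid") when
    the rounded lag is < 1 or the relative rounding error exceeds 25%.
    """
    if speed_mps <= 0 or bin_width_cm <= 0 or decode_bin_s <= 0:
        raise ValueError("speed, bin width and decode bin must all be positive")
    raw = bin_width_cm / (speed_mps * 100.0 * decode_bin_s)
    lag = int(round(raw))
    if lag < 1:
        return None
    if abs(lag - raw) / raw >= ROUNDING_TOLERANCE - 1e-12:
        return None
    return lag


def n_track_states(track_length: float, bin_width: float) -> int:
    """Number of states after merging a short trailing bin into its neighbour."""
    n_full = int(np.floor(track_length / bin_width))
    remainder = track_length - n_full * bin_width
    if remainder == 0:
        return n_full
    # a trailing bin shorter than half a bin merges leftward
    return n_full if remainder < bin_width / 2 else n_full + 1


def discretize_track(
    positions: np.ndarray, bin_width: float, track_length: float | None = None
) -> np.ndarray:
    """State labels floor(position / bin_width), right-closed at boundaries.

    A position exactly on a bin boundary belongs to the higher bin; the last
    partial bin is merged into its neighbour when shorter than half a bin.
    """
    x = np.asarray(positions, dtype=float)
    if np.any(x < 0):
        raise ValueError("positions must be non-negative")
    if track_length is None:
        track_length = float(x.max())
    n_states = n_track_states(track_length, bin_width)
    labels = np.floor(x / bin_width).astype(int)
    return np.clip(labels, 0, n_states - 1)


def coarsen_posterior(space: StateSpace, factor: int) -> StateSpace:
    """Sum fine-scale posterior columns into groups of ``factor`` bins.

    A trailing group smaller than half of ``factor`` merges into the previous
    group, mirroring :func:`n_track_states`.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return space
    n_fine = space.n_states
    groups = np.arange(n_fine) // factor
    n_groups = groups.max() + 1
    tail = np.sum(groups == n_groups - 1)
    if n_groups > 1 and tail < factor / 2:
        groups[groups == n_groups - 1] = n_groups - 2
        n_groups -= 1
    M = np.zeros((n_fine, n_groups))
    M[np.arange(n_fine), groups] = 1.0
    return StateSpace(
        values=space.values @ M,
        sample_interval=space.sample_interval,
        state_labels=[f"pos{g}" for g in range(n_groups)],
        segment_ids=space.segment_ids,
        mode="posterior",
    )


@dataclass
class MultiscaleResult:
    """Per-speed combined sequenceness with the per-scale inputs retained."""

    speeds: np.ndarray
    bin_widths: list[float]
    forward: np.ndarray  # (n_speeds,) combined beta_M, NaN where no scale valid
    backward: np.ndarray
    per_scale_forward: np.ndarray  # (n_speeds, n_scales) NaN where invalid
    per_scale_backward: np.ndarray
    per_scale_variance_f: np.ndarray
    per_scale_variance_b: np.ndarray
    excluded: list[tuple[float, float, str]]  # (speed, bin_width, reason)
    first_level: dict = field(default_factory=dict)  # (width, lag) -> EmpiricalTransitions
    lags_used: dict = field(default_factory=dict)  # (speed index, scale index) -> lag
    decode_bin: float = 0.010

    @property
    def difference(self) -> np.ndarray:
        return self.forward - self.backward

    @property
    def total(self) -> np.ndarray:
        """Forward + backward combined strength."""
        return self.forward + self.backward


def _combine(betas: np.ndarray, variances: np.ndarray) -> float:
    """Inverse-variance weighted mean over the valid scales."""
    ok = np.isfinite(betas) & np.isfinite(variances) & (variances > 0)
    if not ok.any():
        return np.nan
    w = 1.0 / variances[ok]
    return float(np.sum(betas[ok] * w) / np.sum(w))


def multiscale_sequenceness(
    spaces: dict[float, StateSpace],
    templates: dict[float, TransitionTemplate | np.ndarray],
    speeds: np.ndarray,
    decode_bin: float = 0.010,
) -> MultiscaleResult:
    """Inverse-variance combination of per-scale sequenceness over speeds.

    ``spaces`` maps bin width (cm) to the posterior StateSpace at that
    discretisation; ``templates`` maps bin width to the forward hypothesis
    matrix at that scale (e.g. the one-step line matrix).
    """
    widths = sorted(spaces)
    speeds = np.asarray(speeds, dtype=float)
    n_speeds, n_scales = speeds.size, len(widths)
    psf = np.full((n_speeds, n_scales), np.nan)
    psb = np.full((n_speeds, n_scales), np.nan)
    vf = np.full((n_speeds, n_scales), np.nan)
    vb = np.full((n_speeds, n_scales), np.nan)
    excluded: list[tuple[float, float, str]] = []
    first_level: dict = {}
    lags_used: dict = {}
    for si, speed in enumerate(speeds):
        for wi, width in enumerate(widths):
            lag = speed_to_lag(speed, width, decode_bin)
            if lag is None:
                excluded.append((float(speed), width, "no valid integer lag"))
                continue
            key = (width, lag)
            if key not in first_level:
                try:
                    # posterior rows sum to one, so the constant already lies
                    # in the predictor span: fit without an intercept
                    first_level[key] = empirical_transitions(
                        spaces[width], lag, FirstLevelDesign(intercept=False)
                    )
                except Exception as exc:  # lag exceeds all events at this scale
                    first_level[key] = None
                    excluded.append((float(speed), width, str(exc)))
            emp = first_level[key]
            if emp is None:
                continue
            res = sequenceness(emp, templates[width])
            psf[si, wi] = res.z_forward[0]
            psb[si, wi] = res.z_backward[0]
            vf[si, wi] = res.variance[0, 0]
            vb[si, wi] = res.variance[0, 1]
            lags_used[(si, wi)] = lag
    forward = np.array([_combine(psf[s], vf[s]) for s in range(n_speeds)])
    backward = np.array([_combine(psb[s], vb[s]) for s in range(n_speeds)])
    return MultiscaleResult(
        speeds=speeds,
        bin_widths=widths,
        forward=forward,
        backward=backward,
        per_scale_forward=psf,
        per_scale_backward=psb,
        per_scale_variance_f=vf,
        per_scale_variance_b=vb,
        excluded=excluded,
        first_level={k: v for k, v in first_level.items() if v is not None},
        lags_used=lags_used,
        decode_bin=decode_bin,
    )


def speed_curve_inference(
    result: MultiscaleResult,
    templates: dict[float, TransitionTemplate | np.ndarray],
    scheme: PermutationScheme,
    alpha: float = 0.05,
    direction: str = "forward",
) -> tuple[float, np.ndarray]:
    """Max-over-speeds permutation threshold for the combined curve.

    Per null sample, one independent state permutation is drawn at each
    scale, the combined curve is recomputed through the same inverse-
    variance pipeline, and its maximum over speeds enters the null.  Returns
    (threshold, null curves (n_perm, n_speeds)).
    """
    widths = result.bin_widths
    rng = np.random.default_rng(scheme.seed)
    per_scale_templates = {}
    for w in widths:
        t = templates[w]
        Tm = t.matrix if isinstance(t, TransitionTemplate) else np.asarray(t, float)
        sub = PermutationScheme(
            mode=scheme.mode,
            sequence_membership=scheme.sequence_membership,
            n_permutations=scheme.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        per_scale_templates[w] = generate_state_permutations(sub, Tm)
    n_speeds = result.speeds.size
    null = np.full((scheme.n_permutations, n_speeds), np.nan)
    col = {"forward": 0, "backward": 1}
    # cache vec(beta) per (scale, lag) once
    vecs = {
        key: emp.betas[0].ravel() for key, emp in result.first_level.items()
    }
    for k in range(scheme.n_permutations):
        betas = np.full((n_speeds, len(widths)), np.nan)
        variances = np.full((n_speeds, len(widths)), np.nan)
        for wi, w in enumerate(widths):
            tpl = per_scale_templates[w][k]
            D = np.column_stack(
                [t.matrix.ravel() for t in build_templates(tpl.matrix)]
            )
            pinv = np.linalg.pinv(D)
            gram_diag = np.diag(np.linalg.inv(D.T @ D))
            dof = D.shape[0] - D.shape[1]
            for si in range(n_speeds):
                lag = result.lags_used.get((si, wi))
                if lag is None:
                    continue
                y = vecs[(w, lag)]
                z = pinv @ y
                resid = y - D @ z
                sigma2 = (resid @ resid) / dof if dof > 0 else 0.0
                var = sigma2 * gram_diag
                if direction == "total":
                    betas[si, wi] = z[0] + z[1]
                    variances[si, wi] = var[0] + var[1]
                else:
                    c = col[direction]
                    betas[si, wi] = z[c]
                    variances[si, wi] = var[c]
        null[k] = [_combine(betas[s], variances[s]) for s in range(n_speeds)]
    finite = np.where(np.isfinite(null), null, -np.inf)
    threshold = max_stat_threshold(finite, alpha, use_abs=scheme.use_abs_null)
    return threshold, null
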