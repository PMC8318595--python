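"""Second-order inference: contrasts, time interactions, ROI bias guards.

Because sequenceness lives inside a linear model, questions that compare
replay across directions, conditions, transitions or time reduce to linear
contrasts c'beta of effect estimates (c = (1, -1) on (Z_F, Z_B) is exactly
the forward-backward difference D) or to interaction regressors: multiplying
each state's time course with z-scored (hence demeaned) time yields an extra
first-level block whose second-level projection measures whether sequence
strength drifts over the session; demeaning renders the interaction
approximately orthogonal to the main effect so both fit in one regression.

When an effect is averaged over a data-selected region of interest (e.g.
speeds where forward + backward replay is significant), only effects
orthogonal to the selection statistic admit unbiased inference: the
difference F - B is orthogonal to the sum F + B, and any time interaction is
orthogonal to a time-averaged selection, but F alone or B alone are not —
``roi_certify`` encodes those rules and refuses biased requests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StateSpace, TransitionTemplate
from .glm import FirstLevelDesign, empirical_transitions, sequenceness

__all__ = [
    "ContrastSpec",
    "RoiSpec",
    "linear_contrast",
    "contrast_permutation_bounds",
    "time_interaction_fit",
    "roi_certify",
    "spatial_trend_weights",
]


@dataclass
class ContrastSpec:
    """Weights over effects; trend contrasts must sum to zero."""

    weights: np.ndarray
    name: str = "contrast"
    trend: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("contrast weights must be finite")
        if self.trend and abs(self.weights.sum()) > 1e-9:
            raise ValueError("trend contrast weights must sum to zero")


def spatial_trend_weights(n_effects: int) -> np.ndarray:
    """Centred integer ramp -k..k (n odd) or half-steps (n even)."""
    w = np.arange(n_effects, dtype=float)
    return w - w.mean()


def linear_contrast(beta_vec: np.ndarray, c: ContrastSpec | np.ndarray) -> float:
    """c' beta.  Inference goes through the same permutation machinery by
    recomputing the contrast on each permuted effect vector."""
    w = c.weights if isinstance(c, ContrastSpec) else np.asarray(c, dtype=float)
    beta_vec = np.asarray(beta_vec, dtype=float)
    if w.shape != beta_vec.shape:
        raise ValueError(
            f"contrast length {w.shape} does not match effects {beta_vec.shape}"
        )
    return float(w @ beta_vec)


def contrast_permutation_bounds(
    observed_effects: np.ndarray,
    null_effects: np.ndarray,
    c: ContrastSpec | np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Two-sided permutation interval for a contrast.

    ``null_effects`` is (n_perm, n_effects): the same effects recomputed
    under each permuted template.  Returns the observed contrast, the
    alpha/2 and 1 - alpha/2 nearest-rank percentiles of the permuted
    contrasts, and a two-sided permutation p-value.
    """
    value = linear_contrast(observed_effects, c)
    w = c.weights if isinstance(c, ContrastSpec) else np.asarray(c, float)
    null = np.asarray(null_effects, dtype=float) @ w
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = (1 + np.sum(np.abs(null) >= abs(value))) / (1 + null.size)
    return {"value": value, "lower": float(lo), "upper": float(hi), "p": float(p)}


def time_interaction_fit(
    space: StateSpace,
    t_f: TransitionTemplate | np.ndarray,
    lag: int,
) -> dict:
    """Sequence main effect and its time modulation in one regression.

    The first level gains a block X(t) .* z-scored time; the second level is
    applied separately to the main-effect betas and the interaction betas.
    Positive time effects mean sequence strength grows over the session.
    """
    design = FirstLevelDesign(time_interaction=True)
    emp = empirical_transitions(space, lag, design)
    main = sequenceness(emp, t_f, sample_interval=space.sample_interval)
    from .core import EmpiricalTransitions

    inter = EmpiricalTransitions(
        betas=emp.extra["time_interaction"], lags=[int(lag)]
    )
    timed = sequenceness(inter, t_f, sample_interval=space.sample_interval)
    return {
        "forward": float(main.z_forward[0]),
        "backward": float(main.z_backward[0]),
        "forward_time": float(timed.z_forward[0]),
        "backward_time": float(timed.z_backward[0]),
        "main": main,
        "time": timed,
    }


@dataclass
class RoiSpec:
    """A data-selected region of interest and the effects safe to test in it.

    ``selection`` names the statistic used to pick the ROI (e.g.
    "forward+backward"); only effects orthogonal to it are certified.
    """

    selection: str
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    certified: list[str] = field(default_factory=list)


_KNOWN_EFFECTS = {
    "forward",
    "backward",
    "forward+backward",
    "forward-backward",
    "spatial_trend",
}


def roi_certify(roi: RoiSpec, effect: str) -> tuple[bool, str]:
    """(allowed, reason) for testing ``effect`` inside the ROI.

    Refusals quote the bias: an effect correlated with the selection
    statistic (including the statistic itself, and F or B alone when the ROI
    was selected on F + B) cannot be tested without selection bias.  Time
    interactions and between-transition contrasts are orthogonal to a
    time/transition-averaged selection and are allowed, as is anything the
    caller has explicitly certified.
    """
    if effect in roi.certified:
        return True, "explicitly certified orthogonal to the selection"
    known = effect in _KNOWN_EFFECTS or effect.startswith("time_x_")
    if not known:
        raise ValueError(f"unknown effect {effect!r}")
    if effect == roi.selection:
        return False, (
            "selection bias: the effect under test is the ROI selection "
            "statistic itself"
        )
    if effect.startswith("time_x_"):
        return True, (
            "time interactions look for differences over time and are "
            "orthogonal to a time-averaged selection"
        )
    if effect == "spatial_trend":
        return True, (
            "between-transition contrasts compare transitions that "
            "contributed equally to the selection"
        )
    if roi.selection == "forward+backward":
        if effect in ("forward", "backward"):
            return False, (
                "selection bias: forward and backward each correlate with "
                "their sum, which defined the ROI; unbiased first-order "
                "inference on either alone is not possible here"
            )
        if effect == "forward-backward":
            return True, "the difference of terms is orthogonal to their sum"
    if roi.selection in ("forward", "backward") and effect == roi.selection:
        return False, "selection bias"
    return False, (
        f"effect {effect!r} is not certified orthogonal to selection "
        f"{roi.selection!r}"
    )
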