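"""End-to-end pipeline orchestration, configuration and result serialization.

``run_pipeline`` ties the stages together on simulated data: generate task
and rest data, train state decoders, decode the rest data, compute the
sequenceness curve over lags, and test it with the state-identity
permutation null.  Every run is deterministic given the config seed and
writes the resolved config next to its results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .decoding import decode_states, train_classifiers
from .glm import empirical_transitions
from .inference import PermutationScheme, group_sequenceness
from .simulate import SimulationConfig, simulate_rest_data, simulate_task_data

logger = logging.getLogger("tdlm")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "save_result_json"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input summary."""


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults mirror the standard analysis: lags 1-60 samples at 100 Hz,
    alpha 0.05, replay-score percentile 95, 100 ms quiet window, track
    scales {5, 10, 20, 40} cm.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_subjects: int = 24
    lags: list[int] = field(default_factory=lambda: list(range(1, 61)))
    alpha: float = 0.05
    n_permutations: int = 399
    permutation_mode: str = "all_states"
    use_abs_null: bool = False
    regularization: tuple[str, float] = ("l1", 0.01)
    null_ratio: float = 1.0
    onset_percentile: float = 95.0
    quiet_window_ms: float = 100.0
    scales_cm: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0)
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        for key, val in list(sim.items()):
            if isinstance(val, np.ndarray):
                sim[key] = val.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if sim and not isinstance(sim, SimulationConfig):
            osc = sim.pop("oscillation", None)
            if osc is not None and isinstance(osc, dict):
                from .simulate import OscillationSpec

                osc = OscillationSpec(**osc)
            for key in ("sensor_covariance", "injected_transition_matrix"):
                if sim.get(key) is not None:
                    sim[key] = np.asarray(sim[key])
            if sim.get("lag_gamma") is not None:
                sim["lag_gamma"] = tuple(sim["lag_gamma"])
            sim = SimulationConfig(oscillation=osc, **sim)
        if d.get("regularization") is not None:
            d["regularization"] = tuple(d["regularization"])
        if d.get("scales_cm") is not None:
            d["scales_cm"] = tuple(d["scales_cm"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(simulation=sim or SimulationConfig(), **{
            k: v for k, v in d.items() if k in known and k != "simulation"
        })

    def save_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def simulate_decoded_subject(
    sim: SimulationConfig,
    seed: int,
    regularization: tuple[str, float] = ("l1", 0.01),
    null_ratio: float = 1.0,
):
    """One simulated subject: task -> classifiers -> decoded rest StateSpace."""
    cfg = sim.with_seed(seed)
    task = simulate_task_data(cfg)
    cls = train_classifiers(
        task.data,
        task.labels,
        regularization,
        null_ratio=null_ratio,
        null_data=task.null_data,
        seed=seed,
    )
    rest, onsets = simulate_rest_data(cfg)
    space = decode_states(rest, cls, sample_interval=1.0 / cfg.sample_rate)
    return space, onsets, cls


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> train -> decode -> sequenceness -> state-permutation test.

    Returns a result bundle (dict); writes JSON/CSV, the permutation audit
    and a sequenceness figure when ``config.output_dir`` is set.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    sim = config.simulation
    T_F = sim.resolved_transitions()
    per_subject = []
    stage = "simulate/train/decode"
    try:
        for s in range(config.n_subjects):
            subj_seed = int(rng.integers(2**31 - 1))
            space, _, _ = simulate_decoded_subject(
                sim, subj_seed, config.regularization, config.null_ratio
            )
            stage = "first-level GLM"
            lag_betas = [
                empirical_transitions(space, lag).betas[0] for lag in config.lags
            ]
            from .core import EmpiricalTransitions

            per_subject.append(
                EmpiricalTransitions(betas=np.stack(lag_betas), lags=list(config.lags))
            )
        stage = "group inference"
        scheme = PermutationScheme(
            mode=config.permutation_mode,
            n_permutations=config.n_permutations,
            seed=config.seed,
            use_abs_null=config.use_abs_null,
        )
        group = group_sequenceness(per_subject, T_F, scheme, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed for config seed {config.seed} "
            f"({config.n_subjects} subjects, {len(config.lags)} lags): {exc}"
        ) from exc
    sample_interval = 1.0 / sim.sample_rate
    result = {
        "version": __version__,
        "seed": config.seed,
        "lags_samples": list(config.lags),
        "lags_ms": [lag * sample_interval * 1e3 for lag in config.lags],
        "group_forward": group.group_forward.tolist(),
        "group_backward": group.group_backward.tolist(),
        "difference": (group.group_forward - group.group_backward).tolist(),
        "threshold": group.threshold,
        "p_value": group.p_value,
        "significant": bool(group.significant),
        "observed_max": group.observed_max,
        "n_permutations": config.n_permutations,
        "elapsed_s": None,
    }
    result["elapsed_s"] = time.time() - t0
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save_yaml(out / "config.yaml")
        save_result_json(result, out / "sequenceness.json")
        _write_curve_csv(result, out / "sequenceness.csv")
        np.savetxt(out / "permutation_null.csv", group.null_forward, delimiter=",")
        try:
            _plot_curve(result, out / "sequenceness.png")
        except Exception:  # headless plotting is best-effort
            logger.exception("figure generation failed")
        logger.info("pipeline finished in %.1fs -> %s", result["elapsed_s"], out)
    return result


def save_result_json(result: dict, path) -> None:
    Path(path).write_text(json.dumps(result, indent=2))


def _write_curve_csv(result: dict, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "lag_samples": result["lags_samples"],
            "lag_ms": result["lags_ms"],
            "z_f": result["group_forward"],
            "z_b": result["group_backward"],
            "d": result["difference"],
        }
    ).to_csv(path, index=False)


def _plot_curve(result: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result["lags_ms"], result["group_forward"], "r-", label="forward $Z_F$")
    ax.plot(result["lags_ms"], result["group_backward"], "b-", label="backward $Z_B$")
    ax.axhline(result["threshold"], ls=":", c="grey", label="permutation threshold")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("sequenceness")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
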