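"""End-to-end spikes-to-sequenceness convenience for linear-track sessions.

Runs the rodent front-end (rate maps per scale, place-cell selection,
candidate-event detection, per-event posterior decoding, event
concatenation) and hands the per-scale posterior state spaces to the
multi-scale combination.  Physical smoothing is held fixed at 10 cm across
scales (sigma = 10 cm / bin width in bins).
"""

from __future__ import annotations

import numpy as np

from .core import StateSpace
from .multiscale import MultiscaleResult, multiscale_sequenceness
from .rodent import (
    EventConfig,
    RateMapConfig,
    classify_place_cells,
    compute_rate_maps,
    concatenate_events,
    decode_posterior,
    detect_candidate_events,
)
from .simulate import TrackSession, line_transition_matrix

__all__ = ["track_session_multiscale", "decode_session_events"]

_SMOOTH_CM = 10.0


def decode_session_events(
    session: TrackSession,
    bin_width: float,
    decode_bin: float = 0.010,
    direction: str = "outbound",
    event_config: EventConfig | None = None,
) -> tuple[StateSpace, np.ndarray, list]:
    """Posterior StateSpace of all candidate events at one spatial scale.

    Returns (concatenated posterior, place-cell mask, events).
    """
    cfg = session.config
    maps = compute_rate_maps(
        session.spike_cells,
        session.spike_times,
        session.position_t,
        session.position_x,
        session.speed,
        cfg.n_cells,
        cfg.track_length,
        RateMapConfig(
            bin_width=bin_width, smoothing_sigma=max(1.0, _SMOOTH_CM / bin_width)
        ),
    )
    place = classify_place_cells(maps)
    if not place.any():
        raise ValueError("no place cells pass the selection criteria")
    cell_idx = np.flatnonzero(place)
    remap = -np.ones(cfg.n_cells, dtype=int)
    remap[cell_idx] = np.arange(cell_idx.size)
    rest_cells, rest_times = session.rest_spikes()
    keep = np.isin(rest_cells, cell_idx)
    rest_cells, rest_times = remap[rest_cells[keep]], rest_times[keep]
    events = detect_candidate_events(
        rest_cells,
        rest_times,
        int(place.sum()),
        session.run_end,
        session.run_end + cfg.rest_duration,
        event_config,
    )
    if not events:
        return None, place, []
    dir_maps = [maps[direction][c] for c in cell_idx]
    posteriors = []
    for ev in events:
        posteriors.append(
            decode_posterior(
                rest_cells, rest_times, dir_maps, ev.start, ev.end, decode_bin
            )
        )
    return concatenate_events(posteriors), place, events


def track_session_multiscale(
    session: TrackSession,
    bin_widths: list[float],
    speeds: np.ndarray,
    decode_bin: float = 0.010,
    direction: str = "outbound",
) -> tuple[MultiscaleResult, dict]:
    """Spikes -> per-scale posteriors -> inverse-variance combined curve.

    Returns (result, per-scale forward templates) so the permutation
    machinery can be applied downstream.
    """
    spaces: dict[float, StateSpace] = {}
    templates: dict[float, np.ndarray] = {}
    for width in bin_widths:
        space, _, events = decode_session_events(
            session, width, decode_bin, direction
        )
        if space is None:
            raise ValueError("no candidate events detected in this session")
        spaces[width] = space
        templates[width] = line_transition_matrix(space.n_states)
    result = multiscale_sequenceness(spaces, templates, speeds, decode_bin)
    return result, templates
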