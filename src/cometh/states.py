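"""Discretization of MC ratios into methylation states and forward distances.

The MC ratio in [0, 1] is cut into four states: A = [0, 0.25) no/low
methylation, B = [0.25, 0.5) low/partial, C = [0.5, 0.75) partial/high,
D = [0.75, 1] high/full (the upper bound is closed).  Sites whose coverage
falls below a threshold (default 3X) or whose ratio is missing are labelled
NA.  The forward distance of a site is the bp gap to the next CpG on the
same strand; the last site of a track has no forward distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .track import NA_STATE, STATES, MethylationTrack


@dataclass(frozen=True)
class StateAssignmentConfig:
    """Parameters of the discretization.

    min_coverage
        Sites with fewer reads are labelled NA (default 3, i.e. <3X -> NA).
        Set to 0 to disable the coverage filter.
    boundaries
        Interior interval edges splitting [0, 1] into the four states.
        Each edge belongs to the state on its right (half-open intervals);
        a ratio of exactly 1 is in the last state.
    """

    min_coverage: int = 3
    boundaries: tuple[float, float, float] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if self.min_coverage < 0:
            raise ValidationError("min_coverage must be >= 0")
        b = self.boundaries
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValidationError(
                "state boundaries must be strictly increasing within (0, 1)"
            )


DEFAULT_CONFIG = StateAssignmentConfig()


def assign_state(
    mc_ratio: float | None,
    coverage: int,
    config: StateAssignmentConfig = DEFAULT_CONFIG,
) -> str:
    """Assign the methylation state of a single site.

    Returns one of ``"A"``, ``"B"``, ``"C"``, ``"D"`` or ``"NA"``.  NA is
    returned when the ratio is missing or coverage < ``config.min_coverage``.
    """
    missing = mc_ratio is None or (isinstance(mc_ratio, float) and np.isnan(mc_ratio))
    if not missing and not 0.0 <= mc_ratio <= 1.0:
        raise ValidationError(f"mc_ratio {mc_ratio} outside [0, 1]")
    if missing or coverage < config.min_coverage:
        return NA_STATE
    idx = int(np.searchsorted(config.boundaries, mc_ratio, side="right"))
    return STATES[idx]


def annotate_states(
    track: MethylationTrack,
    config: StateAssignmentConfig = DEFAULT_CONFIG,
) -> MethylationTrack:
    """Return a copy of the track with a ``state`` column.

    Site order and count are unchanged; every site receives exactly one
    state.  Vectorized equivalent of mapping :func:`assign_state` over the
    rows.
    """
    ratio = track.df["mc_ratio"].to_numpy(dtype=float)
    cov = track.df["coverage"].to_numpy()
    present = ~np.isnan(ratio)
    if ((ratio[present] < 0) | (ratio[present] > 1)).any():
        raise ValidationError("mc_ratio outside [0, 1]")
    idx = np.searchsorted(config.boundaries, np.where(present, ratio, 0.0), side="right")
    states = np.array(STATES, dtype=object)[idx]
    states[~present | (cov < config.min_coverage)] = NA_STATE
    df = track.df.copy()
    df["state"] = states
    return MethylationTrack(track.sample_id, track.chrom, df)


def compute_forward_distances(track: MethylationTrack) -> MethylationTrack:
    """Return a copy of the track with a ``distance`` column.

    ``distance[i] = position[i+1] - position[i]``; the last site's distance
    is NaN.  Distances are computed for every site regardless of its state
    (NA sites included).
    """
    pos = track.positions
    dist = np.full(len(pos), np.nan)
    if len(pos) > 1:
        dist[:-1] = np.diff(pos).astype(float)
    df = track.df.copy()
    df["distance"] = dist
    return MethylationTrack(track.sample_id, track.chrom, df)


def annotate(
    track: MethylationTrack,
    config: StateAssignmentConfig = DEFAULT_CONFIG,
) -> MethylationTrack:
    """State assignment and forward distances in one step."""
    return compute_forward_distances(annotate_states(track, config))
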