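"""Trajectory statistics: chemotactic index, migration speed, aggregation.

The chemotactic index (C.I.) of a track is the signed component of its net
displacement along the up-gradient axis divided by its total path length:
+1 for a straight run up the gradient, 0 for undirected wander, negative for
net movement down-gradient.  Migration speed is total path length over the
track's own duration (pauses count in the denominator).  Per-condition
aggregates are mean ± SEM over tracks, matching how per-patient values are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import Track

__all__ = [
    "UndefinedMetricError",
    "MetricsSummary",
    "chemotactic_index",
    "migration_speed",
    "summarize_condition",
    "per_track_table",
]

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """A metric is undefined for this track (e.g. zero path length)."""


@dataclass(frozen=True)
class MetricsSummary:
    """Per-condition aggregate: mean ± SEM of C.I. and speed over tracks."""

    condition_label: str
    n_tracks: int
    mean_ci: float
    sem_ci: float
    mean_speed: float
    sem_speed: float
    n_excluded: int = 0


def _path_length(track: Track) -> float:
    segs = np.diff(track.xy, axis=0)
    return float(np.sum(np.linalg.norm(segs, axis=1)))


def chemotactic_index(track: Track, gradient_axis) -> float:
    """Signed net displacement along ``gradient_axis`` over total path length.

    Raises :class:`UndefinedMetricError` for a stationary track (zero path
    length), which callers exclude from aggregation with a logged count.
    """
    if len(track) < 2:
        raise UndefinedMetricError("track needs at least 2 samples")
    axis = np.asarray(gradient_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    path = _path_length(track)
    if path == 0.0:
        raise UndefinedMetricError("stationary track: C.I. undefined")
    net = track.xy[-1] - track.xy[0]
    return float(np.dot(net, axis) / path)


def migration_speed(track: Track) -> float:
    """Total path length divided by the track's duration, µm/s."""
    if len(track) < 2:
        raise UndefinedMetricError("track needs at least 2 samples")
    duration = track.t[-1] - track.t[0]
    return _path_length(track) / float(duration)


def summarize_condition(tracks: list[Track], gradient_axis, label: str = "") -> MetricsSummary:
    """Aggregate per-track C.I. and speed into a condition summary.

    Tracks with undefined C.I. (stationary) are excluded and counted.  SEM is
    the sample sd over tracks divided by √n (0 when n = 1).
    """
    cis, speeds, excluded = [], [], 0
    for tr in tracks:
        try:
            ci = chemotactic_index(tr, gradient_axis)
        except UndefinedMetricError:
            excluded += 1
            continue
        cis.append(ci)
        speeds.append(migration_speed(tr))
    if not cis:
        raise ValueError(f"no valid tracks for condition {label!r}")
    if excluded:
        log.info("condition %s: excluded %d stationary track(s)", label, excluded)
    cis_a, speeds_a = np.asarray(cis), np.asarray(speeds)
    n = cis_a.size

    def sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return MetricsSummary(
        condition_label=label,
        n_tracks=n,
        mean_ci=float(np.mean(cis_a)),
        sem_ci=sem(cis_a),
        mean_speed=float(np.mean(speeds_a)),
        sem_speed=sem(speeds_a),
        n_excluded=excluded,
    )


def per_track_table(tracks: list[Track], gradient_axis):
    """Per-track metrics as a DataFrame (track_id, ci, speed_um_s).

    Stationary tracks appear with NaN C.I. and are flagged ``excluded``.
    """
    import pandas as pd

    rows = []
    for tr in tracks:
        try:
            ci = chemotactic_index(tr, gradient_axis)
            speed = migration_speed(tr)
            rows.append((tr.track_id, ci, speed, False))
        except UndefinedMetricError:
            rows.append((tr.track_id, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=["track_id", "ci", "speed_um_s", "excluded"])
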