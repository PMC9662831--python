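"""Sliding-window classification of trajectory segments.

Oscillatory (processive) and regularly positioned motion are separable by
the sign of the velocity autocorrelation at lag 1: spring-like motion gives
a negative value at a lag equal to the sampling time, processive back-and-
forth motion a positive one.  A window slides along the track, the lag-1
velocity autocorrelation is computed inside it, and the window's centre
point is labelled accordingly.  Runs of at least ``min_run`` identical
labels form segments; shorter runs and window-edge points are undetermined.
Defaults: window 12, min_run 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import Trajectory

__all__ = [
    "OSCILLATORY",
    "REGULAR",
    "UNDETERMINED",
    "SegmentLabels",
    "sliding_window_labels",
    "segments_from_labels",
    "oscillatory_fraction_by_length",
]

OSCILLATORY = "oscillatory"
REGULAR = "regular"
UNDETERMINED = "undetermined"


@dataclass
class SegmentLabels:
    """Per-timepoint labels and the maximal qualifying segments.

    ``labels[i]`` ∈ {oscillatory, regular, undetermined}; ``segments`` are
    (start, end, label) with end inclusive, each a run of >= min_run
    identical determined labels.
    """

    labels: list[str]
    segments: list[tuple[int, int, str]]
    window: int
    min_run: int


def _lag1_velocity_autocorr(x: np.ndarray) -> float:
    """Mean-subtracted, variance-normalised lag-1 autocorrelation of the
    stepwise velocities inside one window."""
    v = np.diff(x)
    v = v - v.mean()
    denom = float(np.dot(v, v))
    if denom == 0.0:
        return 0.0
    return float(np.dot(v[:-1], v[1:]) / denom)


def sliding_window_labels(
    traj: Trajectory | np.ndarray, window: int = 12, plasmid: int = 0
) -> list[str]:
    """Label each timepoint by the lag-1 velocity autocorrelation of the
    window centred on it: positive → oscillatory, otherwise → regular.

    The centre of an even window of size w is index w//2 within the window.
    Points too close to either end for a full window are undetermined; a
    track shorter than the window is entirely undetermined.
    """
    if isinstance(traj, Trajectory):
        x = traj.series(plasmid)
    else:
        x = np.asarray(traj, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    labels = [UNDETERMINED] * n
    if n < window:
        return labels
    for start in range(0, n - window + 1):
        ac1 = _lag1_velocity_autocorr(x[start : start + window])
        labels[start + window // 2] = OSCILLATORY if ac1 > 0.0 else REGULAR
    return labels


def segments_from_labels(
    labels: Sequence[str], min_run: int = 6, window: int = 12
) -> SegmentLabels:
    """Keep maximal same-label runs of length >= min_run as segments;
    relabel shorter determined runs as undetermined."""
    labels = list(labels)
    n = len(labels)
    segments: list[tuple[int, int, str]] = []
    out = list(labels)
    i = 0
    while i < n:
        lab = labels[i]
        j = i
        while j < n and labels[j] == lab:
            j += 1
        if lab != UNDETERMINED:
            if j - i >= min_run:
                segments.append((i, j - 1, lab))
            else:
                for k in range(i, j):
                    out[k] = UNDETERMINED
        i = j
    return SegmentLabels(labels=out, segments=segments, window=window, min_run=min_run)


def classify(
    traj: Trajectory | np.ndarray,
    window: int = 12,
    min_run: int = 6,
    plasmid: int = 0,
) -> SegmentLabels:
    """Convenience: sliding-window labels then segment formation."""
    labels = sliding_window_labels(traj, window=window, plasmid=plasmid)
    return segments_from_labels(labels, min_run=min_run, window=window)


def oscillatory_fraction_by_length(
    items: Iterable[tuple[Trajectory | np.ndarray, float]],
    length_bins: Sequence[float],
    window: int = 12,
    min_run: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of segment timepoints labelled oscillatory, binned by cell
    length.

    ``items`` yields (trajectory, cell_length_um) pairs; every timepoint in a
    qualifying segment contributes to its cell-length bin.  Undetermined
    points are excluded from the denominators.  Empty bins are NaN.
    Returns (bin_centers, fraction).
    """
    edges = np.asarray(length_bins, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least 2 bin edges")
    osc = np.zeros(edges.size - 1)
    tot = np.zeros(edges.size - 1)
    for traj, length in items:
        b = int(np.digitize(length, edges)) - 1
        if not (0 <= b < edges.size - 1):
            continue
        seg = classify(traj, window=window, min_run=min_run)
        for lab in seg.labels:
            if lab == UNDETERMINED:
                continue
            tot[b] += 1
            if lab == OSCILLATORY:
                osc[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, osc / np.maximum(tot, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, frac
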