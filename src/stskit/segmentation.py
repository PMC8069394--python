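"""Sit-to-stand cycle segmentation.

The spine-middle joint's vertical trajectory rises to a peak each time the
subject stands up and falls back to a local minimum on sitting down. Peaks
are counted as sit-ups (NSU); the stretch from a local minimum to the next
peak is an *ascending* phase, from a peak to the next minimum a *descending*
phase.

Peak detection runs on a lightly smoothed trajectory (centered moving
average, 0.5 s by default) with a prominence floor and a minimum peak
separation; all three are configurable. Valleys are placed at the global
minimum between consecutive peaks, before the first peak, and — when the
trajectory genuinely descends afterwards — after the last peak, so the
extremum sequence strictly alternates valley/peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .errors import ContractError, DataQualityError
from .joints import SPINE_MID
from .session_io import Session

__all__ = [
    "SegmentationParams",
    "VerticalTrajectory",
    "Extremum",
    "PhaseSegment",
    "vertical_trajectory",
    "find_extrema",
    "partition_phases",
    "count_sit_ups",
    "segment_session",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    ``smoothing_window_s``: centered moving-average window (0 disables).
    ``min_prominence_m``: minimum peak prominence; seat-to-stand excursions
    are 0.2-0.4 m, so 0.10 m rejects sway and sensor jitter.
    ``min_separation_s``: minimum spacing between retained peaks.
    ``max_dropout_frac``: tolerated fraction of frames with the spine-middle
    joint untracked before the session is refused.
    """

    smoothing_window_s: float = 0.5
    min_prominence_m: float = 0.10
    min_separation_s: float = 1.5
    max_dropout_frac: float = 0.10


@dataclass
class VerticalTrajectory:
    """Spine-middle height over time: smoothed (``z_m``) and raw series."""

    t_s: np.ndarray
    z_m: np.ndarray
    raw_z_m: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t_s) == len(self.z_m) == len(self.raw_z_m)):
            raise ContractError("trajectory series must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ContractError("trajectory times must be strictly increasing")

    @property
    def sample_period_s(self) -> float:
        return float(np.median(np.diff(self.t_s)))


@dataclass(frozen=True)
class Extremum:
    kind: Literal["peak", "valley"]
    index: int
    t_s: float
    z_m: float


@dataclass(frozen=True)
class PhaseSegment:
    """One ascending (valley→peak) or descending (peak→valley) half-cycle.

    ``frame_span`` is the half-open [first, last) sample-index range; the
    shared boundary extremum belongs to the following segment's span.
    """

    kind: Literal["ascending", "descending"]
    start: Extremum
    end: Extremum
    frame_span: tuple[int, int]

    def __post_init__(self) -> None:
        expected = ("valley", "peak") if self.kind == "ascending" else ("peak", "valley")
        if (self.start.kind, self.end.kind) != expected:
            raise ContractError(
                f"{self.kind} segment must run {expected[0]} → {expected[1]}"
            )
        if not self.start.t_s < self.end.t_s:
            raise ContractError("segment start must precede its end")

    @property
    def duration_s(self) -> float:
        return self.end.t_s - self.start.t_s


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def vertical_trajectory(
    session: Session,
    smoothing_window_s: float = 0.5,
    max_dropout_frac: float = 0.10,
) -> VerticalTrajectory:
    """Extract the spine-middle vertical trajectory.

    Untracked gaps are linearly interpolated in time; smoothing is a centered
    moving average over ``smoothing_window_s`` (0 keeps the raw series).

    Raises :class:`DataQualityError` when the spine-middle joint is untracked
    in more than ``max_dropout_frac`` of the frames.
    """
    t = session.t_s
    z = session.positions()[:, SPINE_MID, 2].astype(float)
    missing = ~np.isfinite(z)
    frac = missing.mean()
    if frac > max_dropout_frac:
        raise DataQualityError(
            f"spine-middle joint untracked in {frac:.0%} of frames "
            f"(limit {max_dropout_frac:.0%})"
        )
    raw = z.copy()
    if missing.any():
        z = z.copy()
        z[missing] = np.interp(t[missing], t[~missing], z[~missing])
        raw = z.copy()

    if smoothing_window_s > 0:
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        window = max(1, int(round(smoothing_window_s / dt)))
        smooth = _moving_average(z, window)
    else:
        smooth = z.copy()
    return VerticalTrajectory(t_s=t, z_m=smooth, raw_z_m=raw)


def _argmin_first(z: np.ndarray, lo: int, hi: int) -> int:
    """Index of the earliest minimum of z[lo:hi] (ties broken to the left)."""
    return lo + int(np.argmin(z[lo:hi]))


def find_extrema(
    traj: VerticalTrajectory,
    min_prominence_m: float = 0.10,
    min_separation_s: float = 1.5,
) -> list[Extremum]:
    """Detect stand-up peaks and interleaved sitting valleys.

    Peaks must clear ``min_prominence_m`` and be at least ``min_separation_s``
    apart (the higher of two close peaks wins). On flat plateaus the earliest
    sample is used. A valley is inserted at the global minimum between
    consecutive peaks, one before the first peak, and one after the last peak
    when the trajectory drops at least the prominence floor again. The result
    strictly alternates valley/peak.
    """
    z = traj.z_m
    if len(z) < 3:
        raise ContractError("trajectory must contain at least 3 samples")
    dt = traj.sample_period_s
    distance = max(1, int(round(min_separation_s / dt)))
    peaks, props = find_peaks(
        z,
        prominence=min_prominence_m,
        distance=distance,
        plateau_size=(1, None),
    )
    if len(peaks) == 0:
        return []
    # plateau tie-break: earliest sample of a flat peak
    peaks = props["left_edges"]

    extrema: list[Extremum] = []

    def add(kind: str, idx: int) -> None:
        extrema.append(Extremum(kind=kind, index=int(idx), t_s=float(traj.t_s[idx]), z_m=float(z[idx])))

    first = int(peaks[0])
    if first > 0:
        add("valley", _argmin_first(z, 0, first))
    for left, right in zip(peaks[:-1], peaks[1:]):
        add("peak", left)
        add("valley", _argmin_first(z, int(left) + 1, int(right)))
    add("peak", peaks[-1])
    last = int(peaks[-1])
    if last < len(z) - 1:
        vi = _argmin_first(z, last + 1, len(z))
        if z[last] - z[vi] >= min_prominence_m:
            add("valley", vi)
    return extrema


def partition_phases(extrema: list[Extremum]) -> list[PhaseSegment]:
    """Pair alternating extrema into ascending/descending phase segments."""
    for a, b in zip(extrema[:-1], extrema[1:]):
        if a.kind == b.kind:
            raise ContractError("extrema must strictly alternate valley/peak")
        if not a.t_s < b.t_s:
            raise ContractError("extrema must be time-ordered")
    segments: list[PhaseSegment] = []
    for a, b in zip(extrema[:-1], extrema[1:]):
        kind = "ascending" if a.kind == "valley" else "descending"
        segments.append(
            PhaseSegment(kind=kind, start=a, end=b, frame_span=(a.index, b.index))
        )
    return segments


def count_sit_ups(extrema: list[Extremum]) -> int:
    """NSU: number of stand-up peaks detected in the session."""
    return sum(1 for e in extrema if e.kind == "peak")


def segment_session(
    session: Session, params: SegmentationParams | None = None
) -> tuple[VerticalTrajectory, list[Extremum], list[PhaseSegment]]:
    """Convenience pipeline: trajectory → extrema → phase segments."""
    params = params or SegmentationParams()
    traj = vertical_trajectory(
        session,
        smoothing_window_s=params.smoothing_window_s,
        max_dropout_frac=params.max_dropout_frac,
    )
    extrema = find_extrema(
        traj,
        min_prominence_m=params.min_prominence_m,
        min_separation_s=params.min_separation_s,
    )
    return traj, extrema, partition_phases(extrema)
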