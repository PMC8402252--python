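"""Preprocessing of motion-capture recordings.

Covers four stages: resampling 120 Hz recordings to the common 60 Hz rate
(with anti-alias filtering, since spectral features later use energy up to
29 Hz), detecting turns from the pelvis heading rate, detecting foot-ground
contacts from foot height and speed, and cutting the recording into
straight-gait segments with turns excluded.

Coordinate convention matches :mod:`gaitclass.synthetic`: y vertical,
gait plane x-z, positions in metres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import binary_closing, minimum_filter1d, uniform_filter1d

from .synthetic import (
    HORIZONTAL_AXES,
    LEFT_FOOT,
    PELVIS,
    RIGHT_FOOT,
    VERTICAL_AXIS,
    MotionRecording,
)

__all__ = [
    "NoGaitDetectedError",
    "FootContactSeries",
    "GaitSegment",
    "subsample_to_60hz",
    "detect_turns",
    "detect_foot_contacts",
    "segment_straight_walks",
]


class NoGaitDetectedError(RuntimeError):
    """Raised when a recording contains no detectable stepping."""


@dataclass
class FootContactSeries:
    """Per-foot strictly increasing sample indices of stance onsets."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("left", "right"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} contact indices must be strictly increasing")
            setattr(self, name, idx)

    def pooled(self) -> list[tuple[int, str]]:
        """Contacts of both feet merged in time order (ties: left first)."""
        events = [(int(i), "left") for i in self.left] + [
            (int(i), "right") for i in self.right
        ]
        return sorted(events)

    def pooled_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.pooled()], dtype=int)

    @property
    def n_total(self) -> int:
        return len(self.left) + len(self.right)

    def restrict(self, start: int, end: int) -> "FootContactSeries":
        return FootContactSeries(
            left=self.left[(self.left >= start) & (self.left < end)],
            right=self.right[(self.right >= start) & (self.right < end)],
        )


@dataclass
class GaitSegment:
    """One straight-walk slice ``[start, end)`` of a recording."""

    recording: MotionRecording
    start: int
    end: int
    contacts: FootContactSeries

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must satisfy end > start")

    @property
    def participant_id(self) -> str:
        return self.recording.participant_id

    @property
    def label(self) -> str:
        return self.recording.label

    @property
    def severity(self) -> float:
        return self.recording.severity

    @property
    def sampling_rate(self) -> int:
        return self.recording.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def joint(self, name: str) -> np.ndarray:
        return self.recording.joints[name][self.start : self.end]


def subsample_to_60hz(recording: MotionRecording) -> MotionRecording:
    """Return the recording at 60 Hz.

    60 Hz input is returned unchanged.  120 Hz input is zero-phase FIR
    low-pass filtered with a 29 Hz cutoff (below the new Nyquist, matching
    the 29 Hz maximum valid analysis frequency) and decimated by two.
    """
    if recording.sampling_rate == 60:
        return recording
    if recording.sampling_rate != 120:
        raise ValueError(f"unsupported sampling rate {recording.sampling_rate}")
    n = recording.n_samples
    numtaps = 101
    taps = signal.firwin(numtaps, cutoff=29.0, fs=120.0)
    joints = {}
    for name, pos in recording.joints.items():
        if n > 3 * numtaps:
            filtered = signal.filtfilt(taps, [1.0], pos, axis=0)
        else:  # too short for stable zero-phase filtering; decimate directly
            filtered = pos
        joints[name] = filtered[::2].copy()
    return MotionRecording(
        participant_id=recording.participant_id,
        label=recording.label,
        severity=recording.severity,
        sampling_rate=60,
        joints=joints,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_turns(
    recording: MotionRecording,
    window_s: float = 0.5,
    heading_rate_threshold_deg_s: float = 45.0,
    heading_lowpass_hz: float = 0.5,
    min_speed: float = 0.05,
    merge_gap_s: float = 1.5,
    min_turn_s: float = 0.3,
) -> list[tuple[int, int]]:
    """Detect turning intervals from the pelvis heading rate.

    The horizontal pelvis track is low-pass filtered well below step
    frequency (so lateral sway does not masquerade as heading change), the
    heading is the angle of the resulting velocity, and samples whose
    absolute heading rate exceeds the threshold — at walking speed — are
    flagged.  Flagged runs closer than ``merge_gap_s`` are merged (a single
    180-degree reversal can dip briefly below threshold mid-turn), runs
    shorter than ``min_turn_s`` are discarded (gait-onset transients), and
    the survivors are dilated by ``window_s`` on each side.

    A recording too short to filter returns an empty list.
    """
    fs = recording.sampling_rate
    pelvis = recording.joints[PELVIS][:, list(HORIZONTAL_AXES)]
    n = len(pelvis)
    window = max(1, round(window_s * fs))
    sos = signal.butter(2, heading_lowpass_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * 2 + 1)
    if n <= max(2 * window, padlen + 1):
        return []
    smooth = signal.sosfiltfilt(sos, pelvis, axis=0)
    velocity = np.gradient(smooth, axis=0) * fs
    speed = np.hypot(velocity[:, 0], velocity[:, 1])
    heading = np.unwrap(np.arctan2(velocity[:, 1], velocity[:, 0]))
    rate = np.degrees(np.abs(np.gradient(heading))) * fs
    rate[speed < min_speed] = 0.0
    mask = rate > heading_rate_threshold_deg_s
    if not mask.any():
        return []
    merge_gap = max(1, round(merge_gap_s * fs))
    mask = binary_closing(mask, structure=np.ones(merge_gap + 1, dtype=bool))
    min_turn = max(1, round(min_turn_s * fs))
    intervals = [(s, e) for s, e in _runs(mask) if e - s >= min_turn]
    return [(max(0, s - window), min(n, e + window)) for s, e in intervals]


def detect_foot_contacts(
    recording: MotionRecording,
    contact_height_fraction: float = 0.1,
    speed_threshold: float = 0.05,
    smooth_samples: int = 5,
    merge_gap: int = 2,
) -> FootContactSeries:
    """Detect stance onsets of both feet.

    Per foot: positions are smoothed with a zero-phase moving average,
    stance is flagged where the vertical coordinate falls below
    ``minimum + contact_height_fraction * range`` *and* the foot speed
    falls below ``speed_threshold`` (m/s); gaps up to ``merge_gap`` samples
    inside a stance run are closed; the first sample of each run is the
    onset.

    Raises :class:`NoGaitDetectedError` when both feet yield fewer than two
    onsets (e.g. a stationary standing recording).
    """
    fs = recording.sampling_rate
    onsets: dict[str, np.ndarray] = {}
    for side, joint in (("left", LEFT_FOOT), ("right", RIGHT_FOOT)):
        pos = recording.joints[joint]
        smooth = uniform_filter1d(pos, size=smooth_samples, axis=0, mode="nearest")
        height = smooth[:, VERTICAL_AXIS]
        velocity = np.gradient(smooth, axis=0) * fs
        speed = np.linalg.norm(velocity, axis=1)
        # forward-looking minimum: the zero-phase position smoothing delays
        # apparent stillness by ~2 samples, so a sample counts as slow when
        # the speed estimate drops below threshold within the next 2 samples
        speed = minimum_filter1d(speed, size=3, origin=-1, mode="nearest")
        h_lo, h_hi = height.min(), height.max()
        low = height <= h_lo + contact_height_fraction * (h_hi - h_lo)
        mask = low & (speed <= speed_threshold)
        if merge_gap > 0 and mask.any():
            mask = binary_closing(
                mask, structure=np.ones(merge_gap + 1, dtype=bool)
            )
        prev = np.concatenate([[False], mask[:-1]])
        onsets[side] = np.flatnonzero(mask & ~prev)
    series = FootContactSeries(left=onsets["left"], right=onsets["right"])
    if len(series.left) < 2 and len(series.right) < 2:
        raise NoGaitDetectedError(
            "no gait detected: fewer than 2 stance onsets on both feet"
        )
    return series


def segment_straight_walks(
    recording: MotionRecording,
    turns: list[tuple[int, int]],
    contacts: FootContactSeries,
    min_contacts: int = 4,
) -> list[GaitSegment]:
    """Cut the complement of the turn intervals into straight-gait segments.

    Each maximal turn-free interval is retained when it contains at least
    ``min_contacts`` stance onsets pooled over both feet; the contact series
    is restricted to the segment and recording metadata propagates.
    """
    n = recording.n_samples
    turns = sorted(turns)
    segments: list[GaitSegment] = []
    cursor = 0
    bounds = list(turns) + [(n, n)]
    for turn_start, turn_end in bounds:
        start, end = cursor, min(turn_start, n)
        cursor = max(cursor, turn_end)
        if end <= start:
            continue
        restricted = contacts.restrict(start, end)
        if restricted.n_total >= min_contacts:
            segments.append(
                GaitSegment(recording=recording, start=start, end=end, contacts=restricted)
            )
    return segments
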