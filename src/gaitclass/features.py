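"""Six gait features computed per straight-walk segment.

The feature set parametrizes each segment of straight gait with:

* **cadence** — steps per minute, from pooled foot contacts,
* **step length (SL)** — median 3-D Euclidean distance between adjacent
  foot contacts (feet pooled),
* **step trajectory (ST)** — median arc length of the swinging foot's
  sampled path between adjacent contacts,
* **relative step length** — SL/ST, a step-optimality ratio in (0, 1]
  (the chord never exceeds the arc),
* **COM STD** — standard deviation of the pelvis (centre-of-mass proxy)
  lateral coordinate after rotating the horizontal track so that forward
  progress lies along the first principal axis,
* **band energies** — pelvis acceleration power integrated over the
  [3, 15] Hz and [15, 29] Hz bands (length-normalised periodogram with a
  Hann window); 29 Hz is the maximum valid frequency at the 60 Hz rate.

Ataxic gait raises COM STD, step-length variability and high-band energy
and lowers cadence, which is what makes these six numbers discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .preprocess import GaitSegment
from .synthetic import HORIZONTAL_AXES, PELVIS

__all__ = [
    "FeatureError",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "step_cadence",
    "step_length",
    "step_trajectory",
    "relative_step_length",
    "com_std",
    "band_energy",
    "extract_features",
    "features_table",
    "LOW_BAND",
    "HIGH_BAND",
]

LOW_BAND = (3.0, 15.0)
HIGH_BAND = (15.0, 29.0)

#: Fixed column order of the feature table (metadata first).
FEATURE_COLUMNS = [
    "cadence",
    "step_length",
    "step_trajectory",
    "relative_step_length",
    "com_std",
    "energy_low",
    "energy_high",
]
META_COLUMNS = ["participant_id", "label", "severity"]


class FeatureError(ValueError):
    """A segment violates a feature's precondition."""


@dataclass(frozen=True)
class FeatureVector:
    cadence: float
    step_length: float
    step_trajectory: float
    relative_step_length: float
    com_std: float
    energy_low: float
    energy_high: float
    participant_id: str
    label: str
    severity: float

    def validate(self) -> None:
        values = [
            self.cadence,
            self.step_length,
            self.step_trajectory,
            self.relative_step_length,
            self.com_std,
            self.energy_low,
            self.energy_high,
        ]
        if not all(np.isfinite(values)):
            raise FeatureError("feature vector contains non-finite values")
        if self.cadence <= 0:
            raise FeatureError("cadence must be positive")
        if not (0 < self.relative_step_length <= 1 + 1e-9):
            raise FeatureError("relative_step_length must lie in (0, 1]")
        if self.energy_low < 0 or self.energy_high < 0:
            raise FeatureError("band energies must be non-negative")


def _pooled_events(segment: GaitSegment) -> list[tuple[int, str]]:
    events = segment.contacts.pooled()
    if len(events) < 2:
        raise FeatureError("insufficient steps: fewer than 2 pooled contacts")
    return events


def _contact_position(segment: GaitSegment, index: int, side: str) -> np.ndarray:
    return segment.recording.joints[f"{side}_foot"][index]


def step_cadence(segment: GaitSegment) -> float:
    """Steps per minute: (pooled contacts - 1) / elapsed time, unbiased on
    short segments because intervals, not events, are counted."""
    events = _pooled_events(segment)
    span = (events[-1][0] - events[0][0]) / segment.sampling_rate
    if span <= 0:
        raise FeatureError("insufficient steps: contacts span zero time")
    return (len(events) - 1) / span * 60.0


def _step_distances(segment: GaitSegment) -> np.ndarray:
    events = _pooled_events(segment)
    positions = np.array(
        [_contact_position(segment, idx, side) for idx, side in events]
    )
    return np.linalg.norm(np.diff(positions, axis=0), axis=1)


def step_length(segment: GaitSegment) -> float:
    """Median 3-D distance between adjacent pooled foot contacts (metres)."""
    return float(np.median(_step_distances(segment)))


def step_trajectory(segment: GaitSegment) -> float:
    """Median arc length of the swinging foot between adjacent contacts.

    For the step ending at contact ``i+1``, the swinging foot is the one
    that lands there; its arc is the polyline length of its sampled path
    from the previous pooled contact instant to the landing.
    """
    events = _pooled_events(segment)
    arcs = []
    for (start, _), (end, side) in zip(events[:-1], events[1:]):
        path = segment.recording.joints[f"{side}_foot"][start : end + 1]
        arcs.append(float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum()))
    return float(np.median(arcs))


def relative_step_length(sl: float, st: float) -> float:
    """SL/ST; 1 means the foot took the straight-line (optimal) path."""
    if st <= 0:
        raise FeatureError("step trajectory must be positive")
    if sl > st + 1e-9:
        raise FeatureError(
            f"invariant violation: step length {sl} exceeds trajectory {st}"
        )
    return min(sl / st, 1.0)


def com_std(segment: GaitSegment) -> float:
    """SD (metres) of the pelvis lateral coordinate, the body-sway measure.

    The horizontal pelvis track is rotated so that forward progress is the
    first principal axis; the SD of the orthogonal (lateral) coordinate is
    returned.  Population SD (ddof=0).
    """
    pelvis = segment.joint(PELVIS)[:, list(HORIZONTAL_AXES)]
    if len(pelvis) < 2:
        raise FeatureError("segment too short for COM STD")
    centred = pelvis - pelvis.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    lateral = centred @ vt[1]
    return float(lateral.std())


def band_energy(
    segment: GaitSegment,
    band: tuple[float, float],
    joint: str = PELVIS,
) -> float:
    """Pelvis-acceleration power in ``band`` (Hz), length-normalised.

    Acceleration is the second-order central finite difference of the
    joint position along each axis; per axis, the periodogram (Hann window,
    mean removed) is integrated over the band, summed over axes and divided
    by the segment sample count.
    """
    fs = segment.sampling_rate
    lo, hi = band
    if not (0 <= lo < hi <= fs / 2):
        raise FeatureError(f"band {band} must lie within (0, {fs / 2}) Hz")
    n = segment.n_samples
    if n < fs:
        raise FeatureError("segment too short for spectral estimate")
    pos = segment.joint(joint)
    acc = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) * fs**2
    total = 0.0
    for axis in range(pos.shape[1]):
        freqs, psd = periodogram(
            acc[:, axis], fs=fs, window="hann", detrend="constant"
        )
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() >= 2:
            total += float(np.trapezoid(psd[mask], freqs[mask]))
        elif mask.any():
            total += float(psd[mask].sum() * (freqs[1] - freqs[0]))
    return total / n


def extract_features(segment: GaitSegment, segment_id: str | None = None) -> FeatureVector:
    """Assemble all six features plus metadata; fails atomically."""
    try:
        sl = step_length(segment)
        st = step_trajectory(segment)
        vector = FeatureVector(
            cadence=step_cadence(segment),
            step_length=sl,
            step_trajectory=st,
            relative_step_length=relative_step_length(sl, st),
            com_std=com_std(segment),
            energy_low=band_energy(segment, LOW_BAND),
            energy_high=band_energy(segment, HIGH_BAND),
            participant_id=segment.participant_id,
            label=segment.label,
            severity=segment.severity,
        )
    except FeatureError as err:
        tag = segment_id if segment_id is not None else (
            f"{segment.participant_id}[{segment.start}:{segment.end}]"
        )
        raise FeatureError(f"segment {tag}: {err}") from err
    vector.validate()
    return vector


def features_table(segments: list[GaitSegment]) -> pd.DataFrame:
    """One row per segment, fixed column order, locale-independent floats."""
    rows = []
    for i, segment in enumerate(segments):
        vec = extract_features(segment, segment_id=str(i))
        rows.append(
            {
                "participant_id": vec.participant_id,
                "label": vec.label,
                "severity": vec.severity,
                **{col: getattr(vec, col) for col in FEATURE_COLUMNS},
            }
        )
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
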