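"""Synthetic motion-capture gait generator with exact ground truth.

Produces per-joint 3-D position time series (metres, 60 or 120 Hz) for a
walker traversing a corridor in straight passes separated by 180-degree
turns.  The kinematic step model is deliberately simple — alternating
single-foot swings with cosine-eased forward progress and a sinusoidal
vertical lift — because it makes every foot-ground contact instant, every
drawn step length and every turn interval analytically known.  Those known
quantities (:class:`GroundTruth`) are the oracle against which the event
detectors and gait features are validated.

Ataxic gait is emulated by a non-negative ``severity`` axis that scales
lateral centre-of-mass sway, step-length variability and high-frequency
tremor up, and cadence down (see :class:`EffectSizes`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ParameterError",
    "GaitParams",
    "EffectSizes",
    "MotionRecording",
    "GroundTruth",
    "band_limited_noise",
    "apply_severity",
    "generate_recording",
    "generate_cohort",
]

LEFT_FOOT = "left_foot"
RIGHT_FOOT = "right_foot"
PELVIS = "pelvis"
CANONICAL_JOINTS = (LEFT_FOOT, RIGHT_FOOT, PELVIS)

#: Axis convention: right-handed, y is vertical (up), gait plane is x-z.
VERTICAL_AXIS = 1
HORIZONTAL_AXES = (0, 2)


class ParameterError(ValueError):
    """A generator parameter is outside its admissible domain."""


@dataclass(frozen=True)
class GaitParams:
    """Kinematic parameters of one simulated walk.

    Units: metres, seconds, Hz; cadence in steps/minute.  ``severity`` is
    metadata carried through to the recording — the kinematics depend only
    on the explicit parameters (use :func:`apply_severity` to couple them).
    """

    cadence: float = 110.0
    step_length_mean: float = 0.65
    step_length_sd: float = 0.02
    step_height: float = 0.12
    swing_wobble: float = 0.01
    sway_amplitude: float = 0.02
    tremor_amplitude: float = 0.001
    tremor_band: tuple[float, float] = (15.0, 29.0)
    walk_length: float = 100.0
    n_passes: int = 9
    sampling_rate: int = 60
    severity: float = 0.0
    turn_duration_s: float = 2.0
    turn_offset: float = 0.5
    lead_in_s: float = 0.5

    def validate(self) -> None:
        if not self.cadence > 0:
            raise ParameterError("cadence must be > 0")
        if not self.step_length_mean > 0:
            raise ParameterError("step_length_mean must be > 0")
        if self.step_length_sd < 0:
            raise ParameterError("step_length_sd must be >= 0")
        if self.step_height < 0:
            raise ParameterError("step_height must be >= 0")
        if self.swing_wobble < 0:
            raise ParameterError("swing_wobble must be >= 0")
        if self.sway_amplitude < 0:
            raise ParameterError("sway_amplitude must be >= 0")
        if self.tremor_amplitude < 0:
            raise ParameterError("tremor_amplitude must be >= 0")
        if self.sampling_rate not in (60, 120):
            raise ParameterError("sampling_rate must be 60 or 120")
        lo, hi = self.tremor_band
        if not (0 <= lo < hi):
            raise ParameterError("tremor_band must satisfy 0 <= low < high")
        if hi >= self.sampling_rate / 2:
            raise ParameterError(
                "tremor_band upper bound must be below the Nyquist frequency"
            )
        if not self.walk_length > 0:
            raise ParameterError("walk_length must be > 0")
        if self.n_passes < 1:
            raise ParameterError("n_passes must be >= 1")
        if self.severity < 0:
            raise ParameterError("severity must be >= 0")
        if self.turn_duration_s <= 0:
            raise ParameterError("turn_duration_s must be > 0")


@dataclass(frozen=True)
class EffectSizes:
    """Multiplicative severity couplings.

    At severity ``s`` the affected parameters become::

        sway_amplitude   *= 1 + sway * s
        swing_wobble     *= 1 + wobble * s
        step_length_sd   *= 1 + step_variability * s
        tremor_amplitude *= 1 + tremor * s
        cadence          *= 1 - cadence * s        (floored at 10%)

    All-zero effect sizes are the identity: ataxic and healthy recordings
    are then statistically indistinguishable.
    """

    sway: float = 2.5
    wobble: float = 9.0
    step_variability: float = 6.0
    tremor: float = 8.0
    cadence: float = 0.15

    def identity(self) -> bool:
        return (
            self.sway
            == self.wobble
            == self.step_variability
            == self.tremor
            == self.cadence
            == 0
        )


@dataclass
class MotionRecording:
    """Per-joint 3-D position time series plus participant metadata."""

    participant_id: str
    label: str
    severity: float
    sampling_rate: int
    joints: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.label not in ("healthy", "ataxic"):
            raise ValueError(f"label must be 'healthy' or 'ataxic', got {self.label!r}")
        if self.sampling_rate not in (60, 120):
            raise ValueError("sampling_rate must be 60 or 120")
        lengths = {name: len(pos) for name, pos in self.joints.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"joint sequences differ in length: {lengths}")
        for name, pos in self.joints.items():
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 2 or pos.shape[1] != 3:
                raise ValueError(f"joint {name!r} must be an (n, 3) array")
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"joint {name!r} contains non-finite coordinates")
            self.joints[name] = pos

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.joints.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GroundTruth:
    """Exact event annotations emitted alongside a generated recording."""

    contact_times: dict[str, np.ndarray]
    turn_intervals: list[tuple[int, int]]
    per_step_lengths: np.ndarray

    def pooled_contacts(self) -> np.ndarray:
        """All contact sample indices of both feet, sorted."""
        return np.sort(np.concatenate(list(self.contact_times.values())))


def band_limited_noise(
    n: int,
    fs: float,
    band: tuple[float, float],
    rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise whose spectrum is confined to ``band`` (Hz).

    Constructed by drawing complex Gaussian rFFT coefficients on the in-band
    bins only, so >99% of periodogram energy lies inside the band by
    construction.  Scaled to the requested RMS.
    """
    if n < 2 or rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spectrum = np.zeros(len(freqs), dtype=complex)
    k = int(mask.sum())
    if k == 0:
        return np.zeros(n)
    spectrum[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spectrum, n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x * (rms / sd)


def apply_severity(
    base: GaitParams, severity: float, effects: EffectSizes
) -> GaitParams:
    """Shift the severity-coupled parameters of ``base`` (monotone in severity)."""
    if severity < 0:
        raise ParameterError("severity must be >= 0")
    return replace(
        base,
        sway_amplitude=base.sway_amplitude * (1 + effects.sway * severity),
        swing_wobble=base.swing_wobble * (1 + effects.wobble * severity),
        step_length_sd=base.step_length_sd * (1 + effects.step_variability * severity),
        tremor_amplitude=base.tremor_amplitude * (1 + effects.tremor * severity),
        cadence=base.cadence * max(0.1, 1 - effects.cadence * severity),
        severity=severity,
    )


def _draw_step_length(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd**2) truncated at zero (rejection sampling)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if value > 0:
            return value
    raise ParameterError("step length distribution has almost no mass above zero")


def generate_recording(
    params: GaitParams,
    participant_id: str,
    seed: int,
    label: str = "healthy",
) -> tuple[MotionRecording, GroundTruth]:
    """Simulate one walk; bit-identical output for identical arguments.

    The walker stands for ``lead_in_s``, then performs ``n_passes`` straight
    passes of alternating swings, reversing direction during a
    ``turn_duration_s`` turn between passes (both feet glide to a walking
    line offset ``turn_offset`` metres laterally).  Each swing advances the
    swinging foot so it lands a freshly drawn step length beyond the most
    recent foot contact; the landing sample index and drawn length are
    recorded as ground truth.  The pelvis (centre-of-mass proxy) is a
    one-step moving average of the feet midpoint, plus a lateral sway
    sinusoid at step frequency and a band-limited tremor component.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    spp = max(2, round(fs * 60.0 / params.cadence))  # samples per step
    pass_length = params.walk_length / params.n_passes
    steps_per_pass = max(2, round(pass_length / params.step_length_mean))
    lead = round(params.lead_in_s * fs)
    turn_n = round(params.turn_duration_s * fs)
    n = (
        lead
        + params.n_passes * steps_per_pass * spp
        + (params.n_passes - 1) * turn_n
        + lead
    )

    feet = {LEFT_FOOT: np.zeros((n, 3)), RIGHT_FOOT: np.zeros((n, 3))}
    pos = {LEFT_FOOT: np.zeros(3), RIGHT_FOOT: np.zeros(3)}
    contacts: dict[str, list[int]] = {LEFT_FOOT: [0], RIGHT_FOOT: [0]}
    step_lengths: list[float] = []
    turn_intervals: list[tuple[int, int]] = []

    t = lead  # sample cursor; [0, lead) is the standing lead-in at the origin
    direction = 1.0
    z_line = 0.0
    x_front = 0.0  # x of the most recent foot contact
    step_index = 0

    tau_step = (np.arange(spp) / spp)[:, None]  # tau in [0, 1)
    ease_step = 0.5 * (1 - np.cos(np.pi * tau_step))
    # raised-cosine lift: peaks at step_height mid-swing, zero height and
    # zero vertical velocity at take-off and touchdown
    lift = params.step_height * np.sin(np.pi * tau_step[:, 0]) ** 2
    # lateral circumduction bulge of the swinging foot (zero position and
    # velocity at take-off and landing); grows with severity via the sway
    # coupling, lowering the SL/ST step-optimality ratio in ataxic gait
    wobble = params.swing_wobble * np.sin(np.pi * tau_step[:, 0]) ** 2

    for p in range(params.n_passes):
        for _ in range(steps_per_pass):
            foot = RIGHT_FOOT if step_index % 2 == 0 else LEFT_FOOT
            other = LEFT_FOOT if foot == RIGHT_FOOT else RIGHT_FOOT
            length = _draw_step_length(
                rng, params.step_length_mean, params.step_length_sd
            )
            landing = np.array([x_front + direction * length, 0.0, z_line])
            start = pos[foot]
            feet[foot][t : t + spp] = start + (landing - start) * ease_step
            feet[foot][t : t + spp, VERTICAL_AXIS] = lift
            feet[foot][t : t + spp, 2] += wobble
            feet[other][t : t + spp] = pos[other]
            t += spp
            pos[foot] = landing
            if t < n:
                contacts[foot].append(t)
            step_lengths.append(length)
            x_front = landing[0]
            step_index += 1
        if p < params.n_passes - 1:
            turn_intervals.append((t, t + turn_n))
            z_new = z_line + params.turn_offset
            # tau starts at 0 so the sample at the turn onset still holds the
            # exact landing position of the final step of the pass
            tau_turn = (np.arange(turn_n) / turn_n)[:, None]
            ease_turn = 0.5 * (1 - np.cos(np.pi * tau_turn))
            for foot in (LEFT_FOOT, RIGHT_FOOT):
                target = pos[foot].copy()
                target[2] = z_new
                feet[foot][t : t + turn_n] = (
                    pos[foot] + (target - pos[foot]) * ease_turn
                )
                pos[foot] = target
            t += turn_n
            z_line = z_new
            direction = -direction

    for foot in (LEFT_FOOT, RIGHT_FOOT):
        feet[foot][t:] = pos[foot]

    mid = 0.5 * (feet[LEFT_FOOT] + feet[RIGHT_FOOT])
    pelvis = uniform_filter1d(mid, size=spp, axis=0, mode="nearest")
    time = np.arange(n) / fs
    step_freq = params.cadence / 60.0
    pelvis[:, 2] += params.sway_amplitude * np.sin(2 * np.pi * step_freq * time)
    if params.tremor_amplitude > 0:
        per_axis_rms = params.tremor_amplitude / np.sqrt(3)
        for axis in range(3):
            pelvis[:, axis] += band_limited_noise(
                n, fs, params.tremor_band, per_axis_rms, rng
            )

    recording = MotionRecording(
        participant_id=participant_id,
        label=label,
        severity=params.severity,
        sampling_rate=fs,
        joints={
            LEFT_FOOT: feet[LEFT_FOOT],
            RIGHT_FOOT: feet[RIGHT_FOOT],
            PELVIS: pelvis,
        },
    )
    truth = GroundTruth(
        contact_times={
            foot: np.asarray(idx, dtype=int) for foot, idx in contacts.items()
        },
        turn_intervals=turn_intervals,
        per_step_lengths=np.asarray(step_lengths),
    )
    return recording, truth


def generate_cohort(
    n_healthy: int,
    n_ataxic: int,
    severity_range: tuple[float, float] = (0.25, 1.0),
    base_params: GaitParams | None = None,
    effect_sizes: EffectSizes | None = None,
    seed: int = 0,
) -> list[tuple[MotionRecording, GroundTruth]]:
    """Generate a seeded cohort of healthy and ataxic recordings.

    Healthy participants are drawn at severity 0; ataxic severities are
    drawn uniformly from ``severity_range`` and coupled to the kinematics
    through ``effect_sizes`` (monotone shifts).  Per-recording seeds are
    spawned deterministically from the master seed.
    """
    if n_healthy < 1 or n_ataxic < 0:
        raise ParameterError("cohort counts must be n_healthy >= 1, n_ataxic >= 0")
    base = base_params if base_params is not None else GaitParams()
    effects = effect_sizes if effect_sizes is not None else EffectSizes()
    if n_ataxic > 0:
        if severity_range is None or severity_range[1] < severity_range[0]:
            raise ParameterError(
                "severity_range must be a non-empty interval when n_ataxic > 0"
            )
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_healthy + n_ataxic + 1)
    severity_rng = np.random.default_rng(children[0])
    severities = (
        severity_rng.uniform(severity_range[0], severity_range[1], size=n_ataxic)
        if n_ataxic > 0
        else np.empty(0)
    )

    cohort: list[tuple[MotionRecording, GroundTruth]] = []
    for i in range(n_healthy):
        rec_seed = int(children[1 + i].generate_state(1)[0] % (2**31))
        cohort.append(
            generate_recording(
                replace(base, severity=0.0), f"H{i + 1:02d}", rec_seed, "healthy"
            )
        )
    for j in range(n_ataxic):
        rec_seed = int(children[1 + n_healthy + j].generate_state(1)[0] % (2**31))
        params = apply_severity(base, float(severities[j]), effects)
        cohort.append(
            generate_recording(params, f"A{j + 1:02d}", rec_seed, "ataxic")
        )
    return cohort
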