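"""Synthetic running-gait and fabric-sensor simulator.

Generates cohorts of virtual runners with ground-truth lower-body joint
angles, garment strain-sensor voltages correlated with those angles through
a noisy, mildly nonlinear piezoresistive model, and a pelvis marker-grid
strain field with a known informative subset of candidate sensor positions.
Every downstream stage (strain field, placement optimization, preprocessing,
CNN regression, evaluation) is exercised on this simulator.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams, so identical seeds produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "CHANNEL_NAMES",
    "SENSOR_NAMES",
    "SAGITTAL_CHANNELS",
    "ProtocolSpec",
    "ParticipantProfile",
    "SensorModel",
    "GridModel",
    "JointAngleSeries",
    "SensorSeries",
    "MarkerGridSeries",
    "Trial",
    "Cohort",
    "sample_profile",
    "simulate_joint_angles",
    "simulate_sensor_voltages",
    "simulate_marker_grid",
    "generate_cohort",
    "random_placement_instance",
]

#: Joint-angle channel order used throughout the package.
CHANNEL_NAMES = (
    "hip_sag",
    "hip_front",
    "hip_trans",
    "knee_sag",
    "ankle_sag",
    "ankle_front",
)

#: Indices of the sagittal-plane channels (hip, knee, ankle) in CHANNEL_NAMES.
SAGITTAL_CHANNELS = (0, 3, 4)

#: Sensor column order: four pelvis, two knee (front), three ankle sensors.
SENSOR_NAMES = (
    "pelvis_1",
    "pelvis_2",
    "pelvis_3",
    "pelvis_4",
    "knee_1",
    "knee_2",
    "ankle_1",
    "ankle_2",
    "ankle_3",
)

# Nominal waveform constants (degrees). Channel means and harmonic
# amplitudes are literature-plausible for treadmill running: sagittal ranges
# of motion dominate frontal/transverse ones (hip sag ~50 deg, knee sag
# ~90 deg vs ~12-15 deg out of plane).
_ANGLE_MEAN = np.array([25.0, 2.0, 0.0, 50.0, 5.0, 0.0])
_ANGLE_HARMONICS = np.array(
    [
        [20.0, 6.0, 2.0],  # hip sagittal
        [6.0, 2.5, 1.0],  # hip frontal
        [5.0, 2.0, 0.8],  # hip transverse
        [38.0, 12.0, 4.0],  # knee sagittal
        [18.0, 6.0, 2.0],  # ankle sagittal
        [6.0, 2.0, 0.8],  # ankle frontal
    ]
)
# Fixed harmonic phase offsets (radians) giving each channel a distinct,
# asymmetric within-stride shape.
_HARMONIC_PHASE = np.array(
    [
        [0.0, 0.9, 1.7],
        [1.1, 2.3, 0.4],
        [2.2, 0.6, 1.9],
        [0.5, 1.4, 2.8],
        [1.8, 0.2, 1.1],
        [2.7, 1.0, 0.3],
    ]
)
#: Nominal full range of motion per channel, used to normalize angles into
#: a dimensionless working variable for the sensor / marker-grid models.
ANGLE_NORM = np.array([50.0, 15.0, 12.0, 90.0, 45.0, 14.0])

_CADENCE_SLOPE = 2.5  # strides/min per km/h
_SPEED_AMP_SLOPE = 0.03  # fractional amplitude growth per km/h around 10


@dataclass(frozen=True)
class ProtocolSpec:
    """Treadmill protocol: which speeds, how long, how often, at what rate.

    Defaults reproduce the study protocol: 3 repeats x 5 speeds x 60 s at
    100 Hz = 15 one-minute trials (90,000 frames) per participant.
    """

    speeds: tuple[float, ...] = (8.0, 9.0, 10.0, 11.0, 12.0)
    trial_duration: float = 60.0
    repeats: int = 3
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("trial_duration and sample_rate must be positive")
        if self.repeats < 1 or not self.speeds:
            raise ValueError("need at least one repeat and one speed")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))

    @property
    def n_trials(self) -> int:
        return self.repeats * len(self.speeds)


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-runner parameters: gait timing/shape and sensor electronics."""

    participant_id: str
    cadence_base: float  # strides/min at 10 km/h
    amplitude_scale: np.ndarray  # (6,) unitless, > 0
    phase_offset: np.ndarray  # (6,) radians
    sensor_gain: np.ndarray  # (9,) unitless
    sensor_noise_sd: float  # volts
    baseline_v0: np.ndarray  # (9,) volts, > 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.amplitude_scale) <= 0):
            raise ValueError("amplitude_scale must be positive")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")
        if np.any(np.asarray(self.baseline_v0) <= 0):
            raise ValueError("baseline_v0 must be positive")


# Default sensor loading matrix (9 sensors x 6 channels): pelvis sensors load
# mainly on the three hip channels, knee sensors on the knee, ankle sensors
# on the two ankle channels, with small physiological cross-talk.
_DEFAULT_LOADING = np.array(
    [
        [0.90, 0.30, 0.10, 0.05, 0.00, 0.00],
        [0.20, 0.80, 0.30, 0.00, 0.00, 0.00],
        [0.40, -0.50, 0.70, 0.00, 0.00, 0.00],
        [0.70, 0.40, -0.50, 0.05, 0.00, 0.00],
        [0.10, 0.00, 0.00, 0.90, 0.10, 0.00],
        [0.05, 0.00, 0.00, 0.80, -0.15, 0.00],
        [0.00, 0.00, 0.00, 0.10, 0.85, 0.20],
        [0.00, 0.00, 0.00, 0.05, 0.70, -0.40],
        [0.00, 0.00, 0.00, 0.00, 0.50, 0.75],
    ]
)


@dataclass(frozen=True)
class SensorModel:
    """Piezoresistive mapping from joint angles to sensor voltages.

    Each sensor sees a latent strain-like drive ``e = scale * (z @ w)`` where
    ``z`` are range-normalized joint angles, then
    ``V = V0 * (1 + gain * sat(e)) + noise``.

    The saturating map ``sat`` is ``s * tanh(e / s)`` with ``s = 0.3``: the
    fiber sensors are linear below 30% strain, so operation stays in the
    near-linear regime by default; ``saturation="linear"`` switches to the
    identity for exact-recovery tests.
    """

    loading: np.ndarray = field(default_factory=lambda: _DEFAULT_LOADING.copy())
    drive_scale: float = 0.35
    saturation: str = "tanh"  # "tanh" | "linear"
    sat_scale: float = 0.3
    drift_amplitude: float = 0.0  # volts; slow drift, off by default

    def apply_saturation(self, e: np.ndarray) -> np.ndarray:
        if self.saturation == "linear":
            return e
        if self.saturation == "tanh":
            return self.sat_scale * np.tanh(e / self.sat_scale)
        raise ValueError(f"unknown saturation {self.saturation!r}")


@dataclass(frozen=True)
class JointAngleSeries:
    """Reference kinematics of one trial: six angle channels in degrees."""

    participant_id: str
    speed: float
    trial_index: int
    t: np.ndarray  # (frames,) seconds
    angles: np.ndarray  # (frames, 6) degrees, CHANNEL_NAMES order

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]


@dataclass(frozen=True)
class SensorSeries:
    """Nine sensor voltages of one trial plus the static-standing baseline."""

    participant_id: str
    speed: float
    trial_index: int
    v: np.ndarray  # (frames, 9) volts
    v0: np.ndarray  # (9,) volts


@dataclass(frozen=True)
class MarkerGridSeries:
    """Trajectories of the 50-marker garment grid for one participant/speed."""

    participant_id: str
    speed: float
    positions: np.ndarray  # (frames, n_markers, 3) cm
    grid_rows: int
    grid_cols: int
    neutral_positions: np.ndarray  # (n_markers, 3) cm, standing posture
    informative_pairs: tuple[tuple[int, int], ...] = ()  # (marker_a, marker_b)


@dataclass(frozen=True)
class Trial:
    angles: JointAngleSeries
    sensors: SensorSeries


@dataclass(frozen=True)
class Cohort:
    trials: tuple[Trial, ...]
    profiles: tuple[ParticipantProfile, ...]
    protocol: ProtocolSpec
    sensor_model: SensorModel

    def participant_trials(self, participant_id: str) -> list[Trial]:
        return [t for t in self.trials if t.angles.participant_id == participant_id]


def sample_profile(rng: np.random.Generator, participant_id: str) -> ParticipantProfile:
    """Draw one virtual runner's gait and sensor parameters."""
    return ParticipantProfile(
        participant_id=participant_id,
        cadence_base=float(80.0 + rng.normal(0.0, 3.0)),
        amplitude_scale=np.clip(rng.normal(1.0, 0.08, 6), 0.7, 1.3),
        phase_offset=rng.normal(0.0, 0.15, 6),
        sensor_gain=np.clip(rng.normal(1.0, 0.10, 9), 0.6, 1.4),
        sensor_noise_sd=0.004,
        baseline_v0=rng.uniform(1.2, 1.8, 9),
    )


def stride_frequency(profile: ParticipantProfile, speed: float) -> float:
    """Stride frequency in Hz; strictly increasing with treadmill speed."""
    return (profile.cadence_base + _CADENCE_SLOPE * (speed - 10.0)) / 60.0


def simulate_joint_angles(
    profile: ParticipantProfile,
    speed: float,
    trial_index: int,
    protocol: ProtocolSpec,
    rng: np.random.Generator,
    butterworth: bool = True,
) -> JointAngleSeries:
    """One trial of six-channel joint angles: truncated Fourier series over
    the stride cycle with speed-dependent cadence and amplitude, plus
    participant-specific scale and phase.

    ``butterworth=True`` applies the zero-phase 4th-order 6 Hz low-pass used
    to condition reference kinematics.
    """
    n = protocol.frames_per_trial
    t = np.arange(n) / protocol.sample_rate
    f_stride = stride_frequency(profile, speed)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    speed_amp = 1.0 + _SPEED_AMP_SLOPE * (speed - 10.0)
    trial_amp = np.clip(rng.normal(1.0, 0.02, 6), 0.9, 1.1)

    phase = 2.0 * np.pi * f_stride * t  # (n,)
    angles = np.empty((n, 6))
    for c in range(6):
        wave = np.zeros(n)
        for h in range(3):
            wave += _ANGLE_HARMONICS[c, h] * np.sin(
                (h + 1) * (phase + phase0)
                + _HARMONIC_PHASE[c, h]
                + profile.phase_offset[c]
            )
        angles[:, c] = (
            _ANGLE_MEAN[c]
            + profile.amplitude_scale[c] * speed_amp * trial_amp[c] * wave
        )

    if butterworth:
        b, a = signal.butter(4, 6.0, fs=protocol.sample_rate)
        angles = signal.filtfilt(b, a, angles, axis=0)

    return JointAngleSeries(
        participant_id=profile.participant_id,
        speed=speed,
        trial_index=trial_index,
        t=t,
        angles=angles,
    )


def normalized_angles(angles: np.ndarray) -> np.ndarray:
    """Map degrees to the dimensionless working variable z (roughly ±0.6)."""
    return (angles - _ANGLE_MEAN) / ANGLE_NORM


def simulate_sensor_voltages(
    angles: JointAngleSeries,
    profile: ParticipantProfile,
    seed: int | np.random.Generator,
    model: SensorModel | None = None,
) -> SensorSeries:
    """Map a trial's joint angles to nine sensor voltages.

    ``V = V0 * (1 + gain * sat(drive)) + Gaussian noise (+ optional drift)``
    where the drive of each sensor is a sensor-specific linear combination
    of range-normalized angles. The loading matrix lives on the
    :class:`SensorModel`, so the ground-truth mapping is recoverable.
    """
    model = model or SensorModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a = np.asarray(angles.angles, dtype=float)
    if a.ndim != 2 or a.shape[1] != 6:
        raise ValueError(f"angles must be (frames, 6), got {a.shape}")
    z = normalized_angles(a)
    e = model.drive_scale * (z @ model.loading.T)  # (frames, 9)
    v = profile.baseline_v0 * (1.0 + profile.sensor_gain * model.apply_saturation(e))
    if profile.sensor_noise_sd > 0:
        v = v + rng.normal(0.0, profile.sensor_noise_sd, v.shape)
    if model.drift_amplitude > 0:
        drift = model.drift_amplitude * np.sin(
            2.0 * np.pi * angles.t / max(angles.t[-1], 1e-9) + rng.uniform(0, 2 * np.pi)
        )
        v = v + drift[:, None]
    return SensorSeries(
        participant_id=angles.participant_id,
        speed=angles.speed,
        trial_index=angles.trial_index,
        v=v,
        v0=profile.baseline_v0.copy(),
    )


def generate_cohort(
    n_participants: int,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    sensor_model: SensorModel | None = None,
    butterworth: bool = True,
) -> Cohort:
    """Generate a full virtual cohort: per participant, ``repeats`` blocks of
    every speed (slow to fast within a block, as in the treadmill protocol),
    with paired angle and voltage series per trial.

    Deterministic given ``seed``; participants draw from independent named
    sub-streams so adding a participant never perturbs earlier ones.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    protocol = protocol or ProtocolSpec()
    sensor_model = sensor_model or SensorModel()

    root = np.random.SeedSequence(seed)
    participant_seeds = root.spawn(n_participants)
    trials: list[Trial] = []
    profiles: list[ParticipantProfile] = []
    for p, pseed in enumerate(participant_seeds):
        profile_ss, *trial_ss = pseed.spawn(1 + protocol.n_trials)
        profile = sample_profile(np.random.default_rng(profile_ss), f"P{p + 1:02d}")
        profiles.append(profile)
        idx = 0
        for repeat in range(protocol.repeats):
            for speed in protocol.speeds:
                rng = np.random.default_rng(trial_ss[idx])
                ja = simulate_joint_angles(
                    profile, speed, idx, protocol, rng, butterworth=butterworth
                )
                sv = simulate_sensor_voltages(ja, profile, rng, sensor_model)
                trials.append(Trial(angles=ja, sensors=sv))
                idx += 1
    return Cohort(
        trials=tuple(trials),
        profiles=tuple(profiles),
        protocol=protocol,
        sensor_model=sensor_model,
    )


# ---------------------------------------------------------------------------
# Marker-grid strain field
# ---------------------------------------------------------------------------

# Mixing matrix from the three hip channels to the four informative
# positions: three channel-dominant rows plus one balanced row, so the full
# hip state is linearly recoverable from the informative subset.
_INFORMATIVE_MIX = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.577, 0.577, 0.577],
    ]
)
_MIX_NORM = np.array([0.6, 0.6, 0.6, 1.05])  # scales each row's drive to ~[-1, 1]


@dataclass(frozen=True)
class GridModel:
    """Parameters of the pelvis marker-grid simulator.

    The grid is ``grid_rows x grid_cols`` markers on the worn garment with
    ``spacing`` cm between neighbors (>= 4 cm: the garment stretches when
    worn). Informative positions are vertical top-edge pairs at
    ``informative_cols``; the upper marker of each translates along the pair
    axis by an affine function of a hip-angle mix, producing up to
    ``peak_strain`` strain. All other markers carry smooth in-plane noise
    motion (amplitude ``background_amp`` cm) uncorrelated with the gait, so
    a realistic share of uninformative candidates still strains past the
    10% placement filter.
    """

    grid_rows: int = 5
    grid_cols: int = 10
    spacing: float = 4.4  # cm, worn-garment neighbor distance
    informative_cols: tuple[int, ...] = (1, 3, 6, 8)
    peak_strain: float = 0.15
    background_amp: float = 0.52  # cm
    background_cutoff_hz: float = 2.0
    marker_noise_sd: float = 0.02  # cm, white jitter on every marker

    def background_contrast(self) -> np.ndarray:
        """Fixed in-plane displacement amplitudes (cm) per marker, (n, 2).

        A checkerboard of moving vs anchored markers with mild deterministic
        amplitude variation: it emulates how worn-garment slack redistributes
        in a stable spatial pattern, so uninformative neighbor pairs strain
        past the 10% rule consistently in every trial.
        """
        amp = np.zeros((self.n_markers, 2))
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                if (r + c) % 2 == 0:
                    continue
                m = self.marker_index(r, c)
                amp[m, 0] = self.background_amp * (0.88 + 0.24 * ((2 * r + 3 * c) % 7) / 6)
                amp[m, 1] = self.background_amp * (0.88 + 0.24 * ((3 * r + 2 * c) % 7) / 6)
        return amp

    @property
    def n_markers(self) -> int:
        return self.grid_rows * self.grid_cols

    def marker_index(self, row: int, col: int) -> int:
        return row * self.grid_cols + col

    def neutral_grid(self) -> np.ndarray:
        """Neutral (standing) marker positions, cm; grid in the x-y plane."""
        pos = np.zeros((self.n_markers, 3))
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                m = self.marker_index(r, c)
                pos[m, 0] = c * self.spacing
                pos[m, 1] = -r * self.spacing  # row 0 on top
        return pos

    def informative_marker_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.marker_index(0, c), self.marker_index(1, c))
            for c in self.informative_cols
        )


def _smooth_noise(
    rng: np.random.Generator, n_frames: int, n_series: int, cutoff: float, rate: float
) -> np.ndarray:
    """Independent smooth noise signals, each normalized to max |.| = 1."""
    white = rng.normal(0.0, 1.0, (n_frames, n_series))
    if n_frames > 18:  # filtfilt needs padding room
        b, a = signal.butter(2, cutoff, fs=rate)
        white = signal.filtfilt(b, a, white, axis=0)
    peak = np.max(np.abs(white), axis=0)
    peak[peak == 0] = 1.0
    return white / peak


def simulate_marker_grid(
    angles: JointAngleSeries,
    grid_model: GridModel | None = None,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 100.0,
) -> MarkerGridSeries:
    """Simulate the garment marker grid driven by one trial's hip angles.

    The returned series records which marker pairs were designated
    informative, so placement-recovery experiments have ground truth.
    """
    gm = grid_model or GridModel()
    if gm.grid_rows < 2 or gm.grid_cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a = np.asarray(angles.angles, dtype=float)
    n = a.shape[0]
    neutral = gm.neutral_grid()
    pos = np.repeat(neutral[None, :, :], n, axis=0)

    # Informative motion: upper marker of each designated vertical pair moves
    # along +y (away from its partner) by spacing * peak_strain * g(t), with
    # g an affine mix of range-normalized hip angles squashed into [0.05, 1].
    z_hip = normalized_angles(a)[:, :3]
    drive = (z_hip @ _INFORMATIVE_MIX.T) / _MIX_NORM[None, :]
    g = 0.525 + 0.475 * np.clip(drive, -1.0, 1.0)  # (n, 4) in [0.05, 1]
    informative = gm.informative_marker_pairs()
    info_markers: set[int] = set()
    for i, (top, bottom) in enumerate(informative):
        pos[:, top, 1] += gm.spacing * gm.peak_strain * g[:, i]
        info_markers.update((top, bottom))

    # Background motion: one smooth gait-independent drive signal per trial
    # (normalized to peak 1) moves markers in-plane with the grid's fixed
    # spatial contrast pattern; informative markers stay anchored.
    if gm.background_amp > 0:
        amp = gm.background_contrast()
        amp[list(info_markers), :] = 0.0
        h = _smooth_noise(rng, n, 1, gm.background_cutoff_hz, sample_rate)[:, 0]
        if h.max() > h.min():  # rescale to exactly [-1, 1]: every trial reaches
            h = 2.0 * (h - h.min()) / (h.max() - h.min()) - 1.0  # both extremes

        pos[:, :, 0] += amp[None, :, 0] * h[:, None]
        pos[:, :, 1] += amp[None, :, 1] * h[:, None]

    if gm.marker_noise_sd > 0:
        pos += rng.normal(0.0, gm.marker_noise_sd, pos.shape)

    return MarkerGridSeries(
        participant_id=angles.participant_id,
        speed=angles.speed,
        positions=pos,
        grid_rows=gm.grid_rows,
        grid_cols=gm.grid_cols,
        neutral_positions=neutral,
        informative_pairs=informative,
    )


# ---------------------------------------------------------------------------
# Abstract randomized placement instances (for optimizer benchmarking)
# ---------------------------------------------------------------------------


def random_placement_instance(
    n_candidates: int,
    n_participants: int = 3,
    n_frames: int = 240,
    informative_fraction: float = 0.6,
    noise_sd_range: tuple[float, float] = (0.02, 0.2),
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """A small abstract sensor-placement problem.

    Each participant runs a hip-like three-channel periodic trajectory;
    candidate signals are random linear mixes of it (a fraction carry no
    signal at all) plus heteroscedastic noise. Returns per-participant
    ``(strains, hip_angles)`` lists, suitable for the leave-one-person-out
    linear objective.
    """
    rng = np.random.default_rng(seed)
    loadings = rng.normal(0.0, 1.0, (n_candidates, 3))
    dead = rng.random(n_candidates) > informative_fraction
    loadings[dead] = 0.0
    noise_sd = rng.uniform(*noise_sd_range, n_candidates)
    offsets = rng.normal(0.0, 0.2, n_candidates)

    strains: list[np.ndarray] = []
    angles: list[np.ndarray] = []
    for _ in range(n_participants):
        t = np.arange(n_frames) / 100.0
        f = rng.uniform(1.2, 1.5)
        ph = rng.uniform(0.0, 2.0 * np.pi, 3)
        amp = rng.uniform(0.8, 1.2, 3)
        z = np.stack(
            [
                amp[c]
                * (
                    np.sin(2 * np.pi * f * t + ph[c])
                    + 0.3 * np.sin(4 * np.pi * f * t + 2 * ph[c])
                )
                for c in range(3)
            ],
            axis=1,
        )
        s = offsets + z @ loadings.T + rng.normal(0.0, 1.0, (n_frames, n_candidates)) * noise_sd
        hip = z * np.array([25.0, 7.0, 6.0]) + np.array([25.0, 2.0, 0.0])
        strains.append(s)
        angles.append(hip)
    return strains, angles
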