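"""Synthetic level-walking gait trials.

Generates the statistical structure the downstream analysis assumes: eight
channels of nonnormalized, band-limited (10-400 Hz) surface EMG whose
amplitude is modulated by gait-phase-locked activation bursts scaled with
walking speed, together with time-aligned sagittal ankle angle (deg) and
body-mass-normalized ankle moment (Nm/kg) trajectories, heel-strike event
annotations, and a per-trial walking speed drawn from 0.3-2.3 m/s.

The EMG surrogate is the standard amplitude-modulated band-limited-noise
model: a zero-mean Gaussian carrier band-passed to the sEMG analog band is
multiplied samplewise by a nonnegative activation envelope; no per-channel
rescaling is ever applied, so channel amplitudes stay on their raw
(microvolt-like) scale.  Mechanical signals live on a separate, slower clock
(default 100 Hz vs 1000 Hz) so that downstream stages must align explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps_signal

from .combinations import MUSCLES
from .errors import IdentifierError, ValidationError

__all__ = [
    "Burst",
    "MusclePhasing",
    "SynthConfig",
    "GaitTrial",
    "stride_time",
    "activation_envelope",
    "synthesize_emg",
    "ankle_templates",
    "generate_trial",
    "generate_dataset",
]


@dataclass(frozen=True)
class Burst:
    """One activation burst: center and width in %GC, amplitude in signal units."""

    center: float
    width: float
    amp: float

    def __post_init__(self):
        if not (0 <= self.center < 100):
            raise ValidationError(f"burst center must lie in [0, 100), got {self.center}")
        if self.width <= 0:
            raise ValidationError(f"burst width must be > 0, got {self.width}")
        if self.amp < 0:
            raise ValidationError(f"burst amplitude must be >= 0, got {self.amp}")


@dataclass(frozen=True)
class MusclePhasing:
    """Per-muscle burst timing plus a nonnegative tonic baseline."""

    bursts: tuple[Burst, ...]
    tonic: float = 2.0

    def __post_init__(self):
        if self.tonic < 0:
            raise ValidationError("tonic baseline must be >= 0")


def _default_muscle_params() -> dict[str, MusclePhasing]:
    # Textbook level-walking EMG phasing: TA active around heel strike and in
    # swing; plantar flexors (SO, MG, PL) through stance into push-off; RF/VM
    # in loading response and pre/early swing; BF around heel strike and late
    # swing; GMax in early stance.  Amplitudes are arbitrary microvolt-like
    # units; these are generator parameters, not claims about any dataset.
    b = Burst
    return {
        "TA": MusclePhasing((b(7.5, 5.0, 60.0), b(92.5, 5.0, 60.0))),
        "SO": MusclePhasing((b(35.0, 12.0, 80.0),)),
        "MG": MusclePhasing((b(40.0, 10.0, 90.0),)),
        "PL": MusclePhasing((b(33.0, 12.0, 70.0),)),
        "RF": MusclePhasing((b(10.0, 6.0, 50.0), b(62.0, 5.0, 45.0))),
        "VM": MusclePhasing((b(10.0, 6.0, 55.0), b(62.0, 5.0, 40.0))),
        "BF": MusclePhasing((b(5.0, 4.0, 50.0), b(90.0, 6.0, 55.0))),
        "GMax": MusclePhasing((b(12.0, 8.0, 45.0),)),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic gait generator.

    Parameters
    ----------
    fs_emg, fs_mech
        Sampling rates of the EMG and mechanical (angle/moment) clocks, Hz.
    speed_range
        Closed interval of walking speeds, m/s.
    n_strides_per_trial
        Complete gait cycles per trial.
    muscle_params
        Burst centers/widths (%GC), amplitudes and tonic baseline per muscle.
    noise_floor
        Baseline additive sEMG noise SD, in the same arbitrary units as the
        burst amplitudes.
    band
        Carrier passband (Hz); must fit under the EMG Nyquist frequency.
    envelope_gain0, envelope_gain1
        Speed gain g(v) = gain0 + gain1 * v multiplying every burst; gain1 >= 0
        makes sEMG amplitude increase monotonically with walking speed.
    push_off_gain
        Multiplier on the speed-scaled push-off component of the ankle
        templates (both the plantar-flexion excursion and the moment bump).
    angle_noise_sd, moment_noise_sd
        Additive measurement-noise SDs on the mechanical channels (deg, Nm/kg).
    """

    fs_emg: float = 1000.0
    fs_mech: float = 100.0
    speed_range: tuple[float, float] = (0.3, 2.3)
    n_strides_per_trial: int = 10
    muscle_params: dict[str, MusclePhasing] = field(default_factory=_default_muscle_params)
    noise_floor: float = 2.0
    band: tuple[float, float] = (10.0, 400.0)
    envelope_gain0: float = 0.5
    envelope_gain1: float = 0.5
    push_off_gain: float = 1.0
    angle_noise_sd: float = 0.25
    moment_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.speed_range
        if not (0 < lo < hi):
            raise ValidationError("speed_range must satisfy 0 < lower < upper")
        if not (0 < self.band[0] < self.band[1] < self.fs_emg / 2):
            raise ValidationError("band must satisfy 0 < low < high < fs_emg/2")
        if self.n_strides_per_trial < 1:
            raise ValidationError("n_strides_per_trial must be >= 1")
        if set(self.muscle_params) != set(MUSCLES):
            raise ValidationError(f"muscle_params must define exactly the muscles {MUSCLES}")
        if self.noise_floor < 0 or self.envelope_gain1 < 0:
            raise ValidationError("noise_floor and envelope_gain1 must be >= 0")


@dataclass
class GaitTrial:
    """One walking trial: raw sEMG, ankle mechanics, events and metadata.

    ``emg`` is [n_emg_samples x 8] in canonical muscle order; ``angle`` (deg)
    and ``moment`` (Nm/kg) live on the mechanical clock; ``events`` are
    heel-strike sample indices on the mechanical clock.
    """

    emg: np.ndarray
    angle: np.ndarray
    moment: np.ndarray
    events: np.ndarray
    speed: float
    subject_id: str
    trial_id: str
    fs_emg: float
    fs_mech: float

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[1] != len(MUSCLES):
            raise ValidationError("emg must be [n_samples x 8]")
        n_mech = len(self.angle)
        if len(self.moment) != n_mech:
            raise ValidationError("angle and moment must share the mechanical clock")
        for name, arr in (("emg", self.emg), ("angle", self.angle), ("moment", self.moment)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if len(self.events) < 2:
            raise ValidationError("at least 2 heel-strike events (>=1 complete cycle) required")
        if np.any(np.diff(self.events) <= 0):
            raise ValidationError("events must be strictly increasing")
        if self.events[0] < 0 or self.events[-1] >= n_mech:
            raise ValidationError("events must lie within the mechanical series")
        dur_emg = self.emg.shape[0] / self.fs_emg
        dur_mech = n_mech / self.fs_mech
        if abs(dur_emg - dur_mech) > 1.0 / self.fs_mech + 1e-9:
            raise ValidationError("EMG and mechanical durations differ by more than one mechanical sample")

    @property
    def n_cycles(self) -> int:
        return len(self.events) - 1

    def emg_channel(self, muscle: str) -> np.ndarray:
        if muscle not in MUSCLES:
            raise IdentifierError(f"unknown muscle: {muscle!r}")
        return self.emg[:, MUSCLES.index(muscle)]


def stride_time(speed: float) -> float:
    """Stride duration (s) for a walking speed (m/s).

    A fixed monotone decreasing surrogate, clamped to physiological bounds:
    1.9 - 0.5 * speed, clipped to [0.8, 1.8] s.
    """
    return float(np.clip(1.9 - 0.5 * speed, 0.8, 1.8))


def _quantized_stride(speed: float, fs_mech: float) -> tuple[int, float]:
    """Stride duration snapped to the mechanical sample grid."""
    sps = int(round(fs_mech * stride_time(speed)))
    return sps, sps / fs_mech


def _circular_gauss(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump in circular %GC distance; exactly periodic in phase."""
    d = np.abs(phase - center)
    d = np.minimum(d, 100.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def activation_envelope(
    muscle_id: str, gc_phase: np.ndarray, speed: float, config: SynthConfig
) -> np.ndarray:
    """Nonnegative activation envelope of one muscle over gait phase.

    Sum of circular-Gaussian bursts in %GC scaled by the monotone speed gain
    g(v) = gain0 + gain1 * v, plus the muscle's tonic baseline.
    """
    if muscle_id not in MUSCLES:
        raise IdentifierError(f"unknown muscle: {muscle_id!r}")
    gc_phase = np.asarray(gc_phase, dtype=float)
    if np.any((gc_phase < 0) | (gc_phase >= 100)):
        raise ValidationError("gc_phase values must lie in [0, 100)")
    lo, hi = config.speed_range
    if not (lo <= speed <= hi):
        raise ValidationError(f"speed {speed} outside configured range [{lo}, {hi}]")
    mp = config.muscle_params[muscle_id]
    gain = config.envelope_gain0 + config.envelope_gain1 * speed
    env = np.zeros_like(gc_phase)
    for b in mp.bursts:
        env += b.amp * _circular_gauss(gc_phase, b.center, b.width)
    return gain * env + mp.tonic


def _bandpass_carrier(n: int, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD zero-mean Gaussian noise band-passed to the sEMG analog band.

    4th-order Butterworth applied forward-backward (zero phase).
    """
    white = rng.standard_normal(n)
    sos = sps_signal.butter(
        4, config.band, btype="bandpass", fs=config.fs_emg, output="sos"
    )
    carrier = sps_signal.sosfiltfilt(sos, white)
    carrier -= carrier.mean()
    sd = carrier.std()
    if sd > 0:
        carrier /= sd
    return carrier


def synthesize_emg(
    envelope: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Amplitude-modulated band-limited-noise sEMG surrogate.

    The envelope multiplies a unit-SD band-limited Gaussian carrier
    samplewise; additive Gaussian noise at the configured noise floor is then
    added.  The output is nonnormalized: no per-channel rescaling.
    """
    envelope = np.asarray(envelope, dtype=float)
    if not np.all(np.isfinite(envelope)):
        raise ValidationError("envelope contains non-finite values")
    if np.any(envelope < 0):
        raise ValidationError("envelope must be nonnegative")
    carrier = _bandpass_carrier(len(envelope), config, rng)
    out = envelope * carrier
    if config.noise_floor > 0:
        out = out + config.noise_floor * rng.standard_normal(len(envelope))
    return out


def ankle_templates(
    gc_phase: np.ndarray, speed: float, config: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic ankle angle (deg) and moment (Nm/kg) templates over %GC.

    Smooth periodic curves built from circular-Gaussian bumps: dorsiflexion
    through mid-stance, a speed-scaled plantar-flexion excursion at push-off,
    and a plantar-flexor moment peaking in mid-to-late stance with a small
    dorsiflexor dip after heel strike.  The moment is near zero through late
    swing.  Both curves are exactly continuous across the 100 -> 0 wrap.
    """
    gc_phase = np.asarray(gc_phase, dtype=float)
    if np.any((gc_phase < 0) | (gc_phase >= 100)):
        raise ValidationError("gc_phase values must lie in [0, 100)")
    g = _circular_gauss
    push = config.push_off_gain
    angle = (
        10.0 * g(gc_phase, 40.0, 12.0)
        - 3.0 * g(gc_phase, 6.0, 4.0)
        - push * (8.0 + 4.0 * speed) * g(gc_phase, 63.0, 5.0)
    )
    moment = (
        push * (0.8 + 0.35 * speed) * g(gc_phase, 45.0, 9.0)
        - 0.15 * g(gc_phase, 8.0, 4.0)
    )
    return angle, moment


def _phase_of_times(t: np.ndarray, stride_s: float) -> np.ndarray:
    phi = 100.0 * np.mod(t / stride_s, 1.0)
    # guard against 100.0 from floating round-off at stride boundaries
    phi[phi >= 100.0] -= 100.0
    return phi


def generate_trial(
    config: SynthConfig,
    speed: float,
    subject_id: str = "S00",
    trial_id: str = "T0000",
    seed: int = 0,
) -> GaitTrial:
    """Generate one complete synthetic walking trial.

    Stride duration follows the fixed monotone speed map (quantized to the
    mechanical grid); heel-strike events sit at stride boundaries; each EMG
    channel is an amplitude-modulated carrier under that muscle's envelope;
    angle and moment are the templates plus additive measurement noise.
    Bitwise deterministic given (config, speed, seed).
    """
    lo, hi = config.speed_range
    if not (lo <= speed <= hi):
        raise ValidationError(f"speed {speed} outside configured range [{lo}, {hi}]")
    n_strides = config.n_strides_per_trial
    sps, stride_s = _quantized_stride(speed, config.fs_mech)
    n_mech = n_strides * sps + 1
    n_emg = int(round(config.fs_emg * n_strides * stride_s))
    events = np.arange(0, n_strides + 1) * sps

    rng = np.random.default_rng(seed)
    t_emg = np.arange(n_emg) / config.fs_emg
    phi_emg = _phase_of_times(t_emg, stride_s)
    emg = np.empty((n_emg, len(MUSCLES)))
    for j, muscle in enumerate(MUSCLES):
        env = activation_envelope(muscle, phi_emg, speed, config)
        emg[:, j] = synthesize_emg(env, config, rng)

    t_mech = np.arange(n_mech) / config.fs_mech
    phi_mech = _phase_of_times(t_mech, stride_s)
    angle, moment = ankle_templates(phi_mech, speed, config)
    if config.angle_noise_sd > 0:
        angle = angle + config.angle_noise_sd * rng.standard_normal(n_mech)
    if config.moment_noise_sd > 0:
        moment = moment + config.moment_noise_sd * rng.standard_normal(n_mech)

    return GaitTrial(
        emg=emg,
        angle=angle,
        moment=moment,
        events=events,
        speed=float(speed),
        subject_id=subject_id,
        trial_id=trial_id,
        fs_emg=config.fs_emg,
        fs_mech=config.fs_mech,
    )


def sample_speeds(config: SynthConfig, n_trials: int, seed: int) -> np.ndarray:
    """Jittered-stratified walking speeds covering the configured range.

    One speed is drawn uniformly inside each of n equal-width bins and the
    bin order is shuffled, so any reasonably sized random split of the
    trials covers the full speed range.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = config.speed_range
    order = rng.permutation(n_trials)
    jitter = rng.random(n_trials)
    return lo + (hi - lo) * (order + jitter) / n_trials


def generate_dataset(config: SynthConfig, n_trials: int, seed: int) -> list[GaitTrial]:
    """Generate ``n_trials`` trials with deterministic per-trial seeds."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    speeds = sample_speeds(config, n_trials, seed)
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    trials = []
    for i in range(n_trials):
        trials.append(
            generate_trial(
                config,
                speed=float(speeds[i]),
                subject_id=f"S{i % 5:02d}",
                trial_id=f"T{i:04d}",
                seed=int(trial_seeds[i]),
            )
        )
    return trials
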