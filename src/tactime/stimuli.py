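"""Noisy vibration stimuli and the two-stimulus trial design.

A vibration is a sequence of plate velocities drawn i.i.d. from a zero-mean
Gaussian at 1 kHz.  Its *intensity* I is the mean absolute speed, which for a
zero-mean Gaussian with standard deviation sigma equals sigma * sqrt(2/pi)
(half-normal mean).  Its *duration* T is the length of the sequence in ms.

A trial presents two vibrations and is summarized by the normalized feature
differences

    delta_I = (I2 - I1) / (I2 + I1)
    delta_T = (T2 - T1) / (T2 + T1)

both bounded in (-1, 1), antisymmetric under swapping the stimuli, and zero on
the diagonal.  The psychometric design fixes stimulus 1 at a reference
(334 ms, 64 mm/s) and spans seven log-spaced comparison levels per feature, so
that the reference is the geometric mean of the design extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SAMPLE_RATE_KHZ = 1.0
#: mean of |X| for X ~ N(0, sigma^2), divided by sigma
HALF_NORMAL_FACTOR = math.sqrt(2.0 / math.pi)

#: canonical design extremes and references
DEFAULT_T1_MS = 334.0
DEFAULT_I1_MMS = 64.0
DURATION_RANGE_MS = (161.0, 694.0)
INTENSITY_RANGE_MMS = (34.0, 119.0)
N_LEVELS = 7
DEFAULT_N_SEEDS = 50

LIGHT_CONDITIONS = (
    "none",
    "excite_stim1",
    "excite_stim2",
    "inhibit_stim2",
    "external_led",
)


@dataclass(frozen=True)
class VibrationStimulus:
    """A single noisy vibration trace sampled at 1 kHz."""

    velocity_trace: np.ndarray
    duration_ms: float
    nominal_sigma: float
    seed_id: int = 0

    @property
    def intensity(self) -> float:
        """Nominal intensity: sigma * sqrt(2/pi), used to label trials."""
        return self.nominal_sigma * HALF_NORMAL_FACTOR

    @property
    def empirical_mean_speed(self) -> float:
        return float(np.mean(np.abs(self.velocity_trace)))

    @property
    def n_samples(self) -> int:
        return int(self.velocity_trace.shape[0])


def generate_vibration(
    sigma: float, duration_ms: float, rng_seed: int | np.random.Generator = 0
) -> VibrationStimulus:
    """Draw a zero-mean Gaussian velocity trace at 1 kHz.

    Parameters
    ----------
    sigma : float
        Standard deviation of the plate velocity in mm/s; must be positive.
    duration_ms : float
        Stimulus duration in ms (>= 1); the trace has
        ``floor(duration_ms * 1 kHz)`` samples.
    rng_seed : int or numpy Generator
        Source of randomness; a fixed integer gives a reproducible trace.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got sigma={sigma!r}")
    if not duration_ms >= 1:
        raise ValueError(
            f"duration_ms must be at least 1 ms, got duration_ms={duration_ms!r}"
        )
    rng = np.random.default_rng(rng_seed)
    n = int(math.floor(duration_ms * SAMPLE_RATE_KHZ))
    trace = rng.normal(0.0, sigma, size=n)
    seed_id = rng_seed if isinstance(rng_seed, (int, np.integer)) else -1
    return VibrationStimulus(trace, float(duration_ms), float(sigma), int(seed_id))


def generate_seed_set(
    sigma: float,
    duration_ms: float,
    n_seeds: int = DEFAULT_N_SEEDS,
    base_seed: int = 0,
) -> list[VibrationStimulus]:
    """Resample ``n_seeds`` traces from the same Gaussian ("seeds").

    The traces differ in local features but share the same nominal intensity.
    """
    out = []
    for k in range(n_seeds):
        stim = generate_vibration(sigma, duration_ms, base_seed + k)
        out.append(replace(stim, seed_id=k))
    return out


def delta_t(t1_ms: float, t2_ms: float) -> float:
    """Normalized duration difference (T2 - T1) / (T2 + T1)."""
    if not (t1_ms > 0 and t2_ms > 0):
        raise ValueError(f"durations must be positive, got T1={t1_ms!r}, T2={t2_ms!r}")
    return (t2_ms - t1_ms) / (t2_ms + t1_ms)


def delta_i(i1: float, i2: float) -> float:
    """Normalized intensity difference (I2 - I1) / (I2 + I1)."""
    if not (i1 > 0 and i2 > 0):
        raise ValueError(f"intensities must be positive, got I1={i1!r}, I2={i2!r}")
    return (i2 - i1) / (i2 + i1)


def congruence_label(dt: float, di: float, atol: float = 1e-12) -> str:
    """congruent if the two features point the same way, incongruent if
    opposite, neutral if either difference is zero."""
    if abs(dt) <= atol or abs(di) <= atol:
        return "neutral"
    return "congruent" if (dt > 0) == (di > 0) else "incongruent"


def log_spaced_levels(low: float, high: float, n: int = N_LEVELS) -> np.ndarray:
    """Geometric series between the design extremes (inclusive)."""
    if not (low > 0 and high > low):
        raise ValueError(f"need 0 < low < high, got low={low!r}, high={high!r}")
    return np.geomspace(low, high, n)


def duration_levels(n: int = N_LEVELS) -> np.ndarray:
    return log_spaced_levels(*DURATION_RANGE_MS, n)


def intensity_levels(n: int = N_LEVELS) -> np.ndarray:
    return log_spaced_levels(*INTENSITY_RANGE_MMS, n)


@dataclass(frozen=True)
class TrialSpec:
    """One two-stimulus comparison trial."""

    t1_ms: float
    t2_ms: float
    i1: float
    i2: float
    light: str = "none"
    task: str = "duration"

    def __post_init__(self):
        if self.light not in LIGHT_CONDITIONS:
            raise ValueError(
                f"light must be one of {LIGHT_CONDITIONS}, got {self.light!r}"
            )
        if self.task not in ("duration", "intensity"):
            raise ValueError(f"task must be duration or intensity, got {self.task!r}")

    @property
    def delta_t(self) -> float:
        return delta_t(self.t1_ms, self.t2_ms)

    @property
    def delta_i(self) -> float:
        return delta_i(self.i1, self.i2)

    @property
    def congruence(self) -> str:
        return congruence_label(self.delta_t, self.delta_i)

    def swapped(self) -> "TrialSpec":
        """Exchange stimulus 1 and stimulus 2 (labels follow the stimuli)."""
        light = {
            "excite_stim1": "excite_stim2",
            "excite_stim2": "excite_stim1",
        }.get(self.light, self.light)
        return TrialSpec(self.t2_ms, self.t1_ms, self.i2, self.i1, light, self.task)


def build_trial_matrix(
    task: str = "duration",
    durations: np.ndarray | None = None,
    intensities: np.ndarray | None = None,
    reference_t: float = DEFAULT_T1_MS,
    reference_i: float = DEFAULT_I1_MMS,
    light_conditions: tuple[str, ...] = ("none",),
) -> list[TrialSpec]:
    """Enumerate the stimulus generalization matrix.

    Stimulus 1 is fixed at the reference; stimulus 2 crosses every comparison
    duration with every comparison intensity, replicated for each requested
    light condition.  Each trial carries its delta indices and congruence
    label through :class:`TrialSpec` properties.
    """
    if durations is None:
        durations = duration_levels()
    if intensities is None:
        intensities = intensity_levels()
    durations = np.asarray(durations, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if durations.size == 0 or intensities.size == 0:
        raise ValueError("durations and intensities must be non-empty")
    trials = []
    for light in light_conditions:
        for t2 in durations:
            for i2 in intensities:
                trials.append(
                    TrialSpec(reference_t, float(t2), reference_i, float(i2), light, task)
                )
    return trials


def build_congruence_trials(
    short_t: float | None = None,
    long_t: float | None = None,
    low_i: np.ndarray | None = None,
    high_i: np.ndarray | None = None,
    reference_t: float = DEFAULT_T1_MS,
    reference_i: float = DEFAULT_I1_MMS,
    light: str = "none",
    task: str = "duration",
) -> list[TrialSpec]:
    """Trials for the congruence analysis: stimulus 2 short & low or long &
    high (congruent) versus short & high or long & low (incongruent), judged
    against the intermediate reference."""
    levels_t = duration_levels()
    levels_i = intensity_levels()
    if short_t is None:
        short_t = float(levels_t[2])  # ~262 ms
    if long_t is None:
        long_t = float(levels_t[4])  # ~426 ms
    if low_i is None:
        low_i = levels_i[:3]  # ~34, 42, 52 mm/s
    if high_i is None:
        high_i = levels_i[4:]  # ~78, 96, 119 mm/s
    trials = []
    for t2 in (short_t, long_t):
        for i2 in np.concatenate([np.asarray(low_i), np.asarray(high_i)]):
            trials.append(TrialSpec(reference_t, float(t2), reference_i, float(i2), light, task))
    return trials


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Tabulate a trial list (columns: trial, T1, T2, I1, I2, light,
    congruence, task plus the delta indices)."""
    rows = []
    for k, tr in enumerate(trials):
        rows.append(
            dict(
                trial=k,
                T1=tr.t1_ms,
                T2=tr.t2_ms,
                I1=tr.i1,
                I2=tr.i2,
                light=tr.light,
                congruence=tr.congruence,
                task=tr.task,
                delta_T=tr.delta_t,
                delta_I=tr.delta_i,
            )
        )
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(r.T1, r.T2, r.I1, r.I2, r.light, r.task)
        for r in frame.itertuples(index=False)
    ]


def stimulus_to_frame(stim: VibrationStimulus) -> pd.DataFrame:
    """Trace as (time_ms, velocity_mm_s) suitable for CSV round-trips."""
    t = np.arange(stim.n_samples) / SAMPLE_RATE_KHZ
    return pd.DataFrame({"time_ms": t, "velocity_mm_s": stim.velocity_trace})
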