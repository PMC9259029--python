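"""Synthetic roll-stimulus waveforms and head-roll response trials.

Generates the sinusoidal tether stimulus (optionally with quarter-cycle
linear on/off ramps) and head-relative-to-thorax responses with known
generative gain and phase, plus wingbeat-band contamination (~30 Hz),
low-amplitude head wobble (~12 Hz) and broadband noise, so that the whole
downstream metrics pipeline can be validated against ground truth.
All angles are degrees at the interface; radians are used only internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "StimulusSpec",
    "ResponseModel",
    "FeedbackModel",
    "TrialMeta",
    "Trial",
    "generate_stimulus",
    "generate_response",
    "simulate_feedback_loop",
    "feedback_frequency_response",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the imposed sinusoidal roll stimulus.

    ``amplitude`` is the half-range in degrees (peak-to-peak = 2 * amplitude).
    When ``ramp_endpoints`` is set, the first and last quarter cycle of the
    sinusoid are replaced by linear ramps joining 0 to the adjacent extreme,
    which keeps the mean absolute angular speed at ``4 * amplitude * frequency``
    while avoiding the acceleration spike of a cold sinusoid start.
    """

    frequency: float = 2.0
    amplitude: float = 30.0
    n_cycles: int = 8
    sample_rate: float = 1200.0
    ramp_endpoints: bool = True

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.sample_rate <= 2 * self.frequency:
            raise ValueError(
                "sample_rate must exceed 2 * frequency "
                f"(got fs={self.sample_rate}, f={self.frequency})"
            )

    @property
    def n_samples(self) -> int:
        """Number of samples covering ``n_cycles`` full periods (endpoint open)."""
        return int(round(self.n_cycles / self.frequency * self.sample_rate))

    @property
    def period_samples(self) -> int:
        """Samples per stimulus period (rounded)."""
        return int(round(self.sample_rate / self.frequency))

    @property
    def ramp_samples(self) -> int:
        """Samples in one quarter-cycle ramp (0 when ramps are disabled)."""
        if not self.ramp_endpoints:
            return 0
        return int(round(self.sample_rate / (4.0 * self.frequency)))

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency


@dataclass(frozen=True)
class ResponseModel:
    """Generative model of the head-relative-to-thorax response.

    ``gain`` and ``phase`` (degrees) are the ground-truth polar response:
    the deterministic part of the output is
    ``gain * amplitude * sin(2*pi*f*t + phase)``.  Phase 180 deg is perfect
    anti-phase compensation.  On top of that the model adds a wingbeat-band
    sinusoid (default 30 Hz), a small head-wobble sinusoid (default 12 Hz) —
    each with a per-trial random phase — and white Gaussian noise.
    """

    gain: float = 0.6
    phase: float = 177.6
    wingbeat_freq: float = 30.0
    wingbeat_amp: float = 2.0
    wobble_freq: float = 12.0
    wobble_amp: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError(f"gain must be >= 0, got {self.gain}")
        for name in ("wingbeat_amp", "wobble_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.wingbeat_freq <= 0 or self.wobble_freq <= 0:
            raise ValueError("contamination frequencies must be > 0")


@dataclass(frozen=True)
class FeedbackModel:
    """Two-channel delayed feedback driving the head command.

    Head command = -(visual_gain * stim delayed by visual_delay
                     + mech_gain * stim delayed by mech_delay),
    low-pass filtered by a first-order lag with ``neck_time_constant``.
    This is a deliberately simple extrapolation of a two-pathway loop;
    no claim of biomechanical fidelity is made.
    """

    visual_gain: float = 1.0
    visual_delay: float = 0.0
    mech_gain: float = 0.0
    mech_delay: float = 0.0
    neck_time_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.visual_gain < 0 or self.mech_gain < 0:
            raise ValueError("feedback gains must be >= 0")
        if self.visual_delay < 0 or self.mech_delay < 0:
            raise ValueError("delays must be >= 0")
        if self.neck_time_constant < 0:
            raise ValueError("neck_time_constant must be >= 0")


@dataclass(frozen=True)
class TrialMeta:
    frequency: float
    amplitude: float
    light_condition: str = ""
    treatment: str = ""
    animal_id: str = ""
    trial_id: str = ""


@dataclass
class Trial:
    """One stimulus-response recording: uniform time base plus two angle series."""

    time: np.ndarray
    theta_thorax: np.ndarray
    theta_head_thorax: np.ndarray
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.theta_thorax = np.asarray(self.theta_thorax, dtype=float)
        self.theta_head_thorax = np.asarray(self.theta_head_thorax, dtype=float)
        n = self.time.size
        if self.theta_thorax.size != n or self.theta_head_thorax.size != n:
            raise ValueError("angle series must match the time base in length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time must be uniformly sampled")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def __len__(self) -> int:
        return int(self.time.size)


def generate_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Return the thorax-roll stimulus (degrees) defined by ``spec``.

    The base waveform is ``amplitude * sin(2*pi*frequency*t)`` sampled at
    ``sample_rate`` over ``n_cycles`` periods.  With ``ramp_endpoints`` the
    first quarter cycle becomes a line 0 -> +amplitude and the last quarter
    cycle a line -amplitude -> 0, each of duration ``1/(4*frequency)``;
    position stays continuous and the waveform starts/ends at 0 (within one
    sample).  Identical specs yield bitwise-identical arrays.
    """
    f, a, fs = spec.frequency, spec.amplitude, spec.sample_rate
    n = spec.n_samples
    t = np.arange(n) / fs
    theta = a * np.sin(2.0 * np.pi * f * t)
    if spec.ramp_endpoints:
        nq = spec.ramp_samples
        slope = 4.0 * a * f  # reaches the extreme in exactly 1/(4f) s
        theta[:nq] = slope * t[:nq]
        # last quarter cycle: sinusoid sits at -a at t = duration - 1/(4f)
        t0 = spec.duration - 1.0 / (4.0 * f)
        theta[n - nq:] = -a + slope * (t[n - nq:] - t0)
    return theta


def generate_response(
    stimulus: np.ndarray,
    model: ResponseModel,
    spec: StimulusSpec,
    meta: TrialMeta | None = None,
) -> Trial:
    """Build a synthetic trial around ``stimulus`` with known gain/phase.

    The deterministic component ignores the stimulus ramps on purpose: it is
    the steady-state sinusoidal response, and the ramp windows are excluded
    from analysis downstream.  The same seed always produces the same trial.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.size != spec.n_samples:
        raise ValueError(
            f"stimulus length {stimulus.size} does not match spec ({spec.n_samples})"
        )
    rng = np.random.default_rng(model.seed)
    t = np.arange(spec.n_samples) / spec.sample_rate
    phi = np.deg2rad(model.phase)
    resp = model.gain * spec.amplitude * np.sin(2.0 * np.pi * spec.frequency * t + phi)
    # contamination phases are always drawn so the seed stream is stable
    wb_phase, wob_phase = rng.uniform(0.0, 2.0 * np.pi, size=2)
    resp = resp + model.wingbeat_amp * np.sin(
        2.0 * np.pi * model.wingbeat_freq * t + wb_phase
    )
    resp = resp + model.wobble_amp * np.sin(
        2.0 * np.pi * model.wobble_freq * t + wob_phase
    )
    resp = resp + rng.normal(0.0, model.noise_sd, size=spec.n_samples)
    if meta is None:
        meta = TrialMeta(frequency=spec.frequency, amplitude=spec.amplitude)
    return Trial(time=t, theta_thorax=stimulus, theta_head_thorax=resp, meta=meta)


def _delay(x: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return x.copy()
    out = np.empty_like(x)
    out[:n] = 0.0
    out[n:] = x[:-n]
    return out


def simulate_feedback_loop(
    stimulus: np.ndarray,
    fb: FeedbackModel,
    spec: StimulusSpec,
    meta: TrialMeta | None = None,
) -> Trial:
    """Drive the two-delay feedback model with ``stimulus`` and package a Trial.

    Delays are rounded to whole samples; the first-order neck lag uses the
    exact exponential update ``y[n] = a*y[n-1] + (1-a)*u[n]`` with
    ``a = exp(-dt/tau)``, so :func:`feedback_frequency_response` is an exact
    oracle for the steady-state output.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.size != spec.n_samples:
        raise ValueError("stimulus length does not match spec")
    fs = spec.sample_rate
    nv = int(round(fb.visual_delay * fs))
    nm = int(round(fb.mech_delay * fs))
    if nv >= stimulus.size or nm >= stimulus.size:
        raise ValueError("feedback delay exceeds the record length")
    u = -(fb.visual_gain * _delay(stimulus, nv) + fb.mech_gain * _delay(stimulus, nm))
    if fb.neck_time_constant > 0:
        a = np.exp(-1.0 / (fs * fb.neck_time_constant))
        y = signal.lfilter([1.0 - a], [1.0, -a], u)
    else:
        y = u
    t = np.arange(spec.n_samples) / fs
    if meta is None:
        meta = TrialMeta(frequency=spec.frequency, amplitude=spec.amplitude)
    return Trial(time=t, theta_thorax=stimulus, theta_head_thorax=y, meta=meta)


def feedback_frequency_response(fb: FeedbackModel, frequency: float, sample_rate: float) -> complex:
    """Exact discrete-time transfer function of :func:`simulate_feedback_loop`.

    Evaluated at ``frequency`` with the same sample-rounded delays and
    exponential low-pass discretization; ``abs()`` is the steady-state gain
    and ``angle()`` the response phase relative to the stimulus.
    """
    w = 2.0 * np.pi * frequency / sample_rate  # radians per sample
    nv = int(round(fb.visual_delay * sample_rate))
    nm = int(round(fb.mech_delay * sample_rate))
    h = -(fb.visual_gain * np.exp(-1j * w * nv) + fb.mech_gain * np.exp(-1j * w * nm))
    if fb.neck_time_constant > 0:
        a = np.exp(-1.0 / (sample_rate * fb.neck_time_constant))
        h = h * (1.0 - a) / (1.0 - a * np.exp(-1j * w))
    return complex(h)
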