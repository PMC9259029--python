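"""Per-trial response quantification: gain, phase, compensation error, coherence.

Conventions
-----------
* Phases are degrees in [0, 360).  A response ``g*A*sin(2*pi*f*t + psi)`` to
  the stimulus ``A*sin(2*pi*f*t)`` has phase ``psi``; 180 deg is perfect
  anti-phase compensation.  Both estimators (cross-correlation lag and FFT
  angle difference) recover ``psi`` under this convention.
* The compensation error ``epsilon`` of a polar response (r, theta) is its
  distance in the polar plane from the perfect-stabilization point (1, 180):
  ``epsilon = sqrt(1 + r**2 + 2*r*cos(theta))``, ranging 0..2 for r <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import AnalysisWindow, exclude_ramps, lowpass_filter
from .synthetic_data import StimulusSpec, Trial

__all__ = [
    "PolarResponse",
    "TrialMetrics",
    "PsdConfig",
    "AnalysisConfig",
    "UndefinedPhaseError",
    "amplitude_at",
    "compute_gain",
    "phase_xcorr",
    "phase_fft",
    "polar_distance",
    "compensation_error",
    "msc_coherence",
    "analyze_trial",
]

#: polar coordinates of perfect head stabilization (unit gain, anti-phase)
PERFECT_STABILIZATION = (1.0, 180.0)


class UndefinedPhaseError(ValueError):
    """Raised when a phase estimate is undefined (flat / zero-power series)."""


@dataclass(frozen=True)
class PolarResponse:
    """A (gain, phase-degrees) point in the polar response plane."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"gain must be >= 0, got {self.r}")
        object.__setattr__(self, "theta", float(self.theta) % 360.0)


@dataclass(frozen=True)
class PsdConfig:
    """Welch parameters for the coherence estimate.

    One stimulus cycle per segment gives enough averages on a 7-cycle
    analysis window to keep the independent-noise coherence floor near 0.1
    (two-cycle segments leave it above 0.2).
    """

    cycles_per_segment: float = 1.0
    overlap: float = 0.5
    window: str = "hann"

    def nperseg(self, f: float, sample_rate: float) -> int:
        return int(round(self.cycles_per_segment * sample_rate / f))


@dataclass(frozen=True)
class AnalysisConfig:
    filter_order: int = 7
    filter_cutoff: float = 25.0
    epsilon_phase: str = "xcorr"  # or "fft"
    min_stim_amplitude: float = 1e-6
    psd: PsdConfig = field(default_factory=PsdConfig)


@dataclass(frozen=True)
class TrialMetrics:
    """Derived quantities of a single trial.

    ``phase_xcorr``/``phase_fft`` are NaN (with ``"phase_undefined"`` in
    ``flags``) when the response carries no signal to phase against.
    """

    gain: float
    phase_xcorr: float
    phase_fft: float
    epsilon: float
    coherence: float
    stim_amplitude: float
    resp_amplitude: float
    flags: tuple[str, ...] = ()


def _windowed(series: np.ndarray, window: AnalysisWindow) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if window.end > series.size:
        raise ValueError("analysis window exceeds series length")
    return series[window.slice]


def _exact_bin(f: float, n: int, sample_rate: float) -> int:
    """DFT bin index of frequency ``f`` for an ``n``-sample window."""
    k = f * n / sample_rate
    if k < 1.0:
        raise ValueError(
            f"window of {n} samples is shorter than one cycle of {f} Hz"
        )
    k_round = int(round(k))
    if abs(k - k_round) > 1e-6:
        raise ValueError(
            f"{f} Hz is not on the DFT grid of a {n}-sample window at "
            f"{sample_rate} Hz (bin {k:.6f}); trim to whole cycles first"
        )
    return k_round


def amplitude_at(
    series: np.ndarray, f: float, sample_rate: float, window: AnalysisWindow
) -> float:
    """Single-sided Fourier amplitude (degrees, half-range) at frequency ``f``.

    The window must span a whole number of cycles of ``f`` so that the
    component falls on an exact DFT bin (no leakage, no interpolation).
    """
    x = _windowed(series, window)
    k = _exact_bin(f, x.size, sample_rate)
    spectrum = np.fft.rfft(x)
    return 2.0 * abs(spectrum[k]) / x.size


def compute_gain(
    stim: np.ndarray,
    resp: np.ndarray,
    f: float,
    sample_rate: float,
    window: AnalysisWindow,
    min_stim_amplitude: float = 1e-6,
) -> float:
    """Amplitude-ratio gain: response amplitude over stimulus amplitude at ``f``."""
    a_stim = amplitude_at(stim, f, sample_rate, window)
    if a_stim < min_stim_amplitude:
        raise ValueError(
            f"stimulus amplitude at {f} Hz ({a_stim:.3g} deg) is below the "
            f"floor ({min_stim_amplitude:.3g} deg): no stimulus to normalize by"
        )
    return amplitude_at(resp, f, sample_rate, window) / a_stim


def phase_xcorr(
    stim: np.ndarray,
    resp: np.ndarray,
    f: float,
    sample_rate: float,
    window: AnalysisWindow,
) -> float:
    """Phase (degrees, [0, 360)) from the lag maximizing the cross-correlation.

    The correlation is circular, which is exact because the analysis window
    spans a whole number of stimulus cycles (a linear correlation's
    ``N - |lag|`` overlap taper would bias the peak toward zero lag).  The
    search is restricted to one stimulus period on either side of zero; among
    numerical ties the smallest ``|lag|`` wins.  The lag is converted through
    ``phase = 360 * f * dt`` with the sign fixed so that a response
    ``sin(2*pi*f*t + psi)`` yields ``psi`` — the same convention as
    :func:`phase_fft`.  Resolution is one sample, i.e. ``360*f/sample_rate``
    degrees.
    """
    s = _windowed(stim, window)
    r = _windowed(resp, window)
    s = s - s.mean()
    r = r - r.mean()
    if not np.any(s) or not np.any(r):
        raise UndefinedPhaseError("phase undefined for a flat (zero-variance) series")
    period = int(round(sample_rate / f))
    n = s.size
    # circular cross-correlation: c[k] = sum_n r[n] * s[(n - k) mod N]
    c = np.fft.irfft(np.fft.rfft(r) * np.conj(np.fft.rfft(s)), n)
    lags = np.arange(n)
    lags[lags > n // 2] -= n
    keep = np.abs(lags) <= period
    c, lags = c[keep], lags[keep]
    cmax = c.max()
    tol = 1e-9 * max(abs(cmax), 1.0)
    tied = np.flatnonzero(c >= cmax - tol)
    best = tied[np.lexsort((lags[tied], np.abs(lags[tied])))[0]]
    # correlate(r, s) peaks at lag = -psi/omega for r = sin(w n + psi)
    dt = lags[best] / sample_rate
    return (-360.0 * f * dt) % 360.0


def phase_fft(
    stim: np.ndarray,
    resp: np.ndarray,
    f: float,
    sample_rate: float,
    window: AnalysisWindow,
) -> float:
    """Phase (degrees, [0, 360)) from the FFT angle difference at the ``f`` bin.

    Unlike :func:`phase_xcorr` this is not quantized to the lag grid.
    """
    s = _windowed(stim, window)
    r = _windowed(resp, window)
    k = _exact_bin(f, s.size, sample_rate)
    s_c = np.fft.rfft(s - s.mean())[k]
    r_c = np.fft.rfft(r - r.mean())[k]
    scale = 2.0 / s.size
    if abs(s_c) * scale < 1e-12 or abs(r_c) * scale < 1e-12:
        raise UndefinedPhaseError(
            f"phase undefined: no power at {f} Hz in stimulus or response"
        )
    return float(np.degrees(np.angle(r_c) - np.angle(s_c)) % 360.0)


def polar_distance(p1: PolarResponse, p2: PolarResponse) -> float:
    """Euclidean distance between two polar points (law of cosines)."""
    dtheta = math.radians(p1.theta - p2.theta)
    d2 = p1.r**2 + p2.r**2 - 2.0 * p1.r * p2.r * math.cos(dtheta)
    return math.sqrt(max(d2, 0.0))


def compensation_error(p: PolarResponse) -> float:
    """Distance of a polar response from perfect stabilization (1, 180 deg).

    ``epsilon = sqrt(1 + r**2 + 2*r*cos(theta))``: 0 at (1, 180), 2 at (1, 0),
    1 at r = 0.
    """
    e2 = 1.0 + p.r**2 + 2.0 * p.r * math.cos(math.radians(p.theta))
    return math.sqrt(max(e2, 0.0))


def msc_coherence(
    stim: np.ndarray,
    resp: np.ndarray,
    f: float,
    sample_rate: float,
    window: AnalysisWindow,
    psd_config: PsdConfig | None = None,
) -> float:
    """Magnitude-squared coherence at the bin nearest ``f`` (Welch estimate).

    ``Cxy(f) = |Pxy|**2 / (Pxx * Pyy)`` in [0, 1].  Requires at least two
    averaging segments — a single-segment estimate is identically 1 and is
    rejected with a pointer to ``psd_config``.
    """
    cfg = psd_config or PsdConfig()
    s = _windowed(stim, window)
    r = _windowed(resp, window)
    nperseg = cfg.nperseg(f, sample_rate)
    noverlap = int(round(cfg.overlap * nperseg))
    step = nperseg - noverlap
    n_segments = 1 + max(s.size - nperseg, 0) // step if s.size >= nperseg else 0
    if n_segments < 2:
        raise ValueError(
            f"window of {s.size} samples yields {n_segments} Welch segment(s) "
            f"of {nperseg} samples; need >= 2 (a single segment is trivially "
            "coherent) — shorten psd_config.cycles_per_segment"
        )
    freqs, cxy = signal.coherence(
        s, r, fs=sample_rate, window=cfg.window, nperseg=nperseg, noverlap=noverlap
    )
    value = float(cxy[np.argmin(np.abs(freqs - f))])
    return min(max(value, 0.0), 1.0)


def _stage(name: str):
    """Context manager tagging errors with the pipeline stage that raised them."""

    class _Stage:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, UndefinedPhaseError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False

    return _Stage()


def analyze_trial(
    trial: Trial,
    spec: StimulusSpec,
    config: AnalysisConfig | None = None,
) -> TrialMetrics:
    """Full per-trial pipeline: filter, exclude ramps, gain/phase/epsilon/coherence.

    Both series pass the identical zero-phase filter so any residual filter
    phase cancels in the phase difference.  Undefined phases (flat responses)
    are reported as NaN with a ``"phase_undefined"`` flag rather than 0.
    Deterministic for fixed input.
    """
    cfg = config or AnalysisConfig()
    f = spec.frequency
    fs = spec.sample_rate
    flags: list[str] = []

    with _stage("lowpass_filter"):
        stim_f = lowpass_filter(trial.theta_thorax, fs, cfg.filter_order, cfg.filter_cutoff)
        resp_f = lowpass_filter(trial.theta_head_thorax, fs, cfg.filter_order, cfg.filter_cutoff)
    with _stage("exclude_ramps"):
        window = exclude_ramps(trial, spec)
    with _stage("amplitude"):
        stim_amp = amplitude_at(stim_f, f, fs, window)
        resp_amp = amplitude_at(resp_f, f, fs, window)
    with _stage("gain"):
        gain = compute_gain(stim_f, resp_f, f, fs, window, cfg.min_stim_amplitude)

    try:
        with _stage("phase"):
            ph_x = phase_xcorr(stim_f, resp_f, f, fs, window)
            ph_f = phase_fft(stim_f, resp_f, f, fs, window)
    except UndefinedPhaseError:
        ph_x = ph_f = float("nan")
        flags.append("phase_undefined")

    phase_for_eps = ph_x if cfg.epsilon_phase == "xcorr" else ph_f
    if math.isnan(phase_for_eps):
        # with no phase the error is only defined at r = 0, where it is 1
        eps = 1.0 if gain < 1e-9 else float("nan")
        if math.isnan(eps):
            flags.append("epsilon_undefined")
    else:
        with _stage("epsilon"):
            eps = compensation_error(PolarResponse(gain, phase_for_eps))

    resp_win = resp_f[window.slice]
    if np.allclose(resp_win, resp_win.mean()):
        coh = float("nan")
        flags.append("coherence_undefined")
    else:
        with _stage("coherence"):
            coh = msc_coherence(stim_f, resp_f, f, fs, window, cfg.psd)

    return TrialMetrics(
        gain=float(gain),
        phase_xcorr=float(ph_x),
        phase_fft=float(ph_f),
        epsilon=float(eps),
        coherence=coh,
        stim_amplitude=float(stim_amp),
        resp_amplitude=float(resp_amp),
        flags=tuple(flags),
    )
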