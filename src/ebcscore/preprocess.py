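"""Raw EMG trace -> standardized envelope.

The scoring chain is: full-wave rectification, integration with a 1-ms
time constant, then per-trial standardization (z-score) against the
0-300 ms pre-CS baseline.  The trial threshold is the baseline mean plus
4 baseline SDs of the standardized envelope; because standardization uses
the same baseline's sample statistics, the threshold equals the SD
multiplier (4.0) exactly, per trial, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError, DegenerateTrialError

#: tolerance (ms) for comparisons on the sample time grid
TIME_EPS_MS = 1e-6

DEFAULT_FS = 10_000.0
DEFAULT_BASELINE_MS = (-300.0, 0.0)
DEFAULT_THRESHOLD_MULTIPLIER = 4.0
DEFAULT_TAU_MS = 1.0

INTEGRATORS = ("exponential", "boxcar")


@dataclass
class RawTrace:
    """One trial's EMG samples on a fixed time axis relative to CS onset."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    t0_ms: float = -300.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigurationError("RawTrace.samples must be one-dimensional")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) * self.dt_ms

    @property
    def span_ms(self) -> Tuple[float, float]:
        return (self.t0_ms, self.t0_ms + self.samples.size * self.dt_ms)


@dataclass
class StandardizedTrace:
    """Integrated, baseline-z-scored envelope plus its baseline statistics.

    ``z`` is unitless; ``baseline_mean``/``baseline_sd`` are in envelope
    units (of the pre-standardization envelope); ``threshold`` is in z
    units and equals ``threshold_multiplier`` for any valid trial.
    """

    z: np.ndarray
    fs: float
    t0_ms: float
    baseline_mean: float
    baseline_sd: float
    threshold: float
    baseline_window_ms: Tuple[float, float] = DEFAULT_BASELINE_MS
    threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.z.size) * self.dt_ms


def rectify(trace: RawTrace) -> RawTrace:
    """Full-wave rectification: sample-wise absolute value, same time axis."""
    return RawTrace(np.abs(trace.samples), fs=trace.fs, t0_ms=trace.t0_ms)


def integrate_array(x: np.ndarray, fs: float, tau_ms: float = DEFAULT_TAU_MS,
                    method: str = "exponential") -> np.ndarray:
    """Integrate a rectified sample array with time constant ``tau_ms``.

    ``exponential`` (default): first-order leaky integrator
    ``y[i] = a*y[i-1] + (1-a)*x[i]`` with ``a = exp(-dt/tau)``, unit DC
    gain, initialized at the first input sample (avoids a baseline ramp).
    ``boxcar``: causal moving average over ``round(tau*fs)`` samples.
    """
    if tau_ms <= 0:
        raise ConfigurationError("integration time constant tau_ms must be > 0")
    if method not in INTEGRATORS:
        raise ConfigurationError(f"unknown integrator {method!r}; expected one of {INTEGRATORS}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    dt_ms = 1000.0 / fs
    if method == "exponential":
        a = np.exp(-dt_ms / tau_ms)
        y, _ = lfilter([1.0 - a], [1.0, -a], x, zi=np.array([a * x[0]]))
        return y
    # boxcar: causal mean of the last w samples, edges padded with x[0]
    w = max(1, int(round(tau_ms * fs / 1000.0)))
    padded = np.concatenate([np.full(w - 1, x[0]), x])
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def integrate(trace: RawTrace, tau_ms: float = DEFAULT_TAU_MS,
              method: str = "exponential") -> RawTrace:
    """Integrate a rectified trace; see :func:`integrate_array`."""
    y = integrate_array(trace.samples, trace.fs, tau_ms=tau_ms, method=method)
    return RawTrace(y, fs=trace.fs, t0_ms=trace.t0_ms)


def baseline_mask(times_ms: np.ndarray,
                  window_ms: Tuple[float, float] = DEFAULT_BASELINE_MS) -> np.ndarray:
    """Samples in the half-open baseline window [lo, hi) on the time grid."""
    lo, hi = window_ms
    return (times_ms >= lo - TIME_EPS_MS) & (times_ms < hi - TIME_EPS_MS)


def standardize(envelope: RawTrace,
                baseline_window_ms: Tuple[float, float] = DEFAULT_BASELINE_MS,
                threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
                ) -> StandardizedTrace:
    """Z-score an envelope against its own pre-CS baseline.

    Raises :class:`DegenerateTrialError` when the baseline SD is zero or
    non-finite (flat baseline); the pipeline marks such trials invalid
    rather than crashing.
    """
    lo, hi = baseline_window_ms
    if not lo < hi:
        raise ConfigurationError("baseline window must have lo < hi")
    t = envelope.times_ms
    if lo < t[0] - TIME_EPS_MS or hi > t[-1] + envelope.dt_ms + TIME_EPS_MS:
        raise ConfigurationError("baseline window lies outside the trace span")
    mask = baseline_mask(t, baseline_window_ms)
    if mask.sum() < 2:
        raise ConfigurationError("baseline window contains fewer than 2 samples")
    base = envelope.samples[mask]
    mean = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    if not np.isfinite(sd) or sd <= 0.0:
        raise DegenerateTrialError("flat baseline: zero baseline SD, trial cannot be standardized")
    z = (envelope.samples - mean) / sd
    st = StandardizedTrace(z=z, fs=envelope.fs, t0_ms=envelope.t0_ms,
                           baseline_mean=mean, baseline_sd=sd,
                           threshold=float("nan"),
                           baseline_window_ms=tuple(baseline_window_ms),
                           threshold_multiplier=threshold_multiplier)
    st.threshold = compute_threshold(st)
    return st


def compute_threshold(st: StandardizedTrace) -> float:
    """Trial threshold: baseline mean + multiplier * baseline SD, in z units.

    Equals the multiplier (default 4.0) to numerical tolerance because the
    standardized baseline has sample mean 0 and SD 1 by construction.
    """
    zb = st.z[baseline_mask(st.times_ms, st.baseline_window_ms)]
    return float(np.mean(zb) + st.threshold_multiplier * np.std(zb, ddof=1))


def process_trace(raw: RawTrace, tau_ms: float = DEFAULT_TAU_MS,
                  integrator: str = "exponential",
                  baseline_window_ms: Tuple[float, float] = DEFAULT_BASELINE_MS,
                  threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
                  ) -> StandardizedTrace:
    """Full preprocessing chain: rectify -> integrate -> standardize."""
    env = integrate(rectify(raw), tau_ms=tau_ms, method=integrator)
    return standardize(env, baseline_window_ms=baseline_window_ms,
                       threshold_multiplier=threshold_multiplier)
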