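import numpy as np
import pytest

from ebcscore.preprocess import StandardizedTrace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_standardized(z, fs=10_000.0, t0_ms=-300.0, threshold=4.0,
                      multiplier=4.0, baseline_window_ms=(-300.0, 0.0)):
    """Directly construct a standardized trace with a known z array."""
    return StandardizedTrace(z=np.asarray(z, dtype=float), fs=fs, t0_ms=t0_ms,
                             baseline_mean=0.0, baseline_sd=1.0,
                             threshold=threshold,
                             baseline_window_ms=baseline_window_ms,
                             threshold_multiplier=multiplier)


def square_z_trace(bursts, span_ms=(-300.0, 3400.0), fs=10_000.0,
                   base_sd=0.5, rng=None, threshold=4.0):
    """Standardized trace with exact square supra-threshold runs.

    Each burst is (onset_ms, duration_ms, amplitude_z) occupying the
    half-open sample range [onset, onset + duration), so the run length in
    samples is exactly duration * fs / 1000.
    """
    n = int(round((span_ms[1] - span_ms[0]) * fs / 1000.0))
    if rng is None:
        z = np.zeros(n)
    else:
        z = rng.normal(0.0, base_sd, n)
    for onset, dur, amp in bursts:
        i0 = int(round((onset - span_ms[0]) * fs / 1000.0))
        i1 = i0 + int(round(dur * fs / 1000.0))
        z[i0:i1] = amp
    return make_standardized(z, fs=fs, t0_ms=span_ms[0], threshold=threshold)
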