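"""Supra-threshold epoch detection, hyperactivity exclusion and CR classification.

A conditioned response (CR) is a contiguous run of standardized-envelope
samples strictly above the trial threshold, lasting strictly more than
10 ms, whose onset falls in the valid CR period 121-3292 ms after CS
onset.  The valid period is split into short (121-1180 ms), middle
(1181-2240 ms) and late/long (2241-3292 ms) latency windows; an epoch
belongs to the window containing its onset.  Trials whose pre-CS baseline
itself crosses threshold for >10 ms are hyperactivity trials and are
excluded from all further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ContractError
from .preprocess import TIME_EPS_MS, StandardizedTrace

DEFAULT_MIN_DURATION_MS = 10.0
WINDOW_NAMES = ("short", "middle", "long")
PEAK_SCOPES = ("epochs", "valid_period")


@dataclass(frozen=True)
class LatencyWindows:
    """Valid CR period and its three latency windows (ms from CS onset).

    The printed bounds are integer-inclusive; on the sample time grid
    membership is evaluated half-open at each internal boundary
    (short [121, 1181), middle [1181, 2241), long [2241, 3292]) so the
    windows are disjoint and tile the whole valid period.
    """

    valid_ms: Tuple[float, float] = (121.0, 3292.0)
    short_ms: Tuple[float, float] = (121.0, 1180.0)
    middle_ms: Tuple[float, float] = (1181.0, 2240.0)
    long_ms: Tuple[float, float] = (2241.0, 3292.0)

    def __post_init__(self) -> None:
        edges = [self.short_ms, self.middle_ms, self.long_ms]
        if not (abs(self.short_ms[0] - self.valid_ms[0]) < 1e-9
                and abs(self.long_ms[1] - self.valid_ms[1]) < 1e-9):
            raise ConfigurationError("latency windows must span the valid CR period")
        for (a, b), (c, d) in zip(edges, edges[1:]):
            if not (a < b < c < d):
                raise ConfigurationError("latency windows must be ordered and disjoint")

    @property
    def names(self) -> Tuple[str, ...]:
        return WINDOW_NAMES

    def bounds(self, name: str) -> Tuple[float, float]:
        try:
            return {"short": self.short_ms, "middle": self.middle_ms,
                    "long": self.long_ms}[name]
        except KeyError:
            raise ConfigurationError(f"unknown latency window {name!r}") from None

    def window_of(self, onset_ms: float) -> Optional[str]:
        """Window containing an epoch onset, or None outside the valid period."""
        if onset_ms < self.valid_ms[0] - TIME_EPS_MS or onset_ms > self.valid_ms[1] + TIME_EPS_MS:
            return None
        if onset_ms < self.middle_ms[0] - TIME_EPS_MS:
            return "short"
        if onset_ms < self.long_ms[0] - TIME_EPS_MS:
            return "middle"
        return "long"


@dataclass(frozen=True)
class Epoch:
    """A maximal contiguous supra-threshold run."""

    onset_ms: float
    offset_ms: float
    duration_ms: float
    peak_z: float
    peak_time_ms: float
    i0: int = field(compare=False, default=-1)  # sample slice [i0, i1)
    i1: int = field(compare=False, default=-1)


@dataclass
class CrMetrics:
    start_latency_ms: float
    peak_latency_ms: float
    peak_amplitude_z: float


@dataclass
class TrialClassification:
    """Validity flags, detected epochs and per-window CR calls for one trial."""

    trial_index: Optional[int] = None
    trial_type: Optional[str] = None
    is_hyperactive: bool = False
    is_valid: bool = True
    reason: Optional[str] = None
    epochs: List[Epoch] = field(default_factory=list)
    cr_flags: Dict[str, bool] = field(default_factory=dict)
    metrics: Dict[str, Optional[CrMetrics]] = field(default_factory=dict)


def _min_run_samples(min_duration_ms: float, fs: float) -> int:
    # run duration is run-length * sample period; strict ">" evaluated in
    # integer sample space to dodge float round-off (10 ms @ 10 kHz -> 101)
    return int(np.floor(min_duration_ms * fs / 1000.0 + 1e-9)) + 1


def _runs(above: np.ndarray) -> List[Tuple[int, int]]:
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def detect_epochs(st: StandardizedTrace,
                  interval_ms: Tuple[float, float],
                  min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
                  right_closed: bool = True) -> List[Epoch]:
    """Maximal runs with z strictly above threshold, onset in ``interval_ms``,
    duration strictly greater than ``min_duration_ms``; ordered by onset.

    ``right_closed=False`` makes the interval half-open on the right (used
    for the pre-CS baseline window).  Runs are found over the whole trace;
    only the onset is constrained to the interval.
    """
    lo, hi = interval_ms
    t = st.times_ms
    if lo < t[0] - TIME_EPS_MS or hi > t[-1] + st.dt_ms + TIME_EPS_MS:
        raise ConfigurationError("detection interval lies outside the trace span")
    n_min = _min_run_samples(min_duration_ms, st.fs)
    above = st.z > st.threshold
    epochs: List[Epoch] = []
    for i0, i1 in _runs(above):
        n = i1 - i0
        if n < n_min:
            continue
        onset = t[i0]
        if onset < lo - TIME_EPS_MS:
            continue
        if right_closed:
            if onset > hi + TIME_EPS_MS:
                continue
        else:
            if onset >= hi - TIME_EPS_MS:
                continue
        seg = st.z[i0:i1]
        k = int(np.argmax(seg))  # first occurrence of the max: earliest tie wins
        duration = n * st.dt_ms
        epochs.append(Epoch(onset_ms=float(onset), offset_ms=float(onset + duration),
                            duration_ms=float(duration), peak_z=float(seg[k]),
                            peak_time_ms=float(t[i0 + k]), i0=int(i0), i1=int(i1)))
    return epochs


def flag_hyperactive(st: StandardizedTrace,
                     min_duration_ms: float = DEFAULT_MIN_DURATION_MS) -> bool:
    """True iff the baseline window contains a supra-threshold epoch (>10 ms)."""
    return len(detect_epochs(st, st.baseline_window_ms,
                             min_duration_ms=min_duration_ms,
                             right_closed=False)) > 0


def extract_metrics(st: StandardizedTrace, epochs: Sequence[Epoch], window: str,
                    windows: Optional[LatencyWindows] = None,
                    peak_scope: str = "epochs") -> CrMetrics:
    """CR metrics for one latency window.

    start latency = onset of the earliest epoch starting in the window;
    peak amplitude/latency = maximum of z (earliest tie) over the union of
    the window's epochs (``peak_scope='epochs'``, default) or over the
    whole valid CR period (``peak_scope='valid_period'``), never beyond
    the end of the valid period.
    """
    windows = windows or LatencyWindows()
    if peak_scope not in PEAK_SCOPES:
        raise ConfigurationError(f"peak_scope must be one of {PEAK_SCOPES}")
    in_w = [e for e in epochs if windows.window_of(e.onset_ms) == window]
    if not in_w:
        raise ContractError(f"extract_metrics called with no epoch in window {window!r}")
    in_w = sorted(in_w, key=lambda e: e.onset_ms)
    start = in_w[0].onset_ms
    t = st.times_ms
    valid_end = windows.valid_ms[1]
    if peak_scope == "epochs":
        idx = np.concatenate([np.arange(e.i0, e.i1) for e in in_w])
    else:
        idx = np.flatnonzero((t >= windows.valid_ms[0] - TIME_EPS_MS)
                             & (t <= valid_end + TIME_EPS_MS))
    idx = idx[t[idx] <= valid_end + TIME_EPS_MS]
    if idx.size == 0:
        raise ContractError("no samples available for peak extraction")
    vals = st.z[idx]
    k = int(np.argmax(vals))
    return CrMetrics(start_latency_ms=float(start),
                     peak_latency_ms=float(t[idx[k]]),
                     peak_amplitude_z=float(vals[k]))


def classify_trial(st: StandardizedTrace, spec=None,
                   windows: Optional[LatencyWindows] = None,
                   min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
                   peak_scope: str = "epochs") -> TrialClassification:
    """Classify one standardized trial.

    Hyperactive trials are marked invalid and receive no CR evaluation.
    Otherwise each latency window is flagged as containing a CR iff some
    detected epoch's onset lies in it (a trial may be flagged in several
    windows), and per-window metrics are extracted for flagged windows.
    """
    windows = windows or LatencyWindows()
    cls = TrialClassification(
        trial_index=getattr(spec, "index", None),
        trial_type=getattr(spec, "trial_type", None),
        cr_flags={w: False for w in windows.names},
        metrics={w: None for w in windows.names},
    )
    if flag_hyperactive(st, min_duration_ms=min_duration_ms):
        cls.is_hyperactive = True
        cls.is_valid = False
        cls.reason = "hyperactive"
        return cls
    epochs = detect_epochs(st, windows.valid_ms, min_duration_ms=min_duration_ms)
    cls.epochs = epochs
    for w in windows.names:
        if any(windows.window_of(e.onset_ms) == w for e in epochs):
            cls.cr_flags[w] = True
            cls.metrics[w] = extract_metrics(st, epochs, w, windows=windows,
                                             peak_scope=peak_scope)
    return cls
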