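"""Synthetic EMG cohort generator with per-trial ground truth.

Emulates the statistical structure the scoring pipeline assumes: band-
limited Gaussian carrier noise (the 0.1-1 kHz acquisition band), one
conditioned-response burst at most per trial whose per-window probability
follows a logistic learning curve across daily sessions, an unconditioned
response after the US on paired trials, occasional spontaneous blinks
(Poisson), and rare hyperactive-baseline trials.  Bursts are injected at
the envelope level: they add to the rectified carrier (which is then
re-signed so the stored trace is a plausible signed EMG), calibrated in
units of the baseline envelope SD, so ground-truth amplitudes live on
the same scale the detector thresholds on.

The four default group parameter sets (saline, PCP, PCP-eNpHR, PCP-EYFP)
are illustrative, not fitted: they reproduce the qualitative orderings of
the study design (saline > PCP; PCP-eNpHR > PCP-EYFP; earlier long-window
peak latencies under PCP), not any published numeric curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, sosfilt, sosfreqz

from .design import (CS_ALONE, PAIRED, DesignParams, SessionSchedule, TrialSpec,
                     build_session_schedule)
from .detect import WINDOW_NAMES, LatencyWindows
from .errors import ConfigurationError
from .preprocess import RawTrace, integrate_array

DEFAULT_SPAN_MS = (-300.0, 3400.0)
DEFAULT_GROUP_SIZES = {"saline": 13, "PCP": 10, "PCP-eNpHR": 12, "PCP-EYFP": 16}


# --------------------------------------------------------------------------
# noise carrier

@lru_cache(maxsize=32)
def _band_sos(band_hz: Tuple[float, float], order: int, fs: float):
    lo, hi = band_hz
    if not 0 < lo < hi < fs / 2:
        raise ConfigurationError(f"noise band {band_hz} must lie inside (0, fs/2)")
    return butter(order, band_hz, btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=32)
def _band_gain(band_hz: Tuple[float, float], order: int, fs: float) -> float:
    # RMS gain of the band-pass for white input: sqrt(mean |H|^2) over frequency
    sos = _band_sos(band_hz, order, fs)
    _, h = sosfreqz(sos, worN=8192, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


@dataclass(frozen=True)
class NoiseModel:
    """Band-limited Gaussian raw-EMG noise (sigma = target raw SD)."""

    sigma: float = 1.0
    band_hz: Tuple[float, float] = (100.0, 1000.0)
    order: int = 4

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")

    def sample(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0.0:
            # rng still consumed so trial streams stay aligned across sigmas
            rng.standard_normal(0)
            return np.zeros(n)
        pad = int(0.2 * fs)  # discard the filter's start-up transient
        w = rng.standard_normal(n + pad)
        y = sosfilt(_band_sos(self.band_hz, self.order, fs), w)[pad:]
        return self.sigma * y / _band_gain(self.band_hz, self.order, fs)


@lru_cache(maxsize=32)
def envelope_baseline_stats(band_hz: Tuple[float, float], order: int, fs: float,
                            tau_ms: float, integrator: str = "exponential",
                            ) -> Tuple[float, float]:
    """Baseline mean/SD of the rectified-and-integrated envelope at sigma=1.

    Monte-Carlo calibration on a long noise stretch with a fixed internal
    seed; both statistics scale linearly with sigma.
    """
    rng = np.random.default_rng(123456789)
    noise = NoiseModel(1.0, band_hz, order).sample(int(5.0 * fs), fs, rng)
    env = integrate_array(np.abs(noise), fs, tau_ms=tau_ms, method=integrator)
    return float(np.mean(env)), float(np.std(env, ddof=1))


# --------------------------------------------------------------------------
# burst templates

@dataclass(frozen=True)
class BurstTemplate:
    """Unimodal burst: fast rise, slower decay; zero outside [onset, onset+duration).

    The shaped kernel peaks at ``onset + peak_fraction * duration`` with
    value ``peak_amplitude``; ``square=True`` gives a flat-top burst
    (used for hyperactive-baseline events).
    """

    onset_ms: float
    duration_ms: float
    peak_amplitude: float
    peak_fraction: float = 0.2
    sharpness: float = 8.0
    square: bool = False

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.peak_amplitude < 0:
            raise ConfigurationError("burst duration must be > 0 and amplitude >= 0")
        if not 0 < self.peak_fraction < 1:
            raise ConfigurationError("peak_fraction must be in (0, 1)")

    def shape(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-peak kernel sampled on ``times_ms``."""
        x = (np.asarray(times_ms) - self.onset_ms) / self.duration_ms
        f = np.zeros_like(x)
        if self.square:
            f[(x >= 0) & (x < 1)] = 1.0
            return f
        inside = (x > 0) & (x < 1)
        xi = x[inside]
        p, k = self.peak_fraction, self.sharpness
        f[inside] = (xi / p) ** (k * p) * ((1 - xi) / (1 - p)) ** (k * (1 - p))
        return f

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        return self.peak_amplitude * self.shape(times_ms)


# --------------------------------------------------------------------------
# learning model

@dataclass(frozen=True)
class GroupParams:
    """Per-group generative parameters.

    Probabilities follow ``p(s) = p_max / (1 + exp(-slope*(s - inflection)))``
    per latency window; CR amplitudes are lognormal in baseline-SD units;
    latencies are Gaussian around a per-window peak-latency mean.
    """

    p_max: Mapping[str, float]
    slope: float
    inflection_session: float
    peak_latency_mean_ms: Mapping[str, float]
    peak_latency_sd_ms: float = 120.0
    amp_log_mean: float = math.log(10.0)
    amp_log_sd: float = 0.25
    cr_duration_ms: float = 250.0
    cr_peak_fraction: float = 0.2
    ur_latency_ms: float = 8.0
    ur_amplitude_sd: float = 25.0
    ur_duration_ms: float = 120.0
    spont_rate_hz: float = 0.02
    spont_amp_log_mean: float = math.log(2.5)
    spont_amp_log_sd: float = 0.6
    spont_duration_ms: float = 150.0
    hyperactive_prob: float = 0.02

    def __post_init__(self) -> None:
        for w, p in self.p_max.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_max[{w!r}]={p} must be in [0, 1]")
        if not 0.0 <= self.hyperactive_prob <= 1.0:
            raise ConfigurationError("hyperactive_prob must be in [0, 1]")
        if self.spont_rate_hz < 0:
            raise ConfigurationError("spont_rate_hz must be >= 0")


@dataclass(frozen=True)
class LearningModel:
    """Cohort-level generative model: group parameter sets + windows."""

    groups: Mapping[str, GroupParams]
    windows: LatencyWindows = field(default_factory=LatencyWindows)
    detection_sd: float = 4.0       # criterion used for ground-truth start times
    onset_margin_ms: float = 60.0   # keeps CR onsets clear of window upper edges

    def group_params(self, group: str) -> GroupParams:
        try:
            return self.groups[group]
        except KeyError:
            raise ConfigurationError(f"unknown group {group!r}") from None

    def cr_probability(self, group: str, window: str, session: float) -> float:
        """Logistic acquisition curve; session numbering starts at 1."""
        gp = self.group_params(group)
        if window not in gp.p_max:
            raise ConfigurationError(f"unknown latency window {window!r}")
        if session < 1:
            raise ConfigurationError("session must be >= 1")
        p_max = gp.p_max[window]
        return p_max / (1.0 + math.exp(-gp.slope * (session - gp.inflection_session)))


def cr_probability(model: LearningModel, group: str, window: str, session: float) -> float:
    return model.cr_probability(group, window, session)


def default_learning_model() -> LearningModel:
    """Illustrative four-group model reproducing the design's orderings."""
    mk = dict
    # at most one CR per trial: the per-window asymptotes must sum to <= 1
    groups = {
        "saline": GroupParams(
            p_max=mk(short=0.12, middle=0.22, long=0.55), slope=1.2,
            inflection_session=3.5,
            peak_latency_mean_ms=mk(short=750.0, middle=1750.0, long=3000.0)),
        "PCP": GroupParams(
            p_max=mk(short=0.06, middle=0.08, long=0.16), slope=0.8,
            inflection_session=4.5,
            peak_latency_mean_ms=mk(short=720.0, middle=1700.0, long=2750.0)),
        "PCP-eNpHR": GroupParams(
            p_max=mk(short=0.10, middle=0.18, long=0.42), slope=1.0,
            inflection_session=4.0,
            peak_latency_mean_ms=mk(short=740.0, middle=1740.0, long=2960.0)),
        "PCP-EYFP": GroupParams(
            p_max=mk(short=0.06, middle=0.08, long=0.18), slope=0.8,
            inflection_session=4.5,
            peak_latency_mean_ms=mk(short=720.0, middle=1700.0, long=2780.0)),
    }
    return LearningModel(groups=groups)


# --------------------------------------------------------------------------
# trial simulation

# hyperactive-baseline event: a brief, very large square burst.  With the
# 300-ms self-referential baseline z-scoring, a burst occupying fraction q
# of the baseline can reach at most z ~ sqrt((1-q)/q), so only brief
# (~13 ms) strong bursts can cross the 4-SD threshold for >10 ms.
HYPER_DURATION_MS = 13.0
HYPER_AMPLITUDE_SD = 100.0


@dataclass
class GroundTruth:
    """Injected events for one simulated trial."""

    is_hyperactive: bool = False
    cr_window: Optional[str] = None
    cr_onset_ms: Optional[float] = None
    cr_start_ms: Optional[float] = None   # predicted first threshold crossing
    cr_peak_ms: Optional[float] = None
    cr_amplitude_sd: Optional[float] = None
    ur_present: bool = False
    spont_times_ms: Tuple[float, ...] = ()


@dataclass
class SimTrial:
    spec: TrialSpec
    raw: RawTrace
    truth: GroundTruth
    group: Optional[str] = None
    session: Optional[int] = None
    subject: Optional[str] = None


def _expected_envelope_crossing(burst: BurstTemplate, times: np.ndarray,
                                fs: float, tau_ms: float,
                                level: float) -> Optional[float]:
    """First grid time at which the expected processed envelope crosses ``level``.

    Bursts add directly to the rectified envelope, so the expected
    envelope elevation is the integrated burst waveform; this predicts
    where detection first sees the burst.  Returns None if the burst
    never reaches the level.
    """
    ee = integrate_array(burst.waveform(times), fs, tau_ms=tau_ms)
    above = np.flatnonzero(ee >= level)
    return float(times[above[0]]) if above.size else None


def simulate_trial(spec: TrialSpec, model: LearningModel, group: str, session: int,
                   noise: Optional[NoiseModel] = None,
                   rng: Optional[np.random.Generator] = None,
                   fs: float = 10_000.0,
                   span_ms: Tuple[float, float] = DEFAULT_SPAN_MS,
                   tau_ms: float = 1.0) -> SimTrial:
    """Simulate one trial's raw EMG trace with full ground-truth labels."""
    gp = model.group_params(group)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(rng)
    if span_ms[0] > -300.0 + 1e-9 or span_ms[1] < spec.timing.cs_duration_ms - 1e-9:
        raise ConfigurationError(
            f"trace span {span_ms} too short; must cover [-300, cs_duration] ms")
    n = int(round((span_ms[1] - span_ms[0]) * fs / 1000.0))
    dt = 1000.0 / fs
    times = span_ms[0] + np.arange(n) * dt

    carrier = noise.sample(n, fs, rng)
    m1, s1 = envelope_baseline_stats(noise.band_hz, noise.order, fs, tau_ms)
    env_mean, env_sd = noise.sigma * m1, noise.sigma * s1
    # bursts are injected at the envelope level: they add to the rectified
    # carrier, so an amplitude of a_sd baseline SDs standardizes to ~a_sd z
    envelope_bursts = np.zeros(n)

    def amp_to_env(a_sd: float) -> float:
        return a_sd * env_sd if env_sd > 0 else a_sd

    truth = GroundTruth()

    # conditioned response: at most one per trial, window drawn from the
    # per-window logistic probabilities (CS-alone trials are scored too)
    probs = [model.cr_probability(group, w, session) for w in WINDOW_NAMES]
    if sum(probs) > 1.0 + 1e-9:
        raise ConfigurationError("per-window CR probabilities must sum to <= 1")
    u = rng.random()
    cr_w = None
    acc = 0.0
    for w, p in zip(WINDOW_NAMES, probs):
        acc += p
        if u < acc:
            cr_w = w
            break
    if cr_w is not None:
        w_lo, w_hi = model.windows.bounds(cr_w)
        lo = max(w_lo, model.windows.valid_ms[0])
        hi = min(w_hi, model.windows.valid_ms[1]) - model.onset_margin_ms
        peak = rng.normal(gp.peak_latency_mean_ms[cr_w], gp.peak_latency_sd_ms)
        rise = gp.cr_peak_fraction * gp.cr_duration_ms
        onset = float(np.clip(peak - rise, lo, hi))
        amp = float(rng.lognormal(gp.amp_log_mean, gp.amp_log_sd))
        burst = BurstTemplate(onset_ms=onset, duration_ms=gp.cr_duration_ms,
                              peak_amplitude=amp_to_env(amp),
                              peak_fraction=gp.cr_peak_fraction)
        envelope_bursts += burst.waveform(times)
        level = model.detection_sd * env_sd
        truth.cr_window = cr_w
        truth.cr_onset_ms = onset
        truth.cr_peak_ms = onset + rise
        truth.cr_amplitude_sd = amp
        truth.cr_start_ms = _expected_envelope_crossing(
            burst, times, fs, tau_ms, level)

    # unconditioned response on paired trials (outside the valid CR period)
    if spec.timing.has_us:
        ur = BurstTemplate(onset_ms=spec.timing.us_onset_ms + gp.ur_latency_ms,
                           duration_ms=gp.ur_duration_ms,
                           peak_amplitude=amp_to_env(gp.ur_amplitude_sd),
                           peak_fraction=0.15)
        envelope_bursts += ur.waveform(times)
        truth.ur_present = True

    # spontaneous blinks: homogeneous Poisson over the whole trace span
    span_s = (span_ms[1] - span_ms[0]) / 1000.0
    n_spont = rng.poisson(gp.spont_rate_hz * span_s)
    spont_times = []
    for _ in range(n_spont):
        t_sp = float(rng.uniform(span_ms[0], span_ms[1] - gp.spont_duration_ms))
        a_sp = float(rng.lognormal(gp.spont_amp_log_mean, gp.spont_amp_log_sd))
        envelope_bursts += BurstTemplate(
            onset_ms=t_sp, duration_ms=gp.spont_duration_ms,
            peak_amplitude=amp_to_env(a_sp)).waveform(times)
        spont_times.append(t_sp)
    truth.spont_times_ms = tuple(sorted(spont_times))

    # hyperactive-baseline trial
    if rng.random() < gp.hyperactive_prob:
        h_onset = float(rng.uniform(-280.0, -40.0 - HYPER_DURATION_MS))
        envelope_bursts += BurstTemplate(
            onset_ms=h_onset, duration_ms=HYPER_DURATION_MS,
            peak_amplitude=amp_to_env(HYPER_AMPLITUDE_SD),
            square=True).waveform(times)
        truth.is_hyperactive = True

    # re-sign the elevated envelope so full-wave rectification recovers
    # |carrier| + bursts exactly (burst energy lives in the envelope, the
    # carrier supplies the band-limited texture)
    sign = np.where(carrier < 0, -1.0, 1.0)
    raw = sign * (np.abs(carrier) + envelope_bursts)
    return SimTrial(spec=spec, raw=RawTrace(raw, fs=fs, t0_ms=span_ms[0]),
                    truth=truth, group=group, session=session)


# --------------------------------------------------------------------------
# cohort

@dataclass(frozen=True)
class SubjectInfo:
    subject: str
    group: str
    index: int


class SyntheticCohort:
    """Lazy subjects x sessions x trials dataset with deterministic seeding.

    Trials are generated on demand; every (subject, session) stream is a
    deterministic function of the top-level seed, so two cohorts built
    with the same seed are bit-for-bit identical without storing traces.
    """

    def __init__(self, design: DesignParams, model: LearningModel,
                 group_sizes: Mapping[str, int], seed: int,
                 noise: Optional[NoiseModel] = None, fs: float = 10_000.0,
                 span_ms: Tuple[float, float] = DEFAULT_SPAN_MS):
        for g, n in group_sizes.items():
            model.group_params(g)
            if n < 1:
                raise ConfigurationError(f"group size for {g!r} must be positive")
        self.design = design
        self.model = model
        self.group_sizes = dict(group_sizes)
        self.seed = int(seed)
        self.noise = noise or NoiseModel()
        self.fs = fs
        self.span_ms = span_ms
        self.subjects: List[SubjectInfo] = []
        i = 0
        for g, size in self.group_sizes.items():
            for k in range(size):
                self.subjects.append(SubjectInfo(f"{g}-{k + 1:02d}", g, i))
                i += 1

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_sessions(self) -> int:
        return self.design.n_sessions

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *key]))

    def session_schedule(self, subject: SubjectInfo, session: int) -> SessionSchedule:
        return build_session_schedule(self.design, self._rng(subject.index, session, 0))

    def iter_session(self, subject: SubjectInfo, session: int) -> Iterator[SimTrial]:
        if not 1 <= session <= self.design.n_sessions:
            raise ConfigurationError(f"session {session} outside 1..{self.design.n_sessions}")
        schedule = self.session_schedule(subject, session)
        rng = self._rng(subject.index, session, 1)
        for spec in schedule:
            trial = simulate_trial(spec, self.model, subject.group, session,
                                   noise=self.noise, rng=rng, fs=self.fs,
                                   span_ms=self.span_ms)
            trial.subject = subject.subject
            yield trial

    def iter_all(self) -> Iterator[SimTrial]:
        for subject in self.subjects:
            for session in range(1, self.design.n_sessions + 1):
                yield from self.iter_session(subject, session)

    def materialize(self, subjects: Optional[Sequence[SubjectInfo]] = None,
                    sessions: Optional[Sequence[int]] = None):
        """Realize a (sub)cohort into an in-memory :class:`~ebcscore.io.Dataset`."""
        from .io import dataset_from_trials
        subjects = list(subjects) if subjects is not None else self.subjects
        sessions = list(sessions) if sessions is not None else list(
            range(1, self.design.n_sessions + 1))
        trials = [t for s in subjects for ses in sessions
                  for t in self.iter_session(s, ses)]
        return dataset_from_trials(trials, design=self.design, seed=self.seed)


def simulate_cohort(design: DesignParams, model: LearningModel,
                    group_sizes: Mapping[str, int], rng_or_seed,
                    **kwargs) -> SyntheticCohort:
    """Build a lazy synthetic cohort (see :class:`SyntheticCohort`)."""
    if isinstance(rng_or_seed, np.random.Generator):
        seed = int(rng_or_seed.integers(0, 2**31 - 1))
    else:
        seed = int(rng_or_seed)
    return SyntheticCohort(design, model, group_sizes, seed, **kwargs)


# --------------------------------------------------------------------------
# summary-level simulator (no EMG): per-subject/session CR% tables

def simulate_summary_cohort(model: LearningModel, group_sizes: Mapping[str, int],
                            n_sessions: int = 7, n_paired: int = 108,
                            subject_sd: float = 0.05,
                            rng: Optional[np.random.Generator] = None):
    """Draw per-subject, per-session, per-window CR% directly from the
    learning curves (binomial over paired trials, with a Gaussian
    subject-level offset on the probability scale).

    Returns a long-format cohort table (measure ``cr_percent``) suitable
    for the statistics layer; useful for calibration and power studies
    where trace-level simulation would be wasteful.
    """
    import pandas as pd
    rng = np.random.default_rng(rng)
    rows = []
    for g, size in group_sizes.items():
        model.group_params(g)
        for k in range(size):
            subject = f"{g}-{k + 1:02d}"
            offset = rng.normal(0.0, subject_sd)
            for s in range(1, n_sessions + 1):
                for w in WINDOW_NAMES:
                    p = float(np.clip(model.cr_probability(g, w, s) + offset, 0.0, 1.0))
                    n_cr = rng.binomial(n_paired, p)
                    rows.append(dict(group=g, subject=subject, session=s, window=w,
                                     measure="cr_percent",
                                     value=100.0 * n_cr / n_paired))
    return pd.DataFrame(rows)
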