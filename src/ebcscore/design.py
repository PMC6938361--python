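"""Stimulus timing and session/trial schedule of the long-delay eyeblink paradigm.

Time origin is CS onset (t = 0 ms) everywhere in the package.  A daily
acquisition session is 12 blocks of 10 trials; each block holds 9 CS-US
paired trials and 1 CS-alone trial at a random position, with inter-trial
intervals drawn uniformly from 25-40 s.  On paired trials the 50-ms US
starts 3300 ms after CS onset and co-terminates with the 3350-ms CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError

PAIRED = "paired"
CS_ALONE = "cs_alone"
TRIAL_TYPES = (PAIRED, CS_ALONE)


@dataclass(frozen=True)
class StimulusTiming:
    """Within-trial stimulus times, in ms relative to CS onset.

    ``us_onset_ms``/``us_duration_ms`` are ``None`` on CS-alone trials.
    For paired trials the US must co-terminate with the CS.
    """

    cs_duration_ms: float = 3350.0
    us_onset_ms: Optional[float] = 3300.0
    us_duration_ms: Optional[float] = 50.0

    def __post_init__(self) -> None:
        if self.cs_duration_ms <= 0:
            raise ConfigurationError("cs_duration_ms must be > 0")
        if (self.us_onset_ms is None) != (self.us_duration_ms is None):
            raise ConfigurationError(
                "us_onset_ms and us_duration_ms must both be set or both be None"
            )
        if self.us_onset_ms is not None:
            if self.us_duration_ms <= 0:
                raise ConfigurationError("us_duration_ms must be > 0 when the US is present")
            if abs(self.us_onset_ms + self.us_duration_ms - self.cs_duration_ms) > 1e-9:
                raise ConfigurationError(
                    "paired trials require US co-termination: "
                    "us_onset_ms + us_duration_ms must equal cs_duration_ms"
                )

    @property
    def has_us(self) -> bool:
        return self.us_onset_ms is not None


def stimulus_times(trial_type: str, timing: Optional[StimulusTiming] = None) -> StimulusTiming:
    """Return the stimulus timing for a trial type (``paired`` or ``cs_alone``)."""
    base = StimulusTiming() if timing is None else timing
    if trial_type == PAIRED:
        if not base.has_us:
            raise ConfigurationError("paired trials require a US in the base timing")
        return base
    if trial_type == CS_ALONE:
        return replace(base, us_onset_ms=None, us_duration_ms=None)
    raise ConfigurationError(f"unknown trial_type {trial_type!r}; expected one of {TRIAL_TYPES}")


@dataclass(frozen=True)
class DesignParams:
    """Session design: block structure, trial composition, ITI range and timing."""

    n_sessions: int = 7
    n_blocks: int = 12
    trials_per_block: int = 10
    paired_per_block: int = 9
    iti_range_s: Tuple[float, float] = (25.0, 40.0)
    timing: StimulusTiming = field(default_factory=StimulusTiming)
    cs_tone_hz: float = 3000.0   # carried as metadata; unused by the analysis
    cs_level_db: float = 85.0

    def __post_init__(self) -> None:
        for name in ("n_sessions", "n_blocks", "trials_per_block", "paired_per_block"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("n_blocks and trials_per_block must be >= 1")
        if self.paired_per_block > self.trials_per_block:
            raise ConfigurationError(
                "paired_per_block must be <= trials_per_block "
                f"({self.paired_per_block} > {self.trials_per_block})"
            )
        lo, hi = self.iti_range_s
        if not lo <= hi:
            raise ConfigurationError(f"iti_range_s lower bound must be <= upper ({lo} > {hi})")
        if lo < 0:
            raise ConfigurationError("iti_range_s must be non-negative")

    @property
    def trials_per_session(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def paired_per_session(self) -> int:
        return self.n_blocks * self.paired_per_block


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    index: int
    block: int
    trial_type: str
    iti_s: float
    timing: StimulusTiming


@dataclass
class SessionSchedule:
    """Ordered trial list for one daily session."""

    params: DesignParams
    trials: Sequence[TrialSpec]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialSpec]:
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def n_paired(self) -> int:
        return sum(1 for t in self.trials if t.trial_type == PAIRED)

    @property
    def n_cs_alone(self) -> int:
        return sum(1 for t in self.trials if t.trial_type == CS_ALONE)


def build_session_schedule(params: DesignParams, rng) -> SessionSchedule:
    """Generate one session schedule.

    The CS-alone trial(s) occupy uniformly random positions within each
    block; ITIs are continuous-uniform on ``params.iti_range_s``.  The
    block composition (paired/CS-alone counts) is exact for every seed.
    """
    rng = np.random.default_rng(rng)
    paired_timing = stimulus_times(PAIRED, params.timing)
    alone_timing = stimulus_times(CS_ALONE, params.timing)
    lo, hi = params.iti_range_s
    trials = []
    idx = 0
    n_alone = params.trials_per_block - params.paired_per_block
    for block in range(params.n_blocks):
        types = [PAIRED] * params.paired_per_block + [CS_ALONE] * n_alone
        order = rng.permutation(len(types))
        for j in order:
            tt = types[j]
            iti = float(rng.uniform(lo, hi))
            timing = paired_timing if tt == PAIRED else alone_timing
            trials.append(TrialSpec(index=idx, block=block, trial_type=tt,
                                    iti_s=iti, timing=timing))
            idx += 1
    return SessionSchedule(params=params, trials=tuple(trials))
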