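"""Session-level aggregation of trial classifications.

CR% is the percentage of valid trials containing a CR, computed per
latency window; peak amplitude and start/peak latencies are averaged over
CR trials only.  The default scope restricts denominators to paired
trials (CS-alone trials are analyzed separately).  Hyperactive and
degenerate trials never contribute to any metric; trial accounting is
conserved (total = valid + hyperactive + degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .design import CS_ALONE, PAIRED
from .detect import WINDOW_NAMES, TrialClassification
from .errors import ConfigurationError, DatasetError

SCOPES = ("paired_only", "all_trials")
MEASURES = ("cr_percent", "peak_amplitude", "start_latency", "peak_latency")


@dataclass
class WindowStats:
    n_cr: int = 0
    cr_percent: Optional[float] = None
    mean_peak_amplitude: Optional[float] = None
    mean_start_latency: Optional[float] = None
    mean_peak_latency: Optional[float] = None


@dataclass
class SessionSummary:
    """Per-subject, per-session behavioral summary with trial accounting."""

    subject: str
    group: str
    session: int
    scope: str
    n_total: int
    n_valid: int
    n_hyperactive: int
    n_degenerate: int
    undefined: bool  # True when no valid trial exists; CR% is then undefined
    windows: Dict[str, WindowStats] = field(default_factory=dict)


def summarize_session(classifications: Sequence[TrialClassification],
                      subject: str, group: str, session: int,
                      scope: str = "paired_only",
                      window_names: Sequence[str] = WINDOW_NAMES) -> SessionSummary:
    """Aggregate one subject-session's classifications into a summary.

    With zero valid trials the summary is returned flagged ``undefined``
    (CR% is None, not 0); downstream statistics drop it.
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"scope must be one of {SCOPES}")
    if scope == "paired_only":
        if any(c.trial_type is None for c in classifications):
            raise ConfigurationError("paired_only scope requires trial_type on every trial")
        pool = [c for c in classifications if c.trial_type == PAIRED]
    else:
        pool = list(classifications)
    n_total = len(pool)
    n_hyper = sum(1 for c in pool if c.is_hyperactive)
    n_degen = sum(1 for c in pool if not c.is_valid and not c.is_hyperactive)
    n_valid = n_total - n_hyper - n_degen
    summary = SessionSummary(subject=subject, group=group, session=session,
                             scope=scope, n_total=n_total, n_valid=n_valid,
                             n_hyperactive=n_hyper, n_degenerate=n_degen,
                             undefined=(n_valid == 0))
    for w in window_names:
        ws = WindowStats()
        crs = [c for c in pool if c.is_valid and c.cr_flags.get(w, False)]
        ws.n_cr = len(crs)
        if n_valid > 0:
            ws.cr_percent = 100.0 * ws.n_cr / n_valid
        if ws.n_cr > 0:
            ms = [c.metrics[w] for c in crs]
            ws.mean_peak_amplitude = float(np.mean([m.peak_amplitude_z for m in ms]))
            ws.mean_start_latency = float(np.mean([m.start_latency_ms for m in ms]))
            ws.mean_peak_latency = float(np.mean([m.peak_latency_ms for m in ms]))
        summary.windows[w] = ws
    return summary


def summaries_to_frame(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Wide, human-readable summary table (one row per subject-session)."""
    rows = []
    for s in summaries:
        row = dict(subject=s.subject, group=s.group, session=s.session, scope=s.scope,
                   n_total=s.n_total, n_valid=s.n_valid,
                   n_hyperactive=s.n_hyperactive, n_degenerate=s.n_degenerate,
                   undefined=s.undefined)
        for w, ws in s.windows.items():
            row[f"n_cr_{w}"] = ws.n_cr
            row[f"cr_percent_{w}"] = ws.cr_percent
            row[f"peak_amplitude_{w}"] = ws.mean_peak_amplitude
            row[f"start_latency_{w}"] = ws.mean_start_latency
            row[f"peak_latency_{w}"] = ws.mean_peak_latency
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_cohort(summaries: Iterable[SessionSummary]) -> pd.DataFrame:
    """Long-format cohort table keyed by (group, subject, session, window, measure).

    Missing conditional means (no CR trials) and undefined CR% are encoded
    as absent rows, never as zeros.  Duplicate keys raise.
    """
    rows = []
    for s in summaries:
        for w, ws in s.windows.items():
            values = dict(cr_percent=ws.cr_percent,
                          peak_amplitude=ws.mean_peak_amplitude,
                          start_latency=ws.mean_start_latency,
                          peak_latency=ws.mean_peak_latency)
            for measure, value in values.items():
                if value is None:
                    continue
                rows.append(dict(group=s.group, subject=s.subject, session=s.session,
                                 window=w, measure=measure, value=float(value)))
    table = pd.DataFrame(rows, columns=["group", "subject", "session",
                                        "window", "measure", "value"])
    if len(table):
        key = table[["subject", "session", "window", "measure"]]
        dup = key.duplicated()
        if dup.any():
            first = key[dup].iloc[0].to_dict()
            raise DatasetError(f"duplicate cohort-table key: {first}")
    return table
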