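"""Trial scorer: the full raw-trace -> classification chain as an estimator.

`EyeblinkScorer` is a stateless scikit-learn-style transformer (``fit``
validates parameters, ``transform`` maps raw trial traces to
:class:`~ebcscore.detect.TrialClassification` objects), so it composes
with sklearn pipelines and ``get_params``/``set_params`` machinery.
Degenerate trials (flat baseline) come back flagged invalid rather than
raising.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Tuple

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .detect import (DEFAULT_MIN_DURATION_MS, LatencyWindows, TrialClassification,
                     classify_trial)
from .errors import ConfigurationError, DegenerateTrialError
from .preprocess import (DEFAULT_BASELINE_MS, DEFAULT_TAU_MS,
                         DEFAULT_THRESHOLD_MULTIPLIER, RawTrace, process_trace)


class EyeblinkScorer(BaseEstimator, TransformerMixin):
    """Score trials: rectify, integrate, standardize, detect and classify CRs.

    Parameters
    ----------
    tau_ms : integration time constant (ms).
    integrator : ``"exponential"`` (leaky integrator, default) or ``"boxcar"``.
    baseline_window_ms : pre-CS baseline window, default [-300, 0) ms.
    threshold_multiplier : trial threshold in baseline SDs (default 4).
    min_duration_ms : strict minimum supra-threshold duration (default 10 ms).
    windows : latency windows; defaults to the standard 121-3292 ms split.
    peak_scope : ``"epochs"`` (default) or ``"valid_period"`` for the CR peak.
    """

    def __init__(self, tau_ms: float = DEFAULT_TAU_MS, integrator: str = "exponential",
                 baseline_window_ms: Tuple[float, float] = DEFAULT_BASELINE_MS,
                 threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
                 min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
                 windows: Optional[LatencyWindows] = None,
                 peak_scope: str = "epochs"):
        self.tau_ms = tau_ms
        self.integrator = integrator
        self.baseline_window_ms = baseline_window_ms
        self.threshold_multiplier = threshold_multiplier
        self.min_duration_ms = min_duration_ms
        self.windows = windows
        self.peak_scope = peak_scope

    def fit(self, X=None, y=None) -> "EyeblinkScorer":
        if self.tau_ms <= 0:
            raise ConfigurationError("tau_ms must be > 0")
        if self.threshold_multiplier <= 0:
            raise ConfigurationError("threshold_multiplier must be > 0")
        self.windows_ = self.windows or LatencyWindows()
        return self

    def score_trial(self, raw: RawTrace, spec=None) -> TrialClassification:
        """Score a single trial; degenerate baselines yield an invalid trial."""
        if not hasattr(self, "windows_"):
            self.fit()
        try:
            st = process_trace(raw, tau_ms=self.tau_ms, integrator=self.integrator,
                               baseline_window_ms=self.baseline_window_ms,
                               threshold_multiplier=self.threshold_multiplier)
        except DegenerateTrialError:
            return TrialClassification(
                trial_index=getattr(spec, "index", None),
                trial_type=getattr(spec, "trial_type", None),
                is_hyperactive=False, is_valid=False, reason="degenerate",
                cr_flags={w: False for w in self.windows_.names},
                metrics={w: None for w in self.windows_.names})
        return classify_trial(st, spec=spec, windows=self.windows_,
                              min_duration_ms=self.min_duration_ms,
                              peak_scope=self.peak_scope)

    def transform(self, X: Iterable) -> List[TrialClassification]:
        """Score an iterable of trials.

        Items may be ``RawTrace``, ``(RawTrace, TrialSpec)`` pairs, or
        simulated trials exposing ``.raw`` and ``.spec`` attributes.
        """
        if not hasattr(self, "windows_"):
            self.fit()
        out = []
        for item in X:
            if isinstance(item, RawTrace):
                out.append(self.score_trial(item))
            elif hasattr(item, "raw") and hasattr(item, "spec"):
                out.append(self.score_trial(item.raw, spec=item.spec))
            else:
                raw, spec = item
                out.append(self.score_trial(raw, spec=spec))
        return out


def classifications_to_frame(classifications: Iterable[TrialClassification],
                             **extra_cols) -> pd.DataFrame:
    """Per-trial classification table (one row per trial), CSV-ready."""
    rows = []
    for c in classifications:
        row = dict(extra_cols)
        row.update(trial_index=c.trial_index, trial_type=c.trial_type,
                   is_valid=c.is_valid, is_hyperactive=c.is_hyperactive,
                   reason=c.reason, n_epochs=len(c.epochs))
        for w, flag in c.cr_flags.items():
            row[f"cr_{w}"] = flag
            m = c.metrics.get(w)
            row[f"start_latency_{w}_ms"] = m.start_latency_ms if m else None
            row[f"peak_latency_{w}_ms"] = m.peak_latency_ms if m else None
            row[f"peak_amplitude_{w}_z"] = m.peak_amplitude_z if m else None
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:
        # stable dtypes across sessions with no CRs (all-missing columns)
        if col.startswith(("start_latency_", "peak_latency_", "peak_amplitude_")):
            df[col] = df[col].astype("float64")
        elif col == "reason":
            df[col] = df[col].astype("object").where(df[col].notna(), "")
    return df
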