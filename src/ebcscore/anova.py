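"""Repeated-measures ANOVA (mixed and one-way) with LSD post hoc tests.

The mixed design has one between-subjects factor (group) and one
within-subjects factor (session).  Classical sums-of-squares
decomposition: the group effect is tested against subjects-within-groups;
session and the group x session interaction are tested against the
session x subjects-within-groups residual.  Unequal group sizes are
handled the standard way for a single between factor (for which the
Type I/II/III hypotheses coincide).  Subjects missing any session are
dropped (complete-case) and logged; nothing is imputed.

LSD post hoc pairwise t tests use the omnibus error terms: the
between-subjects error (on the subject-mean scale) for group pairs and
the within error for session pairs, with no multiplicity correction.
No sphericity correction is applied by default; a Greenhouse-Geisser
adjustment of the within-effect p values is available as an option.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

ANOVA_COLUMNS = ["effect", "ss", "df", "ms", "F", "p", "degenerate"]


@dataclass
class AnovaResult:
    """ANOVA table plus the fitted cell structure needed for post hoc tests."""

    kind: str                      # "mixed" or "one_way"
    table: pd.DataFrame            # columns: effect, ss, df, ms, F, p, degenerate
    group_labels: List[str]
    session_labels: List
    group_data: Dict[str, np.ndarray]   # group -> (n_subjects, n_sessions)
    subject_ids: Dict[str, List[str]]
    dropped_subjects: List[str]
    gg_epsilon: Optional[float] = None

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _f_test(ss_eff: float, df_eff: float, ss_err: float, df_err: float,
            eps: float = 1.0) -> Tuple[float, float, bool]:
    """F and p with degenerate (zero error variance) handling."""
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= 0 or not np.isfinite(ms_err):
        if ss_eff <= 1e-12:
            return 0.0, 1.0, True
        return float("inf"), 0.0, True
    f = ms_eff / ms_err
    p = float(sps.f.sf(f, df_eff * eps, df_err * eps))
    return float(f), p, False


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a sessions covariance matrix."""
    k = cov.shape[0]
    c = np.eye(k) - np.ones((k, k)) / k
    a = c @ cov @ c
    num = np.trace(a) ** 2
    den = (k - 1) * np.trace(a @ a)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _mixed_core(group_data: Dict[str, np.ndarray],
                gg_correction: bool = False) -> Tuple[pd.DataFrame, Optional[float]]:
    """Classical mixed-design decomposition from per-group (n_g x S) arrays."""
    groups = list(group_data)
    sizes = {g: group_data[g].shape[0] for g in groups}
    s_counts = {group_data[g].shape[1] for g in groups}
    if len(s_counts) != 1:
        raise ConfigurationError("all groups must share the same session set")
    S = s_counts.pop()
    N = sum(sizes.values())
    if len(groups) < 2:
        raise ConfigurationError("mixed RM-ANOVA requires >= 2 groups")
    if S < 2:
        raise ConfigurationError("mixed RM-ANOVA requires >= 2 sessions")
    allY = np.concatenate([group_data[g] for g in groups], axis=0)
    grand = allY.mean()
    ss_total = float(((allY - grand) ** 2).sum())
    subj_means = allY.mean(axis=1)
    ss_between_subj = float(S * ((subj_means - grand) ** 2).sum())
    group_means = {g: group_data[g].mean() for g in groups}
    ss_group = float(S * sum(sizes[g] * (group_means[g] - grand) ** 2 for g in groups))
    ss_subj_within = ss_between_subj - ss_group
    sess_means = allY.mean(axis=0)
    ss_session = float(N * ((sess_means - grand) ** 2).sum())
    ss_cells = float(sum(sizes[g] * ((group_data[g].mean(axis=0) - grand) ** 2).sum()
                         for g in groups))
    ss_interaction = ss_cells - ss_group - ss_session
    ss_within_subj = ss_total - ss_between_subj
    ss_error = ss_within_subj - ss_session - ss_interaction
    # numerical guard: tiny negatives from cancellation
    ss_interaction = max(ss_interaction, 0.0)
    ss_error = max(ss_error, 0.0)
    ss_subj_within = max(ss_subj_within, 0.0)

    df_group = len(groups) - 1
    df_subjw = N - len(groups)
    df_session = S - 1
    df_inter = df_group * df_session
    df_error = df_subjw * df_session
    if df_subjw < 1 or df_error < 1:
        raise ConfigurationError("not enough subjects for the error terms")

    eps = None
    eps_use = 1.0
    if gg_correction:
        # pooled within-group covariance of the session profiles
        pooled = np.zeros((S, S))
        dof = 0
        for g in groups:
            y = group_data[g]
            if y.shape[0] > 1:
                pooled += np.cov(y, rowvar=False) * (y.shape[0] - 1)
                dof += y.shape[0] - 1
        if dof > 0:
            eps = _gg_epsilon(pooled / dof)
            eps_use = eps

    f_g, p_g, d_g = _f_test(ss_group, df_group, ss_subj_within, df_subjw)
    f_s, p_s, d_s = _f_test(ss_session, df_session, ss_error, df_error, eps_use)
    f_i, p_i, d_i = _f_test(ss_interaction, df_inter, ss_error, df_error, eps_use)

    table = pd.DataFrame([
        dict(effect="group", ss=ss_group, df=df_group, ms=ss_group / df_group,
             F=f_g, p=p_g, degenerate=d_g),
        dict(effect="subjects_within_groups", ss=ss_subj_within, df=df_subjw,
             ms=ss_subj_within / df_subjw, F=np.nan, p=np.nan, degenerate=False),
        dict(effect="session", ss=ss_session, df=df_session,
             ms=ss_session / df_session, F=f_s, p=p_s, degenerate=d_s),
        dict(effect="group_x_session", ss=ss_interaction, df=df_inter,
             ms=ss_interaction / df_inter, F=f_i, p=p_i, degenerate=d_i),
        dict(effect="error_within", ss=ss_error, df=df_error,
             ms=ss_error / df_error, F=np.nan, p=np.nan, degenerate=False),
    ], columns=ANOVA_COLUMNS)
    return table, eps


def _oneway_core(Y: np.ndarray, gg_correction: bool = False
                 ) -> Tuple[pd.DataFrame, Optional[float]]:
    """One-way RM decomposition for a complete (n_subjects x S) array."""
    n, S = Y.shape
    if n < 2 or S < 2:
        raise ConfigurationError("one-way RM-ANOVA requires >= 2 subjects and >= 2 levels")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subj = float(S * ((Y.mean(axis=1) - grand) ** 2).sum())
    ss_session = float(n * ((Y.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subj - ss_session, 0.0)
    df_session = S - 1
    df_error = (n - 1) * (S - 1)
    eps = None
    eps_use = 1.0
    if gg_correction:
        eps = _gg_epsilon(np.cov(Y, rowvar=False))
        eps_use = eps
    f_s, p_s, d_s = _f_test(ss_session, df_session, ss_error, df_error, eps_use)
    table = pd.DataFrame([
        dict(effect="session", ss=ss_session, df=df_session,
             ms=ss_session / df_session, F=f_s, p=p_s, degenerate=d_s),
        dict(effect="subjects", ss=ss_subj, df=n - 1, ms=ss_subj / (n - 1),
             F=np.nan, p=np.nan, degenerate=False),
        dict(effect="error_within", ss=ss_error, df=df_error,
             ms=ss_error / df_error, F=np.nan, p=np.nan, degenerate=False),
    ], columns=ANOVA_COLUMNS)
    return table, eps


def _pivot(table: pd.DataFrame, measure: str, window: str
           ) -> Tuple[Dict[str, np.ndarray], Dict[str, List[str]], List, List[str]]:
    """Complete-case subjects x sessions arrays per group from the long table."""
    sub = table[(table["measure"] == measure) & (table["window"] == window)]
    if sub.empty:
        raise ConfigurationError(f"no rows for measure={measure!r}, window={window!r}")
    wide = sub.pivot_table(index=["group", "subject"], columns="session",
                           values="value", aggfunc="first")
    sessions = sorted(wide.columns)
    complete = wide.dropna(axis=0)
    dropped = [s for (_, s) in wide.index.difference(complete.index)]
    if dropped:
        logger.info("complete-case filtering dropped subjects: %s", sorted(dropped))
    group_data: Dict[str, np.ndarray] = {}
    subject_ids: Dict[str, List[str]] = {}
    for g in sorted({g for g, _ in complete.index}):
        block = complete.loc[g]
        group_data[g] = block[sessions].to_numpy(dtype=float)
        subject_ids[g] = list(block.index)
    return group_data, subject_ids, sessions, sorted(dropped)


def mixed_rm_anova(table: pd.DataFrame, measure: str, window: str,
                   gg_correction: bool = False) -> AnovaResult:
    """Two-way mixed RM-ANOVA (group x session) on a long cohort table."""
    group_data, subject_ids, sessions, dropped = _pivot(table, measure, window)
    if len(group_data) < 2:
        raise ConfigurationError("mixed RM-ANOVA requires >= 2 groups after filtering")
    for g, y in group_data.items():
        if y.shape[0] == 0:
            raise ConfigurationError(f"empty cell: group {g!r} has no complete subjects")
    tab, eps = _mixed_core(group_data, gg_correction=gg_correction)
    return AnovaResult(kind="mixed", table=tab, group_labels=list(group_data),
                       session_labels=sessions, group_data=group_data,
                       subject_ids=subject_ids, dropped_subjects=dropped,
                       gg_epsilon=eps)


def one_way_rm_anova(table: pd.DataFrame, measure: str, window: str,
                     group: Optional[str] = None,
                     gg_correction: bool = False) -> AnovaResult:
    """One-way RM-ANOVA over sessions (optionally within a single group)."""
    src = table if group is None else table[table["group"] == group]
    group_data, subject_ids, sessions, dropped = _pivot(src, measure, window)
    Y = np.concatenate([group_data[g] for g in group_data], axis=0)
    tab, eps = _oneway_core(Y, gg_correction=gg_correction)
    label = group if group is not None else "all"
    ids = [s for g in subject_ids for s in subject_ids[g]]
    return AnovaResult(kind="one_way", table=tab, group_labels=[label],
                       session_labels=sessions, group_data={label: Y},
                       subject_ids={label: ids}, dropped_subjects=dropped,
                       gg_epsilon=eps)


def lsd_posthoc(result: AnovaResult, factor: str = "group") -> pd.DataFrame:
    """Pairwise LSD t tests using the omnibus ANOVA's error terms.

    Group pairs: subject means against the subjects-within-groups error
    (on the subject-mean scale, df = N - G).  Session pairs: session means
    against the within error (paired-difference SE, df of the within
    residual).  Two-sided p, uncorrected.
    """
    rows = []
    if factor == "group":
        if result.kind != "mixed":
            raise ConfigurationError("group post hoc requires a mixed ANOVA result")
        S = len(result.session_labels)
        subj_means = {g: result.group_data[g].mean(axis=1) for g in result.group_labels}
        df_err = int(result.effect("subjects_within_groups")["df"])
        # subjects-within-groups MS on the subject-mean scale
        ms = result.effect("subjects_within_groups")["ms"] / S
        for gi, gj in itertools.combinations(result.group_labels, 2):
            mi, mj = subj_means[gi].mean(), subj_means[gj].mean()
            ni, nj = subj_means[gi].size, subj_means[gj].size
            se = np.sqrt(ms * (1.0 / ni + 1.0 / nj))
            rows.append(_pair_row(gi, gj, mi - mj, se, df_err))
    elif factor == "session":
        allY = np.concatenate([result.group_data[g] for g in result.group_labels], axis=0)
        n = allY.shape[0]
        ms_err = result.effect("error_within")["ms"]
        df_err = int(result.effect("error_within")["df"])
        sess_means = allY.mean(axis=0)
        for i, j in itertools.combinations(range(len(result.session_labels)), 2):
            se = np.sqrt(ms_err * 2.0 / n)
            rows.append(_pair_row(result.session_labels[i], result.session_labels[j],
                                  sess_means[i] - sess_means[j], se, df_err))
    else:
        raise ConfigurationError("factor must be 'group' or 'session'")
    return pd.DataFrame(rows, columns=["level_i", "level_j", "mean_diff",
                                       "se", "t", "df", "p"])


def _pair_row(li, lj, diff: float, se: float, df: int) -> dict:
    if se <= 0 or not np.isfinite(se):
        t = 0.0 if abs(diff) <= 1e-12 else float("inf") * np.sign(diff)
        p = 1.0 if abs(diff) <= 1e-12 else 0.0
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return dict(level_i=li, level_j=lj, mean_diff=float(diff), se=float(se),
                t=float(t), df=df, p=p)


class MixedRMAnova(BaseEstimator):
    """Mixed RM-ANOVA fitter for long cohort tables (sklearn-style).

    After ``fit(table)``: ``anova_table_``, ``posthoc_group_``,
    ``posthoc_session_``, ``dropped_subjects_``, ``result_``.
    """

    def __init__(self, measure: str = "cr_percent", window: str = "long",
                 alpha: float = 0.05, gg_correction: bool = False):
        self.measure = measure
        self.window = window
        self.alpha = alpha
        self.gg_correction = gg_correction

    def fit(self, table: pd.DataFrame, y=None) -> "MixedRMAnova":
        res = mixed_rm_anova(table, self.measure, self.window,
                             gg_correction=self.gg_correction)
        self.result_ = res
        self.anova_table_ = res.table
        self.posthoc_group_ = lsd_posthoc(res, "group")
        self.posthoc_session_ = lsd_posthoc(res, "session")
        self.dropped_subjects_ = res.dropped_subjects
        return self


class OneWayRMAnova(BaseEstimator):
    """One-way RM-ANOVA fitter (sessions within subjects)."""

    def __init__(self, measure: str = "cr_percent", window: str = "long",
                 group: Optional[str] = None, alpha: float = 0.05,
                 gg_correction: bool = False):
        self.measure = measure
        self.window = window
        self.group = group
        self.alpha = alpha
        self.gg_correction = gg_correction

    def fit(self, table: pd.DataFrame, y=None) -> "OneWayRMAnova":
        res = one_way_rm_anova(table, self.measure, self.window, group=self.group,
                               gg_correction=self.gg_correction)
        self.result_ = res
        self.anova_table_ = res.table
        self.posthoc_session_ = lsd_posthoc(res, "session")
        self.dropped_subjects_ = res.dropped_subjects
        return self
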