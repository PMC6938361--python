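"""Independent brute-force oracles used only by the test suite.

These are written from the definitions, with plain loops, and share no
code with the implementation they check.
"""

import numpy as np
from scipy import stats as sps


def brute_force_epochs(z, times, threshold, interval, min_duration_ms, fs,
                       right_closed=True, eps=1e-6):
    """Enumerate every maximal strictly-supra-threshold run and filter it
    by onset interval and strict minimum duration."""
    lo, hi = interval
    out = []
    n = len(z)
    i = 0
    while i < n:
        if z[i] > threshold:
            j = i
            while j < n and z[j] > threshold:
                j += 1
            run = j - i
            duration = run * 1000.0 / fs
            onset = times[i]
            in_interval = onset >= lo - eps and (
                onset <= hi + eps if right_closed else onset < hi - eps)
            if duration > min_duration_ms and in_interval:
                peak_v = -np.inf
                peak_t = None
                for k in range(i, j):
                    if z[k] > peak_v:
                        peak_v = z[k]
                        peak_t = times[k]
                out.append(dict(onset=onset, offset=onset + duration,
                                duration=duration, peak_z=peak_v, peak_time=peak_t))
            i = j
        else:
            i += 1
    return out


def oracle_mixed_anova(group_data):
    """Mixed-design RM-ANOVA from first principles (loops over cells).

    group_data: mapping group -> list of per-subject session-value lists.
    Returns dict effect -> dict(ss, df, ms, F, p).
    """
    groups = list(group_data)
    S = len(next(iter(group_data.values()))[0])
    all_vals = []
    for g in groups:
        for subj in group_data[g]:
            assert len(subj) == S
            all_vals.extend(subj)
    N = sum(len(group_data[g]) for g in groups)
    grand = sum(all_vals) / len(all_vals)

    ss_total = sum((v - grand) ** 2 for v in all_vals)
    subj_means = {g: [sum(s) / S for s in group_data[g]] for g in groups}
    ss_between_subj = S * sum((m - grand) ** 2
                              for g in groups for m in subj_means[g])
    group_mean = {g: sum(sum(s) for s in group_data[g]) / (len(group_data[g]) * S)
                  for g in groups}
    ss_group = S * sum(len(group_data[g]) * (group_mean[g] - grand) ** 2
                       for g in groups)
    ss_subjw = ss_between_subj - ss_group
    sess_mean = [sum(group_data[g][i][s] for g in groups
                     for i in range(len(group_data[g]))) / N for s in range(S)]
    ss_session = N * sum((m - grand) ** 2 for m in sess_mean)
    ss_cells = 0.0
    for g in groups:
        n_g = len(group_data[g])
        for s in range(S):
            cell = sum(group_data[g][i][s] for i in range(n_g)) / n_g
            ss_cells += n_g * (cell - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_session
    ss_error = ss_total - ss_between_subj - ss_session - ss_inter

    G = len(groups)
    df = dict(group=G - 1, subjw=N - G, session=S - 1,
              inter=(G - 1) * (S - 1), error=(N - G) * (S - 1))

    def eff(ss_e, df_e, ss_r, df_r):
        F = (ss_e / df_e) / (ss_r / df_r)
        return dict(ss=ss_e, df=df_e, ms=ss_e / df_e, F=F,
                    p=float(sps.f.sf(F, df_e, df_r)))

    return dict(group=eff(ss_group, df["group"], ss_subjw, df["subjw"]),
                session=eff(ss_session, df["session"], ss_error, df["error"]),
                interaction=eff(ss_inter, df["inter"], ss_error, df["error"]),
                subjw=dict(ss=ss_subjw, df=df["subjw"], ms=ss_subjw / df["subjw"]),
                error=dict(ss=ss_error, df=df["error"], ms=ss_error / df["error"]))


def oracle_oneway_rm_anova(Y):
    """One-way RM-ANOVA from first principles. Y: list of per-subject lists."""
    n = len(Y)
    S = len(Y[0])
    grand = sum(sum(row) for row in Y) / (n * S)
    ss_total = sum((v - grand) ** 2 for row in Y for v in row)
    ss_subj = S * sum((sum(row) / S - grand) ** 2 for row in Y)
    sess_mean = [sum(Y[i][s] for i in range(n)) / n for s in range(S)]
    ss_sess = n * sum((m - grand) ** 2 for m in sess_mean)
    ss_err = ss_total - ss_subj - ss_sess
    df_sess, df_err = S - 1, (n - 1) * (S - 1)
    F = (ss_sess / df_sess) / (ss_err / df_err)
    return dict(ss_session=ss_sess, ss_subjects=ss_subj, ss_error=ss_err,
                df_session=df_sess, df_error=df_err, F=F,
                p=float(sps.f.sf(F, df_sess, df_err)))
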