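import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from oracles import oracle_mixed_anova, oracle_oneway_rm_anova

from ebcscore import (ConfigurationError, MixedRMAnova, OneWayRMAnova,
                      lsd_posthoc, mixed_rm_anova, one_way_rm_anova)
from ebcscore.anova import _mixed_core, _oneway_core


def long_table(group_data):
    rows = []
    for g, arr in group_data.items():
        for i, subj in enumerate(np.asarray(arr)):
            for s, v in enumerate(subj):
                rows.append(dict(group=g, subject=f"{g}{i}", session=s + 1,
                                 window="long", measure="cr_percent",
                                 value=float(v)))
    return pd.DataFrame(rows)


def seeded_groups(sizes, n_sessions, seed, effects=True):
    rng = np.random.default_rng(seed)
    out = {}
    for gi, (g, n) in enumerate(sizes.items()):
        base = gi * 2.0 if effects else 0.0
        sess = np.linspace(0, 3, n_sessions) * (1 + 0.3 * gi if effects else 0)
        out[g] = base + sess + rng.normal(0, 1.0, (n, n_sessions)) \
            + rng.normal(0, 0.8, (n, 1))
    return out


class TestMixedAnovaAgainstOracle:
    @pytest.mark.parametrize("sizes,n_sessions,seed", [
        ({"a": 4, "b": 4}, 3, 0),
        ({"a": 13, "b": 10, "c": 12, "d": 16}, 7, 1),   # study-sized, unbalanced
        ({"a": 5, "b": 3, "c": 8}, 4, 2),
    ])
    def test_matches_first_principles_oracle(self, sizes, n_sessions, seed):
        data = seeded_groups(sizes, n_sessions, seed)
        res = mixed_rm_anova(long_table(data), "cr_percent", "long")
        exp = oracle_mixed_anova({g: a.tolist() for g, a in data.items()})
        for effect, key in [("group", "group"), ("session", "session"),
                            ("group_x_session", "interaction")]:
            row = res.effect(effect)
            assert row["ss"] == pytest.approx(exp[key]["ss"], abs=1e-8)
            assert row["F"] == pytest.approx(exp[key]["F"], abs=1e-8)
            assert row["p"] == pytest.approx(exp[key]["p"], abs=1e-8)
        assert res.effect("error_within")["ss"] == pytest.approx(
            exp["error"]["ss"], abs=1e-8)

    def test_matches_pingouin(self):
        data = seeded_groups({"a": 6, "b": 9}, 5, 3)
        df = long_table(data)
        res = mixed_rm_anova(df, "cr_percent", "long")
        pgres = pg.mixed_anova(data=df, dv="value", within="session",
                               subject="subject", between="group")
        byname = {r["Source"]: r for _, r in pgres.iterrows()}
        assert res.effect("group")["F"] == pytest.approx(byname["group"]["F"])
        assert res.effect("session")["F"] == pytest.approx(byname["session"]["F"])
        assert res.effect("group_x_session")["F"] == pytest.approx(
            byname["Interaction"]["F"])


class TestOneWayAnova:
    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(0, 1, (8, 5)) + np.linspace(0, 2, 5)
        res, _ = _oneway_core(Y)
        exp = oracle_oneway_rm_anova(Y.tolist())
        row = res[res["effect"] == "session"].iloc[0]
        assert row["ss"] == pytest.approx(exp["ss_session"], abs=1e-8)
        assert row["F"] == pytest.approx(exp["F"], abs=1e-8)
        assert row["p"] == pytest.approx(exp["p"], abs=1e-8)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(5)
        data = {"a": rng.normal(0, 1, (7, 4)) + np.arange(4)}
        df = long_table(data)
        res = one_way_rm_anova(df, "cr_percent", "long")
        pgres = pg.rm_anova(data=df, dv="value", within="session",
                            subject="subject", correction=False)
        assert res.effect("session")["F"] == pytest.approx(
            pgres.iloc[0]["F"])

    def test_identical_sessions_zero_f(self):
        Y = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        res, _ = _oneway_core(Y)
        assert res[res["effect"] == "session"].iloc[0]["F"] == 0.0

    def test_pure_subject_offsets_zero_session_f(self):
        Y = np.repeat(np.arange(6, dtype=float)[:, None], 4, axis=1)
        Y += np.random.default_rng(0).normal(0, 1e-12, Y.shape)
        res, _ = _oneway_core(Y)
        assert res[res["effect"] == "session"].iloc[0]["F"] == pytest.approx(
            0.0, abs=1e-6)


class TestDegenerateAndInvariances:
    def test_all_equal_observations_degenerate(self):
        data = {"a": np.full((3, 4), 5.0), "b": np.full((3, 4), 5.0)}
        res, _ = _mixed_core(data)
        for effect in ("group", "session", "group_x_session"):
            row = res[res["effect"] == effect].iloc[0]
            assert row["F"] == 0.0
            assert row["p"] == 1.0
            assert row["degenerate"]

    def test_copied_group_zero_group_f(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (5, 4))
        res, _ = _mixed_core({"a": a, "b": a.copy()})
        assert res[res["effect"] == "group"].iloc[0]["F"] == pytest.approx(0.0)
        assert res[res["effect"] == "group"].iloc[0]["p"] == pytest.approx(1.0)

    def test_f_invariant_to_affine_transform(self):
        data = seeded_groups({"a": 5, "b": 6}, 4, 7)
        r1, _ = _mixed_core(data)
        r2, _ = _mixed_core({g: 3.0 * a + 100.0 for g, a in data.items()})
        for effect in ("group", "session", "group_x_session"):
            f1 = r1[r1["effect"] == effect].iloc[0]["F"]
            f2 = r2[r2["effect"] == effect].iloc[0]["F"]
            assert f2 == pytest.approx(f1, rel=1e-9)

    def test_too_few_groups_rejected(self):
        data = seeded_groups({"a": 5}, 4, 0)
        with pytest.raises(ConfigurationError):
            _mixed_core(data)

    def test_missing_measure_rejected(self):
        df = long_table(seeded_groups({"a": 3, "b": 3}, 3, 0))
        with pytest.raises(ConfigurationError):
            mixed_rm_anova(df, "peak_amplitude", "long")


class TestCompleteCase:
    def test_subject_with_missing_session_dropped_and_logged(self):
        df = long_table(seeded_groups({"a": 4, "b": 4}, 3, 8))
        df = df[~((df["subject"] == "a0") & (df["session"] == 2))]
        est = MixedRMAnova().fit(df)
        assert est.dropped_subjects_ == ["a0"]
        assert sum(len(v) for v in est.result_.subject_ids.values()) == 7


class TestLsdPosthoc:
    def fitted(self, seed=9, sizes=None):
        data = seeded_groups(sizes or {"a": 5, "b": 7, "c": 6}, 4, seed)
        return mixed_rm_anova(long_table(data), "cr_percent", "long")

    def test_equal_means_give_t0_p1(self):
        a = np.random.default_rng(0).normal(0, 1, (5, 4))
        res = mixed_rm_anova(long_table({"a": a, "b": a.copy()}),
                             "cr_percent", "long")
        ph = lsd_posthoc(res, "group")
        assert ph.iloc[0]["t"] == pytest.approx(0.0)
        assert ph.iloc[0]["p"] == pytest.approx(1.0)

    def test_pair_order_flips_sign_not_p(self):
        res = self.fitted()
        ph = lsd_posthoc(res, "group")
        row = ph[(ph["level_i"] == "a") & (ph["level_j"] == "b")].iloc[0]
        # relabel 'a' as 'z' so the sorted pair order flips (values unchanged)
        data = {("z" if g == "a" else g): res.group_data[g]
                for g in res.group_labels}
        res2 = mixed_rm_anova(long_table(data), "cr_percent", "long")
        ph2 = lsd_posthoc(res2, "group")
        row2 = ph2[(ph2["level_i"] == "b") & (ph2["level_j"] == "z")].iloc[0]
        assert row2["mean_diff"] == pytest.approx(-row["mean_diff"])
        assert row2["p"] == pytest.approx(row["p"])

    def test_p_matches_t_distribution_oracle(self):
        res = self.fitted()
        for factor in ("group", "session"):
            for _, row in lsd_posthoc(res, factor).iterrows():
                expected = 2.0 * (1.0 - sps.t.cdf(abs(row["t"]), row["df"]))
                assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_group_se_uses_between_error_term(self):
        res = self.fitted(sizes={"a": 4, "b": 8})
        S = len(res.session_labels)
        ms = res.effect("subjects_within_groups")["ms"] / S
        row = lsd_posthoc(res, "group").iloc[0]
        assert row["se"] == pytest.approx(np.sqrt(ms * (1 / 4 + 1 / 8)))
        assert row["df"] == res.effect("subjects_within_groups")["df"]

    def test_estimator_wrappers_expose_tables(self):
        df = long_table(seeded_groups({"a": 4, "b": 4}, 3, 1))
        est = MixedRMAnova(measure="cr_percent", window="long").fit(df)
        assert {"effect", "F", "p"}.issubset(est.anova_table_.columns)
        assert len(est.posthoc_group_) == 1
        est2 = OneWayRMAnova().fit(df)
        assert est2.anova_table_.iloc[0]["effect"] == "session"
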