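import dataclasses
import math

import numpy as np
import pytest

from ebcscore import (ConfigurationError, DesignParams, EyeblinkScorer,
                      GroupParams, LatencyWindows, LearningModel, NoiseModel,
                      SyntheticCohort, cr_probability, default_learning_model,
                      flag_hyperactive, process_trace, simulate_trial,
                      stimulus_times)
from ebcscore.design import PAIRED, TrialSpec


def single_group_model(**overrides):
    """One-group model whose every generative channel can be switched off."""
    base = dict(p_max=dict(short=0.0, middle=0.0, long=0.0), slope=5.0,
                inflection_session=1.0,
                peak_latency_mean_ms=dict(short=750.0, middle=1750.0, long=2550.0),
                peak_latency_sd_ms=0.0, amp_log_sd=0.0,
                spont_rate_hz=0.0, hyperactive_prob=0.0, ur_amplitude_sd=0.0)
    base.update(overrides)
    return LearningModel(groups={"g": GroupParams(**base)})


def paired_spec():
    return TrialSpec(index=0, block=0, trial_type=PAIRED, iti_s=30.0,
                     timing=stimulus_times(PAIRED))


class TestCrProbability:
    def test_zero_slope_gives_half_asymptote_everywhere(self):
        m = single_group_model(p_max=dict(short=0.2, middle=0.3, long=0.6),
                               slope=0.0)
        for s in (1, 3, 7):
            assert cr_probability(m, "g", "long", s) == pytest.approx(0.3)

    def test_inflection_session_gives_half_asymptote(self):
        m = single_group_model(p_max=dict(short=0.0, middle=0.0, long=0.5),
                               slope=1.3, inflection_session=4.0)
        assert cr_probability(m, "g", "long", 4) == pytest.approx(0.25)

    def test_asymptote_reached_for_late_sessions(self):
        m = single_group_model(p_max=dict(short=0.0, middle=0.0, long=0.5),
                               slope=2.0, inflection_session=3.0)
        assert cr_probability(m, "g", "long", 50) == pytest.approx(0.5, abs=1e-9)

    def test_unknown_group_or_window_raises(self):
        m = default_learning_model()
        with pytest.raises(ConfigurationError):
            cr_probability(m, "nope", "long", 1)
        with pytest.raises(ConfigurationError):
            cr_probability(m, "saline", "alpha", 1)


class TestSimulateTrial:
    def test_silent_model_gives_identically_zero_trace(self):
        m = single_group_model()
        t = simulate_trial(paired_spec(), m, "g", 1,
                           noise=NoiseModel(sigma=0.0),
                           rng=np.random.default_rng(0))
        assert not t.raw.samples.any()

    def test_short_span_rejected(self):
        m = single_group_model()
        with pytest.raises(ConfigurationError):
            simulate_trial(paired_spec(), m, "g", 1,
                           rng=np.random.default_rng(0), span_ms=(-300.0, 2000.0))

    def test_injected_long_cr_detected_near_truth(self):
        # huge burst with onset 2500 ms: detected start within +-5 ms
        m = single_group_model(p_max=dict(short=0.0, middle=0.0, long=1.0),
                               peak_latency_mean_ms=dict(short=750.0,
                                                         middle=1750.0,
                                                         long=2550.0),
                               amp_log_mean=math.log(500.0))
        scorer = EyeblinkScorer().fit()
        rng = np.random.default_rng(5)
        for _ in range(5):
            t = simulate_trial(paired_spec(), m, "g", 7, rng=rng)
            assert t.truth.cr_window == "long"
            assert t.truth.cr_onset_ms == pytest.approx(2500.0)
            cls = scorer.score_trial(t.raw, spec=t.spec)
            assert cls.cr_flags["long"]
            assert cls.metrics["long"].start_latency_ms == pytest.approx(2500.0,
                                                                         abs=5.0)

    def test_all_hyperactive_when_probability_one(self):
        m = single_group_model(hyperactive_prob=1.0)
        rng = np.random.default_rng(11)
        for _ in range(30):
            t = simulate_trial(paired_spec(), m, "g", 1, rng=rng)
            assert t.truth.is_hyperactive
            assert flag_hyperactive(process_trace(t.raw))

    def test_ur_present_only_on_paired_trials(self):
        m = single_group_model(ur_amplitude_sd=25.0)
        rng = np.random.default_rng(2)
        t = simulate_trial(paired_spec(), m, "g", 1, rng=rng)
        assert t.truth.ur_present
        alone = TrialSpec(index=1, block=0, trial_type="cs_alone", iti_s=30.0,
                          timing=stimulus_times("cs_alone"))
        t2 = simulate_trial(alone, m, "g", 1, rng=rng)
        assert not t2.truth.ur_present

    def test_ur_never_contaminates_valid_window(self):
        # UR-only trials produce no CR flag: the burst starts after 3292 ms
        m = single_group_model(ur_amplitude_sd=25.0)
        scorer = EyeblinkScorer().fit()
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = simulate_trial(paired_spec(), m, "g", 1, rng=rng)
            cls = scorer.score_trial(t.raw, spec=t.spec)
            assert not any(cls.cr_flags.values())

    def test_cr_onsets_stay_inside_valid_period(self):
        m = default_learning_model()
        rng = np.random.default_rng(7)
        w = LatencyWindows()
        for g in m.groups:
            for _ in range(50):
                t = simulate_trial(paired_spec(), m, g, 7, rng=rng)
                if t.truth.cr_window is not None:
                    assert 121.0 <= t.truth.cr_onset_ms <= 3292.0
                    assert w.window_of(t.truth.cr_onset_ms) == t.truth.cr_window


class TestCohort:
    def small_cohort(self, seed=0):
        design = DesignParams(n_sessions=2, n_blocks=2, trials_per_block=5,
                              paired_per_block=4)
        return SyntheticCohort(design, default_learning_model(),
                               {"saline": 2, "PCP": 2}, seed=seed)

    def test_default_cohort_dimensions(self):
        c = SyntheticCohort(DesignParams(), default_learning_model(),
                            {"saline": 13, "PCP": 10, "PCP-eNpHR": 12,
                             "PCP-EYFP": 16}, seed=0)
        assert c.n_subjects == 51
        assert c.n_sessions == 7
        sch = c.session_schedule(c.subjects[0], 1)
        assert len(sch) == 120

    def test_identical_seed_identical_dataset(self):
        a, b = self.small_cohort(3), self.small_cohort(3)
        ta = list(a.iter_session(a.subjects[1], 2))
        tb = list(b.iter_session(b.subjects[1], 2))
        for x, y in zip(ta, tb):
            np.testing.assert_array_equal(x.raw.samples, y.raw.samples)
            assert dataclasses.asdict(x.truth) == dataclasses.asdict(y.truth)

    def test_different_seed_different_traces(self):
        a, b = self.small_cohort(3), self.small_cohort(4)
        ta = next(iter(a.iter_session(a.subjects[0], 1)))
        tb = next(iter(b.iter_session(b.subjects[0], 1)))
        assert not np.array_equal(ta.raw.samples, tb.raw.samples)

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticCohort(DesignParams(), default_learning_model(),
                            {"saline": 0}, seed=0)

    def test_ground_truth_cr_fraction_matches_binomial_bound(self):
        # long-window asymptote 0.6, one session of 108 paired trials
        m = single_group_model(p_max=dict(short=0.0, middle=0.0, long=0.6),
                               slope=2.0, inflection_session=1.0,
                               peak_latency_sd_ms=120.0)
        design = DesignParams(n_sessions=1)
        c = SyntheticCohort(design, m, {"g": 1}, seed=9)
        p = m.cr_probability("g", "long", 20)
        trials = [t for t in c.iter_session(c.subjects[0], 1)]
        # score the ground truth at a late session by regenerating with the
        # asymptotic probability: use session 1 but slope/inflection make p ~ 0.6
        paired = [t for t in trials if t.spec.trial_type == PAIRED]
        frac = np.mean([t.truth.cr_window == "long" for t in paired])
        p1 = m.cr_probability("g", "long", 1)
        bound = 3.0 * math.sqrt(p1 * (1 - p1) / len(paired))
        assert abs(frac - p1) <= bound
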