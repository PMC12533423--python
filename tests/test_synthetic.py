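"""Generator behaviour: determinism, preset structure, distributional shape."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from disfluency.design import DesignSpec, assign_participants, build_counterbalanced_lists
from disfluency.synthetic import (
    EncodingGenConfig,
    RecognitionGenConfig,
    encoding_preset,
    recognition_preset,
    simulate_encoding,
    simulate_full_experiment,
    simulate_recognition,
)
from disfluency.exgauss import ExGaussianParams


@pytest.fixture(scope="module")
def small_design():
    lists = build_counterbalanced_lists(DesignSpec(n_words=18), seed=0)
    subjects = assign_participants(lists, 4)
    return lists, subjects


class TestSimulateEncoding:
    def test_one_trial_per_subject_item(self, small_design):
        lists, subjects = small_design
        cfg = encoding_preset("stage_specific")
        trials = simulate_encoding(cfg, lists, subjects, seed=1)
        # 18 study words + 9 animal-free design -> 18 study rows per subject
        per_subject = trials.groupby("subject_id").size()
        assert (per_subject == 18).all()
        assert (trials["phase"] == "encoding").all()
        assert (trials["status"] == "na").all()

    def test_seed_determinism(self, small_design):
        lists, subjects = small_design
        cfg = encoding_preset("stage_specific")
        a = simulate_encoding(cfg, lists, subjects, seed=5)
        b = simulate_encoding(cfg, lists, subjects, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_encoding(cfg, lists, subjects, seed=6)
        assert not a["rt"].equals(c["rt"])

    def test_stage_specific_shift_and_skew(self):
        # high-blur mu and tau elevated -> slower mean, and the fitted
        # exponential scale recovers the tail inflation (sample skewness is too
        # noisy for the ~0.1 theoretical gap at this n; tau is the stable
        # tail statistic)
        from disfluency.exgauss import fit_exgauss_mle

        lists = build_counterbalanced_lists(DesignSpec(n_words=84), seed=0)
        subjects = assign_participants(lists, 36)
        cfg = encoding_preset("stage_specific")
        cfg.subject_sd = {}
        cfg.item_sd = {}
        trials = simulate_encoding(cfg, lists, subjects, seed=2)
        by_blur = trials.groupby("blur")["rt"]
        means = by_blur.mean()
        assert means["high"] - means["clear"] > 0
        assert (by_blur.skew() > 0).all()
        tau = {
            blur: fit_exgauss_mle(grp.to_numpy())[0].tau
            for blur, grp in by_blur
        }
        assert tau["high"] > tau["clear"]
        assert tau["high"] / tau["clear"] == pytest.approx(
            np.exp(0.43), rel=0.10
        )

    def test_exchangeable_when_conditions_identical(self, small_design):
        lists, subjects = small_design
        p = ExGaussianParams(0.5, 0.05, 0.2)
        cfg = EncodingGenConfig(
            params={b: p for b in ("clear", "low", "high")},
            error_rate={b: 0.0 for b in ("clear", "low", "high")},
            subject_sd={}, item_sd={},
        )
        big_lists = build_counterbalanced_lists(DesignSpec(n_words=84), seed=0)
        big_subj = assign_participants(big_lists, 36)
        trials = simulate_encoding(cfg, big_lists, big_subj, seed=3)
        means = trials.groupby("blur")["rt"].mean()
        sem = trials["rt"].std() / np.sqrt(len(trials) / 3)
        assert np.ptp(means.to_numpy()) < 4 * sem

    def test_mismatched_conditions_error(self, small_design):
        lists, subjects = small_design
        cfg = EncodingGenConfig(params={"clear": ExGaussianParams(0.5, 0.05, 0.2)})
        with pytest.raises(KeyError, match="condition"):
            simulate_encoding(cfg, lists, subjects, seed=0)

    def test_ddm_generator_accuracy_ordering(self):
        # lower drift and higher ter for high blur -> lower accuracy, slower RTs
        from disfluency.ddm import DDMParams, boundary_probability

        lists = build_counterbalanced_lists(DesignSpec(n_words=30), seed=1)
        subjects = assign_participants(lists, 6)
        cfg = EncodingGenConfig(
            generator="ddm",
            params={
                "clear": DDMParams(v=2.5, a=1.2, ter=0.35),
                "low": DDMParams(v=2.5, a=1.2, ter=0.38),
                "high": DDMParams(v=1.5, a=1.2, ter=0.45),
            },
            subject_sd={}, item_sd={},
        )
        trials = simulate_encoding(cfg, lists, subjects, seed=4)
        acc = trials.groupby("blur")["accuracy"].mean()
        assert acc["high"] < acc["clear"]
        # simulated accuracies near the closed-form absorption probabilities
        for blur in ("clear", "high"):
            p_hit = boundary_probability(cfg.params[blur], "upper")
            assert acc[blur] == pytest.approx(p_hit, abs=0.05)


class TestSimulateRecognition:
    def test_chance_at_zero_dprime(self, small_design):
        lists, subjects = small_design
        big_lists = build_counterbalanced_lists(DesignSpec(n_words=84), seed=0)
        big_subj = assign_participants(big_lists, 36)
        cfg = RecognitionGenConfig(
            dprime={b: 0.0 for b in ("clear", "low", "high")},
            criterion={b: 0.0 for b in ("clear", "low", "high")},
            subject_sd_dprime=0.0, subject_sd_criterion=0.0,
        )
        trials = simulate_recognition(cfg, big_lists, big_subj, seed=0)
        p_old = (trials["response"] == "old").mean()
        assert p_old == pytest.approx(0.5, abs=0.01)

    def test_hit_fa_match_normal_cdf(self):
        # d'=1, c=0: P(hit)=Phi(.5)~.691, P(fa)=Phi(-.5)~.309
        lists = build_counterbalanced_lists(DesignSpec(n_words=84), seed=0)
        subjects = assign_participants(lists, 36)
        cfg = RecognitionGenConfig(
            dprime={b: 1.0 for b in ("clear", "low", "high")},
            criterion={b: 0.0 for b in ("clear", "low", "high")},
            subject_sd_dprime=0.0, subject_sd_criterion=0.0,
        )
        trials = simulate_recognition(cfg, lists, subjects, seed=1)
        old = trials[trials["status"] == "old"]
        new = trials[trials["status"] == "new"]
        assert (old["response"] == "old").mean() == pytest.approx(
            stats.norm.cdf(0.5), abs=0.01
        )
        assert (new["response"] == "old").mean() == pytest.approx(
            stats.norm.cdf(-0.5), abs=0.01
        )


class TestFullExperiment:
    def test_exp1a_default_structure(self):
        trials, truth = simulate_full_experiment("1A", seed=0)
        assert truth["n_subjects"] == 216
        assert truth["n_lists"] == 6
        enc = trials[trials["phase"] == "encoding"]
        one_subject = enc[enc["subject_id"] == enc["subject_id"].iloc[0]]
        assert (one_subject["stim_class"] == "word").sum() == 84
        assert (one_subject["stim_class"] == "nonword").sum() == 84
        test = trials[trials["phase"] == "test"]
        assert test.groupby("subject_id").size().iloc[0] == 168

    def test_exp2_structure(self):
        trials, truth = simulate_full_experiment("2", n_subjects=12, n_words=12, seed=0)
        enc = trials[trials["phase"] == "encoding"]
        one = enc[enc["subject_id"] == enc["subject_id"].iloc[0]]
        n_nonanimal = (one["stim_class"] == "nonanimal").sum()
        n_animal = (one["stim_class"] == "animal").sum()
        assert n_nonanimal == 2 * n_animal
        # animals never at test
        test = trials[trials["phase"] == "test"]
        assert (test["stim_class"] == "nonanimal").all()

    def test_zero_subjects_gives_truth_only(self):
        trials, truth = simulate_full_experiment("1A", n_subjects=0, seed=0)
        assert trials.empty
        assert truth["n_lists"] == 6

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            simulate_full_experiment("3", seed=0)

    def test_seed_determinism_full(self):
        a, _ = simulate_full_experiment("1A", n_subjects=6, n_words=6, seed=9)
        b, _ = simulate_full_experiment("1A", n_subjects=6, n_words=6, seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_generated_rts_pass_gof_against_family():
    """Large-n draws match the generating ex-Gaussian (KS distance small)."""
    from disfluency.exgauss import exgauss_cdf

    p = ExGaussianParams(0.55, 0.08, 0.25)
    lists = build_counterbalanced_lists(DesignSpec(n_words=84), seed=0)
    subjects = assign_participants(lists, 36)
    cfg = EncodingGenConfig(
        params={b: p for b in ("clear", "low", "high")},
        error_rate={b: 0.0 for b in ("clear", "low", "high")},
        subject_sd={}, item_sd={},
    )
    trials = simulate_encoding(cfg, lists, subjects, seed=7)
    x = trials["rt"].to_numpy()
    stat = stats.kstest(x, lambda q: exgauss_cdf(q, p)).statistic
    assert stat < 0.01
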