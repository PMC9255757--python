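"""Joint posterior inference: masks, log-joint, sampler contracts, fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogtom import _kernels
from cogtom.asrt import generate_session
from cogtom.inference import (CTFit, FitConfig, HDPHyper, PosteriorSample,
                              _pi_row_conc, diagnostics, fit_ct,
                              fit_fixed_model, fit_markov, log_joint,
                              predict_rts, valid_trial_mask)
from cogtom.later import LaterParams, map_rt, rt_density
from cogtom.models import (HMMParams, ideal_observer, initial_belief,
                           markov_from_hmm, regularize_hmm,
                           sequence_predictions)
from cogtom.synthetic import (SyntheticParticipant, _subseq,
                              ground_truth_probs, simulate_participant)


@pytest.fixture(scope="module")
def late_trials(late_participant, session10):
    return simulate_participant(late_participant, session10, seed=18)


@pytest.fixture(scope="module")
def markov_fit(session10, markov_trials, hyper8, desk_split):
    return fit_markov(session10, markov_trials, hyper8, desk_split)


@pytest.fixture(scope="module")
def markov_fit_on_late(session10, late_trials, hyper8, desk_split):
    return fit_markov(session10, late_trials, hyper8, desk_split)


def _toy_trials(rts_ms, correct=None, types=None):
    n = len(rts_ms)
    return pd.DataFrame({
        "block": 1, "index_in_block": range(1, n + 1),
        "stimulus": ([1, 2, 3, 4] * n)[:n],
        "trial_type": types or ["warmup"] * 5 + ["pattern", "random"] * ((n - 5) // 2),
        "correct": correct if correct is not None else [1] * n,
        "rt_ms": rts_ms,
    })


class TestValidTrialMask:
    def test_clean_block_masks_only_warmups(self):
        t = _toy_trials([300.0] * 85,
                        types=["warmup"] * 5 + ["pattern", "random"] * 40)
        mask = valid_trial_mask(t, FitConfig())
        assert mask.sum() == 80
        assert not mask[:5].any()

    def test_handcrafted_exclusions(self):
        # 10 trials: 5 warm-ups, one incorrect, one 150 ms -> 7 valid would
        # be the count without warm-up masking; with it, 3 of the last 5
        types = ["warmup"] * 5 + ["pattern", "random"] * 2 + ["pattern"]
        correct = [1] * 6 + [0] + [1] * 3
        rts = [300.0] * 8 + [150.0] + [300.0]
        t = _toy_trials(rts, correct=correct, types=types)
        mask = valid_trial_mask(t, FitConfig())
        assert mask.tolist() == [False] * 5 + [True, False, True, False, True]

    def test_all_incorrect_warns_and_fit_refuses(self, pattern):
        seq = generate_session(pattern, n_blocks=1, seed=0)
        t = seq.trials.copy()
        t["correct"] = 0
        t["rt_ms"] = 300.0
        with pytest.warns(UserWarning, match="no valid trials"):
            mask = valid_trial_mask(t, FitConfig())
        assert mask.sum() == 0
        cfg = FitConfig.desk(train_blocks=(1,), test_blocks=(2,), seed=0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no valid trials"):
                fit_markov(None, t, HDPHyper(), cfg)

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="missing columns"):
            valid_trial_mask(pd.DataFrame({"rt_ms": [1.0]}), FitConfig())


class TestLogJoint:
    def _sample(self, seed=0, k=4):
        rng = np.random.default_rng(seed)
        hmm = HMMParams(rng.dirichlet(np.full(k, 1.0), size=k),
                        rng.dirichlet(np.full(4, 1.0), size=k))
        return PosteriorSample(hmm=hmm, later=LaterParams(0.15, 8.0, 2.0),
                               slice_eps=0.1, chain=0, step=0)

    def test_likelihood_is_sum_of_per_trial_densities(self, pattern,
                                                      markov_trials):
        s = self._sample()
        t = markov_trials[markov_trials.block == 1].reset_index(drop=True)
        cfg = FitConfig()
        lj = log_joint(s, None, t, HDPHyper(), cfg)
        preds = sequence_predictions(s.hmm, t.stimulus.to_numpy())
        p_n = preds[np.arange(len(t)), t.stimulus.to_numpy() - 1]
        mask = valid_trial_mask(t, cfg)
        ll = sum(np.log(rt_density(rt / 1000.0, p, s.later))
                 for rt, p in zip(t.rt_ms[mask], p_n[mask]))
        # subtracting the prior term must leave exactly the likelihood
        prior = lj - _kernels.filter_rt_loglik(
            s.hmm.transition, s.hmm.emission,
            t.stimulus.to_numpy() - 1, mask, t.rt_ms.to_numpy() / 1000.0,
            0.15, 8.0, 2.0, 0.0, initial_belief(s.hmm))
        assert lj - prior == pytest.approx(ll, rel=1e-9)

    def test_doubling_data_doubles_likelihood_term(self, markov_trials):
        # with a single-state internal model the per-trial predictions do
        # not depend on history, so concatenating two copies of the data
        # exactly doubles the likelihood term while the prior is unchanged
        hmm = HMMParams(np.ones((1, 1)), np.array([[0.4, 0.3, 0.2, 0.1]]))
        s = PosteriorSample(hmm=hmm, later=LaterParams(0.15, 8.0, 2.0),
                            slice_eps=0.1, chain=0, step=0)
        cfg, hyper = FitConfig(), HDPHyper()
        t1 = markov_trials[markov_trials.block == 1].reset_index(drop=True)
        t2 = pd.concat([t1, t1], ignore_index=True)
        ll1 = self._likelihood_of(s, t1, cfg)
        lj1 = log_joint(s, None, t1, hyper, cfg)
        lj2 = log_joint(s, None, t2, hyper, cfg)
        prior = lj1 - ll1
        assert lj2 - prior == pytest.approx(2.0 * ll1, rel=1e-9)

    @staticmethod
    def _likelihood_of(s, t, cfg):
        mask = valid_trial_mask(t, cfg)
        return _kernels.filter_rt_loglik(
            s.hmm.transition, s.hmm.emission, t.stimulus.to_numpy() - 1,
            mask, t.rt_ms.to_numpy() / 1000.0, s.later.theta0, s.later.mu,
            s.later.sigma, 0.0, initial_belief(s.hmm))

    def test_prior_matches_reference_pdfs(self):
        s = self._sample(seed=1, k=4)
        hyper = HDPHyper(k_max=4)
        conc_pi = _pi_row_conc(hyper, s.slice_eps)
        expect = sum(stats.dirichlet.logpdf(row / row.sum(), conc_pi)
                     for row in s.hmm.transition)
        expect += sum(stats.dirichlet.logpdf(row / row.sum(),
                                             hyper.emission_base)
                      for row in s.hmm.emission)
        expect += stats.gamma.logpdf(0.15, 1.0, scale=1 / 10.0)
        expect += stats.gamma.logpdf(8.0, 1.0, scale=1 / 0.1)
        expect += stats.gamma.logpdf(2.0, 1.0, scale=1 / 0.01)
        from cogtom.inference import _log_prior
        got = _log_prior(s.hmm.transition, s.hmm.emission,
                         np.array([0.15, 8.0, 2.0]), hyper, s.slice_eps, "ct")
        assert got == pytest.approx(expect, rel=1e-9)

    def test_continuous_in_later_parameters(self, markov_trials):
        s = self._sample()
        cfg, hyper = FitConfig(), HDPHyper()
        t = markov_trials[markov_trials.block == 2]
        base = log_joint(s, None, t, hyper, cfg)
        deltas = []
        for h in (1e-3, 1e-4, 1e-5):
            s2 = PosteriorSample(hmm=s.hmm,
                                 later=LaterParams(0.15 + h, 8.0, 2.0),
                                 slice_eps=0.1, chain=0, step=0)
            deltas.append(abs(log_joint(s2, None, t, hyper, cfg) - base))
        assert deltas[0] > deltas[1] > deltas[2]  # shrinks with step size


class TestSliceTruncation:
    def test_eps_zero_keeps_all_states(self):
        b = np.array([0.5, 0.3, 0.15, 0.05])
        kept = b.copy()
        _kernels._truncate_belief(kept, 0.0)
        assert kept == pytest.approx(b)

    def test_support_covers_one_minus_eps(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            b = rng.dirichlet(np.full(8, 0.3))
            kept = b.copy()
            eps = rng.uniform(0.02, 0.2)
            _kernels._truncate_belief(kept, eps)
            survivors = kept > 0
            assert b[survivors].sum() >= 1 - eps - 1e-12
            assert kept.sum() == pytest.approx(1.0)
            # minimality: dropping the smallest survivor would undershoot
            if survivors.sum() > 1:
                smallest = np.min(b[survivors])
                assert b[survivors].sum() - smallest < 1 - eps


class TestFitContracts:
    def test_ct_smoke_two_outer_steps(self, session10, markov_trials, hyper8,
                                      desk_split):
        cfg = FitConfig(n_chains=2, n_outer_steps=2, n_inner_steps=1,
                        train_blocks=desk_split.train_blocks,
                        test_blocks=desk_split.test_blocks, seed=1)
        fit = fit_ct(session10, markov_trials, hyper8, cfg)
        assert fit.model == "ct" and len(fit) == 2  # second half retained
        for s in fit.samples:
            assert s.hmm.transition.shape == (8, 8)
            assert 0.02 <= s.slice_eps <= 0.2

    def test_markov_smoke_and_sample_invariants(self, markov_fit):
        assert markov_fit.model == "markov"
        for s in markov_fit.samples:
            assert s.hmm.emission == pytest.approx(np.eye(4))
            assert s.hmm.transition.sum(axis=1) == pytest.approx(np.ones(4))
            assert (s.hmm.transition >= 0).all()
            assert s.later.theta0 >= 0 and s.later.mu > 0 and s.later.sigma > 0

    def test_markov_recovers_true_transitions(self, markov_fit, markov_truth):
        rows = np.mean([markov_from_hmm(s.hmm)
                        for s in markov_fit.prediction_samples()], axis=0)
        assert np.abs(rows - markov_truth).max() < 0.05

    def test_markov_near_uniform_on_phase_structured_data(
            self, markov_fit_on_late, markov_fit, markov_truth):
        # data whose structure is invisible one step back: the posterior
        # mean transition rows approach the uniform matrix (residual
        # deviation ~0.05 at this data size is finite-sample structure in
        # the RT likelihood), while a fit to genuinely Markov behaviour
        # stays close to its informative ground truth far from uniform
        rows = np.mean([markov_from_hmm(s.hmm)
                        for s in markov_fit_on_late.prediction_samples()],
                       axis=0)
        dev_uniform = np.abs(rows - 0.25).max()
        assert dev_uniform < 0.1
        informative = np.mean([markov_from_hmm(s.hmm)
                               for s in markov_fit.prediction_samples()],
                              axis=0)
        assert np.abs(informative - 0.25).max() > 3 * dev_uniform
        assert np.abs(markov_truth - 0.25).max() > 3 * dev_uniform

    def test_fixed_model_returns_hmm_untouched(self, session10, late_trials,
                                               hyper8, pattern):
        io_reg = regularize_hmm(ideal_observer(pattern))
        cfg = FitConfig.desk(train_blocks=tuple(range(6, 11)),
                             test_blocks=tuple(range(1, 6)), seed=2,
                             n_outer_steps=20)
        fit = fit_fixed_model(io_reg, session10, late_trials, hyper8, cfg)
        for s in fit.samples:
            assert (s.hmm.transition == io_reg.transition).all()
            assert (s.hmm.emission == io_reg.emission).all()

    def test_fixed_model_interval_calibration(self, session10, pattern,
                                              hyper8):
        # 50 replicate datasets from (regularized ideal observer, known
        # LATER params): the 90% intervals cover each truth in >= 86%
        io_reg = regularize_hmm(ideal_observer(pattern))
        truth = LaterParams(0.18, 8.0, 2.0)
        sp = SyntheticParticipant(io_reg, truth, "ideal")
        cover = np.zeros(3)
        n_rep = 50
        for rep in range(n_rep):
            trials = simulate_participant(sp, session10, seed=500 + rep)
            cfg = FitConfig.desk(train_blocks=tuple(range(6, 11)),
                                 test_blocks=tuple(range(1, 6)),
                                 seed=600 + rep)
            fit = fit_fixed_model(io_reg, session10, trials, hyper8, cfg)
            a = np.array([[s.later.theta0, s.later.mu, s.later.sigma]
                          for s in fit.samples])
            for j, tv in enumerate([truth.theta0, truth.mu, truth.sigma]):
                lo, hi = np.quantile(a[:, j], [0.05, 0.95])
                cover[j] += lo <= tv <= hi
        assert (cover / n_rep >= 0.86).all()

    def test_ct_recovery_on_markov_participant(self, ct_fit_markov, session10,
                                               markov_trials,
                                               markov_participant,
                                               heldout_metrics):
        m = heldout_metrics(ct_fit_markov, session10, markov_trials,
                            markov_participant)
        assert m["prob_recovery_r2"] >= 0.8
        assert m["prob_recovery_r2"] > m["rt_r2"]

    def test_prediction_r2_saturates_in_retained_samples(self, ct_fit_markov,
                                                         session10,
                                                         markov_trials,
                                                         heldout_metrics):
        def with_n(n):
            sub = CTFit(samples=ct_fit_markov.prediction_samples(n),
                        config=FitConfig.desk(
                            train_blocks=ct_fit_markov.config.train_blocks,
                            test_blocks=ct_fit_markov.config.test_blocks,
                            n_prediction_samples_per_chain=n),
                        hyper=ct_fit_markov.hyper, model="ct",
                        train_obs=ct_fit_markov.train_obs)
            return heldout_metrics(sub, session10, markov_trials, None)["rt_r2"]

        assert abs(with_n(60) - with_n(120)) < 0.01


class TestPredictRTs:
    def test_single_sample_equals_map_rt_sequence(self, session10,
                                                  markov_fit):
        s = markov_fit.samples[-1]
        single = CTFit(samples=[s], config=markov_fit.config,
                       hyper=markov_fit.hyper, model="markov")
        sub = _subseq(session10, (1, 2))
        rts, probs = predict_rts(single, sub, return_probs=True)
        preds = sequence_predictions(s.hmm, sub)
        p_n = preds[np.arange(len(sub)), sub.stimuli - 1]
        assert rts == pytest.approx(map_rt(p_n, s.later), abs=0)

    def test_order_invariance(self, session10, markov_fit):
        sub = _subseq(session10, (1,))
        a = predict_rts(markov_fit, sub)
        # the same retained set averaged in reverse order gives the same mean
        same = CTFit(samples=markov_fit.prediction_samples()[::-1],
                     config=markov_fit.config, hyper=markov_fit.hyper,
                     model="markov")
        assert predict_rts(same, sub) == pytest.approx(a, abs=1e-12)

    def test_positive_correlation_with_generative_means(self, ct_fit_markov,
                                                        session10,
                                                        markov_participant):
        sub = _subseq(session10, tuple(range(1, 6)))
        rt_hat = predict_rts(ct_fit_markov, sub)
        p_true = ground_truth_probs(markov_participant, sub)
        rt_gen = map_rt(p_true, markov_participant.later)
        assert np.corrcoef(rt_hat, rt_gen)[0, 1] > 0.5


class TestDiagnostics:
    def test_identical_chains_zero_spread(self, markov_fit):
        dup = [PosteriorSample(hmm=s.hmm, later=s.later,
                               slice_eps=s.slice_eps, chain=s.chain + 10,
                               step=s.step)
               for s in markov_fit.samples if s.chain == 0]
        fit = CTFit(samples=[s for s in markov_fit.samples if s.chain == 0]
                    + dup, config=markov_fit.config, hyper=markov_fit.hyper,
                    model="markov", train_obs=markov_fit.train_obs)
        d = diagnostics(fit)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in d["cross_chain_spread"].values())
        assert all(d["cross_chain_agreement"].values())

    def test_well_converged_fit_chains_agree(self, session10, late_trials,
                                             hyper8, pattern):
        io_reg = regularize_hmm(ideal_observer(pattern))
        cfg = FitConfig.desk(train_blocks=tuple(range(6, 11)),
                             test_blocks=tuple(range(1, 6)), seed=7)
        fit = fit_fixed_model(io_reg, session10, late_trials, hyper8, cfg)
        d = diagnostics(fit)
        pooled = np.array([[s.later.theta0, s.later.mu, s.later.sigma]
                           for s in fit.samples])
        for j, name in enumerate(["theta0", "mu", "sigma"]):
            assert d["cross_chain_spread"][name] < 0.5 * pooled[:, j].std()

    def test_single_chain_rejected(self, markov_fit):
        fit = CTFit(samples=[s for s in markov_fit.samples if s.chain == 0],
                    config=markov_fit.config, hyper=markov_fit.hyper,
                    model="markov")
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics(fit)


class TestSerialization:
    def test_jsonl_round_trip(self, markov_fit, tmp_path):
        path = tmp_path / "fit.jsonl"
        markov_fit.to_jsonl(path)
        back = CTFit.from_jsonl(path)
        assert back.model == markov_fit.model
        assert len(back) == len(markov_fit)
        assert back.config == markov_fit.config
        assert back.hyper == markov_fit.hyper
        a, b = markov_fit.samples[-1], back.samples[-1]
        assert (a.hmm.transition == b.hmm.transition).all()
        assert a.later == b.later and a.slice_eps == b.slice_eps
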