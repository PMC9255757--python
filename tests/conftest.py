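"""Shared fixtures.

The expensive posterior fits are session-scoped and shared between the
unit tests and the acceptance suite; every random quantity is seeded so
the suite is reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cogtom.asrt import PatternSequence, generate_session
from cogtom.evaluation import r2_score
from cogtom.inference import (FitConfig, HDPHyper, fit_ct, fit_fixed_model,
                              fit_markov, predict_rts)
from cogtom.later import LaterParams
from cogtom.models import ideal_observer, markov_as_hmm, trigram_predictions
from cogtom.synthetic import (SyntheticParticipant, _subseq,
                              ground_truth_probs, make_ground_truth_models,
                              simulate_participant)


@pytest.fixture(scope="session")
def pattern() -> PatternSequence:
    return PatternSequence((2, 4, 3, 1))


@pytest.fixture(scope="session")
def session10(pattern):
    return generate_session(pattern, n_blocks=10, seed=13)


@pytest.fixture(scope="session")
def later_mid() -> LaterParams:
    return LaterParams(0.18, 8.0, 2.0)


@pytest.fixture(scope="session")
def markov_truth() -> np.ndarray:
    return np.random.default_rng(0).dirichlet(np.full(4, 2.0), size=4)


@pytest.fixture(scope="session")
def markov_participant(markov_truth, later_mid) -> SyntheticParticipant:
    return SyntheticParticipant(markov_as_hmm(markov_truth), later_mid, "custom")


@pytest.fixture(scope="session")
def late_participant(pattern, later_mid) -> SyntheticParticipant:
    sp = make_ground_truth_models(1, pattern)[2]
    return SyntheticParticipant(sp.internal_model, later_mid, "late")


@pytest.fixture(scope="session")
def hyper8() -> HDPHyper:
    return HDPHyper(k_max=8)


@pytest.fixture(scope="session")
def desk_split() -> FitConfig:
    """Desk-scale split on a 10-block session: train on the later half,
    test on the earlier half (same direction as the full protocol)."""
    return FitConfig.desk(train_blocks=tuple(range(6, 11)),
                          test_blocks=tuple(range(1, 6)), seed=3)


@pytest.fixture(scope="session")
def markov_trials(markov_participant, session10) -> pd.DataFrame:
    return simulate_participant(markov_participant, session10, seed=17)


@pytest.fixture(scope="session")
def ct_fit_markov(session10, markov_trials, hyper8, desk_split):
    """CT fit on Markov-participant data, long enough to retain 120
    prediction samples per chain."""
    config = FitConfig.desk(train_blocks=desk_split.train_blocks,
                            test_blocks=desk_split.test_blocks,
                            seed=3, n_outer_steps=240)
    return fit_ct(session10, markov_trials, hyper8, config)


def _heldout_metrics(fit, seq, trials, participant):
    """Test-block RT predictions and recovery metrics for one fit."""
    test = sorted(fit.config.test_blocks)
    sub = _subseq(seq, test)
    sel = trials[trials["block"].isin(test)].reset_index(drop=True)
    ok = ((sel["trial_type"] != "warmup")
          & (sel["rt_ms"] >= fit.config.rt_floor_ms)).to_numpy()
    rt_obs = sel["rt_ms"].to_numpy() / 1000.0
    rt_hat, p_hat = predict_rts(fit, sub, return_probs=True)
    out = {"rt_r2": r2_score(rt_hat[ok], rt_obs[ok])}
    if participant is not None:
        p_true = ground_truth_probs(participant, sub)
        out["prob_recovery_r2"] = r2_score(p_hat[ok], p_true[ok])
    return out


@pytest.fixture(scope="session")
def heldout_metrics():
    return _heldout_metrics


@pytest.fixture(scope="session")
def identification_battery(pattern, markov_participant, late_participant,
                           hyper8):
    """Markov vs ideal-observer fits on data from both participant types,
    three replicate seeds each; shared by the model-identification and
    model-ranking tests."""
    rows = []
    io_hmm = ideal_observer(pattern)
    for rep in range(3):
        seq = generate_session(pattern, n_blocks=10, seed=100 + rep)
        config = FitConfig.desk(train_blocks=tuple(range(6, 11)),
                                test_blocks=tuple(range(1, 6)),
                                seed=200 + rep)
        for sp, data_label in ((markov_participant, "markov"),
                               (late_participant, "ideal")):
            trials = simulate_participant(sp, seq, seed=300 + rep)
            f_mk = fit_markov(seq, trials, hyper8, config)
            f_io = fit_fixed_model(io_hmm, seq, trials, hyper8, config)
            test = sorted(config.test_blocks)
            sub = _subseq(seq, test)
            sel = trials[trials["block"].isin(test)].reset_index(drop=True)
            ok = ((sel["trial_type"] != "warmup")
                  & (sel["rt_ms"] >= config.rt_floor_ms)).to_numpy()
            rt_obs = sel["rt_ms"].to_numpy() / 1000.0
            tri_preds, _ = trigram_predictions(sub)
            tri_p = tri_preds[np.arange(len(sub)), sub.stimuli - 1]
            rows.append({
                "rep": rep, "data": data_label,
                "markov_r2": r2_score(predict_rts(f_mk, sub)[ok], rt_obs[ok]),
                "ideal_r2": r2_score(predict_rts(f_io, sub)[ok], rt_obs[ok]),
                "trigram_r2": r2_score(tri_p[ok], rt_obs[ok]),
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def reduced_grid_run(pattern, hyper8):
    """Reduced 2x2x2 validation grid (early model, 3 blocks) run
    end-to-end at the desk preset."""
    from cogtom.synthetic import (DEFAULT_MU_GRID, DEFAULT_SIGMA_GRID,
                                  DEFAULT_THETA0_GRID, recovery_report,
                                  validation_grid)

    seq = generate_session(pattern, n_blocks=3, seed=9)
    early = make_ground_truth_models(1, pattern)[0]
    datasets = validation_grid([early], DEFAULT_THETA0_GRID[::2],
                               DEFAULT_MU_GRID[::2], DEFAULT_SIGMA_GRID[::2],
                               seq=seq, seed=2)
    config = FitConfig.desk(train_blocks=(2, 3), test_blocks=(1,), seed=4)
    fits = [fit_ct(None, d["trials"], hyper8, config) for d in datasets]
    return datasets, fits, recovery_report(datasets, fits)
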