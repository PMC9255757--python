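"""Synthetic participants and the validation harness.

Ground-truth internal models of three "experience levels" stand in for
participants early, midway, and late in learning the task structure: a
near-Markov 4-state model, a 6-state hybrid that knows pattern elements
alternate with random ones but tracks the phase poorly, and the ideal
observer with softened emissions.  RTs are drawn from the LATER model at
the subjective probability each internal model assigns to the stimulus
that actually appears.  The validation grid crosses the three models with
three values of each RT parameter (3^3 = 27 cells per model, 81 datasets)
and the recovery report compares inferred subjective probabilities and
held-out RT predictions against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .asrt import PatternSequence, StimulusSequence, generate_session
from .evaluation import r2_score
from .inference import CTFit, predict_rts
from .later import LaterParams, sample_rt
from .models import HMMParams, ideal_observer, sequence_predictions

#: default RT-parameter grid (seconds and 1/seconds); spans simulated RT
#: standard deviations bracketing the human range (~30-100 ms)
DEFAULT_THETA0_GRID = (0.12, 0.18, 0.24)
DEFAULT_MU_GRID = (6.0, 8.0, 10.0)
DEFAULT_SIGMA_GRID = (1.0, 2.0, 3.0)


@dataclass
class SyntheticParticipant:
    internal_model: HMMParams
    later: LaterParams
    label: str = "custom"


def _soften(hmm: HMMParams, emission_noise: float, transition_noise: float) -> HMMParams:
    k = hmm.n_states
    phi = (1 - emission_noise) * hmm.emission + emission_noise / 4.0
    pi = (1 - transition_noise) * hmm.transition + transition_noise / k
    return HMMParams(pi, phi)


def _early_model(rng: np.random.Generator) -> HMMParams:
    """Near-Markov 4-state model: identity-like emissions, mildly structured
    transitions — immediate dependencies only, far from the task's truth."""
    pi = rng.dirichlet(np.full(4, 0.7), size=4)
    pi = 0.9 * pi + 0.1 / 4.0  # keep every next-stimulus belief reachable
    pi /= pi.sum(axis=1, keepdims=True)
    phi = np.full((4, 4), 0.05)
    np.fill_diagonal(phi, 0.85)
    phi /= phi.sum(axis=1, keepdims=True)
    return HMMParams(pi, phi)


def _middle_model(pattern: PatternSequence) -> HMMParams:
    """6-state hybrid: four softened pattern states plus two shared random
    states; it knows pattern and random elements alternate but cannot tell
    which phase to return to, so phase tracking stays noisy."""
    pi = np.zeros((6, 6))
    phi = np.zeros((6, 4))
    for i in range(4):
        pi[i, 4] = pi[i, 5] = 0.5  # pattern state -> one of the random states
        phi[i] = 0.3 / 3.0
        phi[i, pattern.elements[i] - 1] = 0.7
    for r in (4, 5):
        pi[r, :4] = 0.23  # poor phase memory: nearly uniform return
        pi[r, 4] = pi[r, 5] = 0.04
        phi[r] = 0.25
    pi /= pi.sum(axis=1, keepdims=True)
    return HMMParams(pi, phi)


def _late_model(pattern: PatternSequence) -> HMMParams:
    """Ideal observer with softened emissions and transitions — essentially
    the true process, with the residual haze of a learned estimate."""
    return _soften(ideal_observer(pattern), emission_noise=0.08,
                   transition_noise=0.04)


def make_ground_truth_models(
    seed: int | np.random.Generator | None = None,
    pattern: PatternSequence = PatternSequence((2, 4, 3, 1)),
) -> list[SyntheticParticipant]:
    """Three internal models of increasing structural fidelity to the task.

    Ordered early, middle, late; their mean KL from the ideal observer's
    predictions decreases in that order (checked in the tests).  The LATER
    parameters attached here are the grid midpoints; the validation grid
    replaces them cell by cell.
    """
    rng = np.random.default_rng(seed)
    later = LaterParams(DEFAULT_THETA0_GRID[1], DEFAULT_MU_GRID[1],
                        DEFAULT_SIGMA_GRID[1])
    return [
        SyntheticParticipant(_early_model(rng), later, "early"),
        SyntheticParticipant(_middle_model(pattern), later, "middle"),
        SyntheticParticipant(_late_model(pattern), later, "late"),
    ]


def fit_stimulus_model(pattern: PatternSequence, n_trials: int,
                       n_states: int = 8,
                       seed: int | None = None) -> HMMParams:
    """Alternative ground-truth construction: fit an HMM to stimuli alone.

    Trains a categorical HMM on ``n_trials`` of ASRT stimuli by EM
    (hmmlearn), emulating a learner whose internal model reflects a given
    amount of exposure.
    """
    from hmmlearn.hmm import CategoricalHMM

    n_blocks = max(1, int(np.ceil(n_trials / 85)))
    seq = generate_session(pattern, n_blocks=n_blocks, seed=seed)
    x = (seq.stimuli[:n_trials] - 1).reshape(-1, 1)
    m = CategoricalHMM(n_components=n_states, n_features=4, random_state=seed,
                       n_iter=200, tol=1e-4, init_params="ste")
    m.fit(x)
    pi = np.clip(m.transmat_, 1e-12, None)
    phi = np.clip(m.emissionprob_, 1e-12, None)
    return HMMParams(pi / pi.sum(axis=1, keepdims=True),
                     phi / phi.sum(axis=1, keepdims=True))


def simulate_participant(
    sp: SyntheticParticipant,
    seq: StimulusSequence,
    seed: int | np.random.Generator | None = None,
    participant_id: str = "synthetic",
    session: int = 1,
) -> pd.DataFrame:
    """Trial table with LATER-sampled RTs for one synthetic participant.

    Filters the stimuli under the participant's internal model, evaluates
    the subjective probability of each realized stimulus, and draws the RT
    from the LATER distribution at that probability.  All responses are
    correct (error simulation is out of scope); RTs are in milliseconds in
    the returned table.
    """
    rng = np.random.default_rng(seed)
    preds = sequence_predictions(sp.internal_model, seq)
    obs0 = seq.stimuli - 1
    p_n = preds[np.arange(len(obs0)), obs0]
    rts = sample_rt(p_n, sp.later, rng)
    rts = np.atleast_1d(rts)
    t = seq.trials.copy()
    t.insert(0, "participant_id", participant_id)
    t.insert(1, "session", session)
    t["response"] = t["stimulus"]
    t["correct"] = 1
    t["rt_ms"] = rts * 1000.0
    return t


def inject_errors(trials: pd.DataFrame, sp: SyntheticParticipant,
                  seq: StimulusSequence, threshold: float = 0.3,
                  rate: float = 0.5,
                  seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Semi-synthetic error trials for the error-prediction analyses.

    The participant simulator generates correct trials only; this
    extension marks a trial incorrect (with a random wrong key as the
    response) with probability ``rate`` whenever the generating model's
    subjective probability of the realized stimulus falls below
    ``threshold`` — errors concentrate where the participant expected
    something else, which is the structure the rank/ROC analyses probe.
    """
    rng = np.random.default_rng(seed)
    p_true = ground_truth_probs(sp, seq)
    out = trials.copy()
    flip = (p_true < threshold) & (rng.random(len(out)) < rate)
    stim = out["stimulus"].to_numpy()
    wrong = np.array([rng.choice([k for k in (1, 2, 3, 4) if k != s])
                      for s in stim[flip]])
    out.loc[flip, "response"] = wrong
    out.loc[flip, "correct"] = 0
    return out


def validation_grid(
    models: list[SyntheticParticipant] | None = None,
    theta0_values: tuple[float, ...] = DEFAULT_THETA0_GRID,
    mu_values: tuple[float, ...] = DEFAULT_MU_GRID,
    sigma_values: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    seq: StimulusSequence | None = None,
    seed: int | None = None,
) -> list[dict]:
    """Cartesian product of ground-truth models and RT parameters.

    Returns one record per dataset: the dataset id encodes the cell
    (model label, grid indices), and each record carries the simulated
    trial table, the generating participant, and the RT standard
    deviation of the simulated data.
    """
    rng = np.random.default_rng(seed)
    if models is None:
        models = make_ground_truth_models(rng)
    if seq is None:
        seq = generate_session(PatternSequence((2, 4, 3, 1)), n_blocks=10, seed=rng)
    datasets = []
    for m in models:
        cells = product(enumerate(theta0_values), enumerate(mu_values),
                        enumerate(sigma_values))
        for (i, th), (j, mu), (k, sg) in cells:
            sp = SyntheticParticipant(m.internal_model,
                                      LaterParams(th, mu, sg), m.label)
            child_seed = int(rng.integers(2**31 - 1))
            trials = simulate_participant(sp, seq, seed=child_seed)
            datasets.append({
                "id": f"{m.label}-t{i}m{j}s{k}",
                "participant": sp,
                "seq": seq,
                "trials": trials,
                "rt_sd_ms": float(trials["rt_ms"].std()),
                "seed": child_seed,
            })
    return datasets


def ground_truth_probs(sp: SyntheticParticipant,
                       seq: StimulusSequence) -> np.ndarray:
    """Per-trial subjective probability of the realized stimulus under the
    generating internal model."""
    preds = sequence_predictions(sp.internal_model, seq)
    return preds[np.arange(len(seq)), seq.stimuli - 1]


def recovery_report(datasets: list[dict], fits: list[CTFit]) -> pd.DataFrame:
    """Per-dataset recovery metrics against ground truth.

    For each dataset/fit pair: held-out RT-prediction R^2 (corr^2, on the
    configured test blocks), subjective-probability recovery R^2 (inferred
    mean prediction of the realized stimulus vs the generating model's),
    and the generating model's own RT R^2 as the attainable ceiling.
    """
    if len(datasets) != len(fits):
        raise ValueError("one fit per dataset required")
    rows = []
    for d, fit in zip(datasets, fits):
        seq, sp, trials = d["seq"], d["participant"], d["trials"]
        test = sorted(set(fit.config.test_blocks) & set(trials["block"]))
        sel = trials[trials["block"].isin(test)].reset_index(drop=True)
        sub = _subseq(seq, test)
        rt_obs = sel["rt_ms"].to_numpy() / 1000.0
        ok = (sel["trial_type"] != "warmup").to_numpy() & \
            (sel["rt_ms"].to_numpy() >= fit.config.rt_floor_ms)
        rt_hat, p_hat = predict_rts(fit, sub, return_probs=True)
        p_true = ground_truth_probs(sp, sub)
        preds_true = sequence_predictions(sp.internal_model, sub)
        obs0 = sub.stimuli - 1
        rt_ceiling = np.array(
            [sp.later.theta0 + (-np.log(max(p, 1e-6))) / sp.later.mu
             for p in preds_true[np.arange(len(obs0)), obs0]])
        rows.append({
            "dataset": d["id"],
            "model": sp.label,
            "rt_sd_ms": d["rt_sd_ms"],
            "rt_r2": r2_score(rt_hat[ok], rt_obs[ok]),
            "prob_recovery_r2": r2_score(p_hat[ok], p_true[ok]),
            "rt_r2_ceiling": r2_score(rt_ceiling[ok], rt_obs[ok]),
        })
    return pd.DataFrame(rows)


def _subseq(seq: StimulusSequence, blocks) -> StimulusSequence:
    # block numbers keep their original values, so the full per-block
    # pattern list is carried along for triplet labelling
    t = seq.trials[seq.trials["block"].isin(blocks)].reset_index(drop=True)
    return StimulusSequence(trials=t, pattern=seq.pattern,
                            n_blocks=seq.n_blocks,
                            block_patterns=list(seq.block_patterns))
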