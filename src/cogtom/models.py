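"""Discrete-HMM internal models and exact reference constructors.

The participant's internal model of the stimulus sequence is a hidden
Markov model: latent states with transition matrix ``pi`` (K x K) and
categorical emission matrix ``phi`` (K x 4).  Belief filtering propagates
the posterior over the current latent state through each observed
stimulus; one-step prediction marginalizes the propagated belief through
the emissions to give the subjective probability of each upcoming
stimulus.  The module also builds the three reference models: the ideal
observer (the true 8-state generative process of the task), the
observation-level Markov model written as an HMM, and the two-back
trigram predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .asrt import PatternSequence, StimulusSequence, analytic_trigram_probabilities

_ROW_TOL = 1e-10


@dataclass
class HMMParams:
    """Internal-model hypothesis: K states, transitions pi, emissions phi."""

    transition: np.ndarray  # (K, K)
    emission: np.ndarray  # (K, 4)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        k = self.transition.shape[0]
        if self.transition.shape != (k, k) or self.emission.shape != (k, 4):
            raise ValueError("transition must be (K,K) and emission (K,4)")
        for name, m in (("transition", self.transition), ("emission", self.emission)):
            if (m < 0).any():
                raise ValueError(f"{name} has negative entries")
            if np.abs(m.sum(axis=1) - 1.0).max() > _ROW_TOL:
                raise ValueError(f"{name} rows must sum to 1 within {_ROW_TOL}")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "transition": self.transition.tolist(),
                "emission": self.emission.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "HMMParams":
        d = json.loads(s)
        hmm = cls(np.array(d["transition"]), np.array(d["emission"]))
        if hmm.n_states != d["n_states"]:
            raise ValueError("n_states inconsistent with transition shape")
        return hmm


def _check_distribution(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if (v < 0).any() or abs(v.sum() - 1.0) > _ROW_TOL:
        raise ValueError(f"{name} must be a probability vector (got sum {v.sum()})")
    return v


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix; uniform fallback.

    Used as the default initial belief: the least-informative belief that
    is dynamically consistent with the hypothesised transitions.  When the
    unit eigenvalue is not unique (periodic or reducible chains) the
    eigenvector average over the unit-circle eigenspace is still a valid
    invariant distribution; if extraction fails numerically we fall back
    to uniform.
    """
    k = transition.shape[0]
    vals, vecs = np.linalg.eig(transition.T)
    close = np.isclose(vals, 1.0, atol=1e-8)
    if not close.any():
        return np.full(k, 1.0 / k)
    v = np.real(vecs[:, close].sum(axis=1))
    if v.sum() <= 0 or (v < -1e-9).any():
        return np.full(k, 1.0 / k)
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def initial_belief(hmm: HMMParams) -> np.ndarray:
    return stationary_distribution(hmm.transition)


def update_belief(belief: np.ndarray, observation: int, hmm: HMMParams) -> np.ndarray:
    """One filtering step: posterior over S_t after observing ``observation``.

    Propagates the prior belief through the transitions, weights by the
    emission probability of the observed stimulus, and renormalizes.
    Raises when the observation has probability zero under every reachable
    state (possible only for degenerate user-supplied models).
    """
    belief = _check_distribution(belief, "belief")
    if observation not in (1, 2, 3, 4):
        raise ValueError(f"observation must be in 1..4, got {observation}")
    unnorm = (belief @ hmm.transition) * hmm.emission[:, observation - 1]
    total = unnorm.sum()
    if total <= 0.0:
        raise ValueError(
            f"observation {observation} is impossible under every reachable state"
        )
    return unnorm / total


def predict_next(belief: np.ndarray, hmm: HMMParams) -> np.ndarray:
    """Subjective next-stimulus probabilities: belief -> pi -> phi."""
    belief = _check_distribution(belief, "belief")
    p = (belief @ hmm.transition) @ hmm.emission
    return p / p.sum()


def sequence_predictions(
    hmm: HMMParams,
    seq: StimulusSequence | np.ndarray,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial predictions made *before* each stimulus is observed.

    Filtering consumes every stimulus — warm-up and error trials included —
    and the belief is carried across block boundaries.  Returns a (T, 4)
    array; row t is the prediction for trial t given trials 1..t-1.
    """
    obs = seq.stimuli if isinstance(seq, StimulusSequence) else np.asarray(seq)
    if len(obs) == 0:
        raise ValueError("sequence is empty")
    belief = initial_belief(hmm) if initial is None else np.asarray(initial, float)
    out = np.empty((len(obs), 4))
    for t, y in enumerate(obs):
        out[t] = predict_next(belief, hmm)
        try:
            belief = update_belief(belief, int(y), hmm)
        except ValueError as e:
            raise ValueError(f"filtering failed at trial {t + 1}: {e}") from e
    return out


def ideal_observer(pattern: PatternSequence) -> HMMParams:
    """The true generative process of the task as an 8-state HMM.

    States alternate Pattern_1, Random_1, ..., Pattern_4, Random_4:
    Pattern_i emits pattern element i with probability 1 and passes to
    Random_i, which emits uniformly and passes to Pattern_{i+1}.  Its
    one-step observable conditionals are uniform — knowing the previous
    stimulus alone says nothing about the next — which is what defeats the
    Markov model on this task.
    """
    pi = np.zeros((8, 8))
    phi = np.zeros((8, 4))
    for i in range(4):
        p_state, r_state = 2 * i, 2 * i + 1
        pi[p_state, r_state] = 1.0
        pi[r_state, (2 * ((i + 1) % 4))] = 1.0
        phi[p_state, pattern.elements[i] - 1] = 1.0
        phi[r_state] = 0.25
    return HMMParams(pi, phi)


def regularize_hmm(hmm: HMMParams, epsilon: float = 1e-3) -> HMMParams:
    """Mix transitions and emissions with a uniform component.

    Deterministic reference models (the exact ideal observer) assign
    probability zero to some warm-up stimulus runs, which makes exact
    filtering of a full block impossible.  Mixing a small uniform
    component (probability ``epsilon``) into every row yields a
    strictly positive model whose predictions differ negligibly while
    filtering any sequence.  Returns ``hmm`` unchanged if all entries are
    already positive.
    """
    if (hmm.transition > 0).all() and (hmm.emission > 0).all():
        return hmm
    k = hmm.n_states
    pi = (1 - epsilon) * hmm.transition + epsilon / k
    phi = (1 - epsilon) * hmm.emission + epsilon / 4.0
    return HMMParams(pi, phi)


def markov_as_hmm(transition4: np.ndarray) -> HMMParams:
    """Observation-level first-order Markov model written as an HMM.

    With one state per observation value and identity emissions, filtering
    reduces to a lookup: the prediction after observing y is row y of
    ``transition4``.
    """
    transition4 = np.asarray(transition4, dtype=float)
    if transition4.shape != (4, 4):
        raise ValueError("transition4 must be 4x4")
    return HMMParams(transition4, np.eye(4))


def markov_from_hmm(hmm: HMMParams) -> np.ndarray:
    """Recover the 4x4 observable conditionals of an identity-emission HMM."""
    if not np.allclose(hmm.emission, np.eye(4)):
        raise ValueError("not an identity-emission (Markov) HMM")
    return hmm.transition.copy()


def trigram_continuation_probabilities(
    pattern: PatternSequence = PatternSequence((1, 2, 3, 4)),
) -> tuple[float, float]:
    """Two-back continuation probabilities derived from the task process.

    Enumerates the 8-state generative machine at stationarity (uniform
    over states, which marginalizes over the pattern/random parity of the
    current trial): the probability that the stimulus two trials ahead is
    the pattern-successor of the current one, and the probability of one
    specific non-successor.  Agrees with the direct parity argument
    (1/2 * 1 + 1/2 * 1/4) and with the constants the trigram predictor
    emits.
    """
    hmm = ideal_observer(pattern)
    pi, phi = hmm.transition, hmm.emission
    two_step = pi @ pi
    w = np.full(8, 1.0 / 8)
    p_high = 0.0
    for s in range(8):
        ahead = two_step[s] @ phi  # distribution of the stimulus 2 ahead
        for y0 in range(4):
            if phi[s, y0] == 0.0:
                continue
            succ = pattern.successor(y0 + 1) - 1
            p_high += w[s] * phi[s, y0] * ahead[succ]
    # the three non-successors are exchangeable: each carries an equal share
    return float(p_high), float((1.0 - p_high) / 3.0)


def trigram_predictions(
    seq: StimulusSequence, pattern: PatternSequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two-back (triplet) model predictions plus high/low labels.

    The first two trials of each block get uniform predictions; every
    later trial puts the analytic high-continuation probability on the
    pattern-successor of the stimulus two back and splits the remainder
    over the three alternatives.  The specific values only matter up to
    the high/low dichotomy, but emitting the analytic ones keeps rank and
    ROC analyses well defined.
    """
    from .asrt import label_triplets

    p_high, p_low = analytic_trigram_probabilities()
    t = seq.trials
    stim = t["stimulus"].to_numpy()
    idx = t["index_in_block"].to_numpy()
    block = t["block"].to_numpy()
    preds = np.full((len(t), 4), 0.25)
    for i in np.flatnonzero(idx > 2):
        pat = seq.block_patterns[block[i] - 1] if pattern is None else pattern
        succ = pat.successor(stim[i - 2])
        preds[i] = p_low
        preds[i, succ - 1] = p_high
    labels = label_triplets(seq)
    return preds, labels
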