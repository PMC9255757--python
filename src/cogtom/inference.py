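"""Doubly-Bayesian inference of internal models from response times.

The experimenter model: a participant filters an HMM internal model
(transitions pi, emissions phi) over the stimulus stream and produces a
response time on each trial through the LATER law
RT = theta0 + (-log p)/r, r ~ N+(mu, sigma), where p is the subjective
probability the internal model assigned to the stimulus that actually
appeared.  Inference targets the joint posterior over (pi, phi, theta0,
mu, sigma) given the stimuli and the valid-trial RTs.

The nonparametric prior over the transition structure is implemented as a
finite truncation at ``k_max`` states whose row prior is
Dirichlet(alpha0/K, ..., alpha0/K, alpha0/K * eps), with the slicing
variable eps ~ Uniform(0.02, 0.2) resampled in an outer Gibbs step; while
eps is in force, filtering is restricted to the belief's 1-eps support.
The continuous parameters are updated between slice steps by an adaptive
Metropolis-within-Gibbs sweep: Dirichlet proposals on simplex rows (with
occasional independence draws from the prior) and log-space Gaussian
proposals on the positive RT parameters.  The filtered likelihood is
cheap to evaluate (compiled kernels), which lets the blocked sweep take
the place of gradient-based inner steps at these model sizes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd

from . import _kernels
from .asrt import StimulusSequence
from .later import LaterParams, map_rt
from .models import HMMParams, regularize_hmm, stationary_distribution

logger = logging.getLogger("cogtom")

MS_PER_S = 1000.0


# --------------------------------------------------------------------------
# configuration


@dataclass
class HDPHyper:
    """Hyperparameters of the truncated hierarchical prior and RT priors.

    ``alpha`` and ``gamma`` are the concentration constants of the
    hierarchical process the truncation approximates; ``alpha0`` scales
    the per-row Dirichlet concentration (the hierarchy gives it no fixed
    value, so it defaults to ``alpha``).  RT priors are shape-rate Gamma
    distributions with time in seconds: tau0 ~ G(1, 10) (mean 0.1 s),
    mu ~ G(1, 0.1) (mean 10 /s), sigma ~ G(1, 0.01) (mean 100 /s).
    """

    alpha: float = 1.3
    gamma: float = 3.8
    emission_base: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8)
    k_max: int = 12
    alpha0: float = 1.3
    tau0_prior: tuple[float, float] = (1.0, 10.0)
    mu_prior: tuple[float, float] = (1.0, 0.1)
    sigma_prior: tuple[float, float] = (1.0, 0.01)

    def __post_init__(self) -> None:
        vals = [self.alpha, self.gamma, self.alpha0, *self.emission_base,
                *self.tau0_prior, *self.mu_prior, *self.sigma_prior]
        if any(v <= 0 for v in vals) or self.k_max < 2:
            raise ValueError("hyperparameters must be positive, k_max >= 2")


@dataclass
class FitConfig:
    """Sampler and data-split configuration.

    The full preset mirrors the reference protocol (4 chains, 1600 outer
    slice steps, 30 inner sweeps, train on blocks 11-20, test on 1-10,
    180 ms fast-response floor); the desk preset is the down-scaled
    configuration used throughout the test suite.
    """

    n_chains: int = 4
    n_outer_steps: int = 1600
    n_inner_steps: int = 30
    n_prediction_samples_per_chain: int = 60
    train_blocks: tuple[int, ...] = tuple(range(11, 21))
    test_blocks: tuple[int, ...] = tuple(range(1, 11))
    rt_floor_ms: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_outer_steps, self.n_inner_steps,
               self.n_prediction_samples_per_chain) < 1:
            raise ValueError("all counts must be positive")
        if set(self.train_blocks) & set(self.test_blocks):
            raise ValueError("train and test blocks must be disjoint")

    @classmethod
    def full(cls, **kw) -> "FitConfig":
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "FitConfig":
        kw.setdefault("n_chains", 2)
        kw.setdefault("n_outer_steps", 200)
        kw.setdefault("n_inner_steps", 5)
        return cls(**kw)


@dataclass
class PosteriorSample:
    """One joint draw of internal-model and RT parameters."""

    hmm: HMMParams
    later: LaterParams
    slice_eps: float
    chain: int
    step: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.slice_eps <= 0.2):
            raise ValueError(f"slice_eps out of range: {self.slice_eps}")

    def key(self) -> bytes:
        return (self.hmm.transition.tobytes() + self.hmm.emission.tobytes()
                + np.array([self.later.theta0, self.later.mu,
                            self.later.sigma]).tobytes())


@dataclass
class CTFit:
    """Collection of retained posterior samples with chain metadata."""

    samples: list[PosteriorSample]
    config: FitConfig
    hyper: HDPHyper
    model: str  # "ct" | "markov" | "fixed"
    train_obs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.samples)

    def chains(self) -> list[int]:
        return sorted({s.chain for s in self.samples})

    def prediction_samples(self, n: int | None = None) -> list[PosteriorSample]:
        """Last ``n`` unique samples per chain (consecutive duplicates
        from rejected sweeps collapse to one)."""
        n = self.config.n_prediction_samples_per_chain if n is None else n
        out: list[PosteriorSample] = []
        for c in self.chains():
            chain = [s for s in self.samples if s.chain == c]
            uniq: list[PosteriorSample] = []
            last_key = None
            for s in chain:
                k = s.key()
                if k != last_key:
                    uniq.append(s)
                    last_key = k
            out.extend(uniq[-n:])
        return out

    def to_jsonl(self, path) -> None:
        from .io import provenance_header

        with open(path, "w") as f:
            head = {
                "record": "header",
                "model": self.model,
                "config": _config_dict(self.config),
                "hyper": _hyper_dict(self.hyper),
                "train_obs": self.train_obs.tolist(),
                **provenance_header(seed=self.config.seed),
            }
            f.write(json.dumps(head) + "\n")
            for s in self.samples:
                f.write(json.dumps({
                    "record": "sample",
                    "chain": s.chain,
                    "step": s.step,
                    "slice_eps": s.slice_eps,
                    "transition": s.hmm.transition.tolist(),
                    "emission": s.hmm.emission.tolist(),
                    "theta0": s.later.theta0,
                    "mu": s.later.mu,
                    "sigma": s.later.sigma,
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "CTFit":
        samples: list[PosteriorSample] = []
        header = None
        with open(path) as f:
            for line in f:
                d = json.loads(line)
                if d["record"] == "header":
                    header = d
                else:
                    samples.append(PosteriorSample(
                        hmm=HMMParams(np.array(d["transition"]),
                                      np.array(d["emission"])),
                        later=LaterParams(d["theta0"], d["mu"], d["sigma"]),
                        slice_eps=d["slice_eps"],
                        chain=d["chain"],
                        step=d["step"],
                    ))
        if header is None:
            raise ValueError(f"{path}: missing header record")
        cfg_d = dict(header["config"])
        for k in ("train_blocks", "test_blocks"):
            cfg_d[k] = tuple(cfg_d[k])
        hyp_d = dict(header["hyper"])
        hyp_d["emission_base"] = tuple(hyp_d["emission_base"])
        for k in ("tau0_prior", "mu_prior", "sigma_prior"):
            hyp_d[k] = tuple(hyp_d[k])
        return cls(samples=samples, config=FitConfig(**cfg_d),
                   hyper=HDPHyper(**hyp_d), model=header["model"],
                   train_obs=np.array(header["train_obs"], dtype=np.int64))


def _config_dict(c: FitConfig) -> dict:
    return {
        "n_chains": c.n_chains, "n_outer_steps": c.n_outer_steps,
        "n_inner_steps": c.n_inner_steps,
        "n_prediction_samples_per_chain": c.n_prediction_samples_per_chain,
        "train_blocks": list(c.train_blocks), "test_blocks": list(c.test_blocks),
        "rt_floor_ms": c.rt_floor_ms, "seed": c.seed,
    }


def _hyper_dict(h: HDPHyper) -> dict:
    return {
        "alpha": h.alpha, "gamma": h.gamma,
        "emission_base": list(h.emission_base), "k_max": h.k_max,
        "alpha0": h.alpha0, "tau0_prior": list(h.tau0_prior),
        "mu_prior": list(h.mu_prior), "sigma_prior": list(h.sigma_prior),
    }


# --------------------------------------------------------------------------
# data preparation


def valid_trial_mask(trials: pd.DataFrame, config: FitConfig) -> np.ndarray:
    """Trials whose RTs enter the likelihood.

    Excludes warm-up trials, incorrect trials, and response times below
    the fast-response floor.  The stimuli of masked trials still feed the
    belief filter.
    """
    required = {"trial_type", "correct", "rt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
    mask = (
        (trials["trial_type"] != "warmup")
        & (trials["correct"].astype(float) == 1)
        & rt.notna()
        & (rt >= config.rt_floor_ms)
    ).to_numpy()
    if not mask.any():
        warnings.warn("no valid trials after exclusions; fits will refuse",
                      stacklevel=2)
    return mask


def _extract_arrays(seq, trials: pd.DataFrame, blocks, config: FitConfig):
    """Contiguous (obs0, valid, rt_s) arrays for the chosen blocks."""
    if trials is None:
        raise ValueError("a trial table is required")
    sel = trials[trials["block"].isin(blocks)].reset_index(drop=True)
    if len(sel) == 0:
        raise ValueError(f"no trials in blocks {sorted(blocks)}")
    if seq is not None:
        st = seq.trials[seq.trials["block"].isin(blocks)]
        if len(st) != len(sel):
            raise ValueError("stimulus sequence and trial table disagree in length")
        obs = st["stimulus"].to_numpy()
    else:
        obs = sel["stimulus"].to_numpy()
    if ((obs < 1) | (obs > 4)).any():
        raise ValueError("stimuli must be in 1..4")
    valid = valid_trial_mask(sel, config)
    rt_s = pd.to_numeric(sel["rt_ms"], errors="coerce").to_numpy() / MS_PER_S
    rt_s = np.where(np.isnan(rt_s), -1.0, rt_s)
    return (obs - 1).astype(np.int64), valid, rt_s


# --------------------------------------------------------------------------
# log densities


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    x = np.clip(x, 1e-300, None)
    return float(((conc - 1.0) * np.log(x)).sum()
                 + lgamma(conc.sum()) - sum(lgamma(a) for a in conc))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -np.inf
    return shape * np.log(rate) - lgamma(shape) + (shape - 1) * np.log(x) - rate * x


def _pi_row_conc(hyper: HDPHyper, eps: float, k: int | None = None) -> np.ndarray:
    k = hyper.k_max if k is None else k
    conc = np.full(k, hyper.alpha0 / k)
    conc[-1] *= max(eps, 1e-3)  # remainder component, down-weighted by the slice
    return conc


def _log_prior(pi, phi, later: np.ndarray, hyper: HDPHyper, eps: float,
               model: str) -> float:
    lp = (_gamma_logpdf(later[0], *hyper.tau0_prior)
          + _gamma_logpdf(later[1], *hyper.mu_prior)
          + _gamma_logpdf(later[2], *hyper.sigma_prior))
    if model == "fixed":
        return lp
    if model == "markov":
        conc = np.full(4, hyper.alpha0 / 4.0)
        for row in pi:
            lp += _dirichlet_logpdf(row, conc)
        return lp
    conc_pi = _pi_row_conc(hyper, eps, pi.shape[0])
    conc_phi = np.array(hyper.emission_base)
    for row in pi:
        lp += _dirichlet_logpdf(row, conc_pi)
    for row in phi:
        lp += _dirichlet_logpdf(row, conc_phi)
    return lp


def log_joint(sample: PosteriorSample, seq, trials: pd.DataFrame,
              hyper: HDPHyper, config: FitConfig) -> float:
    """Log prior + log RT likelihood of one posterior sample.

    The likelihood filters the full supplied sequence (no slice
    truncation) and scores valid-trial RTs with the LATER density at the
    per-trial subjective probability of the realized stimulus.
    """
    obs, valid, rt = _extract_arrays(seq, trials, set(trials["block"]), config)
    later = np.array([sample.later.theta0, sample.later.mu, sample.later.sigma])
    model = "ct" if sample.hmm.emission.shape[0] != 4 or \
        not np.allclose(sample.hmm.emission, np.eye(4)) else "markov"
    lp = _log_prior(sample.hmm.transition, sample.hmm.emission, later, hyper,
                    sample.slice_eps, model)
    if not np.isfinite(lp):
        raise ValueError("non-finite prior term (parameters outside support)")
    init = stationary_distribution(sample.hmm.transition)
    ll = _kernels.filter_rt_loglik(
        sample.hmm.transition, sample.hmm.emission, obs, valid, rt,
        later[0], later[1], later[2], 0.0, init)
    if not np.isfinite(ll):
        raise ValueError("non-finite likelihood term (impossible observation "
                         "or RT outside support)")
    return lp + ll


# --------------------------------------------------------------------------
# the sampler


def _moment_init_later(rt_valid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Moment-matched LATER start: invert the model at a typical surprise."""
    theta0 = max(0.8 * rt_valid.min(), 1e-3)
    r = np.log(4.0) / np.maximum(rt_valid - theta0, 1e-3)
    mu = float(np.clip(r.mean(), 0.5, 100.0))
    sigma = float(np.clip(r.std(), 0.1 * mu, mu))
    jit = rng.uniform(0.9, 1.1, size=3)
    return np.array([theta0 * jit[0], mu * jit[1], sigma * jit[2]])


def _draw_simplex(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    x = rng.dirichlet(conc)
    x = np.clip(x, 1e-10, None)
    return x / x.sum()


def _init_hmm(model: str, chain: int, hyper: HDPHyper,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if model == "markov":
        conc = np.full(4, 1.0)
        pi = np.stack([_draw_simplex(rng, conc) for _ in range(4)])
        return pi, np.eye(4)
    k = hyper.k_max
    pi = np.stack([_draw_simplex(rng, np.full(k, 1.0)) for _ in range(k)])
    if chain == 0:
        # template start: near-identity emissions over the observation alphabet,
        # cycled over states — an informed start for observation-driven structure
        phi = np.full((k, 4), 0.1)
        for i in range(k):
            phi[i, i % 4] = 0.7
        phi /= phi.sum(axis=1, keepdims=True)
    else:
        phi = np.stack([_draw_simplex(rng, np.array(hyper.emission_base))
                        for _ in range(k)])
    return pi, phi


class _Chain:
    """Adaptive Metropolis-within-Gibbs over one chain."""

    PRIOR_JUMP_PROB = 0.1

    def __init__(self, model: str, chain_id: int, obs, valid, rt,
                 hyper: HDPHyper, config: FitConfig,
                 fixed_hmm: HMMParams | None, rng: np.random.Generator):
        self.model = model
        self.chain_id = chain_id
        self.obs, self.valid, self.rt = obs, valid, rt
        self.hyper, self.config = hyper, config
        self.rng = rng
        self.fixed_hmm = fixed_hmm
        self.later = _moment_init_later(rt[valid], rng)
        if model == "fixed":
            assert fixed_hmm is not None
            fixed_hmm = regularize_hmm(fixed_hmm)  # deterministic models
            self.pi = fixed_hmm.transition.copy()
            self.phi = fixed_hmm.emission.copy()
            init = stationary_distribution(self.pi)
            preds = _kernels.filter_predictions(self.pi, self.phi, obs, init)
            self.fixed_ps = preds[np.arange(len(obs)), obs][valid]
        else:
            self.pi, self.phi = _init_hmm(model, chain_id, hyper, rng)
        k = self.pi.shape[0]
        self.kappa_pi = np.full(k, 200.0)
        self.kappa_phi = np.full(k, 200.0)
        self.step_later = np.full(3, 0.15)
        self.accept = {}
        self.eps = 0.1

    # -- target evaluation

    def loglik(self, pi=None, phi=None, later=None) -> float:
        pi = self.pi if pi is None else pi
        phi = self.phi if phi is None else phi
        later = self.later if later is None else later
        if self.model == "fixed":
            return _kernels.later_loglik(self.fixed_ps, self.rt[self.valid],
                                         later[0], later[1], later[2])
        eps = self.eps if self.model == "ct" else 0.0
        init = _kernels.lazy_stationary(pi)
        return _kernels.filter_rt_loglik(pi, phi, self.obs, self.valid, self.rt,
                                         later[0], later[1], later[2], eps, init)

    def _row_conc(self, which: str) -> np.ndarray:
        if which == "pi":
            if self.model == "markov":
                return np.full(4, self.hyper.alpha0 / 4.0)
            return _pi_row_conc(self.hyper, self.eps)
        return np.array(self.hyper.emission_base)

    # -- moves

    def _update_row(self, which: str, i: int, adapt: bool) -> None:
        mat = self.pi if which == "pi" else self.phi
        kappa = self.kappa_pi if which == "pi" else self.kappa_phi
        x = mat[i]
        conc_prior = self._row_conc(which)
        if self.rng.random() < self.PRIOR_JUMP_PROB:
            x_new = _draw_simplex(self.rng, conc_prior)
            log_q = 0.0  # prior proposal cancels against the prior term
            log_prior_diff = 0.0
        else:
            c_fwd = kappa[i] * x + 0.05
            x_new = _draw_simplex(self.rng, c_fwd)
            c_rev = kappa[i] * x_new + 0.05
            log_q = (_dirichlet_logpdf(x, c_rev) - _dirichlet_logpdf(x_new, c_fwd))
            log_prior_diff = (_dirichlet_logpdf(x_new, conc_prior)
                              - _dirichlet_logpdf(x, conc_prior))
        mat_new = mat.copy()
        mat_new[i] = x_new
        ll_new = (self.loglik(pi=mat_new) if which == "pi"
                  else self.loglik(phi=mat_new))
        log_ratio = log_prior_diff + ll_new - self.ll + log_q
        key = (which, i)
        acc = np.log(self.rng.random()) < log_ratio
        if acc:
            mat[i] = x_new
            self.ll = ll_new
        if adapt:
            n_acc, n_tot = self.accept.get(key, (0, 0))
            self.accept[key] = (n_acc + acc, n_tot + 1)
            if n_tot + 1 >= 20:
                rate = self.accept[key][0] / self.accept[key][1]
                kappa[i] *= 0.7 if rate > 0.35 else (1.4 if rate < 0.15 else 1.0)
                kappa[i] = float(np.clip(kappa[i], 5.0, 1e6))
                self.accept[key] = (0, 0)

    def _update_later(self, j: int, adapt: bool) -> None:
        priors = (self.hyper.tau0_prior, self.hyper.mu_prior, self.hyper.sigma_prior)
        z = np.log(self.later[j])
        z_new = z + self.rng.normal(0.0, self.step_later[j])
        later_new = self.later.copy()
        later_new[j] = np.exp(z_new)
        lp_diff = (_gamma_logpdf(later_new[j], *priors[j])
                   - _gamma_logpdf(self.later[j], *priors[j])
                   + (z_new - z))  # Jacobian of the log transform
        ll_new = self.loglik(later=later_new)
        key = ("later", j)
        acc = np.log(self.rng.random()) < lp_diff + ll_new - self.ll
        if acc:
            self.later = later_new
            self.ll = ll_new
        if adapt:
            n_acc, n_tot = self.accept.get(key, (0, 0))
            self.accept[key] = (n_acc + acc, n_tot + 1)
            if n_tot + 1 >= 20:
                rate = self.accept[key][0] / self.accept[key][1]
                self.step_later[j] *= 1.4 if rate > 0.35 else (0.7 if rate < 0.15 else 1.0)
                self.step_later[j] = float(np.clip(self.step_later[j], 1e-3, 2.0))
                self.accept[key] = (0, 0)

    # -- main loop

    def run(self) -> list[PosteriorSample]:
        for attempt in range(20):
            self.ll = self.loglik()
            if np.isfinite(self.ll):
                break
            logger.warning("chain %d: non-finite start (attempt %d); restarting",
                           self.chain_id, attempt)
            if self.model != "fixed":
                self.pi, self.phi = _init_hmm(self.model, self.chain_id + 1,
                                              self.hyper, self.rng)
            self.later = _moment_init_later(self.rt[self.valid], self.rng)
        else:
            raise RuntimeError(f"chain {self.chain_id}: could not find a finite start")

        out: list[PosteriorSample] = []
        n_outer = self.config.n_outer_steps
        k = self.pi.shape[0]
        for step in range(n_outer):
            adapt = step < n_outer // 2
            if self.model == "ct":
                self.eps = float(self.rng.uniform(0.02, 0.2))
                self.ll = self.loglik()  # slice support changed
            for _ in range(self.config.n_inner_steps):
                if self.model != "fixed":
                    for i in range(k):
                        self._update_row("pi", i, adapt)
                    if self.model == "ct":
                        for i in range(k):
                            self._update_row("phi", i, adapt)
                for j in range(3):
                    self._update_later(j, adapt)
            if step >= n_outer // 2:
                out.append(PosteriorSample(
                    hmm=HMMParams(self.pi.copy(), self.phi.copy()),
                    later=LaterParams(*self.later),
                    slice_eps=self.eps if self.model == "ct" else 0.02,
                    chain=self.chain_id, step=step,
                ))
        logger.info("chain %d done: loglik %.1f", self.chain_id, self.ll)
        return out


def _fit(model: str, seq, trials, hyper: HDPHyper, config: FitConfig,
         fixed_hmm: HMMParams | None = None) -> CTFit:
    obs, valid, rt = _extract_arrays(seq, trials, set(config.train_blocks), config)
    if not valid.any():
        raise ValueError("no valid trials in the training blocks")
    samples: list[PosteriorSample] = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        chain = _Chain(model, c, obs, valid, rt, hyper, config, fixed_hmm, rng)
        samples.extend(chain.run())
    return CTFit(samples=samples, config=config, hyper=hyper, model=model,
                 train_obs=obs.copy())


def fit_ct(seq, trials, hyper: HDPHyper | None = None,
           config: FitConfig | None = None) -> CTFit:
    """Joint posterior over the truncated-HDP internal model and LATER
    parameters given training-block stimuli and RTs."""
    return _fit("ct", seq, trials, hyper or HDPHyper(), config or FitConfig())


def fit_markov(seq, trials, hyper: HDPHyper | None = None,
               config: FitConfig | None = None) -> CTFit:
    """Posterior over the 4-state observation-level Markov internal model
    (identity emissions) and LATER parameters."""
    return _fit("markov", seq, trials, hyper or HDPHyper(), config or FitConfig())


def fit_fixed_model(hmm: HMMParams, seq, trials, hyper: HDPHyper | None = None,
                    config: FitConfig | None = None) -> CTFit:
    """Posterior over LATER parameters only, with the internal model frozen
    (used to calibrate the ideal observer or any user-supplied model)."""
    return _fit("fixed", seq, trials, hyper or HDPHyper(), config or FitConfig(),
                fixed_hmm=hmm)


# --------------------------------------------------------------------------
# prediction and diagnostics


def predict_rts(fit: CTFit, seq: StimulusSequence | np.ndarray,
                config: FitConfig | None = None,
                return_probs: bool = False):
    """Across-sample mean per-trial RT prediction on a stimulus sequence.

    Each retained sample filters the full sequence (predictions never see
    the measured RTs) and maps its per-trial subjective probability of the
    realized stimulus through the plug-in LATER prediction; predictions
    are then averaged over samples.  Seconds.
    """
    if len(fit) == 0:
        raise ValueError("empty fit")
    obs = (seq.stimuli if isinstance(seq, StimulusSequence) else np.asarray(seq))
    obs0 = (obs - 1).astype(np.int64)
    samples = fit.prediction_samples()
    rts = np.zeros(len(obs0))
    probs = np.zeros(len(obs0))
    for s in samples:
        init = stationary_distribution(s.hmm.transition)
        preds = _kernels.filter_predictions(s.hmm.transition, s.hmm.emission,
                                            obs0, init)
        p_n = preds[np.arange(len(obs0)), obs0]
        rts += map_rt(p_n, s.later)
        probs += p_n
    rts /= len(samples)
    probs /= len(samples)
    return (rts, probs) if return_probs else rts


def diagnostics(fit: CTFit, occupancy_threshold: float = 0.02) -> dict:
    """Cross-chain agreement of LATER estimates and state-occupancy counts.

    Per chain: posterior means and central 90% intervals of (theta0, mu,
    sigma); the summary flags parameters whose cross-chain mean spread
    exceeds the pooled posterior sd.  Occupied-state counts come from the
    mean filtered belief of each prediction sample on the training
    stimuli.
    """
    chains = fit.chains()
    if len(chains) < 2:
        raise ValueError("diagnostics needs at least 2 chains")
    names = ["theta0", "mu", "sigma"]
    per_chain = {}
    arrs = {}
    for c in chains:
        a = np.array([[s.later.theta0, s.later.mu, s.later.sigma]
                      for s in fit.samples if s.chain == c])
        arrs[c] = a
        per_chain[c] = {
            n: {"mean": float(a[:, j].mean()),
                "ci90": [float(np.quantile(a[:, j], 0.05)),
                         float(np.quantile(a[:, j], 0.95))]}
            for j, n in enumerate(names)
        }
    pooled = np.concatenate(list(arrs.values()))
    spread = {}
    agree = {}
    for j, n in enumerate(names):
        means = np.array([arrs[c][:, j].mean() for c in chains])
        sd = pooled[:, j].std()
        spread[n] = float(means.max() - means.min())
        agree[n] = bool(sd == 0 or spread[n] < sd)
    occ_counts = []
    if fit.model != "fixed" and fit.train_obs.size:
        for s in fit.prediction_samples():
            init = stationary_distribution(s.hmm.transition)
            occ = _kernels.filter_occupancy(s.hmm.transition, s.hmm.emission,
                                            fit.train_obs, init)
            occ_counts.append(int((occ > occupancy_threshold).sum()))
    hist: dict[int, int] = {}
    for c in occ_counts:
        hist[c] = hist.get(c, 0) + 1
    return {"later": per_chain, "cross_chain_spread": spread,
            "cross_chain_agreement": agree,
            "occupied_states": hist}
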