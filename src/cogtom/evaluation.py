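"""Model-comparison metrics and secondary analyses.

Covers the R^2 conventions used for cross-validated RT prediction, mean
Kullback-Leibler divergence between predictive distributions, error-trial
rank and ROC analyses over subjective probabilities, the higher-order
learning score that separates latent-state knowledge from two-back
statistics, and the normalized-CT / linear-decomposition analyses that
split an internal model into Markov-like and ideal-observer-like
contributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .asrt import StimulusSequence

KL_EPS = 1e-6


def r2_score(predicted, observed, variant: str = "corr2") -> float:
    """Explained-variance measure between predictions and observations.

    ``corr2`` (default) is the squared Pearson correlation — invariant to
    affine transforms of the predictions, matching the convention that the
    observed values are a linear function of the prediction plus
    homoscedastic noise.  ``ssr`` is 1 - SSE/SST, which penalizes scale
    and offset errors and can be negative.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or len(predicted) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if not (np.isfinite(predicted).all() and np.isfinite(observed).all()):
        raise ValueError("inputs must be finite")
    if predicted.std() == 0 or observed.std() == 0:
        raise ValueError("zero variance input; R^2 undefined")
    if variant == "corr2":
        return float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    if variant == "ssr":
        sse = ((observed - predicted) ** 2).sum()
        sst = ((observed - observed.mean()) ** 2).sum()
        return float(1.0 - sse / sst)
    raise ValueError(f"unknown variant {variant!r}")


def kl_mean(true_probs, model_probs, eps: float = KL_EPS) -> float:
    """Mean per-trial KL divergence of the true from the model predictive.

    Per trial: sum_i p_i (-log phat_i + log p_i), with 0 log 0 = 0 on the
    true side and the model side floored at ``eps`` (then renormalized).
    The task's ground-truth convention is probability 1 on the pattern
    element for pattern trials and 0.25 everywhere for random trials.
    """
    p = np.atleast_2d(np.asarray(true_probs, dtype=float))
    q = np.atleast_2d(np.asarray(model_probs, dtype=float))
    if p.shape != q.shape or p.shape[1] != 4:
        raise ValueError("expect aligned (T, 4) arrays")
    for name, m in (("true_probs", p), ("model_probs", q)):
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-6 or (m < 0).any():
            raise ValueError(f"{name} rows must be normalized probabilities")
    q = np.clip(q, eps, None)
    q = q / q.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return float(terms.sum(axis=1).mean())


def _fractional_top_rank(preds: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Fraction of 'ranked first' credit per trial, splitting ties k-ways."""
    chosen = preds[np.arange(len(preds)), idx]
    is_max = np.abs(preds - preds.max(axis=1, keepdims=True)) < 1e-12
    top = np.abs(chosen - preds.max(axis=1)) < 1e-12
    return np.where(top, 1.0 / is_max.sum(axis=1), 0.0)


def error_rank_analysis(predictions: np.ndarray,
                        trials: pd.DataFrame) -> dict[str, float]:
    """Fraction of trials where the stimulus / the pressed key ranks first
    among the four subjective probabilities, split by correctness.

    Ties are split fractionally (a k-way tie at the top contributes 1/k),
    so chance level is exactly 0.25.
    """
    for col in ("stimulus", "response", "correct"):
        if col not in trials.columns or trials[col].isna().any():
            raise ValueError(f"trials need a complete {col!r} column")
    preds = np.asarray(predictions, dtype=float)
    if len(preds) != len(trials):
        raise ValueError("predictions and trials must align")
    stim0 = trials["stimulus"].to_numpy().astype(int) - 1
    resp0 = trials["response"].to_numpy().astype(int) - 1
    correct = trials["correct"].to_numpy().astype(bool)
    out = {}
    for what, idx in (("stimulus", stim0), ("choice", resp0)):
        credit = _fractional_top_rank(preds, idx)
        for label, mask in (("correct", correct), ("incorrect", ~correct)):
            out[f"{what}_{label}"] = (
                float(credit[mask].mean()) if mask.any() else np.nan)
    return out


def error_roc(predictions: np.ndarray,
              trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC for predicting correct trials from the subjective probability of
    the realized stimulus; returns (fpr, tpr, auc)."""
    preds = np.asarray(predictions, dtype=float)
    correct = trials["correct"].to_numpy().astype(int)
    if correct.min() == correct.max():
        raise ValueError("need both correct and incorrect trials for a ROC")
    scores = preds[np.arange(len(preds)),
                   trials["stimulus"].to_numpy().astype(int) - 1]
    fpr, tpr, _ = roc_curve(correct, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def higher_order_score(
    seq: StimulusSequence,
    triplet_labels: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray | None = None,
) -> float:
    """RT difference the two-back statistics cannot explain.

    Restricted to trials whose observed triplet (two-back, one-back,
    current) is a *high* triplet, compares the mean of ``values``
    (measured or model-predicted RTs) between trials whose third element
    is a random trial and those where it is a pattern trial, matched on
    the full observed triplet identity: score = mean(random) -
    mean(pattern), averaged over matched triplet identities.  Positive
    means pattern trials are faster than random trials carrying identical
    observations — knowledge beyond triplet statistics.  Triplets whose
    window straddles a block boundary are excluded, as are trials flagged
    invalid.
    """
    t = seq.trials
    stim = t["stimulus"].to_numpy()
    idx = t["index_in_block"].to_numpy()
    ttype = t["trial_type"].to_numpy()
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(t), dtype=bool)
    use = (np.asarray(triplet_labels) == "high") & (idx > 2) & valid \
        & np.isin(ttype, ["pattern", "random"])
    groups: dict[tuple, dict[str, list[float]]] = {}
    for i in np.flatnonzero(use):
        key = (stim[i - 2], stim[i - 1], stim[i])
        groups.setdefault(key, {"pattern": [], "random": []})[ttype[i]].append(
            values[i])
    diffs = [np.mean(g["random"]) - np.mean(g["pattern"])
             for g in groups.values() if g["pattern"] and g["random"]]
    if not diffs:
        empty = ("pattern" if not any(g["pattern"] for g in groups.values())
                 else "random")
        raise ValueError(f"no matched triplets: the {empty}-third condition "
                         "is empty")
    return float(np.mean(diffs))


def normalized_ct(ct_r2: float, markov_r2: float) -> float:
    """Margin by which the inferred internal model outperforms the Markov
    inductive bias: ct_r2 - markov_r2."""
    return float(ct_r2) - float(markov_r2)


def decompose_ct(ct_pred, markov_pred, ideal_pred) -> tuple[np.ndarray, float, float]:
    """Linear decomposition of per-trial CT predictions into Markov and
    ideal-observer contributions.

    Ordinary least squares of ``ct_pred`` on (markov_pred, ideal_pred, 1);
    returns (weights, offset, fit R^2).  A high R^2 means the inferred
    model is a blend of the two reference strategies on this sequence.
    """
    ct = np.asarray(ct_pred, dtype=float)
    mk = np.asarray(markov_pred, dtype=float)
    io = np.asarray(ideal_pred, dtype=float)
    if not (len(ct) == len(mk) == len(io)) or len(ct) < 4:
        raise ValueError("need aligned vectors of length >= 4")
    x = np.column_stack([mk, io, np.ones(len(ct))])
    cond = np.linalg.cond(x)
    if cond > 1e8:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")
    coef, _, _, _ = np.linalg.lstsq(x, ct, rcond=None)
    fitted = x @ coef
    sst = ((ct - ct.mean()) ** 2).sum()
    r2 = float(1.0 - ((ct - fitted) ** 2).sum() / sst) if sst > 0 else 1.0
    return coef[:2], float(coef[2]), r2
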