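"""ASRT stimulus sequences.

In the Alternating Serial Reaction Time task a deterministic 4-element
pattern alternates trial-by-trial with uniformly random stimuli over the
four possible locations.  Each block opens with a handful of random warm-up
trials, after which the 8-element alternating unit (pattern, random,
pattern, random, ...) repeats; the pattern re-enters every block at the
same phase.  This module generates and annotates such sequences and houses
the analytic triplet ("trigram") probabilities that make the task's
two-back statistics explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = (1, 2, 3, 4)

#: column order of a stimulus/trial table
TRIAL_COLUMNS = ["block", "index_in_block", "stimulus", "trial_type", "pattern_phase"]


@dataclass(frozen=True)
class PatternSequence:
    """The deterministic 4-element pattern, e.g. (2, 4, 3, 1) for '2r4r3r1r'."""

    elements: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.elements) != 4 or sorted(self.elements) != [1, 2, 3, 4]:
            raise ValueError(
                f"pattern must be a permutation of {ALPHABET}, got {self.elements}"
            )

    def rotations(self) -> set[tuple[int, ...]]:
        e = self.elements
        return {e[i:] + e[:i] for i in range(4)}

    def canonical(self) -> "PatternSequence":
        """Representative of this pattern's cyclic-rotation class."""
        return PatternSequence(min(self.rotations()))

    def same_rotation_class(self, other: "PatternSequence") -> bool:
        return other.elements in self.rotations()

    def successor(self, stimulus: int) -> int:
        """Pattern element that follows ``stimulus`` in the cycle."""
        i = self.elements.index(stimulus)
        return self.elements[(i + 1) % 4]


@dataclass
class StimulusSequence:
    """Ordered ASRT trials plus the pattern(s) that generated them.

    ``trials`` is a DataFrame with columns ``block`` (1-based),
    ``index_in_block`` (1-based), ``stimulus`` (1..4), ``trial_type``
    (warmup/pattern/random) and ``pattern_phase`` (0..3, -1 where absent).
    """

    trials: pd.DataFrame
    pattern: PatternSequence
    n_blocks: int
    block_patterns: list[PatternSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.block_patterns:
            self.block_patterns = [self.pattern] * self.n_blocks

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimuli(self) -> np.ndarray:
        return self.trials["stimulus"].to_numpy()

    @property
    def block_length(self) -> int:
        return int((self.trials["block"] == 1).sum())


def canonical_patterns() -> set[PatternSequence]:
    """One representative per cyclic-rotation class of 4-element patterns.

    Two patterns that are rotations of one another generate identical
    stimulus statistics (the task can start the cycle anywhere), so the six
    classes — not the 24 raw permutations — are the distinct ASRT designs.
    """
    return {PatternSequence(p).canonical() for p in itertools.permutations(ALPHABET)}


def generate_session(
    pattern: PatternSequence,
    n_blocks: int = 25,
    block_warmup: int = 5,
    pattern_repeats: int = 10,
    seed: int | np.random.Generator | None = None,
) -> StimulusSequence:
    """Generate one ASRT session.

    Each block holds ``block_warmup`` i.i.d. uniform random trials followed
    by ``pattern_repeats`` repetitions of the 8-element alternating unit
    (pattern trial, random trial, ...), giving the standard 85-trial block
    at the defaults.  Random trials may repeat any stimulus, including the
    one about to appear as a pattern element.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    frames = [
        _generate_block(pattern, b, block_warmup, pattern_repeats, rng)
        for b in range(1, n_blocks + 1)
    ]
    trials = pd.concat(frames, ignore_index=True)
    return StimulusSequence(trials=trials, pattern=pattern, n_blocks=n_blocks)


def _generate_block(
    pattern: PatternSequence,
    block: int,
    block_warmup: int,
    pattern_repeats: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = block_warmup + 8 * pattern_repeats
    stimulus = np.empty(n, dtype=np.int64)
    trial_type = np.empty(n, dtype=object)
    phase = np.full(n, -1, dtype=np.int64)

    stimulus[:block_warmup] = rng.integers(1, 5, size=block_warmup)
    trial_type[:block_warmup] = "warmup"

    for r in range(pattern_repeats):
        for k in range(4):
            i = block_warmup + 8 * r + 2 * k
            stimulus[i] = pattern.elements[k]
            trial_type[i] = "pattern"
            phase[i] = k
            stimulus[i + 1] = rng.integers(1, 5)
            trial_type[i + 1] = "random"

    return pd.DataFrame(
        {
            "block": block,
            "index_in_block": np.arange(1, n + 1),
            "stimulus": stimulus,
            "trial_type": trial_type,
            "pattern_phase": phase,
        }
    )


def label_triplets(seq: StimulusSequence) -> np.ndarray:
    """Per-trial high/low/undefined triplet labels.

    A trial is *high* when its stimulus equals the pattern-successor of the
    stimulus two trials back (the continuation the two-back statistics
    favour), *low* otherwise.  The first two trials of each block are
    *undefined* — the two-back context is missing.  Interference designs
    use each block's own pattern for the successor map.
    """
    t = seq.trials
    labels = np.full(len(t), "low", dtype=object)
    stim = t["stimulus"].to_numpy()
    idx = t["index_in_block"].to_numpy()
    block = t["block"].to_numpy()
    labels[idx <= 2] = "undefined"
    for i in np.flatnonzero(idx > 2):
        pat = seq.block_patterns[block[i] - 1]
        if stim[i] == pat.successor(stim[i - 2]):
            labels[i] = "high"
    return labels


def generate_interference_design(
    pattern_a: PatternSequence,
    pattern_b: PatternSequence,
    blocks_per_switch: int = 5,
    n_blocks: int = 20,
    seed: int | np.random.Generator | None = None,
    block_warmup: int = 5,
    pattern_repeats: int = 10,
) -> StimulusSequence:
    """Session alternating between two patterns every ``blocks_per_switch``
    blocks (the design used when original and interfering sequences are
    tested within one session)."""
    if pattern_a.same_rotation_class(pattern_b):
        raise ValueError("pattern_a and pattern_b are in the same rotation class")
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    block_patterns: list[PatternSequence] = []
    for b in range(1, n_blocks + 1):
        segment = (b - 1) // blocks_per_switch
        pat = pattern_a if segment % 2 == 0 else pattern_b
        block_patterns.append(pat)
        frames.append(_generate_block(pat, b, block_warmup, pattern_repeats, rng))
    trials = pd.concat(frames, ignore_index=True)
    return StimulusSequence(
        trials=trials,
        pattern=pattern_a,
        n_blocks=n_blocks,
        block_patterns=block_patterns,
    )


def analytic_trigram_probabilities() -> tuple[float, float]:
    """Analytic two-back continuation probabilities, by parity marginalization.

    Marginalizes the ASRT generative process over whether the current trial
    is a pattern or a random element (each with probability 1/2): a pattern
    trial continues the two-back stimulus with its pattern-successor with
    probability 1, a random trial with probability 1/4.  Returns
    ``(p_high, p_low)`` where ``p_low`` is the probability of one specific
    non-successor stimulus.
    """
    parities = {"pattern": 0.5, "random": 0.5}
    p_high = 0.0
    p_low = 0.0
    for parity, w in parities.items():
        if parity == "pattern":
            cond = np.array([1.0, 0.0, 0.0, 0.0])  # successor first, by convention
        else:
            cond = np.full(4, 1.0 / len(ALPHABET))
        p_high += w * cond[0]
        p_low += w * cond[1]
    return float(p_high), float(p_low)
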