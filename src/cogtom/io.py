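"""Trial-table formats and provenance headers.

Trial tables are tab-separated with the header columns
participant_id, session, block, trial, stimulus, trial_type,
pattern_phase, response, correct, rt_ms.  Design-only files (stimuli
without behaviour) leave response/correct/rt_ms empty.  Every file this
package writes opens with '#'-prefixed provenance lines recording the
seed, the package version, and a hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .asrt import PatternSequence, StimulusSequence

FILE_COLUMNS = ["participant_id", "session", "block", "trial", "stimulus",
                "trial_type", "pattern_phase", "response", "correct", "rt_ms"]

_TRIAL_TYPES = {"warmup", "pattern", "random"}


def _pkg_version() -> str:
    try:
        return version("cogtom")
    except PackageNotFoundError:
        return "unknown"


def provenance_header(seed=None, config: dict | None = None) -> dict:
    h = hashlib.sha256(json.dumps(config or {}, sort_keys=True).encode())
    return {"cogtom_version": _pkg_version(), "seed": seed,
            "config_hash": h.hexdigest()[:12]}


def _header_lines(seed=None, config: dict | None = None) -> str:
    prov = provenance_header(seed, config)
    return "".join(f"# {k}={v}\n" for k, v in prov.items())


def write_trials(path, trials: pd.DataFrame, seed=None,
                 config: dict | None = None) -> None:
    """Write a trial table (TSV with provenance header lines)."""
    t = trials.copy()
    if "trial" not in t.columns and "index_in_block" in t.columns:
        t = t.rename(columns={"index_in_block": "trial"})
    for col in FILE_COLUMNS:
        if col not in t.columns:
            t[col] = ""
    with open(path, "w") as f:
        f.write(_header_lines(seed, config))
        t[FILE_COLUMNS].to_csv(f, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table.

    Checks the stimulus alphabet, block monotonicity, and RT positivity;
    raises with the first offending rows listed.  Behavioural columns may
    be empty (design-only files).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FILE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.rename(columns={"trial": "index_in_block"})
    problems = []
    bad_stim = ~df["stimulus"].isin([1, 2, 3, 4])
    if bad_stim.any():
        problems += [f"line {i + 2}: stimulus {df['stimulus'][i]} not in 1..4"
                     for i in df.index[bad_stim][:5]]
    bad_type = ~df["trial_type"].isin(_TRIAL_TYPES)
    if bad_type.any():
        problems += [f"line {i + 2}: trial_type {df['trial_type'][i]!r}"
                     for i in df.index[bad_type][:5]]
    blocks = df["block"].to_numpy()
    if (np.diff(blocks) < 0).any():
        i = int(np.flatnonzero(np.diff(blocks) < 0)[0])
        problems.append(f"line {i + 3}: block numbers decrease")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = rt.notna() & (rt <= 0)
    if bad_rt.any():
        problems += [f"line {i + 2}: rt_ms {rt[i]} not positive"
                     for i in df.index[bad_rt][:5]]
    if problems:
        raise ValueError(f"{path}: schema violations:\n  " + "\n  ".join(problems[:5]))
    df["rt_ms"] = rt
    df["correct"] = pd.to_numeric(df["correct"], errors="coerce")
    return df


def sequence_from_trials(df: pd.DataFrame,
                         pattern: PatternSequence) -> StimulusSequence:
    """Rebuild a StimulusSequence from a (read) trial table."""
    cols = ["block", "index_in_block", "stimulus", "trial_type", "pattern_phase"]
    t = df[cols].copy()
    t["pattern_phase"] = pd.to_numeric(t["pattern_phase"],
                                       errors="coerce").fillna(-1).astype(int)
    return StimulusSequence(trials=t.reset_index(drop=True), pattern=pattern,
                            n_blocks=int(df["block"].max()))


def write_predictions(path, df: pd.DataFrame, seed=None,
                      config: dict | None = None) -> None:
    with open(path, "w") as f:
        f.write(_header_lines(seed, config))
        df.to_csv(f, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def parse_pattern(text: str) -> PatternSequence:
    """Parse '2,4,3,1' into a PatternSequence."""
    return PatternSequence(tuple(int(x) for x in text.split(",")))


def parse_blocks(text: str) -> tuple[int, ...]:
    """Parse '11:20' or '1,2,3' into a block tuple."""
    if ":" in text:
        lo, hi = text.split(":")
        return tuple(range(int(lo), int(hi) + 1))
    return tuple(int(x) for x in text.split(","))
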