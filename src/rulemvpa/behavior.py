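"""Behavioral scoring with the subjective-accuracy rule.

Because no trial-wise feedback is given, a participant who mis-remembers an
instructed rule may consistently apply a self-generated (wrong) rule. The
subjective accuracy of a response is therefore defined relative to the
response *executed* at the previous occurrence of the same stimulus within
the same block; only the first occurrence is scored against the instructed
response. The conventional objective flag (executed == instructed) is kept
alongside. Omissions count as errors under both definitions and the
subjective reference skips over them (falling back to the last non-omitted
execution, else the instructed response).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["score_accuracy", "summarize_performance"]

_GROUP_KEYS = ("subject", "block", "stimulus_id")


def score_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``correct_subjective`` and ``correct_objective`` per-trial flags.

    The table needs columns block, stimulus_id, repetition,
    instructed_response, executed_response (NA = omission); a subject column
    is honored if present. Repetitions of a stimulus within a block must form
    1..n without gaps.
    """
    df = table.copy().reset_index(drop=True)
    keys = [k for k in _GROUP_KEYS if k in df.columns]
    if "stimulus_id" not in keys:
        raise ValueError("table must contain a stimulus_id column")
    subj = np.zeros(len(df), dtype=bool)
    obj = np.zeros(len(df), dtype=bool)
    for _, g in df.groupby(keys, sort=False):
        g = g.sort_values("repetition")
        reps = g["repetition"].to_numpy(int)
        if not np.array_equal(reps, np.arange(1, len(reps) + 1)):
            raise ValueError(
                f"repetitions must form 1..n without gaps (got {reps.tolist()})"
            )
        reference = int(g["instructed_response"].iloc[0])
        for idx, row in g.iterrows():
            executed = row["executed_response"]
            omitted = pd.isna(executed)
            obj[idx] = (not omitted) and int(executed) == int(row["instructed_response"])
            subj[idx] = (not omitted) and int(executed) == reference
            if not omitted:
                reference = int(executed)  # next occurrence scored against this
    df["correct_subjective"] = subj
    df["correct_objective"] = obj
    return df


def summarize_performance(
    scored: pd.DataFrame, accuracy: str = "subjective"
) -> pd.DataFrame:
    """Cell means per subject x condition x repetition.

    Accuracy is the proportion of correct trials (per the chosen rule); RT is
    averaged over correct trials only and is missing for cells without any.
    Feeds directly into the repeated-measures ANOVA with factors
    repetition x condition.
    """
    flag = f"correct_{accuracy}"
    if flag not in scored.columns:
        raise ValueError("run score_accuracy first")
    df = scored.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    rows = []
    for (sub, cond, rep), g in df.groupby(["subject", "condition", "repetition"], sort=True):
        correct = g[flag].to_numpy(bool)
        rts = g.loc[g[flag], "rt_ms"].dropna()
        rows.append(
            {
                "subject": sub,
                "condition": cond,
                "repetition": int(rep),
                "accuracy": float(correct.mean()),
                "rt_ms": float(rts.mean()) if len(rts) else np.nan,
                "n_trials": len(g),
            }
        )
    return pd.DataFrame(rows)
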