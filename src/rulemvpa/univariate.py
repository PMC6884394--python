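"""Condition-mean activation per ROI across stimulus repetitions.

Complements the pattern-similarity analysis: cell estimates are the mean
single-trial beta over correct trials, averaged over ROI voxels, per
subject x condition x repetition x ROI. Mean activity typically declines
steeply over early repetitions even while the identity-specific pattern
code stays stable -- the two measures are deliberately dissociable in the
generative model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["mean_activity"]


def mean_activity(
    beta_set,
    roi_rows: dict,
    correct_flags=None,
) -> pd.DataFrame:
    """Mean beta per (condition, repetition, roi) over correct trials.

    ``roi_rows`` maps ROI name -> voxel row indices. Cells without any
    correct trial are reported with NaN. Error trials are excluded whenever
    ``correct_flags`` is provided.
    """
    meta = beta_set.trial_meta.reset_index(drop=True)
    keep = np.ones(len(meta), dtype=bool)
    if correct_flags is not None:
        keep = np.asarray(correct_flags, dtype=bool)
    rows = []
    conditions = sorted(meta["condition"].unique())
    repetitions = sorted(meta["repetition"].dropna().unique().astype(int))
    for roi, voxels in roi_rows.items():
        voxels = np.asarray(voxels)
        if voxels.size == 0:
            raise ValueError(f"empty ROI {roi!r}")
        roi_means = beta_set.betas[:, voxels].mean(axis=1)
        for cond in conditions:
            for rep in repetitions:
                sel = (
                    (meta["condition"].to_numpy() == cond)
                    & (meta["repetition"].to_numpy(int) == rep)
                    & keep
                )
                rows.append(
                    {
                        "condition": cond,
                        "repetition": rep,
                        "roi": roi,
                        "mean_beta": float(roi_means[sel].mean()) if sel.any() else np.nan,
                        "n_trials": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows)
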