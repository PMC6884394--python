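"""Beta-series functional connectivity between a seed region and targets.

The beta series of a region is the sequence of its single-trial beta
estimates (mean over seed voxels, or per voxel for maps). Connectivity within
a trial window is the Pearson correlation of two beta series over the
selected trials, Fisher z-transformed. The learning-related contrast compares
the connectivity change from early implementation trials (stimulus
repetitions 1 and 2) to late trials (repetitions 7 and 8) between the
intentional-learning and control conditions:

    (z_late - z_early)_learning - (z_late - z_early)_control

Error trials are excluded throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "beta_series_r",
    "seed_series",
    "connectivity_change",
    "connectivity_change_maps",
]

EARLY_REPETITIONS = (1, 2)
LATE_REPETITIONS = (7, 8)


def beta_series_r(seed_series, target_series, trial_subset=None) -> float:
    """Fisher-z-transformed Pearson correlation of two beta series.

    ``trial_subset`` optionally selects trials (boolean or index array).
    Raises on degenerate input: fewer than 4 trials, zero variance, or
    |r| = 1 (infinite z).
    """
    s = np.asarray(seed_series, dtype=float)
    t = np.asarray(target_series, dtype=float)
    if trial_subset is not None:
        s, t = s[trial_subset], t[trial_subset]
    if s.shape != t.shape:
        raise ValueError("series must be aligned")
    if s.size < 4:
        raise ValueError("need at least 4 trials for a beta-series correlation")
    if np.ptp(s) == 0 or np.ptp(t) == 0:
        raise ValueError("zero variance in a beta series")
    r = float(np.corrcoef(s, t)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("perfectly (anti)correlated series: Fisher z is infinite")
    return float(np.arctanh(r))


def seed_series(beta_set, roi_rows) -> np.ndarray:
    """Unweighted mean beta over seed voxels, one value per trial."""
    rows = np.asarray(roi_rows)
    if rows.size == 0:
        raise ValueError("empty seed region")
    return beta_set.betas[:, rows].mean(axis=1)


def _window_mask(meta: pd.DataFrame, condition: str, repetitions) -> np.ndarray:
    return (
        (meta["condition"].to_numpy() == condition)
        & np.isin(meta["repetition"].to_numpy(int), repetitions)
    )


def connectivity_change(
    seed: np.ndarray,
    target: np.ndarray,
    trial_meta: pd.DataFrame,
    correct_flags=None,
    learning_condition: str = "learning",
    control_condition: str = "control",
    early=EARLY_REPETITIONS,
    late=LATE_REPETITIONS,
    per_block: bool = False,
) -> float:
    """Per-subject late-minus-early connectivity contrast, learning vs control.

    Trials are pooled across blocks within each condition x window before
    correlating (``per_block=True`` instead correlates within blocks and
    averages the z values). Windows in which every trial is an error raise a
    ValueError so the caller can flag the subject as missing.
    """
    meta = trial_meta.reset_index(drop=True)
    if int(meta["repetition"].max()) < max(late):
        raise ValueError("design lacks the late repetition window (needs 8 repetitions)")
    keep = np.ones(len(meta), dtype=bool)
    if correct_flags is not None:
        keep = np.asarray(correct_flags, dtype=bool)  # error trials excluded

    def window_z(condition, reps):
        sel = _window_mask(meta, condition, reps) & keep
        if not sel.any():
            raise ValueError(f"no usable trials in ({condition}, {reps})")
        if per_block:
            zs = []
            for _, g in meta[sel].groupby("block"):
                zs.append(beta_series_r(seed[g.index], target[g.index]))
            return float(np.mean(zs))
        return beta_series_r(seed[sel], target[sel])

    z = {
        (c, w): window_z(cond, reps)
        for c, cond in (("learning", learning_condition), ("control", control_condition))
        for w, reps in (("early", early), ("late", late))
    }
    return (z[("learning", "late")] - z[("learning", "early")]) - (
        z[("control", "late")] - z[("control", "early")]
    )


def connectivity_change_maps(
    seed: np.ndarray,
    target_betas: np.ndarray,
    trial_meta: pd.DataFrame,
    target_rows=None,
    **kwargs,
) -> np.ndarray:
    """Per-voxel connectivity-change contrast within a target mask."""
    rows = np.arange(target_betas.shape[1]) if target_rows is None else np.asarray(target_rows)
    out = np.full(rows.size, np.nan)
    for i, row in enumerate(rows):
        try:
            out[i] = connectivity_change(seed, target_betas[:, row], trial_meta, **kwargs)
        except ValueError:
            pass
    return out
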