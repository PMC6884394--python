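"""Stage-resolved identity-specific pattern similarity.

The core statistic compares multivoxel pattern correlations between trial
pairs that repeat the *same* stimulus against pairs showing *different*
stimuli, within one task block and one implementation stage (a pair of
consecutive repetitions of every stimulus, so each stimulus contributes
exactly two trials per stage). With 4 stimuli x 2 occurrences this is the
mean of 4 same-stimulus correlations minus the mean of 24 different-stimulus
correlations; a positive difference ("delta") indicates rule-identity-specific
coding. Block-wise deltas can additionally be adjusted for sequence-induced
bias by regressing them on the deltas measured in a white-matter control
volume and keeping the intercept (the ROI effect expected at zero measured
bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SimilarityResult",
    "stage_similarity",
    "blockwise_similarity",
    "wm_bias_adjust",
    "subject_similarity",
    "aggregate_stages_early_late",
    "sphere_offsets",
    "searchlight_similarity",
]


@dataclass
class SimilarityResult:
    """Same-vs-different pattern correlation summary for one block-stage."""

    mean_same_r: float
    mean_diff_r: float
    delta: float
    n_same_pairs: int
    n_diff_pairs: int
    block_index: int | None = None
    condition: str | None = None
    stage: int | None = None


def stage_similarity(trial_betas, stimulus_labels, fisher_z: bool = False) -> SimilarityResult:
    """Identity-specific pattern similarity for one block-stage.

    Parameters
    ----------
    trial_betas : (n_trials, n_voxels) single-trial beta patterns.
    stimulus_labels : per-trial stimulus ids; every label must occur exactly
        twice (two consecutive occurrences per stimulus define a stage).
    fisher_z : apply atanh to the pairwise correlations before averaging
        (off by default; the statistic is defined on plain correlations).
    """
    betas = np.asarray(trial_betas, dtype=float)
    labels = np.asarray(stimulus_labels)
    if betas.ndim != 2:
        raise ValueError("trial_betas must be 2-D (trials x voxels)")
    if betas.shape[0] != labels.shape[0]:
        raise ValueError("labels must align with beta rows")
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts != 2):
        bad = uniq[counts != 2]
        raise ValueError(f"each stimulus must occur exactly twice in a stage; offending: {bad}")
    if betas.shape[1] < 2:
        raise ValueError("need at least 2 voxels for pattern correlations")
    if np.any(betas.std(axis=1) == 0):
        raise ValueError("constant beta pattern: correlation undefined")

    r = np.corrcoef(betas)
    if fisher_z:
        with np.errstate(divide="ignore"):
            r = np.arctanh(np.clip(r, -1.0, 1.0))
    iu, ju = np.triu_indices(len(labels), k=1)
    same = labels[iu] == labels[ju]
    mean_same = float(np.mean(r[iu[same], ju[same]]))
    mean_diff = float(np.mean(r[iu[~same], ju[~same]]))
    return SimilarityResult(
        mean_same_r=mean_same,
        mean_diff_r=mean_diff,
        delta=mean_same - mean_diff,
        n_same_pairs=int(same.sum()),
        n_diff_pairs=int((~same).sum()),
    )


def blockwise_similarity(
    betas: np.ndarray,
    trial_meta: pd.DataFrame,
    voxel_rows=None,
    stages=None,
    correct_flags=None,
    correct_only: bool = False,
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Per-(block, stage) deltas for one voxel set.

    By default all trials enter, correct and error trials alike. With
    ``correct_only=True`` (a control analysis) error trials are
    dropped and any cell in which a stimulus no longer occurs exactly twice is
    marked missing (NaN) rather than computed.
    """
    meta = trial_meta.reset_index(drop=True)
    data = betas if voxel_rows is None else betas[:, voxel_rows]
    keep = np.ones(len(meta), dtype=bool)
    if correct_only:
        if correct_flags is None:
            raise ValueError("correct_only requires correct_flags")
        keep = np.asarray(correct_flags, dtype=bool)
    rows = []
    for block, block_meta in meta.groupby("block", sort=True):
        condition = block_meta["condition"].iloc[0]
        block_stages = sorted(block_meta["stage"].dropna().unique().astype(int))
        for stage in block_stages:
            if stages is not None and stage not in stages:
                continue
            sel = block_meta.index[(block_meta["stage"] == stage)].to_numpy()
            sel = sel[keep[sel]]
            row = {
                "block": block,
                "condition": condition,
                "stage": stage,
                "delta": np.nan,
                "mean_same_r": np.nan,
                "mean_diff_r": np.nan,
                "n_trials": len(sel),
            }
            try:
                res = stage_similarity(
                    data[sel], block_meta.loc[sel, "stimulus_id"].to_numpy(int), fisher_z=fisher_z
                )
                row.update(
                    delta=res.delta, mean_same_r=res.mean_same_r, mean_diff_r=res.mean_diff_r
                )
            except ValueError:
                pass  # degenerate cell stays missing
            rows.append(row)
    return pd.DataFrame(rows)


def wm_bias_adjust(roi_blockwise_deltas, wm_blockwise_deltas) -> float:
    """Bias-adjusted subject-level delta for one condition-stage cell.

    Regresses the block-wise ROI deltas on the paired white-matter deltas and
    returns the intercept: the ROI delta expected at zero measured bias. Falls
    back to the plain mean (with a warning) when the white-matter deltas carry
    no variance.
    """
    roi = np.asarray(roi_blockwise_deltas, dtype=float)
    wm = np.asarray(wm_blockwise_deltas, dtype=float)
    if roi.shape != wm.shape:
        raise ValueError("ROI and white-matter delta vectors must be paired")
    ok = np.isfinite(roi) & np.isfinite(wm)
    roi, wm = roi[ok], wm[ok]
    if roi.size < 3:
        raise ValueError("need at least 3 paired block values")
    if np.ptp(wm) == 0:
        warnings.warn("white-matter deltas have zero variance; returning unadjusted mean",
                      stacklevel=2)
        return float(np.mean(roi))
    slope, intercept = np.polyfit(wm, roi, 1)
    return float(intercept)


def subject_similarity(
    beta_set,
    roi_rows,
    stages=None,
    wm_rows=None,
    correct_flags=None,
    correct_only: bool = False,
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Subject-level similarity table for one ROI.

    Returns one row per (condition, stage) with the block-averaged delta and,
    when ``wm_rows`` is given, the white-matter-adjusted delta (intercept of
    the within-cell block regression).
    """
    if np.size(roi_rows) == 0:
        raise ValueError("empty ROI")
    kw = dict(
        stages=stages, correct_flags=correct_flags, correct_only=correct_only, fisher_z=fisher_z
    )
    roi_blocks = blockwise_similarity(beta_set.betas, beta_set.trial_meta, roi_rows, **kw)
    wm_blocks = None
    if wm_rows is not None:
        wm_blocks = blockwise_similarity(beta_set.betas, beta_set.trial_meta, wm_rows, **kw)
    rows = []
    for (condition, stage), cell in roi_blocks.groupby(["condition", "stage"], sort=True):
        delta = float(cell["delta"].mean()) if cell["delta"].notna().any() else np.nan
        row = {
            "condition": condition,
            "stage": int(stage),
            "delta": delta,
            "n_blocks": int(cell["delta"].notna().sum()),
        }
        if wm_blocks is not None:
            wm_cell = wm_blocks.merge(
                cell[["block", "stage"]], on=["block", "stage"], how="inner"
            ).sort_values("block")
            try:
                row["delta_wm_adjusted"] = wm_bias_adjust(
                    cell.sort_values("block")["delta"].to_numpy(),
                    wm_cell["delta"].to_numpy(),
                )
            except ValueError:
                row["delta_wm_adjusted"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_stages_early_late(table: pd.DataFrame, value_cols=("delta", "delta_wm_adjusted")) -> pd.DataFrame:
    """Aggregate four stages into early (1,2) and late (3,4) means (8-repetition designs)."""
    df = table.copy()
    df["stage"] = np.where(df["stage"].astype(int) <= 2, "early", "late")
    cols = [c for c in value_cols if c in df.columns]
    group_cols = [c for c in df.columns if c not in cols and c != "n_blocks"]
    agg = {c: "mean" for c in cols}
    if "n_blocks" in df.columns:
        agg["n_blocks"] = "sum"
    return df.groupby(group_cols, sort=True, as_index=False).agg(agg)


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets within Euclidean ``radius`` (in voxel units, center included)."""
    r = int(np.floor(radius))
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def searchlight_similarity(
    beta_set,
    coords: np.ndarray,
    mask_rows=None,
    radius: float = 3.0,
    stages=None,
    correct_flags=None,
    correct_only: bool = False,
    min_voxels: int = 2,
) -> dict:
    """Searchlight map of the similarity delta.

    Parameters
    ----------
    beta_set : TrialBetaSet whose voxel axis aligns with ``coords``.
    coords : (n_voxels, 3) integer voxel coordinates of the analyzed voxels.
    mask_rows : optional row indices restricting both centers and sphere
        members (defaults to all rows).
    radius : sphere radius in voxel units (3 -> 123 voxels in an open field).

    Returns a dict mapping (condition, stage) -> per-center delta array
    (NaN where the sphere holds fewer than ``min_voxels`` usable voxels),
    block-averaged within condition. Center order follows ``mask_rows``.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    coords = np.asarray(coords)
    rows = np.arange(coords.shape[0]) if mask_rows is None else np.asarray(mask_rows)
    if rows.size == 0:
        raise ValueError("empty searchlight mask")
    tree = cKDTree(coords[rows])
    neighborhoods = tree.query_ball_point(coords[rows], r=radius + 1e-9)
    meta = beta_set.trial_meta.reset_index(drop=True)

    cells: dict[tuple, list] = {}
    for block, block_meta in meta.groupby("block", sort=True):
        condition = block_meta["condition"].iloc[0]
        for stage in sorted(block_meta["stage"].dropna().unique().astype(int)):
            if stages is not None and stage not in stages:
                continue
            sel = block_meta.index[block_meta["stage"] == stage].to_numpy()
            if correct_only:
                sel = sel[np.asarray(correct_flags, dtype=bool)[sel]]
            cells.setdefault((condition, stage), []).append(
                (beta_set.betas[sel][:, rows], block_meta.loc[sel, "stimulus_id"].to_numpy(int))
            )

    out = {}
    for key, block_data in cells.items():
        acc = np.zeros(rows.size)
        cnt = np.zeros(rows.size)
        for betas, labels in block_data:
            for c, neigh in enumerate(neighborhoods):
                if len(neigh) < min_voxels:
                    continue
                try:
                    res = stage_similarity(betas[:, neigh], labels)
                except ValueError:
                    continue
                acc[c] += res.delta
                cnt[c] += 1
        with np.errstate(invalid="ignore"):
            out[key] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return out
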