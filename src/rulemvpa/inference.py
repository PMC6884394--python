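"""Group-level statistics for within-subject (repeated-measures) designs.

The factorial ANOVA is built from orthonormal within-subject contrast
variables: for every effect the subject-wise contrast scores are formed, and
F is the ratio of the between-contrast mean square to the subject-by-contrast
mean square. Sphericity is handled by the Greenhouse-Geisser epsilon computed
from the covariance of the contrast variables, and effect sizes are reported
as partial eta squared -- i.e. the full reporting format of the behavioral and
imaging ANOVAs (F, df, GG-corrected p, eta_p^2), including the constant term
that tests the grand mean against zero (equivalent to a squared one-sample t).
Family-wise error control for voxel maps uses sign-flipping max-statistic
permutation instead of random-field theory: assumption-light and
self-contained, at the cost of a permutation-resolution-limited minimum p.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "AnovaResult",
    "rm_anova",
    "linear_contrast",
    "TTestResult",
    "one_sample_t",
    "MapInference",
    "maxstat_fwe",
]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    gg_epsilon: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_tailed: float
    p_one_tailed: float  # H1: mean > 0


@dataclass
class MapInference:
    t_map: np.ndarray
    p_fwe: np.ndarray
    p_uncorrected: np.ndarray
    n_permutations: int
    mask: np.ndarray | None = None


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    if k < 2:
        return np.zeros((0, k))
    return linalg.null_space(np.ones((1, k))).T


def _wide_cells(table: pd.DataFrame, dv: str, within, subject: str):
    levels = {f: sorted(table[f].unique().tolist()) for f in within}
    wide = table.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
    full_cols = pd.MultiIndex.from_product([levels[f] for f in within], names=list(within)) \
        if len(within) > 1 else pd.Index(levels[within[0]], name=within[0])
    try:
        wide = wide.reindex(columns=full_cols)
    except Exception as exc:  # pragma: no cover
        raise ValueError("incomplete design") from exc
    if wide.isna().any().any():
        raise ValueError(
            "missing cells in the within-subject design; aggregate or impute upstream"
        )
    return wide.to_numpy(float), levels


def _effect_matrix(effect, within, levels) -> np.ndarray:
    """Rows = contrast variables of the effect over the full cell ordering."""
    M = np.ones((1, 1))
    for f in within:
        k = len(levels[f])
        block = _orthonormal_contrasts(k) if f in effect else np.full((1, k), 1.0 / k)
        M = np.kron(M, block)
    return M


def _contrast_f(D: np.ndarray, effect_name: str, against_zero: bool) -> AnovaResult:
    """Univariate RM F-test on subject x contrast scores D."""
    n, q = D.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    m = D.mean(axis=0)
    resid = D - m
    ss_eff = n * float(m @ m)
    ss_err = float((resid**2).sum())
    df1, df2 = q, q * (n - 1)
    if ss_err <= 0:
        raise ValueError("zero error variance")
    F = (ss_eff / df1) / (ss_err / df2)
    if q == 1:
        eps = 1.0
    else:
        S = resid.T @ resid / (n - 1)
        eps = float(np.trace(S) ** 2 / (q * np.sum(S * S)))
        eps = min(max(eps, 1.0 / q), 1.0)
    p_unc = float(stats.f.sf(F, df1, df2))
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2))
    return AnovaResult(
        effect=effect_name,
        F=float(F),
        df_num=df1,
        df_den=df2,
        gg_epsilon=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
    )


def rm_anova(table: pd.DataFrame, dv: str, within, subject: str = "subject") -> list[AnovaResult]:
    """Fully crossed within-subject factorial ANOVA.

    Returns the constant term (grand mean vs zero) plus every main effect and
    interaction, each with Greenhouse-Geisser epsilon and partial eta squared.

    Parameters
    ----------
    table : long-format DataFrame with one value per subject x cell (replicate
        rows are cell-averaged).
    dv : value column name.
    within : ordered iterable of within-subject factor column names.
    subject : subject identifier column.
    """
    within = list(within)
    Y, levels = _wide_cells(table, dv, within, subject)
    n_cells = Y.shape[1]
    total_df = sum(len(levels[f]) - 1 for f in within)
    if Y.shape[0] <= total_df + 1:
        raise ValueError("too few subjects for the requested factorial design")

    results = []
    # constant term: grand mean against zero
    grand = Y.mean(axis=1, keepdims=True)
    results.append(_contrast_f(grand, "constant", against_zero=True))
    for size in range(1, len(within) + 1):
        for effect in itertools.combinations(within, size):
            M = _effect_matrix(set(effect), within, levels)
            if M.shape[0] == 0:  # a single-level factor contributes no contrast
                continue
            D = Y @ M.T
            results.append(_contrast_f(D, ":".join(effect), against_zero=False))
    return results


def linear_contrast(
    table: pd.DataFrame,
    dv: str,
    within,
    trend_factor: str,
    subject: str = "subject",
    interaction_with: str | None = None,
) -> AnovaResult:
    """Polynomial linear-trend F-test over one numeric within-subject factor.

    With ``interaction_with`` set, tests whether the linear trend differs
    between the two levels of that factor (the "more pronounced for ..."
    style contrast); otherwise the overall linear trend averaged across all
    remaining factors.
    """
    within = list(within)
    Y, levels = _wide_cells(table, dv, within, subject)
    lv = np.asarray(levels[trend_factor], dtype=float)
    lin = lv - lv.mean()
    lin = lin / np.linalg.norm(lin)
    M = np.ones((1, 1))
    for f in within:
        k = len(levels[f])
        if f == trend_factor:
            block = lin[None, :]
        elif f == interaction_with:
            c = _orthonormal_contrasts(k)
            if c.shape[0] != 1:
                raise ValueError("interaction_with must be a 2-level factor")
            block = c
        else:
            block = np.full((1, k), 1.0 / k)
        M = np.kron(M, block)
    D = Y @ M.T
    name = f"linear({trend_factor})"
    if interaction_with:
        name += f" x {interaction_with}"
    return _contrast_f(D, name, against_zero=True)


def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    """One-sample t-test against ``popmean`` (use on paired differences for paired tests)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, popmean)
    t = float(res.statistic)
    df = int(x.size - 1)
    return TTestResult(
        t=t,
        df=df,
        p_two_tailed=float(res.pvalue),
        p_one_tailed=float(stats.t.sf(t, df)),
    )


def maxstat_fwe(
    subject_maps: np.ndarray,
    n_permutations: int = 1000,
    seed=None,
    mask: np.ndarray | None = None,
) -> MapInference:
    """Sign-flipping max-statistic permutation FWE for one-sample t-maps.

    ``subject_maps`` is (n_subjects, n_voxels). Corrected p at voxel v is
    (1 + #{permutation max-t >= observed t(v)}) / (n_permutations + 1);
    uncorrected p uses the per-voxel permutation distribution, so corrected
    p >= uncorrected p holds by construction.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("subject_maps must be (subjects x voxels)")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
        maps = maps[:, mask]
    n, v = maps.shape

    def tmap(x):
        m = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n))
            return np.where(sd == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)

    t_obs = tmap(maps)
    rng = np.random.default_rng(seed)
    exceed_max = np.zeros(v)
    exceed_vox = np.zeros(v)
    for _ in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = tmap(maps * signs[:, None])
        exceed_max += np.max(t_perm) >= t_obs
        exceed_vox += t_perm >= t_obs
    p_fwe = (1.0 + exceed_max) / (n_permutations + 1.0)
    p_unc = (1.0 + exceed_vox) / (n_permutations + 1.0)
    if mask is not None:
        full = np.ones(mask.size)
        t_full = np.zeros(mask.size)
        pf, pu = full.copy(), full.copy()
        t_full[mask], pf[mask], pu[mask] = t_obs, p_fwe, p_unc
        return MapInference(t_full, pf, pu, n_permutations, mask)
    return MapInference(t_obs, p_fwe, p_unc, n_permutations, None)
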