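"""Single-trial BOLD estimation via least-squares-separate (LSS) GLMs.

Design matrices follow SPM conventions: stick
functions at stimulus onset convolved with the canonical double-gamma HRF at
microtime resolution (TR/16, sampled at the middle microtime bin), an order-10
sine+cosine Fourier basis (20 columns) spanning 44 s time-locked to each
instruction phase, one aggregate feedback regressor, a run constant, a
discrete-cosine high-pass set with K = floor(2*N*TR/cutoff) columns, and
optional AR(1) prewhitening with one pooled rho per run.

The LSS scheme fits, for every implementation trial, a separate GLM with one
regressor for that trial and one for all other implementation trials.
:class:`LssSolver` exploits the fact that [target, others] spans the same
space as [target, sum-of-all-trials]: a single QR factorization of the shared
columns serves every per-trial model, so the full LSS sweep costs little more
than one ordinary GLM while remaining numerically identical to fitting each
per-trial design independently.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, signal, stats

__all__ = [
    "GlmConfig",
    "TrialBetaSet",
    "canonical_hrf",
    "convolve_onsets",
    "build_fourier_basis",
    "build_dct_highpass",
    "build_lss_design",
    "LssSolver",
    "fit_lss",
    "concat_beta_sets",
]


@dataclass(frozen=True)
class GlmConfig:
    """GLM settings. Defaults mirror the SPM-style setup at TR = 2 s."""

    tr_s: float = 2.0
    hpf_cutoff_s: float = 128.0  # 1/128 Hz (use 256.0 for the longer blocks)
    ar1: object = "estimate"  # "estimate" | "off" | fixed rho (float)
    fourier_span_s: float = 44.0
    fourier_n_regressors: int = 20
    #: one shared 20-column set whose basis functions repeat at every
    #: instruction onset (the SPM condition-x-basis convention); set True for
    #: an independent 20-column set per instruction phase instead
    fourier_per_phase: bool = False
    microtime_resolution: int = 16
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_peak_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_ratio: float = 6.0
    hrf_length_s: float = 32.0

    def __post_init__(self):
        if self.hpf_cutoff_s <= 2 * self.tr_s:
            raise ValueError("high-pass cutoff must exceed 2*TR")
        if self.fourier_n_regressors % 2:
            raise ValueError("fourier_n_regressors must be even (sine+cosine pairs)")

    @property
    def dt_s(self) -> float:
        return self.tr_s / self.microtime_resolution

    def replace(self, **kw) -> "GlmConfig":
        return dataclasses.replace(self, **kw)


def default_glm_config(experiment: str) -> GlmConfig:
    """Per-experiment defaults: 1/128 Hz high-pass for exp1, 1/256 Hz for exp2."""
    return GlmConfig(hpf_cutoff_s=128.0 if experiment == "exp1" else 256.0)


@dataclass
class TrialBetaSet:
    """Single-trial beta maps (trial x voxel) with aligned trial metadata."""

    betas: np.ndarray
    trial_meta: pd.DataFrame
    voxel_index: np.ndarray | None = None
    run_index: int | None = None

    def __post_init__(self):
        if self.betas.shape[0] != len(self.trial_meta):
            raise ValueError("trial_meta row count must equal beta row count")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]


def concat_beta_sets(sets) -> TrialBetaSet:
    sets = list(sets)
    betas = np.vstack([s.betas for s in sets])
    meta = pd.concat([s.trial_meta for s in sets], ignore_index=True)
    return TrialBetaSet(betas=betas, trial_meta=meta, voxel_index=sets[0].voxel_index)


def canonical_hrf(config: GlmConfig) -> np.ndarray:
    """Canonical double-gamma HRF sampled at microtime resolution.

    Difference of two gamma densities (peak at ~5 s, undershoot at ~15 s,
    peak:undershoot ratio 6:1) over a 32 s support, normalized to unit peak.
    """
    dt = config.dt_s
    t = np.arange(0.0, config.hrf_length_s + dt / 2, dt)
    peak = stats.gamma.pdf(
        t, a=config.hrf_peak_delay_s / config.hrf_peak_dispersion, scale=config.hrf_peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        a=config.hrf_undershoot_delay_s / config.hrf_undershoot_dispersion,
        scale=config.hrf_undershoot_dispersion,
    )
    h = peak - under / config.hrf_ratio
    return h / h.max()


def _microtime_sample(grid: np.ndarray, config: GlmConfig, n_volumes: int) -> np.ndarray:
    """Sample a microtime-resolution regressor at the middle microtime bin of each TR."""
    m = config.microtime_resolution
    idx = np.arange(n_volumes) * m + m // 2
    return grid[idx]


def convolve_onsets(onsets_s, config: GlmConfig, n_volumes: int) -> np.ndarray:
    """Stick functions at the given onsets convolved with the canonical HRF.

    Returns one column per onset, built at microtime resolution and resampled
    to the TR grid.
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    m = config.microtime_resolution
    n_micro = n_volumes * m
    sticks = np.zeros((n_micro, len(onsets_s)))
    idx = np.round(onsets_s / config.dt_s).astype(int)
    if np.any(idx < 0) or np.any(idx >= n_micro):
        raise ValueError("onset outside the run")
    sticks[idx, np.arange(len(onsets_s))] = 1.0
    h = canonical_hrf(config)
    conv = signal.fftconvolve(sticks, h[:, None], axes=0)[:n_micro]
    return _microtime_sample(conv, config, n_volumes)


def build_fourier_basis(onset_s: float, config: GlmConfig, n_volumes: int) -> np.ndarray:
    """Order-N/2 sine+cosine Fourier set over a window time-locked to ``onset_s``.

    With the default 20 regressors this is sin/cos of harmonics k = 1..10 of a
    44 s window (no DC term), zero outside the window -- a shape-agnostic model
    of the sustained instruction-phase response at microtime accuracy.
    """
    m = config.microtime_resolution
    n_micro = n_volumes * m
    t = np.arange(n_micro) * config.dt_s
    span = config.fourier_span_s
    if onset_s < 0 or onset_s >= n_volumes * config.tr_s:
        raise ValueError("onset outside the run")
    if onset_s + span > n_volumes * config.tr_s:
        warnings.warn("Fourier window overruns the run end; truncating", stacklevel=2)
    rel = t - onset_s
    in_window = (rel >= 0) & (rel < span)
    order = config.fourier_n_regressors // 2
    cols = np.zeros((n_micro, config.fourier_n_regressors))
    for k in range(1, order + 1):
        phase = 2.0 * np.pi * k * rel / span
        cols[in_window, 2 * (k - 1)] = np.sin(phase[in_window])
        cols[in_window, 2 * (k - 1) + 1] = np.cos(phase[in_window])
    return _microtime_sample(cols, config, n_volumes)


def build_dct_highpass(n_volumes: int, config: GlmConfig) -> np.ndarray:
    """Discrete-cosine drift basis, K = floor(2*N*TR/cutoff) columns (SPM convention)."""
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if not np.isfinite(config.hpf_cutoff_s):
        return np.zeros((n_volumes, 0))
    k_max = int(np.floor(2.0 * n_volumes * config.tr_s / config.hpf_cutoff_s))
    n = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n_volumes, 0))


def _implementation_trials(events: pd.DataFrame) -> pd.DataFrame:
    trials = events[events["phase"] == "implementation"]
    return trials.sort_values("onset", kind="stable").reset_index(drop=True)


def _instruction_onsets(events: pd.DataFrame) -> list[float]:
    instr = events[events["phase"] == "instruction"]
    if instr.empty:
        return []
    return sorted(float(g["onset"].min()) for _, g in instr.groupby("block"))


def build_nuisance(events: pd.DataFrame, config: GlmConfig, n_volumes: int):
    """Shared (non-trial) columns: Fourier sets, feedback, constant, DCT drifts."""
    cols, labels = [], []
    onsets = _instruction_onsets(events)
    if onsets and config.fourier_per_phase:
        for i, onset in enumerate(onsets):
            basis = build_fourier_basis(onset, config, n_volumes)
            cols.append(basis)
            labels.extend(f"fourier_phase{i}_{j}" for j in range(basis.shape[1]))
    elif onsets:
        # one basis set for the instruction condition: every basis function
        # repeats at each phase onset, so the set is shared across blocks
        basis = sum(build_fourier_basis(onset, config, n_volumes) for onset in onsets)
        cols.append(basis)
        labels.extend(f"fourier_{j}" for j in range(basis.shape[1]))
    fb = events.loc[events["phase"] == "feedback", "onset"].to_numpy(float)
    if fb.size:
        cols.append(convolve_onsets(fb, config, n_volumes).sum(axis=1, keepdims=True))
        labels.append("feedback")
    cols.append(np.ones((n_volumes, 1)))
    labels.append("constant")
    dct = build_dct_highpass(n_volumes, config)
    cols.append(dct)
    labels.extend(f"dct_{k}" for k in range(1, dct.shape[1] + 1))
    return np.column_stack(cols), labels


def build_lss_design(events: pd.DataFrame, trial_index: int, config: GlmConfig, n_volumes: int):
    """One per-trial LSS design: [target, all-other-trials, nuisance] + labels."""
    trials = _implementation_trials(events)
    if not 0 <= trial_index < len(trials):
        raise IndexError(f"trial_index {trial_index} out of range (n={len(trials)})")
    conv = convolve_onsets(trials["onset"].to_numpy(float), config, n_volumes)
    target = conv[:, trial_index]
    others = conv.sum(axis=1) - target
    nuis, nuis_labels = build_nuisance(events, config, n_volumes)
    X = np.column_stack([target, others, nuis])
    labels = [f"trial_{trial_index}", "other_trials", *nuis_labels]
    return X, labels


def ar1_whitening_matrix_apply(M: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening transform row-wise along time (axis 0)."""
    out = np.empty_like(M, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * M[0]
    out[1:] = M[1:] - rho * M[:-1]
    return out


def estimate_ar1_rho(residuals: np.ndarray, clip: float = 0.95) -> float:
    """Pooled lag-1 autocorrelation over voxels (one rho per run)."""
    num = float(np.sum(residuals[1:] * residuals[:-1]))
    den = float(np.sum(residuals**2))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, clip))


class LssSolver:
    """Precomputed LSS machinery for one run's events and volume count.

    ``fit(data)`` returns the trial x voxel matrix of target-trial betas,
    identical (to numerical precision) to solving every per-trial design from
    :func:`build_lss_design` by least squares.
    """

    def __init__(self, events: pd.DataFrame, config: GlmConfig, n_volumes: int):
        self.config = config
        self.n_volumes = n_volumes
        self.trials = _implementation_trials(events)
        if self.trials.empty:
            raise ValueError("no implementation trials in events")
        self.trial_regressors = convolve_onsets(
            self.trials["onset"].to_numpy(float), config, n_volumes
        )
        self.nuisance, self.nuisance_labels = build_nuisance(events, config, n_volumes)
        self._sum_col = self.trial_regressors.sum(axis=1)

    def _shared(self, Xc: np.ndarray, S: np.ndarray, N: np.ndarray):
        W = np.column_stack([S, N])
        Q, R = np.linalg.qr(W)
        diag = np.abs(np.diag(R))
        scale = np.linalg.norm(W, axis=0)
        bad = np.where(diag <= 1e-10 * np.maximum(scale, 1.0))[0]
        if bad.size:
            names = ["all_trials", *self.nuisance_labels]
            raise np.linalg.LinAlgError(
                "rank-deficient design; collinear columns: "
                + ", ".join(names[i] for i in bad)
            )
        return Q, R

    def estimate_rho(self, data: np.ndarray) -> float:
        """Pooled AR(1) coefficient from mean-model OLS residuals."""
        S, N = self._sum_col, self.nuisance
        W = np.column_stack([S, N])
        resid = data - W @ np.linalg.lstsq(W, data, rcond=None)[0]
        return estimate_ar1_rho(resid)

    def fit(self, data: np.ndarray) -> np.ndarray:
        """LSS betas for a (n_volumes x n_voxels) data matrix."""
        if data.shape[0] != self.n_volumes:
            raise ValueError("data/volume count mismatch")
        if not np.all(np.isfinite(data)):
            raise ValueError("BOLD data must be finite")
        ar1 = self.config.ar1
        if ar1 == "estimate":
            rho = self.estimate_rho(data)
        elif ar1 == "off":
            rho = None
        else:
            rho = float(ar1)
        Xc, S, N, Y = self.trial_regressors, self._sum_col, self.nuisance, data
        if rho is not None:
            Xc = ar1_whitening_matrix_apply(Xc, rho)
            S = ar1_whitening_matrix_apply(S[:, None], rho)[:, 0]
            N = ar1_whitening_matrix_apply(N, rho)
            Y = ar1_whitening_matrix_apply(Y, rho)
        Q, R = self._shared(Xc, S, N)
        QtY = Q.T @ Y  # k x voxels
        QtX = Q.T @ Xc  # k x trials
        U = Xc - Q @ QtX  # residualized target columns
        nu2 = np.sum(U * U, axis=0)
        scale2 = np.sum(Xc * Xc, axis=0)
        bad = np.where(nu2 <= 1e-20 * np.maximum(scale2, 1.0))[0]
        if bad.size:
            raise np.linalg.LinAlgError(
                "rank-deficient design; trial regressors collinear with shared "
                f"columns: {', '.join(f'trial_{i}' for i in bad)}"
            )
        a_target = (U.T @ Y) / nu2[:, None]  # trials x voxels
        # coefficient on the sum-of-all-trials column, per trial model
        e1 = np.zeros(R.shape[0])
        e1[0] = 1.0
        r1 = linalg.solve_triangular(R, e1, trans="T", lower=False)  # first row of R^{-1}
        r1Y = r1 @ QtY  # 1 x voxels
        r1X = r1 @ QtX  # 1 x trials
        a_sum = r1Y[None, :] - r1X[:, None] * a_target
        return a_target + a_sum


def fit_lss(bold_run, events: pd.DataFrame, config: GlmConfig, mask=None) -> TrialBetaSet:
    """Estimate single-trial betas for one run.

    Parameters
    ----------
    bold_run : object with ``data`` (voxel x time) and ``tr_s``; a plain
        (voxel x time) array is also accepted.
    events : events table for the run (BIDS-events-style columns).
    config : GlmConfig. ``ar1="estimate"`` pools one rho per run from the
        mean-model residuals before prewhitening.
    mask : optional boolean/index array selecting voxel rows.
    """
    if isinstance(bold_run, np.ndarray):
        data, run_index = bold_run, None
    else:
        data = np.asarray(bold_run.data)
        run_index = getattr(bold_run, "run_index", None)
    if mask is not None:
        data = data[mask]
        if data.shape[0] == 0:
            raise ValueError("mask selects no voxels")
    if data.shape[0] == 0:
        raise ValueError("no voxels to analyze")
    solver = LssSolver(events, config, n_volumes=data.shape[1])
    betas = solver.fit(data.T)
    voxel_index = None if mask is None else np.flatnonzero(np.asarray(mask))
    return TrialBetaSet(
        betas=betas, trial_meta=solver.trials.copy(), voxel_index=voxel_index, run_index=run_index
    )
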