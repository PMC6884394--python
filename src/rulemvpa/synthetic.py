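"""Ground-truthed synthetic task fMRI with known multivoxel codes.

The generator emulates exactly the statistical structure the downstream
analysis assumes: every implementation trial evokes, in each phantom region, a
mean amplitude that declines over stimulus repetitions plus a region-specific
multivoxel identity code (block-local rule-identity patterns in a prefrontal
"signal" region for memorization conditions only; stimulus-identity patterns
in a visual region and response-identity patterns in a motor region in all
conditions; nothing identity-specific in the dorsolateral null region or in
white matter) plus an independent per-trial pattern. Responses are convolved
with the canonical HRF at TR = 2 s with overlapping responses at 2-4 s SOAs,
instruction phases add sustained boxcar activity, feedback adds an
event-related response, and stationary AR(1) Gaussian noise is superimposed
per voxel. Trial amplitudes in the striatum share a latent factor with the
prefrontal signal region at a configurable, condition- and learning-phase-
dependent coupling, which is what the beta-series connectivity analysis is
meant to recover. A behavioral table realizes a configurable error/RT model
with perseverative errors.

Everything is reproducible from a single seed; the ground-truth sidecar
suffices to rebuild the noiseless BOLD exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import design as _design
from . import glm as _glm
from .design import ExperimentDesign, MEMORIZATION_CONDITIONS

REGION_NAMES = ("vlpfc_signal", "dlpfc_null", "visual", "motor", "white_matter", "striatum")
REGION_LABELS = {name: i + 1 for i, name in enumerate(REGION_NAMES)}


@dataclass
class PhantomAtlas:
    """Integer-labeled phantom ROI volume standing in for anatomical atlases."""

    labels: np.ndarray  # 3-D int array; 0 = background
    voxel_size_mm: float = 3.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        mask = self.labels > 0
        self._coords = np.column_stack(np.nonzero(mask))
        flat_labels = self.labels[mask]
        self._region_rows = {
            name: np.flatnonzero(flat_labels == lab) for name, lab in REGION_LABELS.items()
        }

    @property
    def shape(self):
        return self.labels.shape

    @property
    def n_voxels(self) -> int:
        return self._coords.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """(n_voxels, 3) coordinates of all labeled voxels, in mask order."""
        return self._coords

    def region_rows(self, name: str) -> np.ndarray:
        """Row indices (into the mask ordering) of one region."""
        return self._region_rows[name]

    @property
    def regions(self):
        return {n: r for n, r in self._region_rows.items() if r.size}

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "PhantomAtlas":
        img = nib.load(str(path))
        vox = float(np.abs(img.affine[0, 0]))
        return cls(labels=np.asarray(img.dataobj).astype(int), voxel_size_mm=vox)

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Embed per-mask-voxel values (last axis = voxel) into the 3-D grid."""
        values = np.asarray(values)
        out = np.full(values.shape[:-1] + self.shape, fill, dtype=float)
        i, j, k = self._coords.T
        out[..., i, j, k] = values
        return out


def _default_centers(shape) -> np.ndarray:
    lo = [int(round(0.27 * s)) for s in shape]
    hi = [int(round(0.73 * s)) for s in shape]
    corners = [
        (lo[0], lo[1], lo[2]),
        (lo[0], lo[1], hi[2]),
        (lo[0], hi[1], lo[2]),
        (lo[0], hi[1], hi[2]),
        (hi[0], lo[1], lo[2]),
        (hi[0], hi[1], hi[2]),
        (hi[0], lo[1], hi[2]),
        (hi[0], hi[1], lo[2]),
    ]
    return np.array(corners)


def make_phantom_atlas(
    shape=(24, 24, 24),
    region_sizes=None,
    rng=None,
    *,
    searchlight_radius: float | None = 3.0,
    voxel_size_mm: float = 3.0,
) -> PhantomAtlas:
    """Pack six disjoint compact regions into a voxel grid.

    ``region_sizes`` maps region name -> voxel count (default 200 each). When
    the atlas is intended for searchlight analysis (the default,
    ``searchlight_radius=3``) every region must hold at least a full
    searchlight sphere (123 voxels at radius 3); pass
    ``searchlight_radius=None`` for ROI-only phantoms with smaller regions.
    """
    sizes = {name: 200 for name in REGION_NAMES}
    if region_sizes:
        unknown = set(region_sizes) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")
        sizes.update(region_sizes)
    if searchlight_radius is not None:
        from .mvpa import sphere_offsets

        min_size = len(sphere_offsets(searchlight_radius))
        small = {n: s for n, s in sizes.items() if s < min_size}
        if small:
            raise ValueError(
                f"regions smaller than a radius-{searchlight_radius} searchlight sphere "
                f"({min_size} voxels): {small}"
            )
    n_total = int(np.prod(shape))
    if sum(sizes.values()) > n_total:
        raise ValueError("infeasible packing: region sizes exceed the grid")

    centers = _default_centers(shape)[: len(REGION_NAMES)]
    if rng is not None:
        rng = np.random.default_rng(rng)
        centers = centers + rng.integers(-1, 2, size=centers.shape)
        centers = np.clip(centers, 0, np.asarray(shape) - 1)
    # max radius each region may grow before it could touch a neighbor
    d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    max_r = d.min() / 2.0

    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    flat = grid.reshape(-1, 3)
    labels = np.zeros(n_total, dtype=np.int16)
    for name, center in zip(REGION_NAMES, centers):
        size = sizes[name]
        dist = np.sqrt(((flat - center) ** 2).sum(1))
        order = np.argsort(dist, kind="stable")
        free = order[labels[order] == 0][:size]
        if free.size < size or dist[free[-1]] > max_r:
            raise ValueError(f"infeasible packing: region {name!r} cannot fit {size} voxels")
        labels[free] = REGION_LABELS[name]
    return PhantomAtlas(labels=labels.reshape(shape), voxel_size_mm=voxel_size_mm)


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort (units: arb. BOLD, seconds, ms)."""

    tr_s: float = 2.0
    #: s.d. of the block-local rule-identity code in vlpfc_signal
    #: (memorization conditions only)
    sigma_identity: float = 0.6
    sigma_stim: float = 0.6  # stimulus-identity code in visual, all conditions
    sigma_resp: float = 0.6  # response-identity code in motor, all conditions
    sigma_trial_noise: float = 0.3  # i.i.d. per-trial pattern component
    #: mean evoked amplitude per stimulus repetition (declining engagement)
    amp_by_repetition: tuple = (2.0, 1.6, 1.3, 1.1, 0.95, 0.85, 0.8, 0.75)
    amp_jitter_sd: float = 0.5  # trial-amplitude fluctuation (region-wide)
    instruction_amp: float = 1.0
    feedback_amp: float = 0.5
    noise_sd: float = 1.0  # stationary AR(1) noise s.d.
    ar1_rho: float = 0.3
    #: trial-amplitude correlation between vlpfc_signal and striatum,
    #: per condition for the early (reps 1-2) and late (last two reps) windows
    coupling: dict = field(
        default_factory=lambda: {
            "easy": {"early": 0.1, "late": 0.1},
            "difficult": {"early": 0.1, "late": 0.1},
            "learning": {"early": 0.1, "late": 0.6},
            "control": {"early": 0.1, "late": 0.1},
        }
    )
    #: per-condition (first-repetition, last-repetition) error probability,
    #: linearly interpolated over repetitions
    error_rate: dict = field(
        default_factory=lambda: {
            "easy": (0.15, 0.03),
            "difficult": (0.45, 0.12),
            "learning": (0.15, 0.03),
            "control": (0.05, 0.03),
        }
    )
    #: per-condition (first-rep mean, last-rep mean, s.d.) of correct RTs in ms
    rt_ms: dict = field(
        default_factory=lambda: {
            "easy": (1100.0, 750.0, 150.0),
            "difficult": (1500.0, 950.0, 180.0),
            "learning": (1100.0, 750.0, 150.0),
            "control": (900.0, 700.0, 120.0),
        }
    )
    perseveration_p: float = 0.6  # P(an error repeats a previous wrong execution)
    omission_p: float = 0.0
    n_responses: int = 3

    def __post_init__(self):
        for name in ("sigma_identity", "sigma_stim", "sigma_resp", "sigma_trial_noise",
                     "noise_sd", "amp_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        for cond, (p0, p1) in self.error_rate.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"error probabilities for {cond} must lie in [0, 1]")


@dataclass
class BoldRun:
    """One run's voxel x time data (mask ordering follows the atlas)."""

    data: np.ndarray
    tr_s: float
    run_index: int

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_nifti(self, atlas: PhantomAtlas, path) -> None:
        vol = atlas.embed(self.data.T)  # time x X x Y x Z
        img = nib.Nifti1Image(np.moveaxis(vol, 0, -1).astype(np.float32), atlas.affine)
        img.header["pixdim"][4] = self.tr_s
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, atlas: PhantomAtlas, path, run_index: int, tr_s: float = 2.0) -> "BoldRun":
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)  # X Y Z T
        i, j, k = atlas.coords.T
        return cls(data=vol[i, j, k, :], tr_s=tr_s, run_index=run_index)


@dataclass
class GroundTruth:
    """Everything needed to rebuild the noiseless BOLD and score recovery."""

    rng_seed: int | None
    amplitudes: dict  # region -> (n_trials_total,) true trial amplitudes
    identity_patterns: dict  # region -> {(block, key): pattern over region voxels}
    trial_pattern_noise: np.ndarray  # (n_trials_total, n_mask_voxels)
    coupling_r: np.ndarray  # per-trial target coupling used for vlpfc/striatum
    executed_response: np.ndarray  # per-trial executed response (-1 = omission)
    rt_ms: np.ndarray
    ar1_rho: float

    def to_json(self, path, full: bool = False) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "ar1_rho": self.ar1_rho,
            "amplitudes": {k: v.tolist() for k, v in self.amplitudes.items()},
            "coupling_r": self.coupling_r.tolist(),
            "executed_response": self.executed_response.tolist(),
            "rt_ms": self.rt_ms.tolist(),
        }
        if full:
            payload["identity_patterns"] = {
                region: {f"{b}|{k}": p.tolist() for (b, k), p in pats.items()}
                for region, pats in self.identity_patterns.items()
            }
            payload["trial_pattern_noise"] = self.trial_pattern_noise.tolist()
        Path(path).write_text(json.dumps(payload))


def _coupling_for_trial(config: SimulationConfig, condition: str, repetition: int,
                        n_repetitions: int) -> float:
    windows = config.coupling.get(condition, {"early": 0.0, "late": 0.0})
    early, late = windows["early"], windows["late"]
    if repetition <= 2:
        return early
    if repetition >= n_repetitions - 1:
        return late
    # linear ramp across the middle repetitions
    span = max(n_repetitions - 3, 1)
    w = (repetition - 2) / span
    return early + w * (late - early)


def _simulate_behavior(trials: pd.DataFrame, config: SimulationConfig, rng) -> tuple:
    """Executed responses and RTs with perseverative errors.

    In memorization conditions the reference response is the one last executed
    for that stimulus (subjective rule formation); in the cued control
    condition every trial resets to the instructed response.
    """
    n = len(trials)
    executed = np.full(n, -1, dtype=int)
    rts = np.full(n, np.nan)
    n_reps = {b: int(g["repetition"].max()) for b, g in trials.groupby("block")}
    history: dict[tuple, list[int]] = {}
    last_exec: dict[tuple, int] = {}
    for i, row in enumerate(trials.itertuples(index=False)):
        cond = row.condition
        rep = int(row.repetition)
        key = (row.block, row.stimulus_id)
        p0, p1 = config.error_rate[cond]
        frac = (rep - 1) / max(n_reps[row.block] - 1, 1)
        p_err = p0 + frac * (p1 - p0)
        if config.omission_p and rng.random() < config.omission_p:
            continue
        cued = cond == "control"
        reference = int(row.instructed_response) if (cued or key not in last_exec) \
            else last_exec[key]
        if rng.random() >= p_err:
            resp = reference
        else:
            prior_wrong = [r for r in history.get(key, []) if r != reference]
            if prior_wrong and rng.random() < config.perseveration_p:
                resp = int(rng.choice(prior_wrong))
            else:
                candidates = [r for r in range(config.n_responses) if r != reference]
                resp = int(rng.choice(candidates))
        executed[i] = resp
        last_exec[key] = resp
        history.setdefault(key, []).append(resp)
        m0, m1, sd = config.rt_ms[cond]
        rts[i] = max(200.0, rng.normal(m0 + frac * (m1 - m0), sd))
    return executed, rts


@dataclass
class SubjectData:
    runs: list
    events: pd.DataFrame
    behavior: pd.DataFrame
    ground_truth: GroundTruth


def _instruction_boxcar(events_run: pd.DataFrame, gcfg: _glm.GlmConfig, n_vol: int) -> np.ndarray:
    instr = events_run[events_run["phase"] == "instruction"]
    m = gcfg.microtime_resolution
    n_micro = n_vol * m
    box = np.zeros(n_micro)
    t = np.arange(n_micro) * gcfg.dt_s
    for _, g in instr.groupby("block"):
        on = float(g["onset"].min())
        off = float((g["onset"] + g["duration"]).max())
        box[(t >= on) & (t < off)] = 1.0
    canonical = _glm.canonical_hrf(gcfg)
    conv = sp_signal.fftconvolve(box, canonical)[:n_micro] * gcfg.dt_s
    return _glm._microtime_sample(conv, gcfg, n_vol)


def simulate_subject(
    design: ExperimentDesign,
    atlas: PhantomAtlas,
    config: SimulationConfig,
    rng,
) -> SubjectData:
    """Simulate one subject's BOLD runs, events, behavior, and ground truth."""
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rng_behavior, rng_patterns, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    events = design.events_table()
    trials = events[events["phase"] == "implementation"].reset_index(drop=True)
    n_trials = len(trials)
    M = atlas.n_voxels
    gcfg = _glm.GlmConfig(tr_s=config.tr_s, ar1="off")

    executed, rts = _simulate_behavior(trials, config, rng_behavior)

    # identity patterns, block-local by construction
    patterns: dict[str, dict] = {"vlpfc_signal": {}, "visual": {}, "motor": {}}
    sigma = {"vlpfc_signal": config.sigma_identity, "visual": config.sigma_stim,
             "motor": config.sigma_resp}
    for block in design.blocks:
        b = block.block_index
        nv = {r: atlas.region_rows(r).size for r in patterns}
        for stim in block.implemented:
            if block.condition in MEMORIZATION_CONDITIONS:
                patterns["vlpfc_signal"][(b, int(stim))] = (
                    sigma["vlpfc_signal"] * rng_patterns.standard_normal(nv["vlpfc_signal"])
                )
            patterns["visual"][(b, int(stim))] = (
                sigma["visual"] * rng_patterns.standard_normal(nv["visual"])
            )
        for resp in range(config.n_responses):
            patterns["motor"][(b, resp)] = (
                sigma["motor"] * rng_patterns.standard_normal(nv["motor"])
            )

    # per-trial amplitudes with coupled vlpfc/striatum fluctuations
    amplitudes = {r: np.empty(n_trials) for r in REGION_NAMES}
    coupling_r = np.empty(n_trials)
    reps = trials["repetition"].to_numpy(int)
    conds = trials["condition"].to_numpy()
    base = np.array([config.amp_by_repetition[min(r - 1, len(config.amp_by_repetition) - 1)]
                     for r in reps])
    for i in range(n_trials):
        r = _coupling_for_trial(config, conds[i], reps[i], design.n_repetitions)
        coupling_r[i] = r
        e_v = rng_patterns.standard_normal()
        e_s = r * e_v + np.sqrt(max(1.0 - r**2, 0.0)) * rng_patterns.standard_normal()
        jitters = {
            "vlpfc_signal": e_v,
            "striatum": e_s,
        }
        for region in REGION_NAMES:
            j = jitters.get(region, rng_patterns.standard_normal())
            amplitudes[region][i] = base[i] + config.amp_jitter_sd * j

    trial_noise = config.sigma_trial_noise * rng_patterns.standard_normal((n_trials, M))

    gt = GroundTruth(
        rng_seed=seed,
        amplitudes=amplitudes,
        identity_patterns=patterns,
        trial_pattern_noise=trial_noise,
        coupling_r=coupling_r,
        executed_response=executed,
        rt_ms=rts,
        ar1_rho=config.ar1_rho,
    )

    runs = []
    for run in range(design.n_runs):
        clean = _noiseless_run(design, atlas, config, gt, run, gcfg)
        n_vol = clean.shape[1]
        if config.noise_sd > 0:
            innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1_rho**2)
            burn = 50
            e = rng_noise.standard_normal((M, n_vol + burn)) * innov_sd
            noise = sp_signal.lfilter([1.0], [1.0, -config.ar1_rho], e, axis=1)[:, burn:]
            clean = clean + noise
        runs.append(BoldRun(data=clean, tr_s=config.tr_s, run_index=run))

    behavior = trials[
        ["run", "block", "condition", "stimulus_id", "repetition", "stage",
         "instructed_response"]
    ].copy()
    behavior["executed_response"] = pd.array(
        [e if e >= 0 else pd.NA for e in executed], dtype="Int64"
    )
    behavior["rt_ms"] = rts

    return SubjectData(runs=runs, events=events, behavior=behavior, ground_truth=gt)


def _noiseless_run(design, atlas, config, gt: GroundTruth, run: int,
                   gcfg: _glm.GlmConfig) -> np.ndarray:
    """Rebuild one run's clean (noise-free) voxel x time signal from ground truth."""
    events = design.events_table()
    trials_all = events[events["phase"] == "implementation"].reset_index(drop=True)
    in_run = trials_all["run"].to_numpy() == run
    trials = trials_all[in_run].reset_index(drop=True)
    ev_run = events[events["run"] == run]
    n_vol = design.n_volumes(run, config.tr_s)
    M = atlas.n_voxels
    Xc = _glm.convolve_onsets(trials["onset"].to_numpy(float), gcfg, n_vol)

    P = np.zeros((len(trials), M))
    idx_all = np.flatnonzero(in_run)
    for region in REGION_NAMES:
        rows = atlas.region_rows(region)
        if rows.size == 0:
            continue
        P[:, rows] += gt.amplitudes[region][idx_all, None]
    for region, pats in gt.identity_patterns.items():
        rows = atlas.region_rows(region)
        if rows.size == 0:
            continue
        for i, row in enumerate(trials.itertuples(index=False)):
            if region == "motor":
                resp = gt.executed_response[idx_all[i]]
                if resp < 0:
                    continue  # omission: no response code
                key = (row.block, int(resp))
            else:
                key = (row.block, int(row.stimulus_id))
            if key in pats:
                P[i, rows] += pats[key]
    P += gt.trial_pattern_noise[idx_all]

    clean = (Xc @ P).T  # voxel x time
    instr = _instruction_boxcar(ev_run, gcfg, n_vol) * config.instruction_amp
    clean += instr[None, :]
    fb = ev_run.loc[ev_run["phase"] == "feedback", "onset"].to_numpy(float)
    if fb.size and config.feedback_amp:
        fb_reg = _glm.convolve_onsets(fb, gcfg, n_vol).sum(axis=1) * config.feedback_amp
        clean += fb_reg[None, :]
    return clean


def noiseless_bold(design, atlas, config, gt: GroundTruth) -> list[np.ndarray]:
    """Reconstruct every run's noise-free signal from the ground-truth sidecar."""
    gcfg = _glm.GlmConfig(tr_s=config.tr_s, ar1="off")
    return [_noiseless_run(design, atlas, config, gt, r, gcfg) for r in range(design.n_runs)]


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic, collision-free per-subject seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for c in ss.spawn(n_subjects)]


def simulate_cohort(
    n_subjects: int,
    experiment: str,
    atlas: PhantomAtlas,
    config: SimulationConfig,
    master_seed: int,
    out_dir,
    *,
    overwrite: bool = False,
    design_kwargs: dict | None = None,
    full_ground_truth: bool = False,
) -> list[Path]:
    """Write a cohort to disk (sub-XX/run-Y_bold.nii.gz, events.tsv, behavior.tsv,
    ground_truth.json; atlas.nii.gz at the root)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    atlas.to_nifti(out / "atlas.nii.gz")
    paths = []
    for i, design, data in iter_cohort(
        n_subjects, experiment, atlas, config, master_seed, design_kwargs
    ):
        sub_dir = out / f"sub-{i + 1:02d}"
        sub_dir.mkdir(exist_ok=True)
        for run in data.runs:
            run.to_nifti(atlas, sub_dir / f"run-{run.run_index + 1}_bold.nii.gz")
        _design.write_events(data.events, sub_dir / "events.tsv")
        data.behavior.to_csv(sub_dir / "behavior.tsv", sep="\t", index=False, na_rep="n/a")
        data.ground_truth.to_json(sub_dir / "ground_truth.json", full=full_ground_truth)
        paths.append(sub_dir)
    return paths


def iter_cohort(
    n_subjects: int,
    experiment: str,
    atlas: PhantomAtlas,
    config: SimulationConfig,
    master_seed: int,
    design_kwargs: dict | None = None,
):
    """Yield (subject_index, design, SubjectData) without touching disk.

    Each subject receives a freshly randomized design (own trial sequences)
    and a deterministic seed derived from ``master_seed``.
    """
    kwargs = design_kwargs or {}
    for i, seed in enumerate(subject_seeds(master_seed, n_subjects)):
        design = _design.generate_experiment_design(experiment, seed, **kwargs)
        yield i, design, simulate_subject(design, atlas, config, seed)
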