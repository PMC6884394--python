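"""Experiment designs for instruction-based stimulus-response (S-R) learning tasks.

Each task block pairs a brief instruction phase (novel written nouns framed by
response cues) with an implementation phase in which four of the instructed
nouns are presented repeatedly and the participant executes the memorized
response. The implementation-trial order is built from independently
randomized "atomic" 8-trial sequences -- one per implementation stage, each
containing exactly two occurrences of each of the four implemented stimuli.
Randomizing each stage separately is what makes the stage-resolved
identity-specific pattern-similarity statistic unbiased in expectation under
overlapping BOLD responses; a single fully randomized sequence that is split
into stages only retrospectively does not have this property, which
:func:`estimate_sequence_bias` can demonstrate empirically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("easy", "difficult", "learning", "control")
EXPERIMENTS = ("exp1", "exp2")
PHASES = ("instruction", "implementation", "announce", "feedback")

#: conditions whose correct performance requires memorizing the instructed rules
MEMORIZATION_CONDITIONS = ("easy", "difficult", "learning")

EXPERIMENT_CONDITIONS = {"exp1": ("easy", "difficult"), "exp2": ("learning", "control")}
DEFAULT_BLOCKS_PER_CONDITION = {"exp1": 18, "exp2": 12}
DEFAULT_N_REPETITIONS = {"exp1": 4, "exp2": 8}
DEFAULT_N_RUNS = 3

ANNOUNCE_DURATION_S = 2.0
FEEDBACK_DURATION_S = 2.0
TRIAL_DURATION_S = 1.0
SOA_LEVELS_S = (2.0, 2.5, 3.0, 3.5, 4.0)
PHASE_DELAYS_S = (2.0, 4.0)
N_IMPLEMENTED = 4
N_INSTRUCTED = {"easy": 4, "learning": 4, "control": 4, "difficult": 10}
INSTRUCTION_ITEM_S = {"easy": 2.0, "learning": 2.0, "control": 2.0, "difficult": 1.0}
RESPONSE_COUNT_CHOICES = (2, 3)

EVENT_COLUMNS = [
    "onset",
    "duration",
    "run",
    "block",
    "condition",
    "phase",
    "stimulus_id",
    "repetition",
    "stage",
    "instructed_response",
]


@dataclass
class TrialEvent:
    """One row of the experimental timeline (any phase, not only trials)."""

    run_index: int
    block_index: int
    condition: str
    phase: str
    onset_s: float
    duration_s: float
    stimulus_id: int | None = None
    repetition: int | None = None
    stage: int | None = None
    instructed_response: int | None = None


@dataclass
class BlockDesign:
    """One task block: instruction items plus an implementation-trial sequence."""

    condition: str
    experiment: str
    stimulus_set: list[int]
    implemented: list[int]
    response_map: dict[int, int]
    n_repetitions: int
    events: list[TrialEvent]
    run_index: int = 0
    block_index: int = 0
    response_cued: bool = False
    scheme: str = "atomic"

    @property
    def n_stages(self) -> int:
        return self.n_repetitions // 2

    @property
    def implementation_events(self) -> list[TrialEvent]:
        return [e for e in self.events if e.phase == "implementation"]

    @property
    def end_s(self) -> float:
        last = self.events[-1]
        return last.onset_s + last.duration_s

    def events_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


@dataclass
class ExperimentDesign:
    """A full multi-run design with counterbalanced conditions and delays."""

    experiment: str
    n_runs: int
    blocks: list[BlockDesign]
    rng_seed: int | None = None
    n_repetitions: int = 4
    blocks_per_condition: int = 18

    def run_blocks(self, run_index: int) -> list[BlockDesign]:
        return [b for b in self.blocks if b.run_index == run_index]

    def events_table(self) -> pd.DataFrame:
        frames = [b.events_frame() for b in self.blocks]
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)

    def run_events(self, run_index: int) -> pd.DataFrame:
        ev = self.events_table()
        return ev[ev["run"] == run_index].reset_index(drop=True)

    def run_duration_s(self, run_index: int) -> float:
        ev = self.run_events(run_index)
        return float((ev["onset"] + ev["duration"]).max())

    def n_volumes(self, run_index: int, tr_s: float, tail_s: float = 20.0) -> int:
        return int(math.ceil((self.run_duration_s(run_index) + tail_s) / tr_s))

    def n_implementation_trials(self, run_index: int | None = None) -> int:
        blocks = self.blocks if run_index is None else self.run_blocks(run_index)
        return sum(len(b.implementation_events) for b in blocks)

    def validate(self) -> None:
        conditions = EXPERIMENT_CONDITIONS[self.experiment]
        for cond in conditions:
            n = sum(b.condition == cond for b in self.blocks)
            if n != self.blocks_per_condition:
                raise ValueError(f"{cond}: expected {self.blocks_per_condition} blocks, found {n}")
        per_run = 2 * self.blocks_per_condition // self.n_runs
        for r in range(self.n_runs):
            blocks = self.run_blocks(r)
            if len(blocks) != per_run:
                raise ValueError(f"run {r}: expected {per_run} blocks, found {len(blocks)}")
        ev = self.events_table()
        for r in range(self.n_runs):
            onsets = ev.loc[ev["run"] == r, "onset"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise ValueError(f"run {r}: onsets not strictly increasing")


def events_to_frame(events: list[TrialEvent]) -> pd.DataFrame:
    rows = [
        {
            "onset": e.onset_s,
            "duration": e.duration_s,
            "run": e.run_index,
            "block": e.block_index,
            "condition": e.condition,
            "phase": e.phase,
            "stimulus_id": e.stimulus_id,
            "repetition": e.repetition,
            "stage": e.stage,
            "instructed_response": e.instructed_response,
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    for col in ("stimulus_id", "repetition", "stage", "instructed_response"):
        df[col] = df[col].astype("Int64")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    """Write a BIDS-events-style tab-separated file (onset/duration in seconds)."""
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in ("stimulus_id", "repetition", "stage", "instructed_response"):
        if col in df:
            df[col] = df[col].astype("Int64")
    return df


def generate_atomic_sequence(stimuli, rng) -> list[int]:
    """Return a uniformly random 2x-occurrence sequence of the given stimuli.

    For the canonical four implemented stimuli this is the 8-trial "atomic"
    sequence: every stimulus appears exactly twice, in an order drawn uniformly
    from all admissible arrangements.
    """
    stimuli = list(stimuli)
    if not stimuli:
        raise ValueError("stimuli must be non-empty")
    if len(set(stimuli)) != len(stimuli):
        raise ValueError("duplicate stimulus ids are not allowed")
    rng = np.random.default_rng(rng)
    seq = np.array(stimuli * 2)
    rng.shuffle(seq)
    return [int(s) for s in seq]


def _surjective_map(stimuli, n_responses, rng) -> dict[int, int]:
    """Random stimulus->response assignment covering exactly n_responses responses."""
    while True:
        resp = rng.integers(0, n_responses, size=len(stimuli))
        if len(set(resp.tolist())) == n_responses:
            return {int(s): int(r) for s, r in zip(stimuli, resp)}


def _choose_implemented(stimuli, response_map, n_responses, rng) -> list[int]:
    """Uniform 4-subset of the instructed nouns covering exactly n_responses responses."""
    stimuli = np.asarray(stimuli)
    for _ in range(10_000):
        subset = rng.choice(stimuli, size=N_IMPLEMENTED, replace=False)
        if len({response_map[int(s)] for s in subset}) == n_responses:
            return [int(s) for s in subset]
    raise RuntimeError("could not find an implemented subset covering all responses")


def generate_block_design(
    condition: str,
    experiment: str,
    stimulus_pool,
    rng,
    *,
    n_responses: int | None = None,
    pre_delay_s: float | None = None,
    end_delay_s: float | None = None,
    start_onset_s: float = 0.0,
    run_index: int = 0,
    block_index: int = 0,
    n_repetitions: int | None = None,
    scheme: str = "atomic",
) -> BlockDesign:
    """Generate one task block.

    ``scheme="atomic"`` concatenates one independently randomized atomic
    sequence per stage; ``scheme="retrospective"`` draws a single fully
    randomized sequence and assigns stages by occurrence count only -- the
    biased baseline used for methodological comparison.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if condition not in EXPERIMENT_CONDITIONS[experiment]:
        raise ValueError(f"condition {condition!r} is not part of {experiment}")
    if scheme not in ("atomic", "retrospective"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(rng)
    n_reps = n_repetitions if n_repetitions is not None else DEFAULT_N_REPETITIONS[experiment]
    if n_reps % 2:
        raise ValueError("n_repetitions must be even (stages pair consecutive repetitions)")

    n_instructed = N_INSTRUCTED[condition]
    pool = list(stimulus_pool)
    if len(pool) < n_instructed:
        raise ValueError(f"stimulus pool too small: need {n_instructed}, got {len(pool)}")
    instructed = pool[:n_instructed]

    if n_responses is None:
        n_responses = int(rng.choice(RESPONSE_COUNT_CHOICES))
    if n_responses not in RESPONSE_COUNT_CHOICES:
        raise ValueError("response_map must use 2 or 3 distinct responses")
    response_map = _surjective_map(instructed, n_responses, rng)
    if condition == "difficult":
        implemented = _choose_implemented(instructed, response_map, n_responses, rng)
    else:
        implemented = list(instructed)

    if pre_delay_s is None:
        pre_delay_s = float(rng.choice(PHASE_DELAYS_S))
    if end_delay_s is None:
        end_delay_s = float(rng.choice(PHASE_DELAYS_S))

    n_stages = n_reps // 2
    if scheme == "atomic":
        seq: list[int] = []
        for _ in range(n_stages):
            seq.extend(generate_atomic_sequence(implemented, rng))
    else:
        flat = np.array(implemented * n_reps)
        rng.shuffle(flat)
        seq = [int(s) for s in flat]

    events: list[TrialEvent] = []
    common = dict(run_index=run_index, block_index=block_index, condition=condition)
    t = start_onset_s + pre_delay_s
    events.append(TrialEvent(phase="announce", onset_s=t, duration_s=ANNOUNCE_DURATION_S, **common))
    t += ANNOUNCE_DURATION_S
    item_s = INSTRUCTION_ITEM_S[condition]
    for stim in instructed:
        events.append(
            TrialEvent(
                phase="instruction",
                onset_s=t,
                duration_s=item_s,
                stimulus_id=stim,
                instructed_response=response_map[stim],
                **common,
            )
        )
        t += item_s
    events.append(TrialEvent(phase="announce", onset_s=t, duration_s=ANNOUNCE_DURATION_S, **common))
    t += ANNOUNCE_DURATION_S

    # SOA is onset-to-onset and inserted before each trial, so jitter also
    # separates the implementation announcement from the first trial
    rep_count = {s: 0 for s in implemented}
    for stim in seq:
        t += float(rng.choice(SOA_LEVELS_S))
        rep_count[stim] += 1
        rep = rep_count[stim]
        events.append(
            TrialEvent(
                phase="implementation",
                onset_s=t,
                duration_s=TRIAL_DURATION_S,
                stimulus_id=stim,
                repetition=rep,
                stage=(rep + 1) // 2,
                instructed_response=response_map[stim],
                **common,
            )
        )
    t += TRIAL_DURATION_S + end_delay_s  # delay counted from the last trial's end
    events.append(TrialEvent(phase="feedback", onset_s=t, duration_s=FEEDBACK_DURATION_S, **common))

    return BlockDesign(
        condition=condition,
        experiment=experiment,
        stimulus_set=instructed,
        implemented=implemented,
        response_map=response_map,
        n_repetitions=n_reps,
        events=events,
        run_index=run_index,
        block_index=block_index,
        response_cued=(condition == "control"),
        scheme=scheme,
    )


def _balanced_delays(n: int, rng) -> list[float]:
    """Exactly balanced 2 s / 4 s delays (odd n: the extra level is drawn at random)."""
    levels = list(PHASE_DELAYS_S) * (n // 2)
    if n % 2:
        levels.append(float(rng.choice(PHASE_DELAYS_S)))
    rng.shuffle(levels)
    return [float(x) for x in levels]


def generate_experiment_design(
    experiment: str,
    rng,
    *,
    blocks_per_condition: int | None = None,
    n_runs: int = DEFAULT_N_RUNS,
    n_repetitions: int | None = None,
    scheme: str = "atomic",
) -> ExperimentDesign:
    """Generate a full counterbalanced design.

    Defaults reproduce the canonical paradigm layout: exp1 = 3 runs x 12 blocks
    (18 easy + 18 difficult, 4 repetitions -> 192 implementation trials per
    run); exp2 = 3 runs x 8 blocks (12 learning + 12 control, 8 repetitions
    -> 256 trials per run). Pre-instruction and pre-feedback delays are
    exactly balanced per condition, the 2-vs-3-response assignment alternates
    deterministically within condition, and every block consumes a fresh
    stimulus set.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    bpc = blocks_per_condition if blocks_per_condition is not None else DEFAULT_BLOCKS_PER_CONDITION[experiment]
    n_reps = n_repetitions if n_repetitions is not None else DEFAULT_N_REPETITIONS[experiment]
    conditions = EXPERIMENT_CONDITIONS[experiment]
    if (2 * bpc) % n_runs:
        raise ValueError("total block count must divide evenly across runs")
    if bpc % n_runs:
        raise ValueError("blocks per condition must divide evenly across runs")
    per_run_per_cond = bpc // n_runs

    pre_delays = {c: _balanced_delays(bpc, rng) for c in conditions}
    end_delays = {c: _balanced_delays(bpc, rng) for c in conditions}
    n_resp_seq = {c: [RESPONSE_COUNT_CHOICES[i % 2] for i in range(bpc)] for c in conditions}

    blocks: list[BlockDesign] = []
    next_stimulus = 0
    cond_counter = {c: 0 for c in conditions}
    block_index = 0
    for run in range(n_runs):
        order = [c for c in conditions for _ in range(per_run_per_cond)]
        rng.shuffle(order)
        t = 0.0
        for cond in order:
            i = cond_counter[cond]
            cond_counter[cond] += 1
            n_instr = N_INSTRUCTED[cond]
            pool = list(range(next_stimulus, next_stimulus + n_instr))
            next_stimulus += n_instr
            block = generate_block_design(
                cond,
                experiment,
                pool,
                rng,
                n_responses=n_resp_seq[cond][i],
                pre_delay_s=pre_delays[cond][i],
                end_delay_s=end_delays[cond][i],
                start_onset_s=t,
                run_index=run,
                block_index=block_index,
                n_repetitions=n_reps,
                scheme=scheme,
            )
            blocks.append(block)
            t = block.end_s
            block_index += 1

    design = ExperimentDesign(
        experiment=experiment,
        n_runs=n_runs,
        blocks=blocks,
        rng_seed=seed,
        n_repetitions=n_reps,
        blocks_per_condition=bpc,
    )
    design.validate()
    return design


@dataclass
class BiasEstimate:
    """Per-stage Monte-Carlo estimate of the design-induced similarity bias."""

    stages: np.ndarray
    bias: np.ndarray
    se: np.ndarray
    n_mc: int
    per_draw: np.ndarray | None = None  # draws x stages

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.bias))


def block_trial_table(block: BlockDesign, rezero: bool = True) -> pd.DataFrame:
    """Events frame of a single block, optionally re-zeroed to the block start."""
    ev = block.events_frame()
    if rezero:
        ev = ev.copy()
        ev["onset"] -= float(ev["onset"].min())
    return ev


def estimate_sequence_bias(
    block: BlockDesign,
    glm_config,
    n_mc: int,
    rng,
    *,
    n_voxels: int = 40,
    min_n_mc: int = 100,
    keep_draws: bool = False,
) -> BiasEstimate:
    """Monte-Carlo oracle for the similarity bias induced by one trial sequence.

    Every trial is given an independent random multivoxel pattern (no identity
    structure), noise-free BOLD is synthesized at the block's timing, the LSS
    estimator is run, and the stage-wise same-minus-different correlation
    statistic is computed. Its mean over draws estimates the bias the design
    alone induces; under the atomic scheme this bias averages to zero across
    randomly generated sequences.
    """
    from . import glm as _glm
    from . import mvpa as _mvpa

    if n_mc < min_n_mc:
        raise ValueError(f"n_mc must be >= {min_n_mc}")
    rng = np.random.default_rng(rng)
    ev = block_trial_table(block)
    trials = ev[ev["phase"] == "implementation"].reset_index(drop=True)
    n_trials = len(trials)
    last = float((ev["onset"] + ev["duration"]).max())
    n_vol = int(math.ceil((last + 32.0) / glm_config.tr_s))
    if n_vol < 2:
        raise ValueError("glm_config inconsistent with design timing")
    # noise-free data: AR(1) prewhitening is residual-driven and degenerate here
    solver = _glm.LssSolver(ev, glm_config.replace(ar1="off"), n_vol)
    stages = np.sort(trials["stage"].dropna().unique().astype(int))
    labels = trials["stimulus_id"].to_numpy(int)
    stage_of_trial = trials["stage"].to_numpy(int)

    draws = np.empty((n_mc, len(stages)))
    for d in range(n_mc):
        patterns = rng.standard_normal((n_trials, n_voxels))
        data = solver.trial_regressors @ patterns  # n_vol x n_voxels, noise-free
        betas = solver.fit(data)
        for j, s in enumerate(stages):
            sel = stage_of_trial == s
            res = _mvpa.stage_similarity(betas[sel], labels[sel])
            draws[d, j] = res.delta
    bias = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / math.sqrt(n_mc)
    return BiasEstimate(
        stages=stages,
        bias=bias,
        se=se,
        n_mc=n_mc,
        per_draw=draws if keep_draws else None,
    )


def estimate_design_bias(
    design: "ExperimentDesign",
    glm_config,
    n_mc: int,
    rng,
    *,
    run_index: int = 0,
    n_voxels: int = 40,
) -> pd.DataFrame:
    """Per-block, per-stage similarity bias for one run analyzed in context.

    Unlike :func:`estimate_sequence_bias`, the blocks of the run are fitted
    jointly -- with the shared instruction basis and all other trials of the
    run in the LSS models -- so each block's bias is measured under the same
    regressor environment as in the real analysis. Returns a frame with
    columns block, condition, stage, bias, se.
    """
    from . import glm as _glm
    from . import mvpa as _mvpa

    rng = np.random.default_rng(rng)
    ev = design.run_events(run_index)
    trials = ev[ev["phase"] == "implementation"].reset_index(drop=True)
    n_vol = design.n_volumes(run_index, glm_config.tr_s)
    solver = _glm.LssSolver(ev, glm_config.replace(ar1="off"), n_vol)
    labels = trials["stimulus_id"].to_numpy(int)
    blocks = trials["block"].to_numpy(int)
    stage_of_trial = trials["stage"].to_numpy(int)
    cells = [
        (b, s)
        for b in np.unique(blocks)
        for s in np.unique(stage_of_trial[blocks == b])
    ]
    draws = np.empty((n_mc, len(cells)))
    n_trials = len(trials)
    for d in range(n_mc):
        patterns = rng.standard_normal((n_trials, n_voxels))
        betas = solver.fit(solver.trial_regressors @ patterns)
        for j, (b, s) in enumerate(cells):
            sel = (blocks == b) & (stage_of_trial == s)
            draws[d, j] = _mvpa.stage_similarity(betas[sel], labels[sel]).delta
    cond_of_block = {b.block_index: b.condition for b in design.blocks}
    return pd.DataFrame(
        {
            "block": [b for b, _ in cells],
            "condition": [cond_of_block[b] for b, _ in cells],
            "stage": [s for _, s in cells],
            "bias": draws.mean(axis=0),
            "se": draws.std(axis=0, ddof=1) / math.sqrt(n_mc),
        }
    )


def bias_from_linear_map(
    block: BlockDesign,
    glm_config,
    n_mc: int,
    rng,
    *,
    n_voxels: int = 40,
) -> BiasEstimate:
    """Independent fast route to the same bias via the LSS linear map.

    In the noiseless case the fitted betas are a fixed linear map ``A`` of the
    true trial patterns; the bias expectation can therefore be Monte-Carlo'd
    directly from ``A @ P`` without refitting the GLM per draw. Used as a
    cross-check of :func:`estimate_sequence_bias`.
    """
    from . import glm as _glm
    from . import mvpa as _mvpa

    rng = np.random.default_rng(rng)
    ev = block_trial_table(block)
    trials = ev[ev["phase"] == "implementation"].reset_index(drop=True)
    last = float((ev["onset"] + ev["duration"]).max())
    n_vol = int(math.ceil((last + 32.0) / glm_config.tr_s))
    solver = _glm.LssSolver(ev, glm_config.replace(ar1="off"), n_vol)
    A = solver.fit(solver.trial_regressors)  # betas for identity patterns
    stages = np.sort(trials["stage"].dropna().unique().astype(int))
    labels = trials["stimulus_id"].to_numpy(int)
    stage_of_trial = trials["stage"].to_numpy(int)

    draws = np.empty((n_mc, len(stages)))
    n_trials = len(trials)
    for d in range(n_mc):
        patterns = rng.standard_normal((n_trials, n_voxels))
        betas = A @ patterns
        for j, s in enumerate(stages):
            sel = stage_of_trial == s
            res = _mvpa.stage_similarity(betas[sel], labels[sel])
            draws[d, j] = res.delta
    bias = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / math.sqrt(n_mc)
    return BiasEstimate(stages=stages, bias=bias, se=se, n_mc=n_mc)
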