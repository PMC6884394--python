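"""End-to-end validation suites: bias, recovery, calibration, connectivity.

These functions re-run the full pipeline on freshly simulated data at fixed,
documented problem sizes and summarize the quantities that characterize the
method: the design-induced similarity bias of the atomic-sequence scheme (and
the systematic bias of naive retrospective stage splitting), signal
recovery and regional selectivity on the default cohort, the false-positive
rate of the group test under a null identity code, and the beta-series
connectivity contrast under configured and null coupling. Problem sizes are
chosen so the whole battery runs on a single CPU in minutes; see the methods
note for the rationale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import connectivity as _connectivity
from . import design as _design
from . import glm as _glm
from . import inference as _inference
from . import mvpa as _mvpa
from . import pipeline as _pipeline
from . import synthetic as _synthetic
from .pipeline import PipelineConfig

REDUCED_ATLAS_KW = dict(
    shape=(16, 16, 16),
    region_sizes={"vlpfc_signal": 48, "dlpfc_null": 12, "visual": 12, "motor": 12,
                  "white_matter": 32, "striatum": 48},
    searchlight_radius=None,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for c in ss.spawn(n)]


def structural_counts() -> dict:
    """LSS model counts implied by the generated designs (per run / per subject)."""
    out = {}
    for experiment in ("exp1", "exp2"):
        d = _design.generate_experiment_design(experiment, 0)
        per_run = {d.n_implementation_trials(r) for r in range(d.n_runs)}
        assert len(per_run) == 1
        out[experiment] = {
            "per_run": per_run.pop(),
            "per_subject": d.n_implementation_trials(),
        }
    return out


def bias_suite(
    seed: int,
    n_designs: int = 17,
    n_mc: int = 100,
    scheme: str = "atomic",
    n_voxels: int = 40,
) -> pd.DataFrame:
    """Per-block similarity bias across freshly randomized designs.

    Each design contributes one full-size run (12 blocks at the 4-repetition
    layout) analyzed jointly, so 17 designs give 204 independent random
    blocks at the paradigm's timing (TR 2 s, SOAs 2-4 s).
    """
    gcfg = _glm.default_glm_config("exp1")
    tables = []
    for i, s in enumerate(_spawn_seeds(seed, n_designs)):
        d = _design.generate_experiment_design("exp1", s, n_runs=3, scheme=scheme)
        tab = _design.estimate_design_bias(d, gcfg, n_mc=n_mc, rng=s + 1,
                                           n_voxels=n_voxels)
        tab.insert(0, "design", i)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def bias_summary(table: pd.DataFrame) -> dict:
    """Grand-mean bias per stage with its standard error over blocks."""
    out = {}
    for stage, g in table.groupby("stage"):
        mean = float(g["bias"].mean())
        # spread over blocks dominates the per-block MC error; combine both
        se = float(np.sqrt(g["bias"].var(ddof=1) / len(g) + (g["se"] ** 2).mean() / len(g)))
        out[int(stage)] = {"mean": mean, "se": se, "n_blocks": int(len(g))}
    return out


def recovery_suite(seed: int, n_subjects: int = 20) -> _pipeline.CohortResult:
    """Default synthetic cohort (full paradigm layout, 8 repetitions) analyzed end to end."""
    cfg = PipelineConfig(experiment="exp2", n_subjects=n_subjects, seed=seed)
    return _pipeline.run_cohort(cfg)


def recovery_summary(result: _pipeline.CohortResult) -> dict:
    """Group tests for signal recovery and regional/conditional selectivity."""
    out: dict = {}
    stage_p = {}
    for stage in (1, 2, 3, 4):
        values = result.similarity_values("vlpfc_signal", "learning", stage=stage)
        t = _inference.one_sample_t(values)
        stage_p[stage] = {"mean_delta": float(values.mean()), "t": t.t,
                          "p_one_tailed": t.p_one_tailed}
    out["vlpfc_learning_by_stage"] = stage_p
    for key, roi, cond in (
        ("vlpfc_control", "vlpfc_signal", "control"),
        ("dlpfc_learning", "dlpfc_null", "learning"),
        ("dlpfc_control", "dlpfc_null", "control"),
        ("wm_learning", "white_matter", "learning"),
        ("wm_control", "white_matter", "control"),
        ("visual_learning", "visual", "learning"),
        ("visual_control", "visual", "control"),
        ("motor_learning", "motor", "learning"),
        ("motor_control", "motor", "control"),
    ):
        values = result.similarity_values(roi, cond)
        t = _inference.one_sample_t(values)
        out[key] = {"mean_delta": float(values.mean()), "t": t.t,
                    "p_one_tailed": t.p_one_tailed, "p_two_tailed": t.p_two_tailed}
    return out


def _reduced_atlas():
    return _synthetic.make_phantom_atlas(
        REDUCED_ATLAS_KW["shape"], REDUCED_ATLAS_KW["region_sizes"],
        searchlight_radius=REDUCED_ATLAS_KW["searchlight_radius"],
    )


def calibration_suite(seed: int, n_cohorts: int = 100, n_subjects: int = 15) -> dict:
    """Null false-positive rate of the group-level grand-mean (constant) test.

    Cohorts are simulated with sigma_identity = 0 on a reduced grid (one run
    of six 4-repetition blocks, ROI-only phantom); for each cohort the
    constant term of the condition x stage ANOVA on white-matter-adjusted
    prefrontal deltas is tested at alpha = 0.05.
    """
    atlas = _reduced_atlas()
    sim = _synthetic.SimulationConfig(sigma_identity=0.0)
    gcfg = _glm.default_glm_config("exp1")
    design_kwargs = dict(n_runs=1, blocks_per_condition=3)
    rejections = 0
    p_values = []
    for cohort_seed in _spawn_seeds(seed, n_cohorts):
        rows = []
        for i, dsg, data in _synthetic.iter_cohort(
            n_subjects, "exp1", atlas, sim, cohort_seed, design_kwargs=design_kwargs
        ):
            beta_set = _pipeline.fit_subject_betas(data, dsg, gcfg)
            tab = _mvpa.subject_similarity(
                beta_set,
                atlas.region_rows("vlpfc_signal"),
                wm_rows=atlas.region_rows("white_matter"),
            )
            tab["subject"] = i
            rows.append(tab)
        table = pd.concat(rows, ignore_index=True)
        res = _inference.rm_anova(table, "delta_wm_adjusted", ["condition", "stage"])
        constant = next(r for r in res if r.effect == "constant")
        p_values.append(constant.p_gg)
        rejections += constant.p_gg < 0.05
    return {"n_cohorts": n_cohorts, "rejections": rejections,
            "rate": rejections / n_cohorts, "p_values": p_values}


def connectivity_null_suite(seed: int, n_cohorts: int = 10, n_subjects: int = 12) -> dict:
    """Group connectivity contrast under flat coupling (reduced exp2-style grid)."""
    atlas = _reduced_atlas()
    flat = {c: {"early": 0.1, "late": 0.1} for c in _design.CONDITIONS}
    sim = _synthetic.SimulationConfig(coupling=flat)
    gcfg = _glm.default_glm_config("exp2")
    design_kwargs = dict(n_runs=1, blocks_per_condition=4)
    from . import behavior as _behavior

    rejections, p_values = 0, []
    for cohort_seed in _spawn_seeds(seed, n_cohorts):
        contrasts = []
        for _, dsg, data in _synthetic.iter_cohort(
            n_subjects, "exp2", atlas, sim, cohort_seed, design_kwargs=design_kwargs
        ):
            beta_set = _pipeline.fit_subject_betas(data, dsg, gcfg)
            scored = _behavior.score_accuracy(data.behavior)
            seed_s = _connectivity.seed_series(beta_set, atlas.region_rows("vlpfc_signal"))
            target_s = _connectivity.seed_series(beta_set, atlas.region_rows("striatum"))
            try:
                contrasts.append(_connectivity.connectivity_change(
                    seed_s, target_s, beta_set.trial_meta,
                    correct_flags=scored["correct_subjective"].to_numpy(bool)))
            except ValueError:
                pass
        t = _inference.one_sample_t(contrasts)
        p_values.append(t.p_one_tailed)
        rejections += t.p_one_tailed < 0.05
    return {"n_cohorts": n_cohorts, "rejections": rejections, "p_values": p_values}


def oracle_equivalence(seed: int, n_draws: int = 100) -> float:
    """Max |delta difference| between the implementation and a brute-force oracle."""
    from scipy import stats as sp_stats

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(4), 2)
    worst = 0.0
    for _ in range(n_draws):
        betas = rng.standard_normal((8, 50))
        res = _mvpa.stage_similarity(betas, labels)
        same, diff = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                r = sp_stats.pearsonr(betas[i], betas[j]).statistic
                (same if labels[i] == labels[j] else diff).append(r)
        worst = max(worst, abs(res.delta - (np.mean(same) - np.mean(diff))))
    return worst
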