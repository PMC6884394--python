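"""End-to-end orchestration: configuration, cohort analysis, and reporting.

The canonical in-memory path (`run_cohort`) simulates a cohort, estimates
single-trial betas via LSS, computes white-matter-adjusted identity-specific
pattern similarity per ROI, univariate repetition profiles, behavioral
summaries, and the beta-series connectivity contrast, and aggregates group
statistics. The disk-based path mirrors the same stages through the CLI with
NIfTI/TSV artifacts, a serialized config for provenance, and named seeds for
every random component.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as _behavior
from . import connectivity as _connectivity
from . import glm as _glm
from . import inference as _inference
from . import mvpa as _mvpa
from . import synthetic as _synthetic
from . import univariate as _univariate
from .glm import GlmConfig, TrialBetaSet, default_glm_config
from .synthetic import PhantomAtlas, SimulationConfig

DEFAULT_ROIS = ("vlpfc_signal", "dlpfc_null", "visual", "motor", "white_matter")


@dataclass
class PipelineConfig:
    """Serializable description of one full synthetic-cohort analysis."""

    experiment: str = "exp2"
    n_subjects: int = 20
    seed: int = 0
    blocks_per_condition: int | None = None
    n_runs: int = 3
    n_repetitions: int | None = None
    atlas_shape: tuple = (24, 24, 24)
    region_sizes: dict | None = None
    searchlight_radius: float | None = 3.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    glm: GlmConfig | None = None
    rois: tuple = DEFAULT_ROIS
    wm_adjust: bool = True
    correct_only: bool = False
    fisher_z: bool = False
    aggregate: str | None = None  # None | "early_late"
    connectivity_seed_roi: str = "vlpfc_signal"
    connectivity_target_roi: str = "striatum"

    def resolved_glm(self) -> GlmConfig:
        return self.glm if self.glm is not None else default_glm_config(self.experiment)

    def design_kwargs(self) -> dict:
        kw: dict = {"n_runs": self.n_runs}
        if self.blocks_per_condition is not None:
            kw["blocks_per_condition"] = self.blocks_per_condition
        if self.n_repetitions is not None:
            kw["n_repetitions"] = self.n_repetitions
        return kw

    def make_atlas(self) -> PhantomAtlas:
        return _synthetic.make_phantom_atlas(
            tuple(self.atlas_shape),
            self.region_sizes,
            searchlight_radius=self.searchlight_radius,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["atlas_shape"] = list(self.atlas_shape)
        d["rois"] = list(self.rois)
        d["glm"] = None if self.glm is None else dataclasses.asdict(self.glm)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None and not isinstance(d["sim"], SimulationConfig):
            sim = dict(d["sim"])
            sim["amp_by_repetition"] = tuple(sim.get("amp_by_repetition", ()))
            for key in ("error_rate", "rt_ms", "coupling"):
                if key in sim:
                    sim[key] = {
                        c: tuple(v) if isinstance(v, (list, tuple)) else dict(v)
                        for c, v in sim[key].items()
                    }
            d["sim"] = SimulationConfig(**sim)
        if d.get("glm") is not None and not isinstance(d["glm"], GlmConfig):
            d["glm"] = GlmConfig(**d["glm"])
        d["atlas_shape"] = tuple(d.get("atlas_shape", (24, 24, 24)))
        d["rois"] = tuple(d.get("rois", DEFAULT_ROIS))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def fit_subject_betas(subject_data, design, glm_config: GlmConfig) -> TrialBetaSet:
    """LSS betas for all runs of one subject, concatenated in trial order."""
    sets = []
    for run in subject_data.runs:
        events = subject_data.events[subject_data.events["run"] == run.run_index]
        sets.append(_glm.fit_lss(run, events, glm_config))
    return _glm.concat_beta_sets(sets)


def _aligned_correct_flags(beta_set: TrialBetaSet, scored: pd.DataFrame) -> np.ndarray:
    meta = beta_set.trial_meta.reset_index(drop=True)
    for col in ("block", "stimulus_id", "repetition"):
        if not np.array_equal(meta[col].to_numpy(int), scored[col].to_numpy(int)):
            raise ValueError("behavior table is not aligned with trial betas")
    return scored["correct_subjective"].to_numpy(bool)


@dataclass
class SubjectResult:
    similarity: pd.DataFrame
    univariate: pd.DataFrame
    behavior_summary: pd.DataFrame
    connectivity_contrast: float | None


def analyze_subject(
    subject_data,
    design,
    atlas: PhantomAtlas,
    config: PipelineConfig,
    beta_set: TrialBetaSet | None = None,
) -> SubjectResult:
    """All subject-level analyses from simulated (or loaded) data."""
    if beta_set is None:
        beta_set = fit_subject_betas(subject_data, design, config.resolved_glm())
    scored = _behavior.score_accuracy(subject_data.behavior)
    correct = _aligned_correct_flags(beta_set, scored)

    wm_rows = atlas.region_rows("white_matter") if config.wm_adjust else None
    tables = []
    for roi in config.rois:
        tab = _mvpa.subject_similarity(
            beta_set,
            atlas.region_rows(roi),
            # the white-matter control region cannot be adjusted against itself
            wm_rows=None if roi == "white_matter" else wm_rows,
            correct_flags=correct,
            correct_only=config.correct_only,
            fisher_z=config.fisher_z,
        )
        tab.insert(0, "roi", roi)
        tables.append(tab)
    similarity = pd.concat(tables, ignore_index=True)
    if config.aggregate == "early_late":
        similarity = _mvpa.aggregate_stages_early_late(similarity)

    uni = _univariate.mean_activity(
        beta_set,
        {roi: atlas.region_rows(roi) for roi in config.rois},
        correct_flags=correct,
    )
    behavior_summary = _behavior.summarize_performance(scored)

    contrast = None
    if config.experiment == "exp2" and design.n_repetitions >= 8:
        seed = _connectivity.seed_series(
            beta_set, atlas.region_rows(config.connectivity_seed_roi)
        )
        target = _connectivity.seed_series(
            beta_set, atlas.region_rows(config.connectivity_target_roi)
        )
        try:
            contrast = _connectivity.connectivity_change(
                seed, target, beta_set.trial_meta, correct_flags=correct
            )
        except ValueError:
            contrast = None  # subject flagged missing
    return SubjectResult(similarity, uni, behavior_summary, contrast)


@dataclass
class CohortResult:
    config: PipelineConfig
    similarity: pd.DataFrame
    univariate: pd.DataFrame
    behavior: pd.DataFrame
    connectivity: pd.DataFrame
    group: dict = field(default_factory=dict)

    def similarity_values(self, roi: str, condition: str, stage=None,
                          adjusted: bool = True) -> np.ndarray:
        """Subject-level deltas for one cell (stage=None averages stages)."""
        col = "delta_wm_adjusted" if adjusted and "delta_wm_adjusted" in self.similarity else "delta"
        df = self.similarity
        sel = (df["roi"] == roi) & (df["condition"] == condition)
        if stage is not None:
            sel &= df["stage"] == stage
        values = df[sel].groupby("subject")[col].mean().to_numpy(float)
        if col != "delta" and np.all(np.isnan(values)):
            values = df[sel].groupby("subject")["delta"].mean().to_numpy(float)
        return values


def run_cohort(config: PipelineConfig, atlas: PhantomAtlas | None = None) -> CohortResult:
    """Simulate and analyze a full cohort in memory."""
    if atlas is None:
        atlas = config.make_atlas()
    sim_tables, uni_tables, beh_tables, conn_rows = [], [], [], []
    for i, design, data in _synthetic.iter_cohort(
        config.n_subjects,
        config.experiment,
        atlas,
        config.sim,
        config.seed,
        design_kwargs=config.design_kwargs(),
    ):
        res = analyze_subject(data, design, atlas, config)
        for tab, bucket in (
            (res.similarity, sim_tables),
            (res.univariate, uni_tables),
            (res.behavior_summary, beh_tables),
        ):
            tab = tab.copy()
            if "subject" in tab.columns:
                tab["subject"] = i
            else:
                tab.insert(0, "subject", i)
            bucket.append(tab)
        conn_rows.append({"subject": i, "contrast": res.connectivity_contrast})
    result = CohortResult(
        config=config,
        similarity=pd.concat(sim_tables, ignore_index=True),
        univariate=pd.concat(uni_tables, ignore_index=True),
        behavior=pd.concat(beh_tables, ignore_index=True),
        connectivity=pd.DataFrame(conn_rows),
    )
    result.group = group_statistics(result)
    return result


def group_statistics(result: CohortResult) -> dict:
    """One-sample tests per (roi, condition) cell plus the connectivity contrast."""
    out: dict = {"similarity": {}, "connectivity": None}
    df = result.similarity
    for roi in df["roi"].unique():
        for condition in df[df["roi"] == roi]["condition"].unique():
            values = result.similarity_values(roi, condition)
            try:
                t = _inference.one_sample_t(values)
                out["similarity"][(roi, condition)] = {
                    "mean_delta": float(np.mean(values)),
                    "t": t.t,
                    "p_one_tailed": t.p_one_tailed,
                    "p_two_tailed": t.p_two_tailed,
                    "n": int(values.size),
                }
            except ValueError:
                out["similarity"][(roi, condition)] = None
    conn = result.connectivity["contrast"].dropna().to_numpy(float)
    if conn.size >= 2 and np.ptp(conn) > 0:
        t = _inference.one_sample_t(conn)
        out["connectivity"] = {
            "mean_contrast": float(conn.mean()),
            "t": t.t,
            "p_one_tailed": t.p_one_tailed,
            "p_two_tailed": t.p_two_tailed,
            "n": int(conn.size),
        }
    return out


def write_report(result: CohortResult, out_dir) -> Path:
    """Render group tables, a JSON summary, and a summary figure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.similarity.to_csv(out / "similarity.tsv", sep="\t", index=False)
    result.univariate.to_csv(out / "univariate.tsv", sep="\t", index=False)
    result.behavior.to_csv(out / "behavior_summary.tsv", sep="\t", index=False)
    result.connectivity.to_csv(out / "connectivity.tsv", sep="\t", index=False)

    summary = {
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "similarity": {
            f"{roi}|{cond}": stats_
            for (roi, cond), stats_ in result.group["similarity"].items()
        },
        "connectivity": result.group["connectivity"],
    }
    (out / "group_summary.json").write_text(json.dumps(summary, indent=2))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = [
        (roi, cond, s["mean_delta"])
        for (roi, cond), s in result.group["similarity"].items()
        if s is not None
    ]
    if cells:
        fig, ax = plt.subplots(figsize=(8, 4))
        labels = [f"{r}\n{c}" for r, c, _ in cells]
        ax.bar(range(len(cells)), [v for _, _, v in cells])
        ax.set_xticks(range(len(cells)), labels, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("group mean identity-specific delta")
        ax.axhline(0, color="k", lw=0.5)
        fig.tight_layout()
        fig.savefig(out / "group_similarity.png", dpi=120)
        plt.close(fig)
    return out


def log_provenance(out_dir, config: PipelineConfig, stage: str) -> None:
    from . import __version__

    rec = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    path = Path(out_dir) / "provenance.json"
    records = json.loads(path.read_text()) if path.exists() else []
    records.append(rec)
    path.write_text(json.dumps(records, indent=2))
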