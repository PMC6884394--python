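"""Identity-specific pattern similarity: oracle checks, adjustment, searchlight."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rulemvpa import mvpa
from rulemvpa.glm import TrialBetaSet
from rulemvpa.mvpa import (
    aggregate_stages_early_late,
    sphere_offsets,
    stage_similarity,
    subject_similarity,
    wm_bias_adjust,
)


def brute_force_delta(betas, labels):
    """Independent oracle: loop all pairs with scipy's pearsonr."""
    same, diff = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            r = stats.pearsonr(betas[i], betas[j]).statistic
            (same if labels[i] == labels[j] else diff).append(r)
    return np.mean(same) - np.mean(diff), np.mean(same), np.mean(diff), len(same), len(diff)


class TestStageSimilarity:
    def test_two_stimulus_worked_example_matches_pairwise_oracle(self):
        betas = np.array(
            [[1, 2, 3, 4], [1, 2, 3, 5], [4, 3, 2, 1], [4, 3, 1, 2]], dtype=float
        )
        labels = ["S1", "S1", "S2", "S2"]
        res = stage_similarity(betas, labels)
        delta, same, diff, n_same, n_diff = brute_force_delta(betas, labels)
        assert abs(res.delta - delta) < 1e-12
        assert abs(res.mean_same_r - same) < 1e-12
        assert abs(res.mean_diff_r - diff) < 1e-12
        assert (res.n_same_pairs, res.n_diff_pairs) == (n_same, n_diff)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(4), 2)
        for _ in range(25):
            betas = rng.standard_normal((8, 50))
            res = stage_similarity(betas, labels)
            delta, *_ = brute_force_delta(betas, labels)
            assert abs(res.delta - delta) < 1e-12

    def test_pair_counts_for_four_stimuli(self):
        rng = np.random.default_rng(1)
        res = stage_similarity(rng.standard_normal((8, 20)), np.repeat(np.arange(4), 2))
        assert res.n_same_pairs == 4 and res.n_diff_pairs == 24

    def test_identical_repeats_with_orthogonal_stimuli_give_perfect_same_r(self):
        base = np.eye(4)
        betas = np.vstack([base, base])  # each stimulus's two trials identical
        labels = [0, 1, 2, 3, 0, 1, 2, 3]
        res = stage_similarity(betas, labels)
        assert res.mean_same_r == pytest.approx(1.0)
        assert res.delta > 0

    def test_invariant_to_common_voxel_permutation(self):
        rng = np.random.default_rng(2)
        betas = rng.standard_normal((8, 30))
        labels = np.repeat(np.arange(4), 2)
        perm = rng.permutation(30)
        a = stage_similarity(betas, labels)
        b = stage_similarity(betas[:, perm], labels)
        assert a.delta == pytest.approx(b.delta, abs=1e-14)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(3)
        good = rng.standard_normal((8, 10))
        with pytest.raises(ValueError, match="exactly twice"):
            stage_similarity(good, [0, 0, 0, 1, 1, 2, 2, 3])
        with pytest.raises(ValueError, match="2 voxels"):
            stage_similarity(good[:, :1], np.repeat(np.arange(4), 2))
        constant = good.copy()
        constant[2] = 5.0
        with pytest.raises(ValueError, match="constant"):
            stage_similarity(constant, np.repeat(np.arange(4), 2))


class TestWmBiasAdjust:
    def test_constant_wm_deltas_fall_back_to_unadjusted_mean(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = wm_bias_adjust([0.1, 0.3, 0.2], [0.5, 0.5, 0.5])
        assert out == pytest.approx(np.mean([0.1, 0.3, 0.2]))

    def test_roi_identical_to_wm_adjusts_to_zero(self):
        wm = np.array([0.1, -0.2, 0.3, 0.05])
        assert wm_bias_adjust(wm, wm) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation_returns_intercept(self):
        wm = np.array([-0.2, 0.0, 0.1, 0.4, 0.25])
        roi = 0.5 * wm + 0.2
        assert wm_bias_adjust(roi, wm) == pytest.approx(0.2, abs=1e-12)

    def test_requires_three_paired_blocks(self):
        with pytest.raises(ValueError, match="3 paired"):
            wm_bias_adjust([0.1, 0.2], [0.0, 0.1])


def _fake_beta_set(rng, conditions=("easy", "difficult"), n_blocks_per_cond=3,
                   n_stages=2, n_voxels=40, signal=0.0):
    rows, betas = [], []
    block = 0
    for cond in conditions:
        for _ in range(n_blocks_per_cond):
            patterns = {s: rng.standard_normal(n_voxels) for s in range(4)}
            for stage in range(1, n_stages + 1):
                order = rng.permutation(np.repeat(np.arange(4), 2))
                for stim in order:
                    rep = 2 * stage - 1 + sum(
                        1 for r in rows
                        if r["block"] == block and r["stimulus_id"] == stim
                        and r["stage"] == stage
                    )
                    rows.append(
                        {"onset": len(rows) * 3.0, "duration": 1.0, "run": 0,
                         "block": block, "condition": cond, "phase": "implementation",
                         "stimulus_id": int(stim), "repetition": rep, "stage": stage,
                         "instructed_response": 0}
                    )
                    betas.append(signal * patterns[stim] + rng.standard_normal(n_voxels))
            block += 1
    return TrialBetaSet(betas=np.array(betas), trial_meta=pd.DataFrame(rows))


class TestSubjectSimilarity:
    def test_one_row_per_condition_and_stage(self, rng):
        bs = _fake_beta_set(rng)
        tab = subject_similarity(bs, np.arange(40))
        assert len(tab) == 4  # 2 conditions x 2 stages
        assert set(tab["condition"]) == {"easy", "difficult"}
        assert set(tab["stage"]) == {1, 2}
        assert (tab["n_blocks"] == 3).all()

    def test_signal_raises_delta_above_null(self, rng):
        null = subject_similarity(_fake_beta_set(rng, signal=0.0), np.arange(40))
        sig = subject_similarity(_fake_beta_set(rng, signal=1.5), np.arange(40))
        assert sig["delta"].mean() > null["delta"].mean() + 0.2

    def test_degenerate_block_marked_missing(self, rng):
        bs = _fake_beta_set(rng)
        first_block = bs.trial_meta["block"] == 0
        bs.betas[first_block.to_numpy()] = 1.0  # constant patterns -> undefined r
        tab = subject_similarity(bs, np.arange(40))
        easy = tab[tab["condition"] == "easy"]
        assert (easy["n_blocks"] == 2).all()  # degenerate block excluded
        assert np.isfinite(tab["delta"]).all()  # remaining blocks still average

    def test_empty_roi_rejected(self, rng):
        with pytest.raises(ValueError, match="empty ROI"):
            subject_similarity(_fake_beta_set(rng), np.array([], dtype=int))

    def test_correct_only_drops_incomplete_cells(self, rng):
        bs = _fake_beta_set(rng)
        flags = np.ones(bs.n_trials, dtype=bool)
        flags[0] = False  # one error trial -> its (block, stage) cell unusable
        tab = subject_similarity(bs, np.arange(40), correct_flags=flags, correct_only=True)
        meta0 = bs.trial_meta.iloc[0]
        cell = tab[(tab["condition"] == meta0["condition"]) & (tab["stage"] == meta0["stage"])]
        assert cell["n_blocks"].iloc[0] == 2

    def test_wm_adjustment_column_present_and_finite(self, rng):
        bs = _fake_beta_set(rng, n_voxels=80)
        tab = subject_similarity(bs, np.arange(40), wm_rows=np.arange(40, 80))
        assert "delta_wm_adjusted" in tab
        assert np.isfinite(tab["delta_wm_adjusted"]).all()


class TestAggregation:
    def test_early_late_means_for_eight_repetition_design(self):
        tab = pd.DataFrame(
            {
                "roi": ["r"] * 4,
                "condition": ["learning"] * 4,
                "stage": [1, 2, 3, 4],
                "delta": [0.1, 0.3, 0.5, 0.7],
                "n_blocks": [12] * 4,
            }
        )
        agg = aggregate_stages_early_late(tab, value_cols=("delta",))
        early = agg[agg["stage"] == "early"]["delta"].iloc[0]
        late = agg[agg["stage"] == "late"]["delta"].iloc[0]
        assert early == pytest.approx(0.2)
        assert late == pytest.approx(0.6)


class TestSearchlight:
    def test_radius_three_sphere_has_123_voxels(self):
        assert len(sphere_offsets(3)) == 123

    def test_center_of_homogeneous_region_approximates_full_roi_delta(self, rng):
        # compact 7x7x7 region, identity signal everywhere
        coords = np.array([[i, j, k] for i in range(7) for j in range(7) for k in range(7)])
        n_vox = len(coords)
        patterns = {s: rng.standard_normal(n_vox) for s in range(4)}
        rows, betas = [], []
        labels = np.repeat(np.arange(4), 2)
        order = rng.permutation(labels)
        for t, stim in enumerate(order):
            rows.append({"onset": 3.0 * t, "duration": 1.0, "run": 0, "block": 0,
                         "condition": "easy", "phase": "implementation",
                         "stimulus_id": int(stim), "repetition": 1, "stage": 1,
                         "instructed_response": 0})
            betas.append(patterns[stim] + 0.7 * rng.standard_normal(n_vox))
        meta = pd.DataFrame(rows)
        meta["repetition"] = meta.groupby("stimulus_id").cumcount() + 1
        bs = TrialBetaSet(betas=np.array(betas), trial_meta=meta)
        maps = mvpa.searchlight_similarity(bs, coords, radius=3.0)
        center = np.flatnonzero((coords == 3).all(axis=1))[0]
        roi_delta = stage_similarity(bs.betas, meta["stimulus_id"].to_numpy()).delta
        assert abs(maps[("easy", 1)][center] - roi_delta) < 0.15

    def test_small_spheres_marked_missing_and_radius_validated(self, rng):
        coords = np.array([[0, 0, 0], [10, 10, 10], [10, 10, 11], [10, 11, 10]])
        bs = _fake_beta_set(rng, conditions=("easy",), n_blocks_per_cond=1,
                            n_stages=1, n_voxels=4)
        maps = mvpa.searchlight_similarity(bs, coords, radius=1.5)
        vals = maps[("easy", 1)]
        assert np.isnan(vals[0])  # isolated voxel: sphere below minimum size
        assert np.isfinite(vals[1])
        with pytest.raises(ValueError, match="radius"):
            mvpa.searchlight_similarity(bs, coords, radius=0.5)
        with pytest.raises(ValueError, match="empty"):
            mvpa.searchlight_similarity(bs, coords, mask_rows=np.array([], dtype=int))
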