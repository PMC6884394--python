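"""Design generation: atomic sequences, block/experiment structure, bias oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rulemvpa import design, glm
from rulemvpa.design import (
    SOA_LEVELS_S,
    BlockDesign,
    TrialEvent,
    estimate_sequence_bias,
    bias_from_linear_map,
    generate_atomic_sequence,
    generate_block_design,
    generate_experiment_design,
)


class TestAtomicSequence:
    def test_each_stimulus_occurs_exactly_twice_over_many_draws(self):
        rng = np.random.default_rng(1)
        stimuli = [3, 7, 11, 42]
        for _ in range(10_000):
            seq = generate_atomic_sequence(stimuli, rng)
            assert len(seq) == 8
            assert {s: seq.count(s) for s in stimuli} == {s: 2 for s in stimuli}

    @given(st.integers(1, 6))
    @settings(max_examples=20, deadline=None)
    def test_length_is_twice_the_stimulus_count(self, k):
        seq = generate_atomic_sequence(list(range(k)), np.random.default_rng(0))
        assert len(seq) == 2 * k

    def test_single_stimulus_gives_the_only_admissible_sequence(self):
        assert generate_atomic_sequence([9], np.random.default_rng(0)) == [9, 9]

    def test_fixed_seed_reproduces_the_sequence(self):
        a = generate_atomic_sequence([1, 2, 3, 4], np.random.default_rng(7))
        b = generate_atomic_sequence([1, 2, 3, 4], np.random.default_rng(7))
        assert a == b

    def test_duplicate_or_empty_stimuli_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_atomic_sequence([1, 1, 2, 3], np.random.default_rng(0))
        with pytest.raises(ValueError, match="non-empty"):
            generate_atomic_sequence([], np.random.default_rng(0))

    def test_order_varies_across_draws(self):
        rng = np.random.default_rng(2)
        draws = {tuple(generate_atomic_sequence([0, 1, 2, 3], rng)) for _ in range(200)}
        assert len(draws) > 50


class TestBlockDesign:
    @pytest.mark.parametrize(
        "condition,experiment,n_trials,n_items,item_s",
        [
            ("easy", "exp1", 16, 4, 2.0),
            ("difficult", "exp1", 16, 10, 1.0),
            ("learning", "exp2", 32, 4, 2.0),
            ("control", "exp2", 32, 4, 2.0),
        ],
    )
    def test_trial_and_instruction_counts(self, condition, experiment, n_trials, n_items, item_s):
        rng = np.random.default_rng(3)
        pool = list(range(20))
        block = generate_block_design(condition, experiment, pool, rng)
        trials = block.implementation_events
        assert len(trials) == n_trials
        items = [e for e in block.events if e.phase == "instruction"]
        assert len(items) == n_items
        assert all(e.duration_s == item_s for e in items)
        assert len(block.implemented) == 4

    def test_stages_span_eight_trials_each(self):
        block = generate_block_design("learning", "exp2", list(range(4)), np.random.default_rng(4))
        stages = [e.stage for e in block.implementation_events]
        assert sorted(set(stages)) == [1, 2, 3, 4]
        for s in (1, 2, 3, 4):
            assert stages.count(s) == 8
        # stage trials are contiguous under the atomic scheme
        for s in (1, 2, 3, 4):
            idx = [i for i, x in enumerate(stages) if x == s]
            assert idx == list(range(min(idx), min(idx) + 8))

    def test_stage_is_ceil_of_half_repetition(self):
        block = generate_block_design("easy", "exp1", list(range(4)), np.random.default_rng(5))
        for e in block.implementation_events:
            assert e.stage == (e.repetition + 1) // 2
            if e.repetition == 3:
                assert e.stage == 2

    def test_soas_drawn_from_the_five_levels(self):
        block = generate_block_design("easy", "exp1", list(range(4)), np.random.default_rng(6))
        trials = block.implementation_events
        announce_end = [e for e in block.events if e.phase == "announce"][1]
        prev = announce_end.onset_s + announce_end.duration_s
        for e in trials:
            assert e.onset_s - prev in SOA_LEVELS_S
            prev = e.onset_s

    def test_response_map_uses_requested_response_count(self):
        rng = np.random.default_rng(7)
        for n_resp in (2, 3):
            block = generate_block_design(
                "difficult", "exp1", list(range(10)), rng, n_responses=n_resp
            )
            assert len(set(block.response_map.values())) == n_resp
            assert len({block.response_map[s] for s in block.implemented}) == n_resp

    def test_control_blocks_flag_response_cues(self):
        rng = np.random.default_rng(8)
        assert generate_block_design("control", "exp2", list(range(4)), rng).response_cued
        assert not generate_block_design("learning", "exp2", list(range(4)), rng).response_cued

    def test_invalid_condition_experiment_combination(self):
        with pytest.raises(ValueError, match="not part of"):
            generate_block_design("learning", "exp1", list(range(4)), np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown experiment"):
            generate_block_design("easy", "exp3", list(range(4)), np.random.default_rng(0))

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError, match="pool too small"):
            generate_block_design("difficult", "exp1", list(range(6)), np.random.default_rng(0))


class TestExperimentDesign:
    @pytest.mark.parametrize(
        "experiment,blocks_per_run,trials_per_run",
        [("exp1", 12, 192), ("exp2", 8, 256)],
    )
    def test_run_structure(self, experiment, blocks_per_run, trials_per_run):
        d = generate_experiment_design(experiment, 10)
        assert d.n_runs == 3
        for r in range(3):
            assert len(d.run_blocks(r)) == blocks_per_run
            assert d.n_implementation_trials(r) == trials_per_run
        d.validate()

    def test_same_seed_gives_identical_designs_event_by_event(self):
        a = generate_experiment_design("exp2", 99)
        b = generate_experiment_design("exp2", 99)
        pd.testing.assert_frame_equal(a.events_table(), b.events_table())

    def test_phase_delays_exactly_balanced_per_condition(self):
        d = generate_experiment_design("exp1", 11)
        ev = d.events_table()
        for cond in ("easy", "difficult"):
            pre = []
            for block in [b for b in d.blocks if b.condition == cond]:
                run_ev = ev[ev["run"] == block.run_index]
                announce = block.events[0]
                prev_end = run_ev[run_ev["onset"] < announce.onset_s]
                start = float((prev_end["onset"] + prev_end["duration"]).max()) \
                    if len(prev_end) else 0.0
                pre.append(announce.onset_s - start)
            assert sorted(set(pre)) == [2.0, 4.0]
            assert pre.count(2.0) == pre.count(4.0)

    def test_no_stimulus_reuse_across_blocks(self):
        d = generate_experiment_design("exp1", 12)
        seen = set()
        for block in d.blocks:
            assert not (set(block.stimulus_set) & seen)
            seen |= set(block.stimulus_set)

    def test_response_counts_equally_distributed_within_condition(self):
        d = generate_experiment_design("exp2", 13)
        for cond in ("learning", "control"):
            counts = [len(set(b.response_map.values()))
                      for b in d.blocks if b.condition == cond]
            assert counts.count(2) == counts.count(3)

    def test_events_tsv_round_trip(self, tmp_path):
        d = generate_experiment_design("exp1", 14, n_runs=1, blocks_per_condition=1)
        ev = d.events_table()
        design.write_events(ev, tmp_path / "events.tsv")
        back = design.read_events(tmp_path / "events.tsv")
        pd.testing.assert_frame_equal(ev, back, check_dtype=False)

    def test_uneven_run_split_rejected(self):
        with pytest.raises(ValueError):
            generate_experiment_design("exp1", 0, blocks_per_condition=5, n_runs=3)


def _isolated_block(n_trials=16, spacing=35.0):
    """Hand-built block whose trials never overlap (no bias expected)."""
    events, t = [], 2.0
    stimuli = [0, 1, 2, 3]
    rep = {s: 0 for s in stimuli}
    rng = np.random.default_rng(0)
    order = []
    for _ in range(n_trials // 8):
        order.extend(generate_atomic_sequence(stimuli, rng))
    for s in order:
        rep[s] += 1
        events.append(
            TrialEvent(
                run_index=0, block_index=0, condition="easy", phase="implementation",
                onset_s=t, duration_s=1.0, stimulus_id=s, repetition=rep[s],
                stage=(rep[s] + 1) // 2, instructed_response=0,
            )
        )
        t += spacing
    return BlockDesign(
        condition="easy", experiment="exp1", stimulus_set=stimuli, implemented=stimuli,
        response_map={s: 0 for s in stimuli}, n_repetitions=4, events=events,
    )


class TestSequenceBias:
    def test_isolated_trials_have_no_bias(self):
        block = _isolated_block()
        cfg = glm.GlmConfig(hpf_cutoff_s=np.inf)
        est = estimate_sequence_bias(block, cfg, n_mc=150, rng=1)
        assert np.all(np.abs(est.bias) < 3 * est.se + 1e-12)

    def test_requires_minimum_monte_carlo_draws(self):
        block = _isolated_block()
        with pytest.raises(ValueError, match="n_mc"):
            estimate_sequence_bias(block, glm.GlmConfig(), n_mc=10, rng=0)

    def test_fixed_overlapping_sequence_bias_reproduced_by_linear_map_oracle(self):
        # one fixed sequence at tight SOA: nonzero per-stage bias, and the
        # LSS-linear-map route reproduces the full-refit route within MC error
        rng = np.random.default_rng(21)
        block = generate_block_design("easy", "exp1", list(range(4)), rng)
        cfg = glm.default_glm_config("exp1")
        full = estimate_sequence_bias(block, cfg, n_mc=300, rng=5)
        fast = bias_from_linear_map(block, cfg, n_mc=300, rng=6)
        se = np.sqrt(full.se**2 + fast.se**2)
        assert np.all(np.abs(full.bias - fast.bias) < 4 * se)
        assert np.any(np.abs(full.bias) > 2 * full.se)  # overlap does induce bias
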