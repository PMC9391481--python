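"""Outcome classification and the sweep runners."""

import numpy as np
import pytest

from pasim import (
    LesionConfig,
    ThresholdSchedule,
    Trajectory,
    classify_outcome,
    noisy_probe,
    run_bottom_up_impairment,
    run_combined_necrosis,
    run_simulation,
    run_threshold_fluctuation,
)
from pasim.experiments import LABELS, classify_series


class TestClassifySeries:
    # match-index series are the classifier's sole input, so the label
    # rules can be checked on constructed series directly
    def test_immediate_and_sustained_match_is_veridical(self):
        match = np.full(40, 3)
        assert classify_series(match, 3, sustain=5)[0] == "veridical"

    def test_short_excursion_does_not_flip_label(self):
        match = np.full(40, 3)
        match[10:13] = -1  # 3 steps < sustain
        label, final, conv = classify_series(match, 3, sustain=5)
        assert label == "veridical"
        assert final == 3 and conv == 13

    def test_sustained_early_error_then_recovery(self):
        match = np.concatenate([np.full(12, -1), np.full(28, 3)])
        assert (
            classify_series(match, 3, sustain=5)[0]
            == "transient-error-then-veridical"
        )

    def test_pinned_on_wrong_cycle_is_hallucination(self):
        match = np.full(40, 7)
        label, final, _ = classify_series(match, 3, sustain=5)
        assert label == "hallucination-like"
        assert final == 7

    def test_transient_wrong_percept_is_hallucination(self):
        # sustained wrong match in the middle, nothing at the end
        match = np.full(40, -1)
        match[10:20] = 5
        assert classify_series(match, 3, sustain=5)[0] == "hallucination-like"

    def test_alternating_subthreshold_is_non_convergent(self):
        match = np.tile([-1, 2, -1, 4], 10)
        assert classify_series(match, 3, sustain=5)[0] == "non-convergent"

    def test_wrong_run_must_be_one_cycle(self):
        # 5 consecutive wrong-but-different percepts are not a sustained
        # wrong percept
        match = np.full(40, -1)
        match[10:15] = [2, 4, 2, 4, 2]
        assert classify_series(match, 3, sustain=5)[0] == "non-convergent"

    @pytest.mark.parametrize("seed", range(5))
    def test_classification_is_total(self, seed):
        rng = np.random.default_rng(seed)
        match = rng.integers(-1, 4, size=60)
        label, _, _ = classify_series(match, 0, sustain=4)
        assert label in LABELS

    def test_too_short_trajectory_rejected(self):
        from pasim.errors import ConsistencyError

        with pytest.raises(ConsistencyError):
            classify_series(np.array([1, 1]), 1, sustain=5)


class TestClassifyOutcome:
    def test_basin_probe_on_intact_network_is_veridical(self, small_model):
        ps, w = small_model
        rng = np.random.default_rng(2)
        probe = noisy_probe(ps, 1, 0, 0.05, rng)
        traj = run_simulation(probe, 30, w)
        report = classify_outcome(traj, ps, 1)
        assert report.label == "veridical"
        assert report.final_cycle == 1

    def test_pinned_antipercept_trajectory(self, small_model):
        # a trajectory frozen at another cycle's state is hallucination
        ps, _ = small_model
        states = np.tile(ps.state(0, 0), (31, 1))
        traj = Trajectory(states=states)
        report = classify_outcome(traj, ps, input_cycle=1)
        assert report.label == "hallucination-like"
        assert report.final_cycle == 0


class TestControlInvariance:
    def test_no_lesion_control_never_hallucinates(self, default_model):
        # at realistic size the intact network re-forms the percept from
        # every stimulus-onset probe, for any probe-noise seed
        ps, _, w = default_model
        for seed in (0, 1):
            res = run_bottom_up_impairment(
                ps, w, 2100, n_config=2, seed=seed, steps=50,
            )
            assert (res.records.label == "veridical").all()


class TestSweeps:
    def test_frequencies_sum_to_one(self, small_model):
        ps, w = small_model
        res = run_bottom_up_impairment(
            ps, w, 40, n_config=3, seed=5, steps=30
        )
        total = res.frequencies[list(LABELS)].sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_sweep_reproducible_for_fixed_seed(self, small_model):
        ps, w = small_model
        a = run_bottom_up_impairment(ps, w, 40, n_config=3, seed=5, steps=30)
        b = run_bottom_up_impairment(ps, w, 40, n_config=3, seed=5, steps=30)
        assert a.records.equals(b.records)

    def test_single_cell_single_config_frequencies_are_zero_or_one(
        self, small_model
    ):
        ps, w = small_model
        grid = [("cell", LesionConfig(fan_in={"P<-V+M": 40}))]
        res = run_combined_necrosis(
            ps, w, grid, n_config=1, n_probe=1, seed=0, steps=30
        )
        vals = res.frequencies[list(LABELS)].to_numpy()
        assert np.isin(vals, (0.0, 1.0)).all()

    def test_no_lesion_grid_cell_is_fully_veridical(self, default_model):
        ps, _, w = default_model
        grid = [("control", LesionConfig())]
        res = run_combined_necrosis(
            ps, w, grid, n_config=2, seed=1, steps=50
        )
        row = res.frequencies.iloc[0]
        assert row["veridical"] == 1.0
        assert (
            (res.typical["cell"] == "control")
            & (res.typical["label"] == "veridical")
        ).any()

    def test_zero_amplitude_schedule_reduces_to_lesion_only(
        self, small_model
    ):
        ps, w = small_model
        les = LesionConfig(fan_in={"P<-V+M": 30})
        flat = run_threshold_fluctuation(
            ps, w, ThresholdSchedule.perceiving(0.0, 20), n_probe=4,
            seed=3, lesion=les, phases=range(0, 20, 5), steps=30,
        )
        base = run_threshold_fluctuation(
            ps, w, ThresholdSchedule({}), n_probe=4, seed=3, lesion=les,
            phases=[0], steps=30,
        )
        for phase in (0, 5, 10, 15):
            sub = flat.records[flat.records.phase == phase]
            assert sub.label.tolist() == base.records.label.tolist()


class TestStructuredVsRandomDamage:
    def test_targeted_pruning_hallucinates_at_least_as_much_as_diffuse(
        self, default_model
    ):
        # same number of pruned connections, concentrated on the
        # perceiving module's bottom-up inputs vs spread uniformly over
        # all projections: diffuse damage degrades gracefully
        ps, _, w = default_model
        lay = ps.layout
        targeted = LesionConfig(fan_in={"P<-V+M": 525})
        removed = (2100 - 525) * lay.n_perceiving
        frac = removed / (lay.N * lay.N)
        diffuse = LesionConfig(
            fan_in={
                f"{tgt}<-V+M+P": int(round(lay.N * (1 - frac)))
                for tgt in ("V", "M", "P")
            }
        )
        res = run_combined_necrosis(
            ps, w,
            [("targeted", targeted), ("diffuse", diffuse)],
            n_config=3, n_probe=ps.K, seed=21,
        )
        freq = res.frequencies.set_index("cell")
        bad = ["hallucination-like", "transient-error-then-veridical",
               "non-convergent"]
        assert (
            freq.loc["targeted", bad].sum()
            >= freq.loc["diffuse", bad].sum()
        )
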