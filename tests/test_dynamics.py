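"""Synchronous update, cycle detection, overlaps, probes."""

import numpy as np
import pytest

from pasim import (
    InputSignal,
    NetworkState,
    Trajectory,
    detect_cycle,
    noisy_probe,
    overlap,
    run_simulation,
    stimulus_onset_probe,
    update_state,
)
from pasim.learning import WeightMatrix
from pasim.dynamics import step_states


class TestUpdate:
    def test_embedded_state_advances_one_phase(self, tiny_model):
        ps, w = tiny_model
        for mu in range(ps.K):
            for lam in range(ps.L):
                out = update_state(NetworkState(ps.state(mu, lam)), w)
                assert np.array_equal(out.s, ps.state(mu, lam + 1))
                assert out.t == 1

    def test_sign_convention_zero_field_gives_plus_one(self, tiny_ps):
        # all-zero weighted field with zero threshold: sgn(0) = +1
        N = tiny_ps.layout.N
        w = WeightMatrix(
            w=np.zeros((N, N)), block_index={}, source_patterns=tiny_ps
        )
        s = NetworkState(-np.ones(N, dtype=np.int8))
        out = update_state(s, w)
        assert (out.s == 1).all()

    def test_hand_computed_three_neuron_net(self):
        # field = (eps*W) s - theta, by hand with s = [1, -1, 1]:
        #   neuron 0: 1 + 0.5 + 1              =  2.5        -> +1
        #   neuron 1: masked first input, -0.5 - 0.2 = -0.7  -> -1
        #   neuron 2: 0.25 + 0.5 + 0.75 - 1.5  =  0          -> +1 (sgn 0)
        W = np.array(
            [[1.0, -0.5, 1.0], [2.0, 0.0, -0.5], [0.25, -0.5, 0.75]]
        )
        eps = np.array([[1, 1, 1], [0, 1, 1], [1, 1, 1]], dtype=np.uint8)
        s = np.array([1, -1, 1], dtype=np.int8)
        theta = np.array([0.0, 0.2, 1.5])
        out = step_states(s[None, :], W * eps, theta=theta)[0]
        assert out.tolist() == [1, -1, 1]

    def test_dimension_mismatch_rejected(self, tiny_model):
        ps, w = tiny_model
        from pasim.errors import ConsistencyError

        with pytest.raises(ConsistencyError):
            update_state(NetworkState(np.ones(7, dtype=np.int8)), w)


class TestRunSimulation:
    def test_orbit_has_period_L(self, tiny_model):
        ps, w = tiny_model
        traj = run_simulation(NetworkState(ps.state(1, 0)), 4 * ps.L, w)
        assert np.array_equal(traj.states[ps.L], traj.states[0])
        assert detect_cycle(traj, max_period=2 * ps.L) == (ps.L, 0)

    def test_minimal_run_records_two_states(self, tiny_model):
        ps, w = tiny_model
        traj = run_simulation(NetworkState(ps.state(0, 0)), 1, w)
        assert len(traj) == 2

    def test_deterministic(self, small_model):
        ps, w = small_model
        probe = noisy_probe(ps, 0, 0, 0.1, np.random.default_rng(3))
        a = run_simulation(probe, 20, w)
        b = run_simulation(
            NetworkState(probe.s.copy(), probe.t), 20, w
        )
        assert np.array_equal(a.states, b.states)

    def test_persistent_input_pins_visual_block(self, tiny_model):
        # input far above any weighted field forces V to sgn(q)
        ps, w = tiny_model
        q = ps.block(0, 0, "V").astype(float)
        c = float(np.abs(w.w).sum(axis=1).max()) + 1.0
        sig = InputSignal(q=q, mode="persistent", strength=c, duration=5)
        rng = np.random.default_rng(0)
        start = NetworkState(
            rng.choice(np.array([-1, 1], dtype=np.int8), size=ps.layout.N)
        )
        traj = run_simulation(start, 5, w, input_signal=sig)
        v = ps.layout.block("V")
        for k in range(1, 6):
            assert np.array_equal(
                traj.states[k, v], ps.block(0, 0, "V")
            )


class TestDetectCycle:
    def _traj(self, rows):
        return Trajectory(states=np.array(rows, dtype=np.int8))

    def test_constant_trajectory_is_period_one(self):
        t = self._traj([[1, -1]] * 5)
        assert detect_cycle(t, 3) == (1, 0)

    def test_alternating_trajectory(self):
        a, b = [1, 1], [-1, 1]
        t = self._traj([a, b, a, b, a, b])
        assert detect_cycle(t, 4) == (2, 0)

    def test_transient_then_cycle_reports_onset(self):
        a, b, c = [1, 1], [-1, 1], [1, -1]
        t = self._traj([c, a, b, a, b, a])
        assert detect_cycle(t, 4) == (2, 1)

    def test_no_repetition_returns_none(self):
        t = self._traj([[1, 1], [-1, 1], [1, -1], [-1, -1]])
        assert detect_cycle(t, 3) is None


class TestOverlap:
    def test_self_overlap_is_one(self, tiny_model):
        ps, _ = tiny_model
        s = NetworkState(ps.state(1, 2))
        for module in ("V", "M", "P"):
            m = overlap(s, ps, module)
            assert m[ps.row(1, 2)] == pytest.approx(1.0)

    def test_antipattern_overlap_is_minus_one(self, tiny_model):
        ps, _ = tiny_model
        s = NetworkState(-ps.state(1, 2))
        m = overlap(s, ps, "M")
        assert m[ps.row(1, 2)] == pytest.approx(-1.0)

    def test_random_state_has_small_overlap(self, default_model):
        ps, _, _ = default_model
        rng = np.random.default_rng(123)
        for _ in range(5):
            s = NetworkState(
                rng.choice(np.array([-1, 1], dtype=np.int8), size=ps.layout.N)
            )
            # binomial tail: |m| < 0.2 at n=900 except with prob < 1e-3
            assert np.abs(overlap(s, ps, "V")).max() < 0.2

    def test_dead_neurons_excluded_from_normalization(self, tiny_model):
        ps, _ = tiny_model
        from pasim import LesionConfig, make_lesion

        mask = make_lesion(
            LesionConfig(dead_counts={"P": 2}), ps.layout, seed=4
        )
        s = ps.state(0, 0).copy()
        s[mask.dead] = -1
        m = overlap(NetworkState(s), ps, "P", mask)
        assert m[0] == pytest.approx(1.0)


class TestProbes:
    def test_noisy_probe_flips_exact_visual_count(self, default_model):
        ps, _, _ = default_model
        rng = np.random.default_rng(0)
        probe = noisy_probe(ps, 4, 0, 0.05, rng)
        ref = ps.state(4, 0)
        v = ps.layout.block("V")
        assert (probe.s[v] != ref[v]).sum() == 45
        assert np.array_equal(probe.s[v.stop :], ref[v.stop :])

    def test_onset_probe_randomizes_percept_keeps_memory(self, default_model):
        ps, _, _ = default_model
        rng = np.random.default_rng(1)
        probe = stimulus_onset_probe(ps, 2, 0, 0.05, rng)
        ref = ps.state(2, 0)
        m_sl, p_sl = ps.layout.block("M"), ps.layout.block("P")
        assert np.array_equal(probe.s[m_sl], ref[m_sl])
        # random perceiving block: far from the embedded pattern
        agree = (probe.s[p_sl] == ref[p_sl]).mean()
        assert 0.3 < agree < 0.7
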