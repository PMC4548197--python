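"""Dynamics engine: update rule, clamping, gates, batch equivalence."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apoptonet.dynamics import batch_simulate, simulate, step
from apoptonet.network import EdgeSpec, GateRule, NetworkSpec, VertexSpec
from apoptonet.synthetic import GeneratorConfig, fixture_networks, random_network


def two_chain():
    return NetworkSpec(
        (VertexSpec("A", 0, is_input=True), VertexSpec("B", 1)),
        (EdgeSpec("A", "B", +1),), name="chain")


class TestStep:
    def test_absorbing_zero_on_self_degrading_network(self, fixtures):
        net = fixtures["selfdeg1"]
        traj = simulate([0], {}, net, steps=3)
        assert all(s.bits == (0,) for s in traj.states)

    def test_activation_propagates_in_one_step(self):
        traj = simulate([1, 0], {"A": 1}, two_chain(), steps=2)
        assert traj.states[1].bits == (1, 1)

    def test_clamped_vertex_never_deviates(self):
        traj = simulate([0, 1], {"A": 0}, two_chain(), steps=5)
        assert all(s.bits[0] == 0 for s in traj.states)

    def test_hold_on_zero_input_for_regular_vertex(self):
        # B has no active regulator input (A OFF) and is not self-degrading
        traj = simulate([0, 1], {"A": 0}, two_chain(), steps=3)
        assert all(s.bits[1] == 1 for s in traj.states)

    def test_self_degradation_decays_on_zero_input(self):
        net = NetworkSpec(
            (VertexSpec("A", 0, is_input=True),
             VertexSpec("B", 1, is_self_degrading=True)),
            (EdgeSpec("A", "B", +1),), name="sdchain")
        traj = simulate([0, 1], {"A": 0}, net, steps=2)
        assert traj.states[1].bits[1] == 0

    def test_constitutive_vertex_on_unless_inhibited(self):
        net = NetworkSpec(
            (VertexSpec("A", 0, is_input=True),
             VertexSpec("B", 1, is_self_degrading=True, is_constitutive=True)),
            (EdgeSpec("A", "B", -1),), name="constitutive")
        on = simulate([0, 0], {"A": 0}, net, steps=2)
        assert on.states[1].bits[1] == 1
        off = simulate([0, 1], {"A": 1}, net, steps=2)
        assert off.states[1].bits[1] == 0

    def test_step_matches_simulate(self, fixtures):
        net = fixtures["apoptosis_motif"]
        traj = simulate([1, 1, 0, 0], {"STRESS": 1}, net, steps=4)
        s = traj.states[0]
        for t in range(4):
            s = step(s, net)
            assert s.bits == traj.states[t + 1].bits


class TestGates:
    def test_gate_delays_contribution(self, fixtures):
        # IN -> A -> B with threshold-2 gate on A -> B: B must wait one
        # extra step for A's run to reach 2.
        net = fixtures["gated_chain"]
        traj = simulate([1, 0, 0], {"IN": 1}, net, steps=4)
        bits = [s.bits for s in traj.states]
        assert [b[1] for b in bits[:3]] == [0, 1, 1]   # A: rises at t=1
        assert [b[2] for b in bits] == [0, 0, 0, 1, 1]  # B: waits for run>=2

    def test_ungated_chain_is_faster(self):
        net = NetworkSpec(
            (VertexSpec("IN", 0, is_input=True),
             VertexSpec("A", 1, is_self_degrading=True),
             VertexSpec("B", 2, is_self_degrading=True)),
            (EdgeSpec("IN", "A", +1), EdgeSpec("A", "B", +1)),
            name="ungated_chain")
        traj = simulate([1, 0, 0], {"IN": 1}, net, steps=4)
        assert [s.bits[2] for s in traj.states] == [0, 0, 1, 1, 1]

    def test_counter_resets_on_off_step(self, fixtures):
        net = fixtures["gated_chain"]
        # A initially ON with IN off: A decays, its run resets, B never fires
        traj = simulate([0, 1, 0], {"IN": 0}, net, steps=4)
        assert all(s.bits[2] == 0 for s in traj.states)

    def test_initially_on_counts_as_run_one(self, fixtures):
        net = fixtures["gated_chain"]
        traj = simulate([1, 1, 0], {"IN": 1}, net, steps=3)
        # run reaches 2 at t=1, so B fires in the t=1 -> t=2 update
        assert [s.bits[2] for s in traj.states] == [0, 0, 1, 1]


class TestPreconditions:
    def test_zero_steps_rejected(self, fixtures):
        with pytest.raises(ValueError, match="steps"):
            simulate([0], {}, fixtures["selfdeg1"], steps=0)

    def test_dimension_mismatch_rejected(self, fixtures):
        with pytest.raises(ValueError):
            simulate([0, 1], {}, fixtures["selfdeg1"], steps=1)

    def test_missing_input_clamp_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            simulate([0, 0], {}, two_chain(), steps=1)


class TestBatchEquivalence:
    def test_exhaustive_tiny_network(self):
        net = two_chain()
        block = np.array([[a, b] for a in (0, 1) for b in (0, 1)], dtype=np.int8)
        out = batch_simulate(block, {"A": 1}, net, steps=4)
        for i, bits in enumerate(block):
            traj = simulate(bits, {"A": 1}, net, steps=4)
            assert (out[:, i, :] == traj.bit_matrix()).all()

    def test_single_state_block(self, fixtures):
        net = fixtures["apoptosis_motif"]
        out = batch_simulate(np.array([[1, 0, 1, 0]], dtype=np.int8),
                             {"STRESS": 1}, net, steps=6)
        traj = simulate([1, 0, 1, 0], {"STRESS": 1}, net, steps=6)
        assert (out[:, 0, :] == traj.bit_matrix()).all()

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000), data=st.data())
    def test_random_network_block_matches_serial(self, seed, data):
        cfg = GeneratorConfig(n_vertices=10, n_edges=18, n_inputs=1,
                              n_gates=2, seed=seed)
        net = random_network(cfg)
        clamps = {n: 1 for n in net.input_names}
        rng = np.random.default_rng(seed)
        block = rng.integers(0, 2, size=(16, net.n), dtype=np.int8)
        out = batch_simulate(block, clamps, net, steps=8)
        row = data.draw(st.integers(0, 15))
        traj = simulate(block[row], clamps, net, steps=8)
        assert (out[:, row, :] == traj.bit_matrix()).all()


class TestApoptosisMotifTable:
    """Full hand-enumerated transition table of the 4-vertex motif.

    Vertices: STRESS (clamped input), P (constitutive protector,
    self-degrading, inhibited by stress), D (effector, driven by stress
    against P), R (readout copying D).  One synchronous step maps
    (P, D, R) to:

    * STRESS = 1:  P' = 0,       D' = not P,  R' = D
    * STRESS = 0:  P' = 1,       D' = 0,      R' = D
    """

    @pytest.mark.parametrize("stress", [0, 1])
    @pytest.mark.parametrize("p,d,r", [(p, d, r) for p in (0, 1)
                                       for d in (0, 1) for r in (0, 1)])
    def test_successor(self, fixtures, stress, p, d, r):
        net = fixtures["apoptosis_motif"]
        traj = simulate([stress, p, d, r], {"STRESS": stress}, net, steps=1)
        expected = ((stress, 0, 1 - p, d) if stress else (stress, 1, 0, d))
        assert traj.states[1].bits == expected


class TestDeterminism:
    def test_identical_runs(self, fixtures):
        net = fixtures["apoptosis_motif"]
        a = simulate([0, 1, 1, 0], {"STRESS": 1}, net, steps=8)
        b = simulate([0, 1, 1, 0], {"STRESS": 1}, net, steps=8)
        assert [s.bits for s in a.states] == [s.bits for s in b.states]
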