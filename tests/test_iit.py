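"""IIT engine behavior on hand-analyzable networks.

Exhaustive oracle-equivalence against the brute-force enumeration oracle
lives in the acceptance suite; these tests cover closed-form cases,
axioms (reducibility, nonnegativity, symmetry) and the time-average.
"""

import itertools

import numpy as np
import pytest

from rsnphi import (GroundTruthNetwork, StateByNodeTPM, make_coupled_tpm,
                    mu_phi_max, phi_max, simulate_binary_series, system_phi)
from rsnphi.iit import Subsystem, emd, emd_hamming, hamming_matrix
from rsnphi.states import index_to_state, sbs_to_sbn


def copy_loop_tpm():
    """Two nodes that deterministically copy each other every step."""
    probs = np.zeros((4, 2))
    for state in range(4):
        n0, n1 = state & 1, (state >> 1) & 1
        probs[state] = [n1, n0]
    return StateByNodeTPM(probs)


def fair_coins_tpm(n):
    return StateByNodeTPM(np.full((2**n, n), 0.5))


class TestEmd:
    def test_identical_distributions(self, rng):
        p = rng.random(8)
        p /= p.sum()
        assert emd_hamming(p, p, 3) == 0.0

    def test_point_masses_two_bits_apart(self):
        p = np.zeros(8)
        q = np.zeros(8)
        p[0b000] = 1.0
        q[0b101] = 1.0
        assert emd_hamming(p, q, 3) == pytest.approx(2.0, abs=1e-12)

    def test_metric_properties(self, rng):
        for _ in range(20):
            p, q, r = rng.random((3, 8))
            p, q, r = p / p.sum(), q / q.sum(), r / r.sum()
            dpq = emd_hamming(p, q, 3)
            assert dpq == pytest.approx(emd_hamming(q, p, 3), abs=1e-10)
            assert dpq <= (emd_hamming(p, r, 3) + emd_hamming(r, q, 3)
                           + 1e-10)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="normalized"):
            emd(np.array([0.5, 0.2]), np.array([0.5, 0.5]),
                hamming_matrix(1))


class TestRepertoires:
    def test_deterministic_self_copy_pins_past(self):
        """A node copying itself, currently ON, must have been ON."""
        probs = np.zeros((4, 2))
        for state in range(4):
            probs[state] = [state & 1, 0.5]   # node0 copies itself
        sub = Subsystem(StateByNodeTPM(probs), (1, 0))
        rep = sub.cause_repertoire((0,), (0,))
        assert np.allclose(rep, [0.0, 1.0])
        eff = sub.effect_repertoire((0,), (0,))
        assert np.allclose(eff, [0.0, 1.0])

    def test_fair_coins_all_uniform(self):
        sub = Subsystem(fair_coins_tpm(3), (1, 0, 1))
        for r in range(1, 4):
            for mech in itertools.combinations(range(3), r):
                for pur in itertools.combinations(range(3), r):
                    assert np.allclose(sub.cause_repertoire(mech, pur),
                                       1 / 2 ** len(pur))
                    assert np.allclose(sub.effect_repertoire(mech, pur),
                                       1 / 2 ** len(pur))

    def test_two_node_and_gate_bayes(self):
        """Cause repertoire of an AND-like unit equals explicit Bayes."""
        # node0 next = AND of both current nodes; node1 is a fair coin
        probs = np.array([[0.0, 0.5], [0.0, 0.5], [0.0, 0.5], [1.0, 0.5]])
        sub = Subsystem(StateByNodeTPM(probs), (1, 1))
        rep = sub.cause_repertoire((0,), (0, 1))
        # P(node0 on | past) = [0, 0, 0, 1] -> posterior mass all on (1,1)
        assert np.allclose(rep, [0, 0, 0, 1])
        rep_off = Subsystem(StateByNodeTPM(probs), (0, 1)).cause_repertoire(
            (0,), (0, 1))
        assert np.allclose(rep_off, [1 / 3, 1 / 3, 1 / 3, 0])

    def test_zero_probability_conditioning_falls_back_to_uniform(self):
        probs = np.column_stack([np.ones(4), np.full(4, 0.5)])
        sub = Subsystem(StateByNodeTPM(probs), (0, 0))   # node0 OFF: impossible
        rep = sub.cause_repertoire((0,), (0, 1))
        assert np.allclose(rep, 0.25)
        assert sub.uniform_fallbacks == 1


class TestSmallPhiAndConcepts:
    def test_isolated_node_is_reducible(self):
        """With no within-subsystem interaction there are no concepts."""
        sub = Subsystem(fair_coins_tpm(2), (0, 0))
        assert sub.conceptual_structure().concepts == []

    def test_copy_loop_singletons_are_concepts(self):
        sub = Subsystem(copy_loop_tpm(), (1, 1))
        ces = sub.conceptual_structure()
        mechs = {c.mechanism for c in ces.concepts}
        assert (0,) in mechs and (1,) in mechs
        for c in ces.concepts:
            assert c.small_phi > 0

    def test_phi_nonnegative_on_random_tpms(self, rng):
        for _ in range(30):
            tpm = StateByNodeTPM(rng.random((8, 3)))
            state = tuple(rng.integers(0, 2, 3))
            sub = Subsystem(tpm, state)
            for r in range(1, 4):
                for mech in itertools.combinations(range(3), r):
                    assert sub.small_phi(mech, "cause").phi >= 0
                    assert sub.small_phi(mech, "effect").phi >= 0

    def test_concept_count_bound(self, rng):
        tpm = StateByNodeTPM(rng.random((8, 3)))
        ces = Subsystem(tpm, (1, 0, 1)).conceptual_structure()
        assert len(ces.concepts) <= 2**3 - 1


class TestSystemPhi:
    def test_disconnected_halves_reduce(self, rng):
        """A TPM that factorizes across a bipartition has Phi = 0."""
        for n, seed in ((2, 0), (3, 1)):
            tpm = make_coupled_tpm(n, 0.0, seed=seed)
            sbn = sbs_to_sbn(tpm)
            for i in range(2**n):
                assert system_phi(sbn, index_to_state(i, n)) == 0.0

    def test_copy_loop_is_integrated(self):
        assert system_phi(copy_loop_tpm(), (1, 1)) > 0.1

    def test_permutation_invariance(self, rng):
        tpm = rng.random((8, 3))
        state = (1, 0, 1)
        perm = [2, 0, 1]   # new node i is old node perm[i]
        # permute the TPM: rows reindexed by permuted bits, columns reordered
        n = 3
        permuted = np.empty_like(tpm)
        for s in range(8):
            bits = [(s >> k) & 1 for k in range(n)]
            old_state = [0] * n
            for new_i, old_i in enumerate(perm):
                old_state[old_i] = bits[new_i]
            old_idx = sum(b << k for k, b in enumerate(old_state))
            permuted[s] = tpm[old_idx][perm]
        new_state = tuple(state[perm[i]] for i in range(n))
        a = system_phi(StateByNodeTPM(tpm), state)
        b = system_phi(StateByNodeTPM(permuted), new_state)
        assert a == pytest.approx(b, abs=1e-9)


class TestPhiMax:
    def test_exhaustive_at_least_full(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            tpm = StateByNodeTPM(r.random((8, 3)))
            state = tuple(r.integers(0, 2, 3))
            assert phi_max(tpm, state, "exhaustive") >= \
                phi_max(tpm, state, "full") - 1e-12

    def test_exhaustive_equals_subset_enumeration(self, rng):
        tpm = StateByNodeTPM(rng.random((8, 3)))
        state = (0, 1, 1)
        by_hand = max(system_phi(tpm, state, nodes)
                      for size in (2, 3)
                      for nodes in itertools.combinations(range(3), size))
        assert phi_max(tpm, state, "exhaustive") == pytest.approx(
            by_hand, abs=1e-12)

    def test_exhaustive_warns_beyond_five_nodes(self):
        tpm = StateByNodeTPM(np.full((64, 6), 0.5))
        with pytest.warns(UserWarning, match="expensive"):
            phi_max(tpm, (0,) * 6, "exhaustive")


class TestMuPhiMax:
    def test_constant_series_equals_single_state(self):
        from rsnphi import BinaryTimeSeries
        series = BinaryTimeSeries(np.tile([1, 0, 1], (40, 1)),
                                  ["a", "b", "c"])
        res = mu_phi_max(series)
        assert res.mu_phi_max == res.per_state_phi[0b101]
        assert np.isnan(res.per_state_phi[0])

    def test_equal_weights_give_unweighted_mean(self):
        from rsnphi import BinaryTimeSeries
        block = np.array([[0, 0, 0], [1, 1, 1]])
        series = BinaryTimeSeries(np.tile(block, (25, 1)), ["a", "b", "c"])
        res = mu_phi_max(series)
        visited = res.per_state_phi[[0, 7]]
        assert res.mu_phi_max == pytest.approx(visited.mean(), abs=1e-12)

    def test_coupling_direction(self):
        """Strong coupling yields more integration than factorized dynamics."""
        wins = 0
        for seed in range(3):
            coupled = GroundTruthNetwork(
                3, make_coupled_tpm(3, 0.8, seed=seed), 0.8)
            free = GroundTruthNetwork(
                3, make_coupled_tpm(3, 0.0, seed=seed), 0.0)
            mc = mu_phi_max(simulate_binary_series(coupled, 500,
                                                   seed=50 + seed)).mu_phi_max
            mf = mu_phi_max(simulate_binary_series(free, 500,
                                                   seed=50 + seed)).mu_phi_max
            wins += mc > mf
        assert wins >= 2
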