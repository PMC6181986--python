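"""Tests of weight constructors and the recurrent-network stepper."""

import numpy as np
import pytest
from scipy.special import expit

from preplaynet.core_dynamics import NeuronParams
from preplaynet.network import (
    CellEnsemble,
    NetworkConfig,
    RecurrentNetwork,
    build_branching_weights,
    build_chain_weights,
    build_ec_weights,
    build_ymaze_weights,
)
from preplaynet.plasticity import PlasticityParams


class TestChainWeights:
    def test_profile_value_without_noise(self):
        w = build_chain_weights(50, w_max=18.0, w_width=5.0, noise=False)
        assert w[10, 15] == pytest.approx(18.0 * np.exp(-0.5), rel=1e-12)
        assert w[10, 15] == pytest.approx(10.9175, abs=1e-3)

    def test_zero_diagonal_and_nonnegative(self, rng):
        w = build_chain_weights(80, rng=rng)
        assert np.all(np.diag(w) == 0.0) and np.all(w >= 0.0)

    def test_symmetric_without_noise(self):
        w = build_chain_weights(40, noise=False)
        np.testing.assert_array_equal(w, w.T)


class TestECWeights:
    def test_familiar_profile(self):
        w = build_ec_weights(30, 50, w_dnd_max=5.0, w_width=5.0)
        assert w[7, 7] == pytest.approx(5.0)
        assert w[7, 12] == pytest.approx(5.0 * np.exp(-0.5), rel=1e-12)
        assert w[7, 12] == pytest.approx(3.0327, abs=1e-3)

    def test_unfamiliar_rows_are_permutations(self, rng):
        fam = build_ec_weights(20, 40)
        unf = build_ec_weights(20, 40, familiarity="unfamiliar", rng=rng)
        for i in range(20):
            np.testing.assert_allclose(np.sort(fam[i]), np.sort(unf[i]))
        assert not np.allclose(fam, unf)


class TestBranchingWeights:
    def test_branches_disconnected(self, rng):
        w = build_branching_weights(20, 30, rng=rng)
        a = slice(20, 50)
        b = slice(50, 80)
        assert np.all(w[a, b] == 0.0) and np.all(w[b, a] == 0.0)

    def test_junction_coupling_value(self):
        w = build_branching_weights(100, 150, w_prime_max=14.0, w_width=5.0,
                                    noise=False)
        # last root neuron to first neuron of either branch: one step apart
        expected = 14.0 * np.exp(-0.5 * (1 / 5.0) ** 2)
        assert w[99, 100] == pytest.approx(expected, rel=1e-12)
        assert w[99, 250] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(13.72, abs=0.01)

    def test_root_branch_symmetry(self):
        w = build_branching_weights(30, 40, noise=False)
        root = slice(0, 30)
        for br in (slice(30, 70), slice(70, 110)):
            np.testing.assert_array_equal(w[root, br], w[br, root].T)


class TestYmazeWeights:
    def test_block_structure(self, rng):
        w = build_ymaze_weights(20, rng=rng)
        assert np.all(w[:20, 20:] == 0.0) and np.all(w[40:, :40] == 0.0)
        assert w[:20, :20].max() > 0


def _quiet_network(n=20, beta=0.0, gamma=1.0, single=False, seed=0):
    cfg = NetworkConfig(
        n_ca3=n, n_ec=n, n_inh=5, v_som_value=0.0, single_compartment=single,
        neuron=NeuronParams(phi=0.1 if single else 0.08, beta=beta, gamma=gamma),
        plasticity=PlasticityParams(alpha=0.9, eta=0.0, eta_inh=0.0, sigma_w=0.0))
    rng = np.random.default_rng(seed)
    net = RecurrentNetwork(cfg, rng)
    net.weights.w_som[:] = 0.0
    net.weights.w_dnd[:] = 0.0
    return net, rng


class TestNetworkStep:
    def test_zero_network_closed_form(self):
        net, rng = _quiet_network(beta=0.0)
        f0 = expit(-5.0)
        for _ in range(20):
            z = net.step(np.zeros(20), np.zeros(20), rng=rng)
        assert np.allclose(net.x, f0) and np.allclose(net.y, f0)
        assert np.allclose(z, (1 + 1.0 * f0) * 0.08 * f0)

    def test_single_compartment_closed_form(self):
        net, rng = _quiet_network(single=True)
        for _ in range(20):
            z = net.step(np.zeros(20), np.zeros(20), rng=rng)
        assert np.allclose(z, 0.1 * expit(-5.0))
        assert z[0] == pytest.approx(6.693e-4, abs=1e-6)

    def test_rates_bounded(self, rng):
        cfg = NetworkConfig(n_ca3=30, n_ec=30, n_inh=5,
                            neuron=NeuronParams(phi=0.08, beta=2.5, gamma=1.0))
        net = RecurrentNetwork(cfg, rng)
        for _ in range(200):
            z = net.step(rng.uniform(0, 0.08, 30), rng.uniform(-5, 15, 30),
                         running=rng.random() < 0.5, rng=rng)
            assert np.all(z >= 0.0) and np.all(z <= (1 + 1.0) * 0.08 + 1e-12)

    def test_weights_stay_valid_under_plasticity(self, rng):
        cfg = NetworkConfig(n_ca3=25, n_ec=25, n_inh=5,
                            plasticity=PlasticityParams(alpha=0.9, eta=1.0,
                                                        eta_inh=1.0, sigma_w=0.01))
        net = RecurrentNetwork(cfg, rng)
        for _ in range(300):
            net.step(rng.uniform(0, 0.08, 25), rng.uniform(0, 10, 25), rng=rng)
        assert np.all(np.diag(net.weights.w_som) == 0.0)
        assert np.all(net.weights.w_som >= 0.0)
        assert np.all(net.weights.w_dnd >= 0.0)
        assert np.all(net.weights.v_dnd >= 0.0)

    def test_deterministic_given_seed(self):
        outs = []
        for _ in range(2):
            net, _ = _quiet_network(seed=3)
            rng = np.random.default_rng(99)
            cfg_rng = np.random.default_rng(7)
            net.weights.w_som[:] = cfg_rng.uniform(0, 5, (20, 20))
            zs = [net.step(np.zeros(20), cfg_rng.uniform(0, 5, 20), rng=rng).copy()
                  for _ in range(50)]
            outs.append(np.array(zs))
        np.testing.assert_array_equal(outs[0], outs[1])


def _com(z):
    tot = z.sum()
    return (z * np.arange(len(z))).sum() / tot if tot > 1e-9 else np.nan


class TestSequencePropagation:
    def _immobile_run(self, w_scale, seed=5, n=150, steps=1500):
        cfg = NetworkConfig(n_ca3=n, n_ec=n, n_inh=50,
                            w_scale=w_scale,
                            neuron=NeuronParams(phi=0.08, beta=2.5, gamma=1.0),
                            plasticity=PlasticityParams(alpha=0.9, eta=0.0,
                                                        eta_inh=0.0, sigma_w=0.0))
        rng = np.random.default_rng(seed)
        net = RecurrentNetwork(cfg, rng)
        net.weights.w_dnd[:] = 0.0
        ext = np.zeros(n)
        coms, pops = [], []
        for k in range(steps):
            e = ext.copy()
            if k < 10:  # 10-ms trigger on the first ten neurons
                e[:10] = 10.0
                e[10:] = -10.0
            z = net.step(np.zeros(n), e, rng=rng)
            coms.append(_com(z))
            pops.append(z.sum())
        return np.array(coms), np.array(pops)

    def test_trigger_launches_propagating_sequence(self):
        coms, pops = self._immobile_run(w_scale=1.0)
        active = pops > 0.5
        assert active.any()
        seq = coms[active]
        # centre of mass starts near the trigger site and traverses the chain
        assert seq[0] < 30
        assert np.nanmax(seq) > 0.8 * 150
        # overall forward motion
        assert np.nanmean(np.diff(seq) >= -1) > 0.8

    def test_weak_recurrence_degrades_propagation(self):
        """Halving the recurrent weights strongly attenuates and slows the
        triggered sequence (the regime where sequence-guided learning
        breaks down)."""
        c_full, p_full = self._immobile_run(w_scale=1.0)
        c_half, p_half = self._immobile_run(w_scale=0.5)
        assert p_half.max() < 0.55 * p_full.max()

        def speed(coms, pops):
            a = pops > 0.5
            seq = coms[a]
            return (seq[-1] - seq[0]) / a.sum() if a.any() else 0.0

        assert speed(c_half, p_half) < 0.7 * speed(c_full, p_full)


class TestCellEnsemble:
    def test_batched_shapes_and_bounds(self, rng):
        cells = CellEnsemble(3, 2, 10, 20, rng, alpha=0.9, beta=2.5,
                             eta=0.2, eta_inh=0.2, v_som=20.0, inhibition=True)
        for _ in range(100):
            cells.step(rng.uniform(0, 0.08, (3, 10)),
                       rng.uniform(0, 0.08, (3, 20)), 1.0, rng)
        assert cells.x.shape == (3, 2)
        assert np.all((cells.x > 0) & (cells.x < 1))
        assert np.all(cells.w_som >= 0) and np.all(cells.v_dnd >= 0)

    def test_per_trial_parameters_differ(self, rng):
        # alpha=0 trial must evolve differently from alpha=1 trial
        cells = CellEnsemble(2, 1, 10, 10, rng, alpha=np.array([0.0, 1.0]),
                             beta=0.0, eta=1.0, sigma_w=0.0)
        cells.w_som[:] = 1.0
        cells.w_dnd[:] = 1.0
        for _ in range(200):
            u = np.full((2, 10), 0.05)
            cells.step(u, u, 1.0, rng)
        assert not np.allclose(cells.w_som[0], cells.w_som[1])
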