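import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glomnose.glomerular import (
    GlomerularNetwork,
    LearningRates,
    default_class_mask,
    disinhibition_check,
    init_network,
    mc_branch_potentials,
    mc_outputs,
    pg_potentials,
    process_sequence,
    update_weights,
)
from glomnose.sensor_sim import FaultSpec
from tests.conftest import make_uniform_responses

GAMMA_B = 10 ** -0.7


def forward_oracle(net, r):
    """Scalar triple-loop evaluation of m_i = sum_j c_ij r_j prod_k (1 - f_ijk d_ik r_k)."""
    m = np.zeros(net.L)
    for i in range(net.L):
        for j in range(net.N):
            prod = 1.0
            for k in range(net.N):
                prod *= 1.0 - net.f[i, j, k] * net.d[i, k] * r[k]
            m[i] += net.c[i, j] * r[j] * prod
    return m


class TestInit:
    def test_default_mask_structure(self):
        mask = default_class_mask(4, 16)
        assert mask.sum() == 16
        assert np.all(mask.sum(axis=0) == 1)
        net = init_network(seed=0)
        assert np.all(net.c[mask == 0] == 0)
        assert np.count_nonzero(net.c) <= 16

    def test_f_density_zero_disables_inhibition(self):
        net = init_network(f_density=0.0, seed=1)
        assert np.all(net.f == 0)
        r = np.full(16, 0.7)
        p = pg_potentials(net, r)
        mb = mc_branch_potentials(net, r, p)
        np.testing.assert_allclose(mb, net.c * r[None, :], atol=1e-15)

    def test_same_seed_identical_weights(self):
        a, b = init_network(seed=3), init_network(seed=3)
        np.testing.assert_array_equal(a.c, b.c)
        np.testing.assert_array_equal(a.d, b.d)
        np.testing.assert_array_equal(a.f, b.f)

    def test_malformed_mask_rejected(self):
        mask = np.zeros((4, 16), dtype=int)
        mask[0] = 1  # sensors of other classes unassigned
        with pytest.raises(ValueError):
            init_network(class_mask=mask)

    def test_f_zero_for_nonexistent_branches(self):
        net = init_network(seed=5)
        assert np.all(net.f[net.class_mask == 0] == 0)


class TestForwardPass:
    def test_pg_potentials_product(self, random_network):
        net = random_network
        assert np.all(pg_potentials(net, np.zeros(16)) == 0)
        net.d = np.ones_like(net.d)
        r = np.linspace(0, 1, 16)
        np.testing.assert_allclose(pg_potentials(net, r), np.tile(r, (4, 1)))
        net.d[0, 0] = 0.5
        r = np.zeros(16)
        r[0] = 0.8
        assert pg_potentials(net, r)[0, 0] == pytest.approx(0.4)

    def test_input_outside_unit_interval_rejected(self, random_network):
        with pytest.raises(ValueError):
            pg_potentials(random_network, np.full(16, 1.5))

    def test_branch_potential_hand_example(self):
        # single active inhibition term: m = 0.5 * 0.8 * (1 - 0.1*0.4) = 0.384
        mask = np.ones((1, 16), dtype=int)
        c = np.zeros((1, 16)); c[0, 0] = 0.5
        d = np.zeros((1, 16)); d[0, 0] = 0.5
        f = np.zeros((1, 16, 16)); f[0, 0, 0] = 0.1
        net = GlomerularNetwork(1, 16, mask, c, d, f)
        r = np.zeros(16); r[0] = 0.8
        p = pg_potentials(net, r)
        assert p[0, 0] == pytest.approx(0.4)
        mb = mc_branch_potentials(net, r, p)
        assert mb[0, 0] == pytest.approx(0.384, abs=1e-15)

    def test_full_inhibition_closed_form(self):
        # f = 0.1 and p = 1 for all 16 inputs: factor 0.9^16
        mask = np.ones((1, 16), dtype=int)
        net = GlomerularNetwork(1, 16, mask, np.full((1, 16), 0.5),
                                np.ones((1, 16)), np.full((1, 16, 16), 0.1))
        r = np.ones(16)
        mb = mc_branch_potentials(net, r, pg_potentials(net, r))
        np.testing.assert_allclose(mb, 0.5 * 0.9 ** 16, rtol=1e-12)

    def test_mc_output_is_branch_sum(self):
        mb = np.array([[0.1, 0.2, 0.3, 0.4]])
        assert mc_outputs(mb)[0] == pytest.approx(1.0)
        assert np.all(mc_outputs(np.zeros((4, 16))) == 0)

    def test_unit_weights_give_replica_count(self):
        mask = default_class_mask(4, 16)
        net = GlomerularNetwork(4, 16, mask, mask.astype(float),
                                np.zeros((4, 16)), np.zeros((4, 16, 16)))
        r = np.ones(16)
        m = mc_outputs(mc_branch_potentials(net, r, pg_potentials(net, r)))
        np.testing.assert_allclose(m, 4.0)

    def test_vectorized_matches_triple_loop(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            net = init_network(seed=trial)
            r = rng.uniform(0, 1, 16)
            m = mc_outputs(mc_branch_potentials(net, r, pg_potentials(net, r)))
            np.testing.assert_allclose(m, forward_oracle(net, r), atol=1e-12)


class TestAdaptation:
    def test_pure_decay_matches_closed_recurrence(self):
        net = init_network(seed=0)
        net.c[:] = net.class_mask.astype(float)  # start every branch at 1
        r = np.zeros(16)
        cs = [net.c[0, 0]]
        for _ in range(50):
            p = pg_potentials(net, r)
            mb = mc_branch_potentials(net, r, p)
            net = update_weights(net, r, mb, p)
            cs.append(net.c[0, 0])
        expect = 1.0
        for t in range(1, 51):
            expect = expect - GAMMA_B * expect ** 2
            assert cs[t] == pytest.approx(expect, abs=1e-12)
        assert cs[1] == pytest.approx(0.8005, abs=1e-4)
        assert cs[2] == pytest.approx(0.6727, abs=1e-4)

    def test_zero_weight_zero_drive_is_fixed_point(self):
        net = init_network(seed=1)
        net.c[:] = 0.0
        r = np.zeros(16)
        p = pg_potentials(net, r)
        mb = mc_branch_potentials(net, r, p)
        out = update_weights(net, r, mb, p)
        assert np.all(out.c == 0)

    def test_small_weights_decay_slower_than_linear(self):
        c_quad = c_lin = 0.05
        for _ in range(100):
            c_quad = c_quad - GAMMA_B * c_quad ** 2
            c_lin = c_lin - GAMMA_B * c_lin
        assert c_quad > c_lin

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_weight_boxes_hold_after_updates(self, seed):
        rng = np.random.default_rng(seed)
        net = init_network(seed=seed)
        for _ in range(10):
            r = rng.uniform(0, 1, 16)
            p = pg_potentials(net, r)
            mb = mc_branch_potentials(net, r, p)
            net = update_weights(net, r, mb, p)
            assert net.c.min() >= 0 and net.c.max() <= 1
            assert net.d.min() >= 0 and net.d.max() <= 1
            assert np.all(net.c[net.class_mask == 0] == 0)
            np.testing.assert_array_equal(net.f, init_network(seed=seed).f)


class TestProcessSequence:
    def test_static_network_is_a_linear_map(self):
        net = init_network(f_density=0.0, seed=2)
        data = make_uniform_responses(30, seed=3)
        _, trace = process_sequence(net, data, adapt=False)
        np.testing.assert_allclose(trace.mc_outputs, data.values @ net.c.T,
                                   atol=1e-12)

    def test_channel_mismatch_rejected(self):
        net = init_network(L=4, N=16)
        data = make_uniform_responses(10, n_channels=12, seed=0)
        data.channel_class = np.repeat(np.arange(1, 5), 3)
        with pytest.raises(ValueError):
            process_sequence(net, data)

    def test_dropout_decays_weight_and_recovery_follows(self):
        net = init_network(seed=4)
        data = make_uniform_responses(300, seed=5, lo=0.3, hi=0.9)
        fault = FaultSpec(0, 100, 200, "dropout")
        _, trace = process_sequence(net, data, adapt=True, faults=[fault],
                                    record_weights=True)
        c0 = trace.c_trace[:, 0, 0]
        in_fault = c0[100:200]
        assert np.all(np.diff(in_fault) <= 1e-12)
        assert in_fault[-1] < 0.1 * in_fault[0]
        # renewed drive after the fault regrows the weight
        assert c0[260] > c0[199]

    def test_forward_then_update_ordering(self):
        # the first recorded output must use the initial weights
        net = init_network(seed=6)
        data = make_uniform_responses(5, seed=7)
        r0 = data.values[0]
        expected = mc_outputs(mc_branch_potentials(net, r0, pg_potentials(net, r0)))
        _, trace = process_sequence(net, data, adapt=True)
        np.testing.assert_allclose(trace.mc_outputs[0], expected, atol=1e-15)


class TestDisinhibition:
    def test_no_inhibition_no_deltas(self):
        net = init_network(f_density=0.0, seed=8)
        delta = disinhibition_check(net, np.full(16, 0.5), k=3)
        assert np.all(delta == 0)

    def test_deltas_nonnegative_and_strict_when_coupled(self):
        rng = np.random.default_rng(9)
        for trial in range(30):
            net = init_network(seed=trial)
            r = rng.uniform(0.05, 1, 16)
            k = int(rng.integers(16))
            delta = disinhibition_check(net, r, k)
            assert delta.min() >= 0
            strict = (net.f[:, :, k] > 0) & (net.d[:, [k]] > 0) \
                & (net.c > 0) & (r[None, :] > 0)
            strict[:, k] = False
            assert np.all(delta[strict] > 0)

    def test_matches_brute_force_recomputation(self):
        net = init_network(seed=10)
        r = np.random.default_rng(11).uniform(0, 1, 16)
        k = 5
        delta = disinhibition_check(net, r, k)
        r2 = r.copy(); r2[k] = 0.0
        m0 = mc_branch_potentials(net, r, pg_potentials(net, r))
        m1 = mc_branch_potentials(net, r2, pg_potentials(net, r2))
        expect = m1 - m0
        expect[:, k] = 0.0
        np.testing.assert_allclose(delta, expect, atol=1e-12)


class TestSerialization:
    def test_json_round_trip(self):
        net = init_network(seed=12, rates=LearningRates(d_drive="potential"))
        clone = GlomerularNetwork.from_json(net.to_json())
        np.testing.assert_array_equal(net.c, clone.c)
        np.testing.assert_array_equal(net.d, clone.d)
        np.testing.assert_array_equal(net.f, clone.f)
        assert clone.rates == net.rates
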