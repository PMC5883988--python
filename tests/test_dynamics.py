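import itertools

import numpy as np
import pytest

from sernet.dynamics import E, R, S, ActivityRaster, SERParams, local_fields, simulate, transition

from conftest import network_from_pairs, zero_network


class TestSERParams:
    @pytest.mark.parametrize("bad", [{"sop": -0.1}, {"nep": 1.1}, {"pi_p": 2.0}])
    def test_rejects_out_of_range(self, bad):
        kwargs = dict(sop=0.5, nep=0.5, pi_p=0.5, pi_n=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            SERParams(**kwargs)

    def test_rejects_bad_comparison(self):
        with pytest.raises(ValueError, match="comparison"):
            SERParams(0.5, 0.5, 0.5, 0.5, comparison="le")


class TestLocalFields:
    def test_worked_example_three_of_four_excited(self):
        # central node 0 with 4 positive neighbors, 3 excited: avg 3/4 >= 0.5
        net = network_from_pairs(5, pos=[(0, 1), (0, 2), (0, 3), (0, 4)])
        states = np.array([S, E, E, E, S], dtype=np.int8)
        fields = local_fields(states, net, SERParams(0.25, 0.25, 0.5, 0.5))
        assert fields.phi_p[0]

    def test_no_negative_neighbors_gives_phi_n_zero(self):
        net = network_from_pairs(3, pos=[(0, 1), (0, 2)])
        states = np.array([S, E, E], dtype=np.int8)
        for pi_n in (0.0, 0.3, 1.0):
            fields = local_fields(states, net, SERParams(0.25, 0.25, 0.5, pi_n))
            assert not fields.phi_n[0]

    def test_phi_s_tracks_susceptible(self):
        net = zero_network(3)
        states = np.array([S, E, R], dtype=np.int8)
        fields = local_fields(states, net, SERParams(0.25, 0.25, 0.5, 0.5))
        np.testing.assert_array_equal(fields.phi_s, [True, False, False])

    def test_five_node_mixed_network_matches_hand_enumeration(self):
        # hand-built: signs and states chosen to cover all field cases
        net = network_from_pairs(
            5,
            pos=[(0, 1), (0, 2), (1, 2), (3, 4)],
            neg=[(0, 3), (1, 4), (2, 4)],
        )
        states = np.array([S, E, S, E, R], dtype=np.int8)
        params = SERParams(0.25, 0.25, pi_p=0.5, pi_n=0.4)
        fields = local_fields(states, net, params)
        # brute-force per-node enumeration
        adj = net.adjacency
        for i in range(5):
            pos_nb = [j for j in range(5) if adj[i, j] == 1]
            neg_nb = [j for j in range(5) if adj[i, j] == -1]
            avg_p = (sum(states[j] == E for j in pos_nb) / len(pos_nb)) if pos_nb else 0.0
            avg_n = (sum(states[j] == E for j in neg_nb) / len(neg_nb)) if neg_nb else 0.0
            assert fields.phi_p[i] == (bool(pos_nb) and avg_p >= params.pi_p)
            assert fields.phi_n[i] == (bool(neg_nb) and avg_n >= params.pi_n)
            assert fields.phi_s[i] == (states[i] == S)

    def test_strict_comparison_switch(self):
        net = network_from_pairs(3, pos=[(0, 1), (0, 2)])
        states = np.array([S, E, S], dtype=np.int8)  # avg_p = 1/2 for node 0
        ge = local_fields(states, net, SERParams(0.25, 0.25, 0.5, 0.5))
        gt = local_fields(states, net, SERParams(0.25, 0.25, 0.5, 0.5, comparison="gt"))
        assert ge.phi_p[0] and not gt.phi_p[0]


class TestTransition:
    def _fields_for(self, states, net, params):
        return local_fields(states, net, params)

    def test_driven_row_110_always_excites(self, rng):
        # node 0: one positive excited neighbor, no negative neighbors
        net = network_from_pairs(2, pos=[(0, 1)])
        states = np.array([S, E], dtype=np.int8)
        for sop in (0.0, 0.5, 1.0):
            params = SERParams(sop, 0.25, pi_p=0.5, pi_n=0.5)
            new = transition(self._fields_for(states, net, params), states, params, rng)
            assert new[0] == E

    def test_suppressed_row_101_never_excites(self, rng):
        net = network_from_pairs(2, neg=[(0, 1)])
        states = np.array([S, E], dtype=np.int8)
        params = SERParams(1.0, 0.25, pi_p=0.5, pi_n=0.5)
        for _ in range(50):
            new = transition(self._fields_for(states, net, params), states, params, rng)
            assert new[0] == S

    def test_sop_zero_row_100_never_excites(self, rng):
        net = zero_network(1)
        states = np.array([S], dtype=np.int8)
        params = SERParams(0.0, 0.25, 0.5, 0.5)
        for _ in range(50):
            new = transition(self._fields_for(states, net, params), states, params, rng)
            assert new[0] == S

    def test_nep_one_recovers_all_refractory(self, rng):
        net = zero_network(4)
        states = np.full(4, R, dtype=np.int8)
        params = SERParams(0.25, 1.0, 0.5, 0.5)
        new = transition(self._fields_for(states, net, params), states, params, rng)
        assert (new == S).all()

    def test_excited_always_becomes_refractory(self, rng):
        net = zero_network(4)
        states = np.full(4, E, dtype=np.int8)
        params = SERParams(0.25, 0.25, 0.5, 0.5)
        new = transition(self._fields_for(states, net, params), states, params, rng)
        assert (new == R).all()

    def test_row_100_excites_at_bernoulli_rate(self):
        # Monte-Carlo vs Bernoulli oracle: 1e5 draws at sop = 0.25
        rng = np.random.default_rng(777)
        net = zero_network(1000)
        states = np.full(1000, S, dtype=np.int8)
        params = SERParams(0.25, 0.25, 0.5, 0.5)
        fields = self._fields_for(states, net, params)
        hits = 0
        n = 0
        for _ in range(100):
            hits += int((transition(fields, states, params, rng) == E).sum())
            n += 1000
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.25) < 4 * se

    def test_inconsistent_fields_assert(self, rng):
        net = zero_network(2)
        states = np.array([S, E], dtype=np.int8)
        params = SERParams(0.25, 0.25, 0.5, 0.5)
        fields = self._fields_for(states, net, params)
        with pytest.raises(AssertionError):
            transition(fields, np.array([E, E], dtype=np.int8), params, rng)


class TestSimulate:
    def test_determinism(self):
        net = network_from_pairs(6, pos=[(0, 1), (1, 2)], neg=[(3, 4)])
        params = SERParams(0.3, 0.3, 0.5, 0.5)
        r1 = simulate(net, params, n_steps=50, seed=42)
        r2 = simulate(net, params, n_steps=50, seed=42)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_different_seeds_differ(self):
        net = zero_network(20)
        params = SERParams(0.3, 0.3, 0.5, 0.5)
        r1 = simulate(net, params, n_steps=50, seed=1)
        r2 = simulate(net, params, n_steps=50, seed=2)
        assert not np.array_equal(r1.values, r2.values)

    def test_raster_shape_and_binary(self):
        net = zero_network(7)
        raster = simulate(net, SERParams(0.3, 0.3, 0.5, 0.5), n_steps=30, seed=0)
        assert raster.values.shape == (30, 7)
        assert np.isin(raster.values, (0, 1)).all()

    def test_nonpositive_steps_error(self):
        net = zero_network(3)
        with pytest.raises(ValueError, match="n_steps"):
            simulate(net, SERParams(0.3, 0.3, 0.5, 0.5), n_steps=0, seed=0)

    def test_no_consecutive_excitation(self):
        # E -> R is unconditional, so a node is never active twice in a row
        net = network_from_pairs(10, pos=[(i, (i + 1) % 10) for i in range(10)])
        raster = simulate(net, SERParams(0.9, 0.9, 0.1, 0.1), n_steps=200, seed=3)
        assert not np.any(raster.values[1:] & raster.values[:-1])

    def test_caller_supplied_initial_state(self):
        net = zero_network(4)
        init = np.array([E, E, E, E], dtype=np.int8)
        raster = simulate(net, SERParams(0.0, 0.0, 0.5, 0.5), n_steps=3, seed=0,
                          initial_states=init)
        # all E -> all R at step 1, then stuck (nep = 0)
        assert not raster.values.any()

    def test_uncoupled_stationary_occupancy(self):
        # analytic stationary distribution of the 3-state chain:
        # p_S = 1/(1 + sop + sop/nep), p_E = sop p_S, p_R = (sop/nep) p_S
        for sop, nep, seed in [(0.25, 0.25, 7), (0.1, 0.3, 8), (0.5, 0.5, 9)]:
            net = zero_network(105)
            raster = simulate(net, SERParams(sop, nep, 0.5, 0.5),
                              n_steps=2000, seed=seed)
            p_s = 1.0 / (1.0 + sop + sop / nep)
            expected = sop * p_s
            per_node = raster.values.mean(axis=0)  # nodes are independent chains
            se = per_node.std(ddof=1) / np.sqrt(per_node.size)
            assert abs(per_node.mean() - expected) < 3 * se

    def test_monotone_excitability_in_sop(self):
        # all-positive ring, strict comparison at pi = 1 disables coupling:
        # pure spontaneous regime, activity must increase with sop
        net = network_from_pairs(30, pos=[(i, (i + 1) % 30) for i in range(30)])
        means = []
        for sop in (0.1, 0.3, 0.6, 0.9):
            params = SERParams(sop, 0.5, pi_p=1.0, pi_n=1.0, comparison="gt")
            acts = [simulate(net, params, n_steps=400, seed=100 + k).values.mean()
                    for k in range(5)]
            means.append(np.mean(acts))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestOneStepDistributionOracle:
    """Exact next-state distribution from the transition rules vs simulation."""

    @staticmethod
    def exact_node_distribution(state, phi_p, phi_n, params):
        """Per-node next-state pmf from the rule table."""
        pmf = {S: 0.0, E: 0.0, R: 0.0}
        if state == E:
            pmf[R] = 1.0
        elif state == R:
            pmf[S] = params.nep
            pmf[R] = 1.0 - params.nep
        else:  # S
            if phi_p and not phi_n:
                pmf[E] = 1.0
            elif phi_n and not phi_p:
                pmf[S] = 1.0
            else:
                pmf[E] = params.sop
                pmf[S] = 1.0 - params.sop
        return pmf

    def test_joint_distribution_total_variation(self):
        net = network_from_pairs(4, pos=[(0, 1), (1, 2)], neg=[(2, 3)])
        params = SERParams(0.3, 0.4, 0.5, 0.5)
        states = np.array([S, E, S, E], dtype=np.int8)
        fields = local_fields(states, net, params)

        # exact joint pmf: nodes transition independently given current state
        node_pmfs = [
            self.exact_node_distribution(states[i], fields.phi_p[i],
                                         fields.phi_n[i], params)
            for i in range(4)
        ]
        exact = {}
        for combo in itertools.product((S, E, R), repeat=4):
            p = 1.0
            for i, s in enumerate(combo):
                p *= node_pmfs[i][s]
            if p > 0:
                exact[combo] = p

        rng = np.random.default_rng(2024)
        n_draws = 10_000
        counts: dict = {}
        for _ in range(n_draws):
            new = transition(fields, states, params, rng)
            key = tuple(int(s) for s in new)
            counts[key] = counts.get(key, 0) + 1

        tv = 0.5 * sum(
            abs(exact.get(k, 0.0) - counts.get(k, 0) / n_draws)
            for k in set(exact) | set(counts)
        )
        assert tv < 0.06

    def test_impossible_outcomes_never_sampled(self):
        net = zero_network(3)
        params = SERParams(0.5, 0.5, 0.5, 0.5)
        states = np.array([E, R, S], dtype=np.int8)
        fields = local_fields(states, net, params)
        rng = np.random.default_rng(5)
        for _ in range(200):
            new = transition(fields, states, params, rng)
            assert new[0] == R            # E -> R always
            assert new[1] in (S, R)       # R -> S or stays
            assert new[2] in (S, E)       # S -> E or stays
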