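"""Unit and property tests for the occupancy model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cratherm.model import (
    ExperimentalState,
    ModelSpec,
    ParameterSet,
    SystemState,
    enumerate_states,
    log_odds_rnapii,
    p_rnapii,
    state_energy,
    state_weight,
)

from conftest import (
    all_experimental_states,
    brute_force_energy,
    brute_force_p_rnapii,
    random_params,
)


def params_from(n_sites, q_site, q_promoter, omega_pairs, omega_pol):
    omega = np.zeros((n_sites, n_sites))
    for (i, j), v in omega_pairs.items():
        omega[i, j] = v
    return ParameterSet(np.asarray(q_site, float), q_promoter, omega, np.asarray(omega_pol, float))


class TestStateEnergy:
    def test_empty_state_has_zero_energy(self, rng):
        p = random_params(rng, 3)
        assert state_energy(p, SystemState((0, 0, 0, 0))) == 0.0

    def test_single_bound_site_contributes_its_q(self):
        p = params_from(1, [-1.0], 7.3, {}, [4.2])
        assert state_energy(p, SystemState((1, 0))) == -1.0

    def test_full_two_site_state_hand_sum(self):
        # -1 - 2 - 0.5 + 0.25 - 0.75 + 0.5 = -3.5
        p = params_from(2, [-1.0, -2.0], -0.5, {(0, 1): 0.25}, [-0.75, 0.5])
        assert state_energy(p, SystemState((1, 1, 1))) == pytest.approx(-3.5, abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        for n in (1, 2, 3, 4):
            for _ in range(20):
                p = random_params(rng, n)
                occ = tuple(rng.integers(0, 2, size=n + 1))
                assert state_energy(p, SystemState(occ)) == pytest.approx(
                    brute_force_energy(p, occ), abs=1e-12
                )

    def test_dimension_mismatch_raises(self, rng):
        p = random_params(rng, 3)
        with pytest.raises(ValueError):
            state_energy(p, SystemState((1, 0)))


class TestStateWeight:
    @pytest.mark.parametrize(
        "energy_rt_units, expected",
        [(0.0, 1.0), (-math.log(2), 2.0), (1.0, math.exp(-1))],
    )
    def test_boltzmann_identities(self, energy_rt_units, expected):
        spec = ModelSpec(1)
        p = params_from(1, [energy_rt_units * spec.rt], 0.0, {}, [0.0])
        w = state_weight(p, SystemState((1, 0)), spec)
        assert w == pytest.approx(expected, rel=1e-12)


class TestEnumerateStates:
    def test_untargeted_control_leaves_only_promoter_free(self, spec3):
        states = enumerate_states(spec3, ExperimentalState(frozenset()))
        assert [s.occupancy for s in states] == [(0, 0, 0, 0), (0, 0, 0, 1)]

    def test_full_targeting_gives_full_space(self, spec3):
        states = enumerate_states(spec3, ExperimentalState(frozenset({0, 1, 2})))
        assert len(states) == 16
        assert len({s.occupancy for s in states}) == 16

    def test_inhibition_frees_the_complement(self, spec3):
        states = enumerate_states(spec3, ExperimentalState(frozenset({0}), "inhibition"))
        assert len(states) == 8
        assert all(s.occupancy[0] == 0 for s in states)

    def test_ordering_is_lexicographic(self, spec3):
        states = enumerate_states(spec3, ExperimentalState(frozenset({0, 2})))
        occs = [s.occupancy for s in states]
        assert occs == sorted(occs)
        assert all(o[1] == 0 for o in occs)


class TestPRnapii:
    def test_zero_parameters_give_half_everywhere(self, spec3):
        p = ParameterSet.zeros(3)
        for exper in all_experimental_states(3):
            assert p_rnapii(p, exper, spec3) == pytest.approx(0.5, abs=1e-12)

    def test_worked_single_site_case(self):
        spec = ModelSpec(1)
        p = params_from(1, [0.0], 0.0, {}, [-spec.rt * math.log(2)])
        assert p_rnapii(p, ExperimentalState(frozenset({0})), spec) == pytest.approx(0.6, abs=1e-12)

    def test_inactive_site_parameters_do_not_matter(self, rng):
        spec = ModelSpec(1)
        for _ in range(10):
            p = random_params(rng, 1)
            p.q_promoter = 0.0
            assert p_rnapii(p, ExperimentalState(frozenset()), spec) == pytest.approx(0.5, abs=1e-12)

    def test_bound_and_unbound_probabilities_sum_to_one(self, rng, spec3):
        from cratherm.model import _admissible_energies, _logsumexp

        for _ in range(20):
            p = random_params(rng, 3)
            for exper in all_experimental_states(3):
                energies, bound = _admissible_energies(p, exper, spec3)
                loga = -energies / spec3.rt
                pb = np.exp(_logsumexp(loga[bound]) - _logsumexp(loga))
                pu = np.exp(_logsumexp(loga[~bound]) - _logsumexp(loga))
                assert pb + pu == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for n in (1, 2, 3, 4):
            spec = ModelSpec(n)
            for _ in range(25):
                p = random_params(rng, n)
                for exper in all_experimental_states(n):
                    assert p_rnapii(p, exper, spec) == pytest.approx(
                        brute_force_p_rnapii(p, exper, spec), abs=1e-10
                    )

    def test_permutation_equivariance(self, rng, spec3):
        perm = [2, 0, 1]
        for _ in range(10):
            p = random_params(rng, 3)
            q_p = p.q_site[perm]
            pol_p = p.omega_site_pol[perm]
            omega_full = p.omega_site_site + p.omega_site_site.T
            omega_perm = omega_full[np.ix_(perm, perm)]
            p_perm = ParameterSet(q_p, p.q_promoter, np.triu(omega_perm, k=1), pol_p)
            for exper in all_experimental_states(3):
                # relabelled state: site perm[i] plays the role of old site i
                relabelled = ExperimentalState(
                    frozenset(perm.index(i) for i in exper.targeted)
                )
                assert p_rnapii(p, exper, spec3) == pytest.approx(
                    p_rnapii(p_perm, relabelled, spec3), abs=1e-12
                )

    def test_untargeted_site_parameters_are_irrelevant(self, rng, spec3):
        exper = ExperimentalState(frozenset({0, 2}))  # site 1 untargeted
        for _ in range(10):
            p = random_params(rng, 3)
            baseline = p_rnapii(p, exper, spec3)
            p.q_site[1] += rng.normal()
            p.omega_site_pol[1] += rng.normal()
            p.omega_site_site[0, 1] += rng.normal()
            p.omega_site_site[1, 2] += rng.normal()
            assert p_rnapii(p, exper, spec3) == pytest.approx(baseline, abs=1e-12)

    def test_favourable_pol_coupling_raises_occupancy(self, rng, spec3):
        exper = ExperimentalState(frozenset({0, 1}))
        for _ in range(10):
            p = random_params(rng, 3)
            before = p_rnapii(p, exper, spec3)
            p.omega_site_pol[0] -= 1.0
            assert p_rnapii(p, exper, spec3) > before

    def test_odds_multiply_without_site_site_coupling(self, rng, spec3):
        # independence: odds(S) = odds(0) * prod odds({i})/odds(0), checked
        # on the log scale where the partition sums keep full precision
        def logodds(p, targeted):
            return log_odds_rnapii(p, ExperimentalState(frozenset(targeted)), spec3)

        for _ in range(20):
            p = random_params(rng, 3)
            p.omega_site_site[:] = 0.0
            base = logodds(p, set())
            for targeted in [{0, 1}, {0, 2}, {1, 2}, {0, 1, 2}]:
                expected = base + sum(logodds(p, {i}) - base for i in targeted)
                assert logodds(p, targeted) == pytest.approx(expected, abs=1e-10)

    def test_log_odds_consistent_with_probability(self, rng, spec3):
        import math

        for _ in range(10):
            p = random_params(rng, 3, -2, 2)
            for exper in all_experimental_states(3):
                pr = p_rnapii(p, exper, spec3)
                assert log_odds_rnapii(p, exper, spec3) == pytest.approx(
                    math.log(pr / (1 - pr)), abs=1e-9
                )

    def test_inhibition_equals_activation_of_complement(self, rng, spec3):
        for _ in range(10):
            p = random_params(rng, 3)
            for exper in all_experimental_states(3, mode="inhibition"):
                complement = frozenset(range(3)) - exper.targeted
                assert p_rnapii(p, exper, spec3) == p_rnapii(
                    p, ExperimentalState(complement), spec3
                )

    def test_promoter_energy_limits_saturate_occupancy(self, rng, spec3):
        p = random_params(rng, 3)
        exper = ExperimentalState(frozenset({0, 1, 2}))
        p.q_promoter = -50 * spec3.rt
        assert p_rnapii(p, exper, spec3) == pytest.approx(1.0, abs=1e-8)
        p.q_promoter = 50 * spec3.rt
        assert p_rnapii(p, exper, spec3) == pytest.approx(0.0, abs=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.integers(1, 3),
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 5.0, allow_nan=False),
    )
    def test_probability_always_in_unit_interval(self, n, seed, scale):
        # scale stays within the fitting box, where the log-domain partition
        # never saturates to exactly 0 or 1 in double precision
        rng = np.random.default_rng(seed)
        spec = ModelSpec(n)
        p = random_params(rng, n, -scale, scale)
        for exper in all_experimental_states(n):
            val = p_rnapii(p, exper, spec)
            assert 0.0 < val < 1.0


class TestTypesAndSerialization:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(0)
        with pytest.raises(ValueError):
            ModelSpec(2, temperature=-1)
        assert ModelSpec(3).n_parameters == 10

    def test_parameter_vector_round_trip(self, rng):
        for n in (1, 2, 3, 4):
            p = random_params(rng, n)
            back = ParameterSet.from_vector(p.to_vector(), n)
            assert np.allclose(back.to_vector(), p.to_vector())

    def test_json_round_trip(self, rng, tmp_path):
        p = random_params(rng, 3)
        path = tmp_path / "params.json"
        p.to_json(path)
        back = ParameterSet.from_json(path)
        assert np.allclose(back.to_vector(), p.to_vector())

    def test_lower_triangle_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(np.zeros(2), 0.0, np.array([[0.0, 0.0], [1.0, 0.0]]), np.zeros(2))

    def test_label_round_trip(self):
        for targeted in [set(), {0}, {0, 2}, {0, 1, 2}]:
            e = ExperimentalState(frozenset(targeted))
            assert ExperimentalState.from_label(e.to_label()) == e
        assert ExperimentalState.from_label("1+3").targeted == frozenset({0, 2})
        assert ExperimentalState.from_label("control").targeted == frozenset()
        with pytest.raises(ValueError):
            ExperimentalState.from_label("1,3")

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            SystemState((0, 2))

    def test_targeted_beyond_n_sites_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalState(frozenset({5})).active_sites(3)
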