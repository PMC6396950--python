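"""Reduced promoter chain, mixture weights, modes, transients."""

import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import given, settings
from scipy import stats

import spkmix as sx


class TestReducedGenerator:
    def test_bursting_generator_entries(self, bursting):
        gen = sx.build_reduced_generator(bursting)
        np.testing.assert_allclose(
            gen.matrix, [[-1.0, 0.1], [1.0, -0.1]]
        )

    def test_self_regulating_rates(self, self_gene_coop):
        # binding at alpha * rho, unbinding at alpha_
        gen = sx.build_reduced_generator(self_gene_coop)
        rho = sx.expected_tf(self_gene_coop, 0, "Xc")
        assert gen.matrix[1, 0] == pytest.approx(1.0 * rho)
        assert gen.matrix[0, 1] == pytest.approx(1.0)

    def test_toggle_matches_closed_form(self, toggle):
        """The 4-state toggle generator has the published closed form with
        rho = (k0/k_)^n beta/(n! beta_)."""
        a, a_ = 1.0, 200.0
        rho = (80.0 / 2.0) ** 2 * 1.0 / (2 * 1.0)
        expect = np.array(
            [
                [-2 * a * rho, a_, a_, 0.0],
                [a * rho, -a_, 0.0, a_],
                [a * rho, 0.0, -a_, a_],
                [0.0, 0.0, 0.0, -2 * a_],
            ]
        )
        gen = sx.build_reduced_generator(toggle)
        np.testing.assert_allclose(gen.matrix, expect)

    def test_no_transitions_into_doubly_bound_toggle_state(self, toggle):
        gen = sx.build_reduced_generator(toggle)
        d11 = sx.state_index(toggle, ("1", "1"))
        off = np.delete(gen.matrix[d11, :], d11)
        assert np.all(off == 0.0)

    def test_columns_sum_to_zero(self, coupled):
        gen = sx.build_reduced_generator(coupled)
        np.testing.assert_allclose(
            gen.matrix.sum(axis=0), 0.0, atol=1e-10
        )
        off_diag = gen.matrix - np.diag(gen.matrix.diagonal())
        assert off_diag.min() >= 0.0

    def test_single_promoter_flip_per_transition(self, coupled):
        gen = sx.build_reduced_generator(coupled)
        for d in gen.states:
            for dp in gen.states:
                if d.index == dp.index:
                    continue
                flips = sum(
                    a != b for a, b in zip(d.config, dp.config)
                )
                if flips > 1:
                    assert gen.matrix[dp.index, d.index] == 0.0


class TestStationaryWeights:
    @given(
        alpha=st.floats(0.05, 50.0),
        alpha_=st.floats(0.05, 50.0),
    )
    @settings(derandomize=True, max_examples=30)
    def test_bursting_weights_closed_form(self, alpha, alpha_):
        spec = sx.build_fixture("bursting_gene", alpha=alpha,
                                alpha_=alpha_)
        lam = sx.stationary_weights(sx.build_reduced_generator(spec))
        total = alpha + alpha_
        np.testing.assert_allclose(
            lam, [alpha_ / total, alpha / total], atol=1e-12
        )

    def test_kernel_and_normalization(self, coupled):
        gen = sx.build_reduced_generator(coupled)
        lam = sx.stationary_weights(gen)
        assert lam.sum() == pytest.approx(1.0, abs=1e-12)
        assert lam.min() >= 0.0
        assert np.abs(gen.matrix @ lam).max() < 1e-10

    def test_reducible_chain_unique_closed_class(self):
        """Non-leaky self-activation: the unbound state absorbs and
        carries all the weight."""
        spec = sx.build_fixture(
            "self_regulating_gene", leaky=False, cooperative=False
        )
        lam = sx.stationary_weights(sx.build_reduced_generator(spec))
        np.testing.assert_allclose(lam, [1.0, 0.0], atol=1e-14)

    def test_frozen_promoter_needs_initial_condition(self):
        spec = sx.build_fixture("bursting_gene", alpha=0.0, alpha_=0.0)
        gen = sx.build_reduced_generator(spec)
        with pytest.raises(sx.NonUniqueStationaryError) as err:
            sx.stationary_weights(gen)
        assert err.value.kernel_dim == 2
        lam = sx.stationary_weights(gen, initial=np.array([0.3, 0.7]))
        np.testing.assert_allclose(lam, [0.3, 0.7])

    def test_absorption_split_from_transient_start(self):
        """A gene whose promoter can only switch off splits its weight by
        where the initial distribution absorbs."""
        spec = sx.build_fixture("bursting_gene", alpha=0.0, alpha_=1.0)
        gen = sx.build_reduced_generator(spec)
        lam = sx.stationary_weights(gen, initial=np.array([0.0, 1.0]))
        np.testing.assert_allclose(lam, [1.0, 0.0], atol=1e-12)


class TestMixture:
    def test_toggle_mixture_matches_displayed_formula(self, toggle):
        """pi(x, y) = [P(x;K)P(y;K) + w P(y;K) delta(x) + w P(x;K)
        delta(y)] / (2w + 1) with w = (alpha/alpha_) rho and K = k0/k_."""
        mix = sx.mixture_pmf(toggle)
        K = 40.0
        w = (1.0 / 200.0) * 800.0
        box = {"X": 70, "Y": 70}
        grid = mix.grid_marginal(box)
        px = stats.poisson.pmf(np.arange(71), K)
        delta = np.zeros(71)
        delta[0] = 1.0
        expect = (
            np.outer(px, px)
            + w * np.outer(delta, px)
            + w * np.outer(px, delta)
        ) / (2 * w + 1)
        np.testing.assert_allclose(grid, expect, atol=1e-12)

    def test_fast_unbinding_limit_single_poisson(self):
        spec = sx.build_fixture("bursting_gene", alpha_=0.0)
        mix = sx.mixture_pmf(spec)
        assert mix.weights[1] == pytest.approx(1.0)
        grid = mix.grid_marginal({"X": 60})
        np.testing.assert_allclose(
            grid, stats.poisson.pmf(np.arange(61), 10.0), atol=1e-12
        )

    def test_fig3_parameter_weights(self, bursting):
        mix = sx.mixture_pmf(bursting)
        np.testing.assert_allclose(
            mix.weights, [1.0 / 11.0, 10.0 / 11.0], atol=1e-12
        )

    def test_mixture_mass_on_truncation_box(self, toggle):
        mix = sx.mixture_pmf(toggle)
        assert mix.grid_marginal().sum() == pytest.approx(1.0, abs=1e-6)

    def test_joint_pmf_includes_multimers(self, self_gene_coop):
        mix = sx.mixture_pmf(self_gene_coop)
        p = mix.pmf_joint({"X": 2, "Xc": 0})
        comps = [
            w * c.pmf({"X": 2, "Xc": 0})
            for w, c in zip(mix.weights, mix.components)
        ]
        assert p == pytest.approx(sum(comps))


class TestModes:
    def test_nonleaky_toggle_three_component_modes(self, toggle):
        report = sx.find_modes(sx.mixture_pmf(toggle), scan_lattice=False)
        assert report.n_component_modes == 3
        locs = {loc for loc, _ in report.component_modes}
        assert locs == {(0.0, 40.0), (40.0, 0.0), (40.0, 40.0)}

    def test_close_poisson_pair_merges_into_one_lattice_maximum(self):
        """Poisson(0.5) and Poisson(1.5) mixed half-and-half yield two
        components but a single lattice maximum (exhaustive-scan
        oracle value computed from the closed-form PMF)."""
        gene = sx.GeneBlock(
            id="X",
            binding_sites=(sx.CONSTITUTIVE,),
            binding_rates=((1.0, 1.0),),
            production_rates={"0": 1.0, "1": 3.0},
            decay_rate=2.0,
        )
        mix = sx.mixture_pmf(sx.GRNSpec(genes=(gene,)))
        np.testing.assert_allclose(mix.weights, [0.5, 0.5])
        report = sx.find_modes(mix)
        assert report.n_component_modes == 2
        assert report.lattice_maxima == [(0,)]

    def test_single_component_mode_at_its_mean(self):
        spec = sx.build_fixture("bursting_gene", alpha_=0.0)
        report = sx.find_modes(sx.mixture_pmf(spec))
        assert report.component_modes == [((10.0,), pytest.approx(1.0))]

    def test_coincident_locations_merge(self):
        """Two configurations with equal production rates collapse to one
        mode whose weight is the sum."""
        gene = sx.GeneBlock(
            id="X",
            binding_sites=(sx.CONSTITUTIVE,),
            binding_rates=((1.0, 1.0),),
            production_rates={"0": 6.0, "1": 6.0},
            decay_rate=2.0,
        )
        mix = sx.mixture_pmf(sx.GRNSpec(genes=(gene,)))
        report = sx.find_modes(mix, scan_lattice=False)
        assert report.component_modes == [((3.0,), pytest.approx(1.0))]

    def test_weight_floor_validated(self, bursting):
        with pytest.raises(ValueError):
            sx.find_modes(sx.mixture_pmf(bursting), weight_floor=1.0)


class TestCooperativityInvariance:
    def test_multimerization_sweep_moves_weights_not_locations(self):
        """Raising beta/beta_ suppresses the (high, high) mode of the
        cooperative toggle monotonically while every component location
        stays bit-identical."""
        ratios = [0.01, 0.1, 1.0, 10.0, 100.0]
        locations, both_high_weight = [], []
        for r in ratios:
            spec = sx.build_fixture("toggle_switch", n=2, beta=r,
                                    beta_minus=1.0)
            mix = sx.mixture_pmf(spec)
            locations.append(mix.locations())
            d00 = sx.state_index(spec, ("0", "0"))
            both_high_weight.append(mix.weights[d00])
        for loc in locations[1:]:
            assert np.array_equal(loc, locations[0])
        assert all(
            b < a for a, b in zip(both_high_weight, both_high_weight[1:])
        )


class TestTransitionMatrix:
    def test_identity_at_time_zero(self, toggle):
        gen = sx.build_reduced_generator(toggle)
        np.testing.assert_allclose(
            sx.transition_matrix(gen, 0.0), np.eye(4), atol=1e-14
        )

    def test_columns_are_stochastic(self, bursting):
        gen = sx.build_reduced_generator(bursting)
        Q = sx.transition_matrix(gen, 0.7)
        np.testing.assert_allclose(Q.sum(axis=0), 1.0, atol=1e-12)

    def test_long_time_columns_reach_stationary_law(self, bursting):
        gen = sx.build_reduced_generator(bursting)
        lam = sx.stationary_weights(gen)
        Q = sx.transition_matrix(gen, 1e4)
        for col in Q.T:
            np.testing.assert_allclose(col, lam, atol=1e-8)

    def test_repressilator_prefers_cyclic_successor(self):
        """From a dominant configuration the next dominant configuration
        follows the ring: the repressee-of-the-repressee turns on next."""
        spec = sx.build_fixture("repressilator")
        gen = sx.build_reduced_generator(spec)
        dom = {}
        for gi in range(3):
            cfg = tuple("0" if i == gi else "1" for i in range(3))
            dom[gi] = sx.state_index(spec, cfg)
        t = 0.05 / np.abs(gen.matrix.diagonal()).max()
        Q = sx.transition_matrix(gen, t)
        # wiring X -| Y -| Z -| X: the successor of X is Z, etc.
        for gi, succ in [(0, 2), (2, 1), (1, 0)]:
            other = ({0, 1, 2} - {gi, succ}).pop()
            assert Q[dom[succ], dom[gi]] > 10 * Q[dom[other], dom[gi]]

    def test_negative_time_rejected(self, bursting):
        gen = sx.build_reduced_generator(bursting)
        with pytest.raises(ValueError):
            sx.transition_matrix(gen, -1.0)


class TestDominantComponents:
    def test_repressilator_concentrates_on_three_single_high_states(self):
        spec = sx.build_fixture("repressilator")
        mix = sx.mixture_pmf(spec)
        idx, cum = sx.dominant_components(mix, concentration=0.99)
        assert len(idx) == 3
        assert cum >= 0.99
        locs = {mix.components[i].location(spec) for i in idx}
        K = 100.0
        assert locs == {(K, 0.0, 0.0), (0.0, K, 0.0), (0.0, 0.0, K)}


class TestSynchronizedLimit:
    def test_single_switch_consistency(self):
        rep = sx.synchronized_limit(
            sx.build_fixture("coupled_toggles", N=1)
        )
        assert rep.n_modes == 3
        assert rep.full_component_count == 3

    def test_three_switch_population_mode_structure(self, coupled):
        rep = sx.synchronized_limit(coupled)
        assert rep.full_component_count == 4**3 - 1
        assert rep.n_modes == (3 + 1) ** 2 - 1
        assert len(rep.interior_modes) == 9
        assert len(rep.boundary_modes) == 6
        extremes = {(150.0, 0.0), (0.0, 150.0)}
        extra = set(rep.boundary_modes) - extremes
        assert extra == {(50.0, 0.0), (100.0, 0.0),
                         (0.0, 50.0), (0.0, 100.0)}

    def test_synchronization_threshold_reported(self, coupled):
        rep = sx.synchronized_limit(coupled)
        assert rep.omega_min == pytest.approx((300.0 - 2.0) / 3.0)
        assert rep.omega == 100.0

    def test_interior_suppression_flag_follows_multimerization(self):
        weak = sx.synchronized_limit(sx.build_fixture("coupled_toggles"))
        strong = sx.synchronized_limit(
            sx.build_fixture("coupled_toggles", beta=50.0)
        )
        assert not weak.interior_suppressed
        assert strong.interior_suppressed

    def test_non_identical_switches_rejected(self):
        spec = sx.build_fixture("coupled_toggles", N=2)
        genes = list(spec.genes)
        genes[0] = sx.GeneBlock(
            id=genes[0].id,
            binding_sites=genes[0].binding_sites,
            binding_rates=genes[0].binding_rates,
            production_rates={"0": 123.0, "1": 0.0},
            decay_rate=genes[0].decay_rate,
            cooperativity=genes[0].cooperativity,
            multimerization_rates=genes[0].multimerization_rates,
        )
        bad = sx.GRNSpec(
            genes=tuple(genes),
            diffusion_couplings=spec.diffusion_couplings,
            epsilon=spec.epsilon,
        )
        with pytest.raises(ValueError, match="identical"):
            sx.synchronized_limit(bad)
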