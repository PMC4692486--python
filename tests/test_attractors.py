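import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hopscape as hs
from hopscape.attractors import (
    AttractorSet,
    absorb_or_add,
    boltzmann_distribution,
    boltzmann_entropy,
    detect_first_bifurcation,
    empirical_entropy,
    euclidean_similarity,
    ising_energy,
    lyapunov_value,
    pearson_similarity,
    sample_attractors,
    sweep_P_density,
    sweep_gain,
)
from hopscape.dynamics import ModelConfig, activation, relax


class TestSimilarities:
    def test_pearson_identity(self):
        x = np.array([0.0, 1.0, 0.5, 0.2])
        assert pearson_similarity(x, x) == pytest.approx(1.0)

    def test_pearson_anticorrelation(self):
        x = np.array([0.0, 1.0, 0.5, 0.2])
        assert pearson_similarity(x, 1 - x) == pytest.approx(-1.0)

    def test_pearson_orthogonal(self):
        assert pearson_similarity([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_pearson_constant_warns_zero(self):
        with pytest.warns(UserWarning):
            assert pearson_similarity([1, 1, 1], [0, 1, 0]) == 0.0

    def test_euclidean_identity(self):
        assert euclidean_similarity([1, 2, 3], [1, 2, 3]) == 1.0

    def test_euclidean_unit_distance(self):
        assert euclidean_similarity([0, 0], [1, 0]) == pytest.approx(0.5)

    def test_euclidean_orthogonal_units(self):
        # distance sqrt(2) -> 1/(1+sqrt(2)) = 0.41421
        assert euclidean_similarity([1, 0], [0, 1]) == pytest.approx(0.414214, abs=1e-6)


class TestAbsorbOrAdd:
    def test_first_pattern_stored(self):
        s = AttractorSet(n_nodes=3)
        idx, new = absorb_or_add(np.array([1.0, 0.0, 0.0]), s)
        assert new and idx == 0 and len(s) == 1
        assert s.attractors[0].cardinality == 1

    def test_duplicate_increments(self):
        s = AttractorSet(n_nodes=3)
        p = np.array([1.0, 0.0, 0.0])
        absorb_or_add(p, s)
        idx, new = absorb_or_add(p.copy(), s)
        assert not new and idx == 0
        assert s.attractors[0].cardinality == 2
        assert len(s) == 1

    def test_complementary_patterns_both_stored(self):
        # complementary half-active patterns: pearson = -1, distance sqrt(N)
        s = AttractorSet(n_nodes=6)
        p = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        absorb_or_add(p, s)
        _, new = absorb_or_add(1 - p, s)
        assert new and len(s) == 2

    def test_cardinality_conservation(self):
        rng = np.random.default_rng(0)
        s = AttractorSet(n_nodes=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(50):
                absorb_or_add((rng.random(10) > 0.5).astype(float), s)
        assert s.cardinalities().sum() == 50 == s.n_equilibrated


class TestSampleAttractors:
    def test_single_node_two_attractors(self, single_node):
        cfg = ModelConfig("SL", G=900.0)
        aset = sample_attractors(single_node, cfg, density_grid=[0.1, 0.9],
                                 n_per_density=50, seed=0)
        assert len(aset) == 2
        dens = np.sort(aset.densities())
        assert dens[0] < 0.01 and dens[1] > 0.99

    def test_sample_count_accounting(self, small_net):
        cfg = ModelConfig("SL", G=900.0)
        aset = sample_attractors(small_net, cfg, density_grid=[0.3, 0.5, 0.7],
                                 n_per_density=20, seed=1)
        assert aset.n_samples == 60
        assert aset.cardinalities().sum() == aset.n_equilibrated

    def test_monostable_below_first_bifurcation(self, small_net):
        gc = 2.0 / small_net.lambda_max()
        cfg = ModelConfig("SL", G=0.5 * gc)
        aset = sample_attractors(small_net, cfg, density_grid=[0.2, 0.5, 0.8],
                                 n_per_density=20, seed=2)
        assert len(aset) == 1

    def test_default_grid_is_33_densities(self):
        from hopscape.attractors import DEFAULT_DENSITY_GRID
        assert len(DEFAULT_DENSITY_GRID) == 33
        assert DEFAULT_DENSITY_GRID[0] == pytest.approx(0.02)
        assert DEFAULT_DENSITY_GRID[-1] == pytest.approx(0.98)

    def test_sl_density_symmetry(self, small_net):
        # SL with P=1 is symmetric around A = 0.5: complementary initial
        # patterns relax to attractors with mirrored densities
        cfg = ModelConfig("SL", G=900.0)
        rng = np.random.default_rng(4)
        X0 = (rng.random((20, 30)) < 0.5).astype(float)
        rowsum = small_net.row_sums()
        Xf, Tf, ok, _ = relax(small_net, cfg, X0)
        Xc, Tc, okc, _ = relax(small_net, cfg, rowsum[None, :] - X0)
        A = activation(Xf, Tf, cfg.G, cfg.P)
        Ac = activation(Xc, Tc, cfg.G, cfg.P)
        both = ok & okc
        np.testing.assert_allclose(
            A[both].mean(axis=1), 1.0 - Ac[both].mean(axis=1), atol=1e-4
        )


class TestLyapunov:
    def test_zero_at_origin(self, small_net):
        cfg = ModelConfig("SL", G=10.0)
        assert lyapunov_value(np.zeros(30), small_net, cfg) == pytest.approx(0.0)

    def test_gradient_matches_drift_1d(self, single_node):
        # for N=1, W=[[1]]: dV/dx = x - A(x)
        cfg = ModelConfig("SL", G=5.0)
        h = 1e-6
        for x in [0.1, 0.3, 0.5, 0.8]:
            vp = lyapunov_value(np.array([x + h]), single_node, cfg)
            vm = lyapunov_value(np.array([x - h]), single_node, cfg)
            grad = (vp - vm) / (2 * h)
            drift = x - activation(x, 0.5, cfg.G, cfg.P)
            assert grad == pytest.approx(drift, abs=1e-6)

    def test_minima_coincide_with_stable_fixed_points_1d(self, single_node):
        cfg = ModelConfig("SL", G=900.0)
        xs = np.linspace(-0.2, 1.2, 14001)
        vals = np.array([lyapunov_value(np.array([x]), single_node, cfg)
                         for x in xs])
        interior = (vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:])
        minima = np.sort(xs[1:-1][interior])
        assert len(minima) == 2
        assert abs(minima[0] - 0.0) < 1e-3 and abs(minima[1] - 1.0) < 1e-3

    def test_dg_rejected(self, small_net):
        with pytest.raises(ValueError):
            lyapunov_value(np.zeros(30), small_net, ModelConfig("DG", G=10.0))


class TestIsingEnergy:
    def test_zero_pattern(self, small_net):
        theta = hs.static_thresholds(small_net, "SL")
        assert ising_energy(np.zeros(30), small_net, theta) == 0.0

    def test_two_node_hand_values(self):
        w = hs.Connectome(np.array([[0.0, 0.4], [0.4, 0.0]]))
        theta = np.array([0.3, 0.3])
        assert ising_energy([1, 1], w, theta) == pytest.approx(-0.4 - 0.6)
        assert ising_energy([1, 0], w, theta) == pytest.approx(-0.3)


class TestBoltzmann:
    def test_equal_energies(self):
        np.testing.assert_allclose(boltzmann_distribution([1.0, 1.0], 2.0), [0.5, 0.5])

    def test_beta_zero_uniform(self):
        np.testing.assert_allclose(boltzmann_distribution([0.0, 5.0, -3.0], 0.0),
                                   np.full(3, 1 / 3))

    def test_hand_value(self):
        np.testing.assert_allclose(
            boltzmann_distribution([0.0, np.log(2.0)], 1.0), [2 / 3, 1 / 3]
        )

    def test_entropy_equal_energies(self):
        assert boltzmann_entropy([1.0, 1.0], 3.0) == pytest.approx(np.log(2))

    def test_entropy_low_temperature_degenerate(self):
        assert boltzmann_entropy([0.0, 1.0], 1e4) == pytest.approx(0.0, abs=1e-3)

    def test_entropy_two_forms_agree(self):
        E = np.array([0.0, 1.0, 2.0])
        p = boltzmann_distribution(E, 1.0)
        direct = -np.sum(p * np.log(p))
        assert boltzmann_entropy(E, 1.0) == pytest.approx(direct, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_distribution([], 1.0)


class TestEmpiricalEntropy:
    def test_single_attractor(self):
        assert empirical_entropy([7]) == 0.0

    def test_equal_pair_one_bit(self):
        assert empirical_entropy([2, 2]) == pytest.approx(1.0)

    def test_upper_bound_3300(self):
        assert round(empirical_entropy(np.ones(3300, dtype=int)), 2) == 11.69

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=30))
    def test_bounds(self, cards):
        h = empirical_entropy(cards)
        assert -1e-12 <= h <= np.log2(len(cards)) + 1e-12


class TestSweeps:
    def test_gain_sweep_single_node(self, single_node):
        cfg = ModelConfig("SL", G=1.0)
        table, _ = sweep_gain(single_node, cfg, [1.0, 1.5, 3.0, 10.0],
                              n_per_density=20, seed=0,
                              density_grid=[0.25, 0.75])
        counts = table.set_index("G")["n_attractors"]
        assert counts[1.0] == 1 and counts[1.5] == 1
        assert counts[3.0] == 2 and counts[10.0] == 2

    def test_empty_gain_grid(self, single_node):
        with pytest.raises(ValueError):
            sweep_gain(single_node, ModelConfig("SL", G=1.0), [])

    def test_sl_low_P_all_down(self, small_net):
        cfg = ModelConfig("SL", G=900.0)
        table = sweep_P_density(small_net, cfg, P_values=[0.01],
                                f0_values=[0.3, 0.7], n_per_cell=10, seed=0)
        assert (table["n_attractors"] == 1).all()
        assert (table["mean_final_density"] < 0.05).all()

    def test_sl_high_P_up_state(self, small_net):
        cfg = ModelConfig("SL", G=900.0)
        table = sweep_P_density(small_net, cfg, P_values=[20.0],
                                f0_values=[0.8], n_per_cell=10, seed=0)
        assert (table["mean_final_density"] > 0.9).all()


class TestFirstBifurcation:
    def test_single_node_exactly_two(self, single_node):
        cfg = ModelConfig("SL", G=1.0)
        grid = np.round(np.arange(1.0, 3.01, 0.1), 10)
        g = detect_first_bifurcation(single_node, cfg, grid)
        assert g == pytest.approx(2.1)  # first grid point above G_c = 2

    def test_matches_eigenvalue_oracle(self, small_net):
        gc = 2.0 / small_net.lambda_max()
        grid = np.round(gc * np.arange(0.8, 1.31, 0.05), 8)
        g = detect_first_bifurcation(small_net, ModelConfig("SL", G=1.0), grid)
        step = grid[1] - grid[0]
        assert g is not None
        assert gc - 1e-6 <= g <= gc + step + 1e-6


class TestOracleEquivalence:
    def test_brute_force_superset(self):
        # exhaustive corner relaxation vs sampling with n >= 4 * 2^N
        n = 8
        c = hs.synthetic_connectome(n, 2, 0.7, 0.15, seed=7)
        w = hs.normalize(c)
        cfg = ModelConfig("SL", G=900.0)
        corners = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
        Xf, Tf, ok, _ = relax(w, cfg, corners)
        Af = activation(Xf, Tf, cfg.G, cfg.P)
        brute = AttractorSet(n_nodes=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(corners)):
                if ok[i]:
                    absorb_or_add(Af[i], brute)
        samp = sample_attractors(w, cfg, density_grid=np.arange(0.1, 0.91, 0.1),
                                 n_per_density=120, seed=11)
        assert len(samp) == len(brute)
        # every sampled attractor matches a brute-force one under the dedup rule
        for a in samp.attractors:
            pear, eucl = brute._similarities(a.pattern)
            assert np.any((pear >= 0.9) | (eucl >= 0.9))
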