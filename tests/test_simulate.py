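"""Diet grids, random coefficients, synthetic libraries, predator generation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qfasajoint import (
    CalibrationCoefficients,
    aitchison_sq_distance,
    closure,
    fit_joint,
    generate_predators,
    make_diet_grid,
    random_cc,
    realistic_diet_fixture,
    run_scenario,
    synth_prey_library,
)
from qfasajoint.simulate import SimulationScenario


def brute_force_grid_count(I, g):
    """Exhaustive enumeration of I-part compositions of g units."""
    return sum(
        1 for combo in itertools.product(range(g + 1), repeat=I) if sum(combo) == g
    )


class TestDietGrid:
    def test_two_types_unit_increment(self):
        grid = make_diet_grid(2, 1.0)
        assert grid.tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_count_matches_exhaustive_enumeration(self):
        grid = make_diet_grid(3, 0.1)
        assert grid.shape[0] == brute_force_grid_count(3, 10)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(2, 5), st.integers(1, 6))
    def test_count_formula_and_exact_sums(self, I, g):
        counts = make_diet_grid(I, 1.0 / g, return_counts=True)
        assert counts.shape[0] == math.comb(I + g - 1, g)
        # exact in integer arithmetic: every row sums to g units
        assert (counts.sum(axis=1) == g).all()
        assert counts.min() >= 0

    def test_lexicographic_order(self):
        counts = make_diet_grid(3, 0.5, return_counts=True)
        assert counts.tolist() == sorted(counts.tolist())

    def test_non_integral_increment_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            make_diet_grid(3, 0.3)


class TestRandomCC:
    def test_sums_to_k(self):
        cc = random_cc(42, seed=0)
        assert cc.values.sum() == pytest.approx(42.0, abs=1e-12)

    def test_reproducible_and_seed_sensitive(self):
        a = random_cc(10, seed=3).values
        b = random_cc(10, seed=3).values
        c = random_cc(10, seed=4).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_interior_of_feasible_region(self):
        for seed in range(5):
            assert random_cc(30, seed=seed).values.min() >= 0.02

    def test_mean_entry_near_one(self):
        # forced by the scaling: entries average K/K = 1
        assert random_cc(500, seed=1).values.mean() == pytest.approx(1.0)


class TestSynthPreyLibrary:
    def test_invariants_at_mammal_dimensions(self):
        lib = synth_prey_library(7, 32, 50, seed=0)
        assert lib.mean_signatures.shape == (7, 32)
        assert np.allclose(lib.mean_signatures.sum(axis=1), 1.0, atol=1e-9)
        assert len(lib.signatures) == 350

    def test_zero_separation_collapses_type_means(self):
        lib = synth_prey_library(4, 10, 200, separation=0.0, seed=0, within_sd=0.0)
        spread = np.abs(lib.mean_signatures - lib.mean_signatures[0]).max()
        assert spread < 1e-12

    def test_separation_increases_between_type_distance(self):
        def mean_pairwise(sep):
            dists = []
            for seed in range(5):
                m = synth_prey_library(4, 10, 1, separation=sep, seed=seed).mean_signatures
                dists += [
                    aitchison_sq_distance(m[i], m[j])
                    for i in range(4) for j in range(i + 1, 4)
                ]
            return np.mean(dists)

        assert mean_pairwise(0.2) < mean_pairwise(1.0) < mean_pairwise(3.0)


class TestGeneratePredators:
    def test_unit_cc_vertex_diet_returns_prey_mean(self, small_library):
        diets = np.eye(3)
        preds = generate_predators(diets, small_library, np.ones(8))
        assert np.allclose(preds.signatures, small_library.mean_signatures, atol=1e-12)

    def test_predator_space_mixture_oracle(self, small_library, rng):
        cc = rng.random(8) + 0.2
        diets = rng.dirichlet(np.ones(3), size=5)
        preds = generate_predators(diets, small_library, cc, mixing="predator")
        xbar = small_library.mean_signatures
        T = np.vstack([closure(cc * xbar[i]) for i in range(3)])
        expected = np.vstack([sum(d[i] * T[i] for i in range(3)) for d in diets])
        assert np.allclose(preds.signatures, expected, atol=1e-14)

    def test_prey_space_two_step_oracle(self, small_library, rng):
        cc = rng.random(8) + 0.2
        diets = rng.dirichlet(np.ones(3), size=5)
        preds = generate_predators(diets, small_library, cc, mixing="prey")
        xbar = small_library.mean_signatures
        expected = np.vstack(
            [closure(closure(sum(d[i] * xbar[i] for i in range(3))) * cc) for d in diets]
        )
        assert np.allclose(preds.signatures, expected, atol=1e-14)

    def test_cc_scale_invariance(self, small_library, rng):
        cc = rng.random(8) + 0.2
        diets = rng.dirichlet(np.ones(3), size=4)
        for mixing in ("predator", "prey"):
            a = generate_predators(diets, small_library, cc, mixing=mixing)
            b = generate_predators(diets, small_library, 3.7 * cc, mixing=mixing)
            assert np.allclose(a.signatures, b.signatures, atol=1e-12)

    def test_dimension_mismatch_rejected(self, small_library):
        with pytest.raises(ValueError):
            generate_predators(np.eye(4), small_library, np.ones(8))


class TestRealisticFixtures:
    @pytest.mark.parametrize("case,I", [("mammal", 7), ("fish", 28)])
    def test_shape_and_closure(self, case, I):
        diets = realistic_diet_fixture(case)
        assert diets.values.shape == (4, I)
        assert np.allclose(diets.values.sum(axis=1), 1.0, atol=1e-9)

    def test_near_threshold_joint_recovery_mammal(self):
        """J=4 low-diversity diets at mammal dimensions still recover truth."""
        sc = SimulationScenario(
            n_prey_types=7, n_fatty_acids=32, seed=3,
            diets=realistic_diet_fixture("mammal").values,
        )
        sim = run_scenario(sc)
        res = fit_joint(sim.predators, sim.library)
        assert np.abs(res.diet.values - sim.true_diets.values).max() < 1e-6
        assert np.abs(res.cc.values - sim.true_cc.values).max() < 1e-6


class TestEndToEnd:
    def test_simulate_then_fit_recovers_truth(self, small_truth):
        preds = generate_predators(
            small_truth["diets"], small_truth["library"], small_truth["cc"]
        )
        res = fit_joint(preds, small_truth["library"])
        assert np.abs(res.diet.values - small_truth["diets"]).max() < 1e-8
        assert np.abs(res.cc.values - small_truth["cc"].values).max() < 1e-8

    def test_scenario_subsampling_is_seeded(self):
        sc = SimulationScenario(
            n_prey_types=3, n_fatty_acids=8, increment=0.25, n_predators=6, seed=9
        )
        a = run_scenario(sc)
        b = run_scenario(sc)
        assert np.array_equal(a.predators.signatures, b.predators.signatures)
        assert a.true_diets.values.shape == (6, 3)
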