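"""Joint and conditioned estimation: arithmetic, objective, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio.stats.composition import clr as skbio_clr

from qfasajoint import (
    CalibrationCoefficients,
    FitConfig,
    IdentifiabilityWarning,
    PredatorSample,
    UnderdeterminedError,
    count_parameters,
    fit_conditioned,
    fit_joint,
    min_predators,
    objective_q,
    summarize_by_class,
)


class TestEstimabilityArithmetic:
    @pytest.mark.parametrize(
        "K,I,expected",
        [(32, 7, 2), (42, 28, 3), (10, 9, 9), (5, 2, 2)],
    )
    def test_min_predators(self, K, I, expected):
        assert min_predators(K, I) == expected

    def test_more_prey_than_fatty_acids_rejected(self):
        with pytest.raises(UnderdeterminedError, match="more fatty acids"):
            min_predators(7, 7)

    @pytest.mark.parametrize(
        "J,I,K,expected",
        [(210, 7, 32, 1291), (210, 28, 42, 5711), (4, 7, 32, 55), (4, 28, 42, 149), (1, 2, 3, 3)],
    )
    def test_count_parameters(self, J, I, K, expected):
        assert count_parameters(J, I, K) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(2, 30), st.integers(3, 50), st.integers(1, 400))
    def test_dof_bookkeeping_equivalence(self, I, K, J):
        """J*(K-1) >= J*(I-1) + (K-1) is the same as J >= ceil((K-1)/(K-I))."""
        if K <= I:
            return
        enough_dof = J * (K - 1) >= count_parameters(J, I, K)
        assert enough_dof == (J >= min_predators(K, I))


class TestObjective:
    def test_zero_at_generating_parameters(self, small_truth):
        q = objective_q(
            small_truth["diets"],
            small_truth["cc"],
            small_truth["predators"],
            small_truth["library"].mean_signatures,
        )
        assert q < 1e-25

    def test_matches_independent_clr_residual_oracle(self, rng):
        # single predator, 2 prey, 3 fatty acids, hand-set values
        xbar = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3]])
        cc = np.array([1.2, 0.9, 0.9])
        diet = np.array([[0.7, 0.3]])
        y = np.array([[0.25, 0.45, 0.30]])
        q = objective_q(diet, cc, y, xbar)
        # oracle: explicit transform, mixture, and skbio clr
        T = (xbar * cc) / (xbar * cc).sum(axis=1, keepdims=True)
        yhat = diet @ T
        expected = float(((skbio_clr(yhat[0]) - skbio_clr(y[0])) ** 2).sum())
        assert q == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_predator_order(self, small_truth, rng):
        lib = small_truth["library"]
        preds = small_truth["predators"]
        diets = np.asarray(small_truth["diets"])
        cc = small_truth["cc"]
        perm = rng.permutation(preds.n_predators)
        q1 = objective_q(diets, cc, preds.signatures, lib.mean_signatures)
        q2 = objective_q(diets[perm], cc, preds.signatures[perm], lib.mean_signatures)
        assert q1 == pytest.approx(q2, rel=1e-12)


class TestJointFit:
    def test_recovers_generating_parameters(self, small_truth):
        res = fit_joint(small_truth["predators"], small_truth["library"])
        assert res.converged
        assert res.objective < 1e-20
        assert np.abs(res.diet.values - small_truth["diets"]).max() < 1e-10
        assert np.abs(res.cc.values - small_truth["cc"].values).max() < 1e-10
        # feasibility of the returned estimates
        assert np.all(res.diet.values >= 0)
        assert np.allclose(res.diet.values.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(res.cc.values >= 0.02 - 1e-8)
        assert res.cc.values.sum() == pytest.approx(8.0, abs=1e-8)

    def test_single_predator_is_confounded(self, small_truth):
        preds = small_truth["predators"]
        one = PredatorSample(preds.signatures[:1], preds.ids[:1], preds.labels)
        with pytest.raises(UnderdeterminedError, match="at least 2 predators"):
            fit_joint(one, small_truth["library"])

    def test_identical_predators_trigger_identifiability_warning(self, small_truth):
        preds = small_truth["predators"]
        same = np.tile(preds.signatures[3], (4, 1))
        sample = PredatorSample(same, tuple(f"p{i}" for i in range(4)), preds.labels)
        with pytest.warns(IdentifiabilityWarning):
            fit_joint(sample, small_truth["library"], FitConfig(n_starts=4, seed=5))

    def test_objective_descends_from_initial_point(self, small_truth):
        lib = small_truth["library"]
        preds = small_truth["predators"]
        J, I = preds.n_predators, lib.n_types
        q0 = objective_q(
            np.full((J, I), 1.0 / I), np.ones(8), preds, lib.mean_signatures
        )
        res = fit_joint(preds, lib)
        assert res.objective <= q0


class TestConditionedFit:
    def test_true_coefficients_recover_true_diets(self, small_truth):
        res = fit_conditioned(
            small_truth["predators"], small_truth["library"], small_truth["cc"]
        )
        assert np.abs(res.diet.values - small_truth["diets"]).max() < 1e-8
        assert res.objectives.max() < 1e-16

    def test_wrong_coefficients_bias_diets(self, small_truth):
        ones = CalibrationCoefficients.ones(8)
        res = fit_conditioned(small_truth["predators"], small_truth["library"], ones)
        assert np.abs(res.diet.values - small_truth["diets"]).max() > 0.01

    def test_objective_separates_over_predators(self, small_truth):
        """Fitting predators one at a time equals fitting them together."""
        preds = small_truth["predators"]
        lib = small_truth["library"]
        full = fit_conditioned(preds, lib, small_truth["cc"])
        for j in [0, 7]:
            solo = fit_conditioned(
                PredatorSample(preds.signatures[j : j + 1], preds.ids[j : j + 1], preds.labels),
                lib,
                small_truth["cc"],
            )
            assert np.allclose(solo.diet.values[0], full.diet.values[j], atol=1e-9)

    def test_agrees_with_joint_on_noise_free_data(self, small_truth):
        joint = fit_joint(small_truth["predators"], small_truth["library"])
        cond = fit_conditioned(
            small_truth["predators"], small_truth["library"], small_truth["cc"]
        )
        assert np.abs(joint.diet.values - cond.diet.values).max() < 1e-8


class TestClassSummary:
    def test_single_member_class(self):
        diet = np.array([[0.2, 0.8]])
        s = summarize_by_class(diet, ["adult"])
        assert np.allclose(s.means[0], [0.2, 0.8])
        assert np.all(s.ses[0] == 0.0)
        assert s.counts[0] == 1

    def test_two_opposite_diets(self):
        diet = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = summarize_by_class(diet, ["a", "a"])
        assert np.allclose(s.means[0], [0.5, 0.5])
        assert np.allclose(s.ses[0], [0.5, 0.5])

    def test_matches_numpy_oracle(self, rng):
        diet = rng.dirichlet(np.ones(4), size=12)
        classes = list("aabbbcccccdd")
        s = summarize_by_class(diet, classes)
        for ci, cl in enumerate(s.classes):
            rows = diet[[x == cl for x in classes]]
            assert np.allclose(s.means[ci], rows.mean(axis=0))
            if rows.shape[0] > 1:
                assert np.allclose(
                    s.ses[ci], rows.std(axis=0, ddof=1) / math.sqrt(rows.shape[0])
                )

    def test_missing_labels_excluded_with_warning(self):
        diet = np.array([[0.5, 0.5], [0.1, 0.9], [0.4, 0.6]])
        with pytest.warns(UserWarning, match="without a class label"):
            s = summarize_by_class(diet, ["a", None, "a"])
        assert s.counts.sum() == 2
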