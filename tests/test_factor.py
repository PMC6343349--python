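"""Fitness-curve and relevance behaviour of single-factor fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsindex.factor import FactorModel, fit_factor, fitness_value, max_youden
from dsindex.variables import VariableSpec

from conftest import oracle_relevance


class TestRelevanceEndpoints:
    def test_identical_distributions_have_relevance_zero(self, cont_spec):
        m = fit_factor([1, 2, 3, 4], [1, 2, 3, 4], cont_spec)
        assert m.relevance == 0.0

    def test_disjoint_distributions_have_relevance_one(self, cont_spec):
        m = fit_factor([5, 6, 7, 8], [1, 2, 3, 4], cont_spec)
        assert m.relevance == 1.0

    def test_partial_overlap_matches_bruteforce(self, cont_spec):
        # cases {3,4,5} vs controls {1,2,3}: best threshold gives J = 2/3
        m = fit_factor([3, 4, 5], [1, 2, 3], cont_spec)
        assert m.relevance == pytest.approx(2 / 3)
        assert m.relevance == pytest.approx(oracle_relevance([3, 4, 5], [1, 2, 3]))

    def test_constant_identical_classes(self, cont_spec):
        m = fit_factor([5.0, 5.0], [5.0, 5.0], cont_spec)
        assert m.relevance == 0.0

    def test_empty_class_raises(self, cont_spec):
        with pytest.raises(ValueError):
            fit_factor([], [1, 2], cont_spec)
        with pytest.raises(ValueError):
            fit_factor([np.nan, np.nan], [1, 2], cont_spec)


class TestFitnessCurve:
    @pytest.fixture
    def model(self, cont_spec):
        return fit_factor([5, 6, 7], [1, 2, 3], cont_spec)

    def test_control_unique_value_scores_zero(self, model):
        assert fitness_value(model, 1) == 0.0

    def test_case_unique_value_scores_one(self, model):
        assert fitness_value(model, 7) == 1.0

    def test_below_support_clamps_to_zero(self, model):
        assert fitness_value(model, -10) == 0.0

    def test_above_support_clamps_to_one(self, model):
        assert fitness_value(model, 100) == 1.0

    def test_midway_value_interpolates_linearly(self, model):
        # support neighbours 3 (fitness 0) and 5 (fitness 1)
        assert fitness_value(model, 4) == pytest.approx(0.5)

    def test_missing_value_gives_missing_fitness(self, model):
        assert np.isnan(fitness_value(model, np.nan))

    def test_cases_low_orientation_mirrors(self, cont_spec):
        m = fit_factor([1, 2, 3], [5, 6, 7], cont_spec)
        assert m.orientation == "cases_low"
        assert m.relevance == 1.0
        assert fitness_value(m, 1) == 1.0
        assert fitness_value(m, 7) == 0.0


class TestOracleEquivalence:
    def test_exhaustive_small_samples(self, cont_spec):
        """All case/control multisets of size <= 3 over a 4-point grid."""
        grid = [0, 1, 2, 3]
        pools = [list(c) for k in (1, 2, 3)
                 for c in itertools.combinations_with_replacement(grid, k)]
        for cases in pools:
            for controls in pools:
                got = fit_factor(cases, controls, cont_spec).relevance
                want = oracle_relevance(cases, controls)
                assert got == pytest.approx(want), (cases, controls)

    @settings(derandomize=True, max_examples=200)
    @given(cases=st.lists(st.integers(0, 4), min_size=1, max_size=6),
           controls=st.lists(st.integers(0, 4), min_size=1, max_size=6))
    def test_random_samples_match_oracle(self, cases, controls):
        spec = VariableSpec("x", "continuous", "g")
        got = fit_factor(cases, controls, spec).relevance
        assert got == pytest.approx(oracle_relevance(cases, controls))


class TestInvariants:
    @settings(derandomize=True, max_examples=100)
    @given(cases=st.lists(st.floats(-50, 50), min_size=1, max_size=10),
           controls=st.lists(st.floats(-50, 50), min_size=1, max_size=10))
    def test_relevance_and_fitness_in_unit_interval(self, cases, controls):
        spec = VariableSpec("x", "continuous", "g")
        m = fit_factor(cases, controls, spec)
        assert 0.0 <= m.relevance <= 1.0
        assert (m.fitness_at_support >= 0).all()
        assert (m.fitness_at_support <= 1).all()

    @pytest.mark.parametrize("transform", [
        lambda x: 3 * x + 7,
        lambda x: x ** 3,
        lambda x: np.exp(x / 10.0),
    ])
    def test_monotone_transform_leaves_relevance_and_fitness(self, cont_spec,
                                                             transform):
        rng = np.random.default_rng(5)
        cases = rng.normal(2, 1, 15)
        controls = rng.normal(0, 1, 15)
        base = fit_factor(cases, controls, cont_spec)
        trans = fit_factor(transform(cases), transform(controls), cont_spec)
        assert trans.relevance == pytest.approx(base.relevance)
        assert trans.orientation == base.orientation
        np.testing.assert_allclose(
            trans.fitness_array(transform(base.support)),
            base.fitness_at_support, atol=1e-12)

    def test_max_youden_agrees_with_fit(self, cont_spec):
        rng = np.random.default_rng(11)
        cases = rng.normal(1, 1, 8)
        controls = rng.normal(0, 1, 8)
        rel, orient = max_youden(cases, controls)
        m = fit_factor(cases, controls, cont_spec)
        assert rel == pytest.approx(m.relevance)
        assert orient == m.orientation


class TestCategorical:
    @pytest.fixture
    def spec(self):
        return VariableSpec("geno", "categorical", "g")

    def test_fitness_is_case_share(self, spec):
        m = fit_factor(["a", "a", "b"], ["b", "b", "a"], spec)
        # p_case(a)=2/3, p_ctrl(a)=1/3 -> fitness 2/3
        assert m.fitness("a") == pytest.approx(2 / 3)
        assert m.fitness("b") == pytest.approx(1 / 3)

    def test_identical_distributions_relevance_zero(self, spec):
        m = fit_factor(["a", "b"], ["a", "b"], spec)
        assert m.relevance == 0.0

    def test_disjoint_categories_relevance_one(self, spec):
        m = fit_factor(["a", "a"], ["b", "b"], spec)
        assert m.relevance == 1.0
        assert m.fitness("a") == 1.0
        assert m.fitness("b") == 0.0

    def test_unseen_category_is_missing(self, spec):
        m = fit_factor(["a"], ["b"], spec)
        assert np.isnan(m.fitness("zzz"))

    def test_binary_kind_uses_category_path(self):
        spec = VariableSpec("flag", "binary", "g")
        m = fit_factor([1, 1, 0], [0, 0, 1], spec)
        assert m.orientation == "per_category"
        assert m.fitness(1) == pytest.approx(2 / 3)


class TestSerialization:
    def test_roundtrip_preserves_scores(self, cont_spec):
        m = fit_factor([3, 4, 5], [1, 2, 3], cont_spec)
        m2 = FactorModel.from_dict(m.to_dict())
        xs = np.linspace(0, 6, 17)
        np.testing.assert_allclose(m2.fitness_array(xs), m.fitness_array(xs))
        assert m2.relevance == m.relevance
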