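"""Principal-component factoring and the loading-threshold selection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsindex import (
    Override,
    prepare,
    RunConfig,
    analyze_group,
    correlation_matrix,
    principal_factor,
    select_variables,
)
from hsindex.factor import PrincipalFactorSelector
from hsindex.index import HumanSecurityIndex

from conftest import PUBLISHED_LOADINGS, flat_specs, make_table, population_pcf_loadings


def power_iteration(mat: np.ndarray, iterations: int = 5000) -> tuple[float, np.ndarray]:
    """Independent leading-eigenpair oracle (deterministic start)."""
    vec = np.ones(mat.shape[0]) / np.sqrt(mat.shape[0])
    for _ in range(iterations):
        nxt = mat @ vec
        nxt = nxt / np.linalg.norm(nxt)
        vec = nxt
    eigenvalue = float(vec @ mat @ vec)
    return eigenvalue, vec


def random_correlation(rng: np.random.Generator, p: int) -> np.ndarray:
    """Random valid correlation matrix via a random data panel."""
    panel = rng.standard_normal((p + 20, p)) @ rng.standard_normal((p, p))
    return np.corrcoef(panel, rowvar=False)


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_offdiagonal(self):
        col = np.array([1.0, 4, 2, 8, 5])
        z = pd.DataFrame({"a": col, "b": col})
        corr = correlation_matrix(z)
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(np.diag(corr.to_numpy()), np.ones(2))

    def test_negated_column_gives_minus_one(self):
        col = np.array([1.0, 4, 2, 8, 5])
        corr = correlation_matrix(pd.DataFrame({"a": col, "b": -col}))
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_quotient_oracle(self):
        """Entries equal independently coded cov/sd ratios to 1e-12."""
        rng = np.random.default_rng(3)
        panel = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
        corr = correlation_matrix(panel)
        x = panel.to_numpy()
        for i in range(4):
            for j in range(4):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                expected = (xi @ xj / 99) / (
                    np.sqrt(xi @ xi / 99) * np.sqrt(xj @ xj / 99)
                )
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(corr, corr.T)

    def test_too_few_rows_or_columns_rejected(self):
        with pytest.raises(ValueError, match="3 counties"):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}))
        with pytest.raises(ValueError, match="2 variables"):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2, 3]}))

    def test_incomplete_data_rejected(self):
        z = pd.DataFrame({"a": [1.0, np.nan, 3], "b": [2.0, 1, 4]})
        with pytest.raises(ValueError, match="complete"):
            correlation_matrix(z)


class TestPrincipalFactor:
    def test_perfect_pair_closed_form(self):
        eigenvalue, loadings = principal_factor(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert eigenvalue == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(loadings, [1.0, 1.0], atol=1e-12)

    # r=0 is excluded: the eigenspace degenerates and the loading vector
    # is no longer unique
    @pytest.mark.parametrize("r", [-0.6, 0.15, 0.3, 0.95])
    def test_two_variable_closed_form(self, r):
        """Eigenvalue 1+|r| with equal loadings sqrt((1+|r|)/2) up to sign."""
        eigenvalue, loadings = principal_factor(np.array([[1.0, r], [r, 1.0]]))
        assert eigenvalue == pytest.approx(1.0 + abs(r), abs=1e-12)
        assert np.allclose(np.abs(loadings), np.sqrt((1 + abs(r)) / 2), atol=1e-12)

    def test_against_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.integers(3, 10)
            corr = random_correlation(rng, int(p))
            eigenvalue, loadings = principal_factor(corr)
            oracle_eig, oracle_vec = power_iteration(corr)
            assert eigenvalue == pytest.approx(oracle_eig, abs=1e-8)
            oracle_loadings = oracle_vec * np.sqrt(oracle_eig)
            if oracle_loadings.sum() < 0:
                oracle_loadings = -oracle_loadings
            assert np.allclose(loadings, oracle_loadings, atol=1e-8)

    def test_loading_identity_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            corr = random_correlation(rng, 6)
            eigenvalue, loadings = principal_factor(corr)
            assert np.sum(loadings**2) == pytest.approx(eigenvalue, abs=1e-9)
            assert np.all(np.abs(loadings) <= 1 + 1e-9)
            assert eigenvalue <= 6 + 1e-9

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(13)
        corr = random_correlation(rng, 5)
        first = principal_factor(corr)
        second = principal_factor(corr.copy())
        assert first[0] == second[0]
        assert np.array_equal(first[1], second[1])
        assert first[1].sum() > 0 or first[1][np.argmax(np.abs(first[1]))] > 0

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            principal_factor(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestSelectVariables:
    @pytest.mark.parametrize(
        "group, expected_count",
        [("economic", 4), ("education", 5), ("crime", 2), ("health", 4)],
    )
    def test_published_selection_counts(self, group, expected_count):
        """Strict |loading| > 0.5 reproduces the published per-group counts."""
        selected = select_variables(PUBLISHED_LOADINGS[group], RunConfig())
        assert len(selected) == expected_count

    def test_economic_excludes_the_exact_half_loading(self):
        selected = select_variables(PUBLISHED_LOADINGS["economic"], RunConfig())
        assert "unemployment_pct" not in selected  # 0.50 fails strict > 0.5
        assert "gini_coefficient" in selected  # |-0.77| qualifies

    def test_inclusive_mode_admits_boundary(self):
        cfg = RunConfig(threshold_mode="inclusive")
        selected = select_variables(PUBLISHED_LOADINGS["economic"], cfg)
        assert "unemployment_pct" in selected and len(selected) == 5

    def test_signed_comparison_drops_negative_loadings(self):
        cfg = RunConfig(use_absolute_loading=False)
        selected = select_variables(PUBLISHED_LOADINGS["economic"], cfg)
        assert "gini_coefficient" not in selected and len(selected) == 3

    def test_all_zero_loadings_select_nothing(self):
        assert select_variables({"a": 0.0, "b": 0.0}, RunConfig()) == []

    def test_overrides_bypass_rule(self):
        loadings = {"a": 0.9, "b": 0.3, "c": 0.8}
        overrides = {"b": Override.FORCE_INCLUDE, "c": Override.FORCE_EXCLUDE}
        assert select_variables(loadings, RunConfig(), overrides) == ["a", "b"]

    def test_config_order_preserved(self):
        loadings = {"z": 0.9, "a": 0.8, "m": 0.7}
        assert select_variables(loadings, RunConfig()) == ["z", "a", "m"]

    @given(st.floats(min_value=0.05, max_value=0.95),
           st.floats(min_value=0.05, max_value=0.95))
    @settings(deadline=None, max_examples=100)
    def test_threshold_monotonicity(self, t1, t2):
        """Raising the threshold never adds variables."""
        lo, hi = sorted([t1, t2])
        loadings = dict(zip("abcdefgh", [0.1, -0.3, 0.55, 0.72, -0.81, 0.49, 0.96, -0.5]))
        low = set(select_variables(loadings, RunConfig(loading_threshold=lo)))
        high = set(select_variables(loadings, RunConfig(loading_threshold=hi)))
        assert high <= low


class TestAnalyzeGroup:
    def test_perfectly_correlated_pair_eigenvalue_two(self):
        base = np.array([1.0, 4, 2, 8, 5, 9])
        table = make_table({"a": base, "b": 2 * base + 3})
        z = prepare(table, flat_specs(["a", "b"]), RunConfig())
        result = analyze_group(z, "economic", RunConfig(), flat_specs(["a", "b"]))
        assert result.eigenvalue == pytest.approx(2.0, abs=1e-9)
        assert result.selected == ["a", "b"]

    def test_group_reduced_to_one_variable_degenerates_with_warning(self):
        table = make_table({"a": [1.0, 4, 2, 8, 5], "flat": [3.0] * 5})
        specs = flat_specs(["a", "flat"])
        z = prepare(table, specs, RunConfig())
        with pytest.warns(UserWarning, match="degenerate"):
            result = analyze_group(z, "economic", RunConfig(), specs)
        assert result.degenerate and result.eigenvalue is None
        assert result.selected == [] and result.loadings == {}

    def test_estimates_converge_to_population_pcf_value(self, big_clean_table,
                                                        study_specs):
        """At n=5000 each group's loadings sit within sampling error of the
        method's population value (leading eigenpair of the model
        correlation matrix) — the attainable consistency statement."""
        hsi = HumanSecurityIndex(specs=study_specs).fit(big_clean_table)
        truth = big_clean_table.meta["truth"]
        for group, result in hsi.factor_results_.items():
            lam = np.array(truth["groups"][group]["loadings"])
            _, expected = population_pcf_loadings(lam)
            estimated = np.array([result.loadings[v]
                                  for v in truth["groups"][group]["variables"]])
            # 0.08 covers eigenvector sampling noise at n=5000 even for the
            # environmental group, whose small eigengap amplifies it
            assert np.abs(estimated - expected).max() < 0.08

    def test_large_n_selection_matches_population_rule(self, big_clean_table,
                                                       study_specs):
        """Selected sets at n=5000 equal the threshold rule applied to the
        population loadings of the principal-component method."""
        hsi = HumanSecurityIndex(specs=study_specs).fit(big_clean_table)
        truth = big_clean_table.meta["truth"]
        for group, result in hsi.factor_results_.items():
            names = truth["groups"][group]["variables"]
            lam = np.array(truth["groups"][group]["loadings"])
            _, expected = population_pcf_loadings(lam)
            predicted = [n for n, l in zip(names, expected) if abs(l) > 0.5]
            assert result.selected == predicted


class TestPrincipalFactorSelector:
    def test_fit_exposes_sklearn_attributes(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(400)
        panel = pd.DataFrame({
            "strong": 0.9 * f + np.sqrt(1 - 0.81) * rng.standard_normal(400),
            "weak": 0.1 * f + np.sqrt(1 - 0.01) * rng.standard_normal(400),
            "mid": 0.8 * f + np.sqrt(1 - 0.64) * rng.standard_normal(400),
        })
        sel = PrincipalFactorSelector(threshold=0.5).fit(panel)
        assert sel.eigenvalue_ > 1.0
        assert sel.support_.tolist() == [True, False, True]
        assert sel.selected_ == ["strong", "mid"]
        assert list(sel.transform(panel).columns) == ["strong", "mid"]
        clone_params = PrincipalFactorSelector(**sel.get_params())
        assert clone_params.get_params() == sel.get_params()
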