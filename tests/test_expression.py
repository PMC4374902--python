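import numpy as np
import pandas as pd
import pytest

from ctra_wellbeing.expression import (
    ExpressionMatrix,
    long_to_wide,
    marker_covariates,
    prepare_ctra_response,
    quantile_normalize,
    sign_adjust,
    standardize_genes,
    to_long_format,
)
from ctra_wellbeing.genesets import CtraGeneSet


def matrix_from(values, genes, subjects, **kw):
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=subjects)
    return ExpressionMatrix(values=df, **kw)


class TestQuantileNormalize:
    def test_identical_distributions_fixed_point(self):
        vals = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]])
        m = matrix_from(vals, ["a", "b", "c"], ["s1", "s2"])
        out = quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), vals)
        assert out.quantile_normalized

    def test_hand_computed_3x3(self):
        # sorted columns: (1,2,3), (10,20,30), (4,5,9) -> reference (5, 9, 14)
        vals = np.array([[1.0, 30.0, 5.0], [2.0, 10.0, 9.0], [3.0, 20.0, 4.0]])
        out = quantile_normalize(matrix_from(vals, list("abc"), list("xyz"))).values.to_numpy()
        expected = np.array([[5.0, 14.0, 9.0], [9.0, 5.0, 14.0], [14.0, 9.0, 5.0]])
        assert np.allclose(out, expected)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 50.0, size=(40, 6))
        out = quantile_normalize(
            matrix_from(vals, [f"g{i}" for i in range(40)], [f"s{j}" for j in range(6)])
        ).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(6):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_ties_get_mean_reference_value(self):
        vals = np.array([[1.0, 5.0], [1.0, 6.0], [3.0, 7.0]])
        out = quantile_normalize(matrix_from(vals, list("abc"), ["s1", "s2"])).values
        assert out.at["a", "s1"] == pytest.approx(out.at["b", "s1"])

    def test_missing_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            quantile_normalize(matrix_from(vals, ["a", "b"], ["s1", "s2"]))


class TestStandardize:
    def test_rows_centered_and_scaled(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.normal(8, 2, (5, 30)), [f"g{i}" for i in range(5)],
                        [f"s{j}" for j in range(30)], value_space="log2")
        out = standardize_genes(m)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12
        assert np.allclose(out.values.std(axis=1, ddof=1), 1.0)

    def test_location_invariance_and_sd_retention(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (3, 10))
        m1 = matrix_from(base, list("abc"), range(10), value_space="log2")
        m2 = matrix_from(base + np.array([[5.0], [1.0], [-2.0]]), list("abc"), range(10),
                         value_space="log2")
        assert np.allclose(standardize_genes(m1).values, standardize_genes(m2).values)
        out = standardize_genes(m1, scale_sd=False)
        assert np.allclose(out.values.std(axis=1, ddof=1), base.std(axis=1, ddof=1))

    def test_hand_computed_z_scores(self):
        vals = np.array([[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 4.0, 4.0]])
        out = standardize_genes(
            matrix_from(vals, ["a", "b"], list("wxyz"), value_space="log2")
        ).values.to_numpy()
        sd0 = np.std([1, 3, 5, 7], ddof=1)
        assert np.allclose(out[0], (vals[0] - 4.0) / sd0)

    def test_zero_variance_gene_named(self):
        vals = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="flatgene"):
            standardize_genes(
                matrix_from(vals, ["flatgene", "ok"], list("abc"), value_space="log2")
            )


def toy_gene_set():
    return CtraGeneSet(symbols=("up1", "up2", "down1"), signs=(1, 1, -1),
                       categories=("proinflammatory", "proinflammatory", "interferon"))


class TestSignAdjust:
    def test_only_negative_rows_negated(self):
        vals = np.arange(12.0).reshape(3, 4)
        m = matrix_from(vals, ["up1", "up2", "down1"], list("wxyz"), value_space="standardized")
        out = sign_adjust(m, toy_gene_set())
        assert np.allclose(out.values.loc["up1"], vals[0])
        assert np.allclose(out.values.loc["down1"], -vals[2])
        assert out.sign_adjusted

    def test_all_positive_set_is_identity(self):
        gs = CtraGeneSet(symbols=("up1", "up2"), signs=(1, 1), categories=("p", "p"))
        vals = np.arange(8.0).reshape(2, 4)
        m = matrix_from(vals, ["up1", "up2"], list("wxyz"), value_space="standardized")
        assert np.allclose(sign_adjust(m, gs).values, vals)

    def test_double_application_guarded_and_involutive(self):
        vals = np.arange(12.0).reshape(3, 4)
        m = matrix_from(vals, ["up1", "up2", "down1"], list("wxyz"), value_space="standardized")
        once = sign_adjust(m, toy_gene_set())
        with pytest.raises(ValueError, match="already"):
            sign_adjust(once, toy_gene_set())
        from dataclasses import replace
        twice = sign_adjust(replace(once, sign_adjusted=False), toy_gene_set())
        assert np.allclose(twice.values, vals)

    def test_commutes_with_sd_standardization(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 1.5, (3, 40))
        m = matrix_from(vals, ["up1", "up2", "down1"], range(40), value_space="log2")
        a = sign_adjust(standardize_genes(m, scale_sd=True), toy_gene_set())
        from dataclasses import replace
        pre = replace(m, values=m.values.mul(
            pd.Series([1, 1, -1], index=["up1", "up2", "down1"]), axis=0))
        b = standardize_genes(pre, scale_sd=True)
        assert np.abs(a.values.to_numpy() - b.values.to_numpy()).max() < 1e-12


class TestMarkersAndLongFormat:
    def _matrix(self, n=10):
        rng = np.random.default_rng(4)
        genes = ["up1", "up2", "down1"] + [f"m{i}" for i in range(8)]
        vals = rng.normal(8, 1, (11, n))
        return matrix_from(vals, genes, [f"s{j}" for j in range(n)], value_space="log2")

    def test_marker_columns_equal_matrix_rows(self):
        m = self._matrix()
        cov = marker_covariates(m, [f"m{i}" for i in range(8)])
        assert cov.shape == (10, 8)
        assert np.allclose(cov["m3"], m.values.loc["m3"])

    def test_marker_arity_and_presence_guards(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="8"):
            marker_covariates(m, [f"m{i}" for i in range(7)])
        with pytest.raises(KeyError, match="absent"):
            marker_covariates(m, [f"m{i}" for i in range(7)] + ["missing"])

    def test_markers_disjoint_from_response_rows(self):
        m = self._matrix()
        response = prepare_ctra_response(m, toy_gene_set())
        assert not set(response.genes) & {f"m{i}" for i in range(8)}

    def test_long_format_counts_and_round_trip(self):
        m = self._matrix()
        response = prepare_ctra_response(m, toy_gene_set())
        predictors = pd.DataFrame(
            {"x": np.arange(10.0)}, index=[f"s{j}" for j in range(10)]
        )
        long = to_long_format(response, toy_gene_set(), predictors)
        assert len(long) == 3 * 10
        assert long.attrs["n_complete"] == 10
        wide = long_to_wide(long)
        assert np.allclose(wide.to_numpy(), response.values.T.to_numpy())

    def test_subject_with_missing_predictor_dropped_entirely(self):
        m = self._matrix()
        response = prepare_ctra_response(m, toy_gene_set())
        predictors = pd.DataFrame(
            {"x": np.arange(10.0), "bmi": [np.nan] + [25.0] * 9},
            index=[f"s{j}" for j in range(10)],
        )
        long = to_long_format(response, toy_gene_set(), predictors)
        assert "s0" not in set(long["subject_id"])
        assert len(long) == 3 * 9
        assert long.attrs["n_complete"] == 9


class TestPipelineOrder:
    def test_raw_input_runs_full_chain(self):
        rng = np.random.default_rng(5)
        genes = ["up1", "up2", "down1"]
        m = matrix_from(rng.gamma(4, 60, (3, 20)), genes, range(20), value_space="raw")
        out = prepare_ctra_response(m, toy_gene_set())
        assert out.value_space == "standardized"
        assert out.quantile_normalized and out.sign_adjusted

    def test_stage_order_enforced(self):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.normal(8, 1, (3, 20)), ["up1", "up2", "down1"], range(20),
                        value_space="log2")
        with pytest.raises(ValueError, match="raw"):
            quantile_normalize(m)
        std = standardize_genes(m)
        with pytest.raises(ValueError, match="log2"):
            standardize_genes(std)
        with pytest.raises(ValueError, match="sign-adjusted"):
            to_long_format(std, toy_gene_set(), pd.DataFrame(index=std.subjects))
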