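"""TPM scaling, correlation, Fisher-z, JSD and bias regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drnakit.concordance import (
    bias_regression,
    compute_tpm,
    correlate_features,
    correlate_samples,
    correlation_sweep,
    fisher_z_test,
    jensen_shannon_divergence,
    sample_jsd,
)
from drnakit.datatypes import AbundanceMatrix


def matrix_of(values, features=None, samples=None, **kw):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=features,
                                        columns=samples), **kw)


class TestTpm:
    def test_length_normalized_hand_example(self):
        matrix = matrix_of([[30.0], [10.0]])
        tpm = compute_tpm(matrix, {"g0": 300.0, "g1": 100.0})
        np.testing.assert_allclose(tpm.data["s0"], [500000.0, 500000.0])
        assert tpm.length_normalized

    def test_unnormalized_hand_example(self):
        matrix = matrix_of([[30.0], [10.0]])
        tpm = compute_tpm(matrix, length_normalize=False)
        np.testing.assert_allclose(tpm.data["s0"], [750000.0, 250000.0])
        assert not tpm.length_normalized

    def test_equal_counts_and_lengths_give_uniform_tpm(self):
        matrix = matrix_of(np.full((4, 2), 7.0))
        tpm = compute_tpm(matrix, dict.fromkeys([f"g{i}" for i in range(4)], 500.0))
        np.testing.assert_allclose(tpm.data.to_numpy(), 1e6 / 4)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        matrix = matrix_of(rng.poisson(50, size=(40, 5)))
        lengths = {f"g{i}": float(l) for i, l in
                   enumerate(rng.integers(200, 5000, size=40))}
        tpm = compute_tpm(matrix, lengths)
        np.testing.assert_allclose(tpm.data.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_total_names_sample(self):
        with pytest.raises(ValueError, match="s0"):
            compute_tpm(matrix_of([[0.0], [0.0]]), length_normalize=False)


class TestCorrelation:
    def test_identical_matrices_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        a = matrix_of(rng.poisson(30, size=(20, 4)))
        res = correlate_samples(a, a)
        np.testing.assert_allclose(res["r"], 1.0)

    def test_positive_scaling_invariance_on_raw_scale(self):
        rng = np.random.default_rng(2)
        a = matrix_of(rng.poisson(30, size=(20, 4)))
        b = matrix_of(2.0 * a.data.to_numpy())
        res = correlate_samples(a, b, scale="raw")
        np.testing.assert_allclose(res["r"], 1.0, atol=1e-12)

    def test_too_few_shared_features_is_an_error(self):
        a = matrix_of([[1.0], [2.0]])
        with pytest.raises(ValueError, match="3 shared"):
            correlate_samples(a, a)

    def test_constant_feature_excluded_with_reason(self):
        rng = np.random.default_rng(3)
        values = rng.poisson(30, size=(5, 6)).astype(float)
        values[0] = 9.0
        a = matrix_of(values)
        b = matrix_of(rng.poisson(30, size=(5, 6)))
        res = correlate_features(a, b).set_index("feature_id")
        assert res.loc["g0", "excluded"] == "zero variance"
        assert np.isnan(res.loc["g0", "r"])

    def test_threshold_above_all_means_empties_result(self):
        rng = np.random.default_rng(4)
        a = matrix_of(rng.poisson(30, size=(5, 6)))
        assert len(correlate_features(a, a, min_expression=1e9)) == 0

    def test_sweep_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        a = matrix_of(rng.poisson(20, size=(30, 6)))
        b = matrix_of(rng.poisson(20, size=(30, 6)))
        thresholds = [0, 5, 15, 25]
        sweep = correlation_sweep(a, b, thresholds)
        for _, row in sweep.iterrows():
            keep = (a.data.mean(axis=1) >= row["min_expression"]) & (
                b.data.mean(axis=1) >= row["min_expression"]
            )
            brute = 0
            for fid in a.data.index[keep]:
                x = np.log2(a.data.loc[fid].to_numpy() + 1)
                y = np.log2(b.data.loc[fid].to_numpy() + 1)
                if np.ptp(x) and np.ptp(y):
                    brute += 1
            assert row["n_features"] == brute


class TestFisherZ:
    def test_equal_correlations_give_null_result(self):
        z, p = fisher_z_test(0.7, 50, 0.7, 50)
        assert z == 0.0
        assert p == 1.0

    def test_known_case_matches_closed_form(self):
        # closed form: (atanh(.9) - atanh(.8)) / sqrt(2/97) = 2.601873...
        z, p = fisher_z_test(0.9, 100, 0.8, 100)
        assert z == pytest.approx(2.601873, abs=1e-5)
        assert p == pytest.approx(0.0092716, abs=1e-6)

    def test_antisymmetric_in_arguments(self):
        z1, p1 = fisher_z_test(0.9, 80, 0.6, 120)
        z2, p2 = fisher_z_test(0.6, 120, 0.9, 80)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_test(1.0, 50, 0.5, 50)


class TestJsd:
    def test_identical_distributions_have_zero_divergence(self):
        assert jensen_shannon_divergence([0.2, 0.8], [0.2, 0.8]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_upper_bound(self):
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_known_mixed_case(self):
        value = jensen_shannon_divergence([1.0, 0.0], [0.5, 0.5])
        assert value == pytest.approx(0.311278, abs=1e-5)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            jensen_shannon_divergence([0.0, 0.0], [0.5, 0.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_direct_kl_summation(self, seed):
        """Property: equals 0.5 KL(p||m) + 0.5 KL(q||m) computed directly."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 12))
        p = rng.random(k) + 1e-12
        q = rng.random(k) + 1e-12
        p /= p.sum()
        q /= q.sum()
        m = 0.5 * (p + q)
        direct = 0.5 * np.sum(p * np.log2(p / m)) + 0.5 * np.sum(
            q * np.log2(q / m)
        )
        value = jensen_shannon_divergence(p, q)
        assert value == pytest.approx(direct, abs=1e-12)
        assert value == pytest.approx(jensen_shannon_divergence(q, p), abs=1e-12)
        assert -1e-12 <= value <= 1.0 + 1e-12

    def test_per_sample_jsd_zero_at_identity(self):
        rng = np.random.default_rng(6)
        a = matrix_of(rng.poisson(40, size=(15, 3)))
        assert (sample_jsd(a, a)["jsd"].abs() < 1e-12).all()


class TestBiasRegression:
    def _models(self, lengths, gcs=None):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(lengths))],
            "length": lengths,
            "gc_fraction": gcs if gcs is not None else [0.5] * len(lengths),
        })

    def test_constant_covariate_rejected(self):
        matrix = matrix_of([[1.0], [2.0], [3.0]])
        with pytest.raises(ValueError, match="zero-variance covariate"):
            bias_regression(matrix, self._models([100, 100, 100]))

    def test_length_proportional_counts_flatten_under_normalization(self):
        """counts = c * length: TPM removes the length effect exactly
        (slope 0), while CPM-style scaling keeps a positive slope."""
        lengths = np.array([200.0, 500.0, 1000.0, 2000.0, 5000.0])
        counts = np.tile(3.0 * lengths[:, None], (1, 4))
        matrix = matrix_of(counts)
        models = self._models(lengths)
        tpm = compute_tpm(matrix, dict(zip(models["gene_id"], lengths)))
        assert bias_regression(tpm, models).slope == pytest.approx(0.0, abs=1e-9)
        cpm = compute_tpm(matrix, length_normalize=False)
        assert bias_regression(cpm, models).slope > 0.1

    def test_r_squared_is_square_of_r(self):
        rng = np.random.default_rng(7)
        lengths = rng.integers(200, 5000, size=30).astype(float)
        matrix = matrix_of(rng.poisson(40, size=(30, 3)))
        fit = bias_regression(matrix, self._models(lengths))
        assert fit.r_squared == pytest.approx(fit.pearson_r**2, abs=1e-12)
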