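import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ruminet import (
    CountMatrix,
    ExpressionMatrix,
    ValidationError,
    cpm,
    filter_by_cpm,
    log_cpm,
    muscle_normalize,
    quantile_normalize_joint,
)


def make_counts(counts, libsizes=None):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"G{i}" for i in range(counts.shape[0])],
        [f"S{j}" for j in range(counts.shape[1])],
        counts,
        library_sizes=libsizes,
    )


def make_expr(values, provenance=("logcpm",), sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"G{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values,
        provenance=list(provenance),
    )


class TestCpm:
    def test_formula(self):
        mat = cpm(make_counts([[10], [90]], libsizes=[100]))
        assert np.allclose(mat[:, 0], [1e5, 9e5])

    def test_all_zero_gene_row(self):
        mat = cpm(make_counts([[0, 0], [5, 5]]))
        assert np.all(mat[0] == 0)

    def test_single_gene_equals_million(self):
        mat = cpm(make_counts([[1234]]))
        assert mat[0, 0] == 1e6

    def test_column_sums_are_million_for_default_libsizes(self):
        rng = np.random.default_rng(3)
        mat = cpm(make_counts(rng.integers(1, 100, size=(30, 4))))
        assert np.allclose(mat.sum(axis=0), 1e6)


class TestFilterByCpm:
    def test_three_cpm_rule(self):
        cm = make_counts([[5, 5], [0, 10]], libsizes=[1_000_000, 1_000_000])
        assert filter_by_cpm(cm, 3.0, "ge") == ["G0"]

    def test_gt_zero_retains_genes_nonzero_everywhere(self):
        cm = make_counts([[1, 1], [0, 5], [3, 2]])
        assert filter_by_cpm(cm, 0.0, "gt") == ["G0", "G2"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        cm = make_counts(rng.integers(0, 50, size=(100, 6)))
        previous = None
        for threshold in (0.5, 1.0, 3.0, 10.0, 100.0):
            kept = set(filter_by_cpm(cm, threshold, "ge"))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestLogCpm:
    def test_zero_count_value(self):
        expr = log_cpm(make_counts([[0]], libsizes=[999_999]))
        assert expr.values[0, 0] == pytest.approx(-1.0)

    def test_count_one(self):
        expr = log_cpm(make_counts([[1]], libsizes=[999_999]))
        assert expr.values[0, 0] == pytest.approx(np.log2(1.5))

    def test_depends_only_on_offset_ratio(self):
        # the transform is a pure function of (count + 0.5)/(libsize + 1):
        # scaling both numerator and denominator leaves the value unchanged
        a = log_cpm(make_counts([[10]], libsizes=[999]))
        assert a.values[0, 0] == pytest.approx(
            np.log2((10 + 0.5) / (999 + 1) * 1e6)
        )
        ratio = (10 + 0.5) / (999 + 1)
        for scale in (2.0, 7.5):
            assert np.log2(ratio * scale / scale * 1e6) == pytest.approx(
                a.values[0, 0]
            )

    def test_finite_for_all_zero_matrix(self):
        expr = log_cpm(make_counts([[0], [5]]))
        assert np.all(np.isfinite(expr.values))


def brute_force_quantile(values):
    """Independent oracle: rank-mean substitution with spanned-tie averaging."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        positions = {}
        for pos, idx in enumerate(order):
            positions.setdefault(col[idx], []).append(pos)
        for idx in range(n):
            span = positions[col[idx]]
            out[idx, j] = reference[span].mean()
    return out


class TestQuantileNormalizeJoint:
    def test_two_column_rank_average(self):
        a = make_expr([[1], [2], [3]])
        b = make_expr([[4], [5], [6]], sample_prefix="T")
        combined = quantile_normalize_joint(a, b)
        assert np.allclose(combined.values[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(combined.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        a = make_expr([[1.0], [5.0], [2.0]])
        b = make_expr([[1.0], [5.0], [2.0]], sample_prefix="T")
        combined = quantile_normalize_joint(a, b)
        assert np.allclose(combined.values, [[1], [5], [2]])

    def test_ties_receive_mean_of_spanned_quantiles(self):
        a = make_expr([[1], [1], [2]])
        b = make_expr([[3], [4], [5]], sample_prefix="T")
        combined = quantile_normalize_joint(a, b)
        assert np.allclose(combined.values[:, 0], [2.25, 2.25, 3.5])

    def test_gene_list_mismatch_reports_difference(self):
        a = make_expr([[1], [2]])
        b = ExpressionMatrix(["G0", "GX"], ["T0"], np.array([[1.0], [2.0]]))
        with pytest.raises(ValidationError, match="GX"):
            quantile_normalize_joint(a, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle_and_preserves_ranks(self, seed):
        rng = np.random.default_rng(seed)
        n, ma, mb = 15, 3, 2
        values = np.round(rng.normal(size=(n, ma + mb)), 1)  # rounding makes ties
        a = make_expr(values[:, :ma])
        b = make_expr(values[:, ma:], sample_prefix="T")
        combined = quantile_normalize_joint(a, b)
        assert np.allclose(combined.values, brute_force_quantile(values), atol=1e-12)
        for j in range(ma + mb):
            orig = values[:, j]
            new = combined.values[:, j]
            for i in range(n):
                for k in range(n):
                    if orig[i] < orig[k]:
                        assert new[i] <= new[k]


class TestMuscleNormalize:
    def test_subtracts_per_sample_muscle_mean(self):
        expr = make_expr([[4, 5], [6, 7], [7, 9]])
        out = muscle_normalize(expr, {"G0", "G1"})  # muscle means [5, 6]
        assert np.allclose(out.values[2], [2, 3])

    def test_muscle_set_mean_exactly_zero(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(10, 4)))
        out = muscle_normalize(expr, {"G0", "G3", "G7"})
        means = out.values[[0, 3, 7], :].mean(axis=0)
        assert np.allclose(means, 0.0, atol=1e-14)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.normal(size=(8, 3)))
        once = muscle_normalize(expr, {"G1", "G2"})
        twice = muscle_normalize(once, {"G1", "G2"})
        assert np.allclose(once.values, twice.values, atol=1e-14)

    def test_between_gene_differences_unchanged(self):
        rng = np.random.default_rng(3)
        expr = make_expr(rng.normal(size=(6, 5)))
        out = muscle_normalize(expr, {"G0"})
        assert np.allclose(
            expr.values[2] - expr.values[4], out.values[2] - out.values[4]
        )

    def test_empty_set_rejected(self):
        expr = make_expr([[1.0]])
        with pytest.raises(ValidationError, match="empty"):
            muscle_normalize(expr, set())
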