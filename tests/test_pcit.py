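import numpy as np
import pytest

from ruminet import (
    CorrelationMatrix,
    ExpressionMatrix,
    ValidationError,
    build_network,
    partial_correlation,
    pcit_keep_mask,
    pearson_matrix,
)


def naive_pcit_reject(r):
    """Independent triple-loop reference for the trio rejection rule."""
    n = r.shape[0]
    reject = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z in (x, y):
                    continue
                pxy = (r[x, y] - r[x, z] * r[y, z]) / np.sqrt(
                    (1 - r[x, z] ** 2) * (1 - r[y, z] ** 2)
                )
                pxz = (r[x, z] - r[x, y] * r[y, z]) / np.sqrt(
                    (1 - r[x, y] ** 2) * (1 - r[y, z] ** 2)
                )
                pyz = (r[y, z] - r[x, y] * r[x, z]) / np.sqrt(
                    (1 - r[x, y] ** 2) * (1 - r[x, z] ** 2)
                )
                terms = []
                for partial, direct in ((pxy, r[x, y]), (pxz, r[x, z]), (pyz, r[y, z])):
                    if direct != 0 and np.isfinite(partial / direct):
                        terms.append(abs(partial / direct))
                if not terms:
                    continue
                eps = float(np.mean(terms))
                if abs(r[x, y]) < eps * abs(r[x, z]) and abs(r[x, y]) < eps * abs(r[y, z]):
                    reject[x, y] = reject[y, x] = True
    return reject


def random_corr(rng, n_genes, n_samples=12):
    x = rng.standard_normal((n_genes, n_samples))
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return r


def corr_matrix(r):
    return CorrelationMatrix([f"G{i}" for i in range(r.shape[0])], r, n_samples=10)


class TestPearsonMatrix:
    def test_identical_and_negated_profiles(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        expr = ExpressionMatrix(
            ["A", "B", "C"], ["S0", "S1", "S2", "S3"],
            np.vstack([base, base, -base]),
        )
        cm = pearson_matrix(expr)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        expr = ExpressionMatrix(
            ["A", "B"], ["S0", "S1", "S2"],
            np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]]),
        )
        assert pearson_matrix(expr).r[0, 1] == pytest.approx(0.5)

    def test_zero_variance_gene_excluded_with_warning(self):
        expr = ExpressionMatrix(
            ["A", "B"], ["S0", "S1", "S2"],
            np.array([[1.0, 1.0, 1.0], [1.0, 3.0, 2.0]]),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = pearson_matrix(expr)
        assert cm.gene_ids == ["B"]

    def test_too_few_samples_rejected(self):
        expr = ExpressionMatrix(["A"], ["S0", "S1"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValidationError, match="3 samples"):
            pearson_matrix(expr)


class TestPartialCorrelation:
    def test_uncorrelated_conditioner_is_identity(self):
        assert partial_correlation(0.6, 0.0, 0.0) == pytest.approx(0.6)

    def test_worked_value(self):
        assert partial_correlation(0.8, 0.5, 0.5) == pytest.approx(0.55 / 0.75)

    def test_exact_product_gives_zero(self):
        assert partial_correlation(0.35, 0.7, 0.5) == pytest.approx(0.0)

    def test_degenerate_conditioner_flagged(self):
        assert np.isnan(partial_correlation(0.5, 1.0, 0.2))

    def test_matches_formula_on_random_valid_triples(self, rng):
        for _ in range(200):
            r = random_corr(rng, 3)
            expected = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
                (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
            )
            assert partial_correlation(r[0, 1], r[0, 2], r[1, 2]) == pytest.approx(
                expected, abs=1e-12
            )


class TestPcitKeepMask:
    def test_two_genes_single_edge_kept(self):
        r = np.array([[1.0, 0.3], [0.3, 1.0]])
        result = pcit_keep_mask(corr_matrix(r))
        assert result.keep_mask[0, 1] and result.keep_mask[1, 0]
        assert not result.keep_mask[0, 0]

    def test_worked_three_gene_example(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.7], [0.9, 0.7, 1.0]])
        result = pcit_keep_mask(corr_matrix(r))
        assert result.keep_mask[0, 1] and result.keep_mask[0, 2]
        assert not result.keep_mask[1, 2]

    def test_diagonal_only_matrix_keeps_nothing_informative(self):
        r = np.eye(4)
        result = pcit_keep_mask(corr_matrix(r))
        net = build_network(corr_matrix(r), result, 0.0)
        assert net.number_of_edges() == 0

    def test_matches_naive_reference_on_random_matrices(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 15))
            r = random_corr(rng, n)
            result = pcit_keep_mask(corr_matrix(r))
            expected = ~naive_pcit_reject(r)
            np.fill_diagonal(expected, False)
            assert np.array_equal(result.keep_mask, expected)

    def test_degenerate_zero_direct_correlation_trio(self):
        # direct r[0,1] = 0: the t1 ratio term is skipped, tolerance averaged
        # over the remaining two; the naive reference applies the same rule
        r = np.array(
            [
                [1.0, 0.0, 0.6],
                [0.0, 1.0, 0.5],
                [0.6, 0.5, 1.0],
            ]
        )
        result = pcit_keep_mask(corr_matrix(r))
        expected = ~naive_pcit_reject(r)
        np.fill_diagonal(expected, False)
        assert np.array_equal(result.keep_mask, expected)

    def test_permutation_equivariance(self, rng):
        r = random_corr(rng, 12)
        mask = pcit_keep_mask(corr_matrix(r)).keep_mask
        perm = rng.permutation(12)
        permuted = pcit_keep_mask(corr_matrix(r[np.ix_(perm, perm)])).keep_mask
        assert np.array_equal(permuted, mask[np.ix_(perm, perm)])


class TestBuildNetwork:
    def _three_gene(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.7], [0.9, 0.7, 1.0]])
        cm = corr_matrix(r)
        return cm, pcit_keep_mask(cm)

    def test_threshold_one_empty(self):
        cm, res = self._three_gene()
        assert build_network(cm, res, 1.0).number_of_edges() == 0

    def test_worked_example_network(self):
        cm, res = self._three_gene()
        net = build_network(cm, res, 0.8)
        assert set(net.nodes()) == {"G0", "G1", "G2"}
        assert {tuple(sorted(e)) for e in net.edges()} == {("G0", "G1"), ("G0", "G2")}
        assert net["G0"]["G1"]["weight"] == pytest.approx(0.9)

    def test_full_mask_zero_threshold_complete_graph(self, rng):
        r = random_corr(rng, 6)
        cm = corr_matrix(r)
        full = pcit_keep_mask(cm)
        full.keep_mask[:] = ~np.eye(6, dtype=bool)
        net = build_network(cm, full, 0.0)
        assert net.number_of_edges() == 15

    def test_monotone_threshold(self, rng):
        r = random_corr(rng, 10)
        cm = corr_matrix(r)
        res = pcit_keep_mask(cm)
        edges = {}
        for t in (0.0, 0.3, 0.6, 0.9):
            edges[t] = {tuple(sorted(e)) for e in build_network(cm, res, t).edges()}
        assert edges[0.9] <= edges[0.6] <= edges[0.3] <= edges[0.0]
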