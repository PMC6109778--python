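import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ruminet import (
    ExpressionMatrix,
    SimConfig,
    ValidationError,
    bh_fdr,
    cluster_mean_expression,
    de_fit,
    log_cpm,
    prioritize,
    rank_joint_negative,
    select_extremes,
    simulate_pair,
)


def make_expr(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        [f"G{i}" for i in range(values.shape[0])], samples, values
    )


class TestSelectExtremes:
    def test_basic_split(self):
        mrt = pd.Series(range(1, 21), index=[f"s{i:02d}" for i in range(20)], dtype=float)
        short, long_ = select_extremes(mrt, 10)
        assert [mrt[s] for s in short] == list(range(1, 11))
        assert [mrt[s] for s in long_] == list(range(11, 21))

    def test_boundary_tie_resolved_by_id_with_warning(self):
        mrt = pd.Series([1, 2, 2, 3, 4, 5], index=list("fedcba"), dtype=float)
        with pytest.warns(UserWarning, match="tie"):
            short, _ = select_extremes(mrt, 2)
        assert short == ["f", "d"]  # ties at 2 broken lexicographically

    def test_k_zero_rejected(self):
        mrt = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            select_extremes(mrt, 0)

    def test_missing_values_do_not_count(self):
        mrt = pd.Series([1.0, np.nan, 3.0], index=list("abc"))
        with pytest.raises(ValidationError, match="non-missing"):
            select_extremes(mrt, 2)


class TestDeFit:
    def test_constant_gene_p_one_convention(self):
        expr = make_expr([[5.0] * 6])
        group = pd.Series(["short"] * 3 + ["long"] * 3, index=expr.sample_ids)
        out = de_fit(expr, group)
        assert out.iloc[0]["coef"] == 0.0
        assert out.iloc[0]["p"] == 1.0

    def test_matches_pooled_two_sample_t(self):
        expr = make_expr([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]])
        group = pd.Series(["short"] * 3 + ["long"] * 3, index=expr.sample_ids)
        out = de_fit(expr, group)
        assert out.iloc[0]["coef"] == pytest.approx(2.0)
        assert out.iloc[0]["t"] == pytest.approx(2.449, abs=1e-3)
        assert out.iloc[0]["p"] == pytest.approx(0.0705, abs=2e-3)

    def test_matches_two_sample_t_on_random_data(self, rng):
        values = rng.normal(size=(30, 14))
        expr = make_expr(values)
        group = pd.Series(["short"] * 7 + ["long"] * 7, index=expr.sample_ids)
        out = de_fit(expr, group)
        for i in range(30):
            t, p = stats.ttest_ind(values[i, 7:], values[i, :7], equal_var=True)
            assert out.iloc[i]["t"] == pytest.approx(t, abs=1e-10)
            assert out.iloc[i]["p"] == pytest.approx(p, abs=1e-10)

    def test_block_confounded_with_group_rejected(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(3, 6)))
        group = pd.Series(["short"] * 3 + ["long"] * 3, index=expr.sample_ids)
        block = pd.Series(["b1"] * 3 + ["b2"] * 3, index=expr.sample_ids)
        with pytest.raises(ValidationError, match="collinear"):
            de_fit(expr, group, block=block)

    def test_composition_confound_removed_by_signature_covariate(self):
        # genes that differ between groups only through tissue composition
        # have a near-zero adjusted group coefficient; without the covariate
        # the same genes show strong spurious differences
        flagged_with, flagged_without = 0, 0
        for seed in range(10):
            cfg = SimConfig(
                n_genes=300,
                cluster_sizes={
                    "muscle": 40, "muscle_junction": 10, "cell_cycle": 15,
                    "epithelial_diff": 15, "general_metab": 20, "lipid_oxo": 15,
                },
                effect_map={"mrt": [("muscle_junction", -0.58)]},
                mrt_muscle_fraction_r=-0.8,  # strong planted confound
                muscle_logit_sd=1.0,
                seed=seed,
            )
            counts_a, _, phen_a, _, truth = simulate_pair(cfg)
            expr = log_cpm(counts_a)
            short, long_ = select_extremes(phen_a.column("mrt"), 10)
            ext = short + long_
            group = pd.Series(["short"] * 10 + ["long"] * 10, index=ext)
            sig = cluster_mean_expression(expr, truth.members("muscle"))
            sub = expr.subset_samples(ext)
            with_cov = de_fit(sub, group, covariate=sig.loc[ext])
            without = de_fit(sub, group)
            muscle = sorted(truth.members("muscle"))
            flagged_with += int((with_cov.loc[muscle, "q"] < 0.1).sum())
            flagged_without += int((without.loc[muscle, "q"] < 0.1).sum())
        assert flagged_without > flagged_with
        assert flagged_with <= 0.1 * flagged_without + 5


def step_up_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            assert np.allclose(bh_fdr(p), step_up_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_and_rank_monotone(self, p_values):
        q = bh_fdr(p_values)
        p = np.asarray(p_values)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestRankJointNegative:
    def _frames(self, pairs):
        idx = [f"G{i}" for i in range(len(pairs))]
        mrt = pd.DataFrame({"r": [a for a, _ in pairs]}, index=idx)
        yld = pd.DataFrame({"r": [b for _, b in pairs]}, index=idx)
        return mrt, yld

    def test_positive_on_either_axis_excluded(self):
        mrt, yld = self._frames([(-0.5, 0.1), (-0.5, -0.1), (0.2, -0.4)])
        assert rank_joint_negative(mrt, yld, 3) == ["G1"]

    def test_ranked_by_sum_most_negative_first(self):
        mrt, yld = self._frames([(-0.5, -0.1), (-0.2, -0.45)])
        assert rank_joint_negative(mrt, yld, 2) == ["G1", "G0"]

    def test_k_exceeding_candidates_warns_and_returns_all(self):
        mrt, yld = self._frames([(-0.5, -0.1), (0.3, -0.4)])
        with pytest.warns(UserWarning, match="candidates"):
            out = rank_joint_negative(mrt, yld, 10)
        assert out == ["G0"]


class TestPrioritize:
    def _de(self, qs):
        idx = [f"G{i}" for i in range(len(qs))]
        return pd.DataFrame(
            {"coef": 1.0, "se": 0.1, "t": 2.0, "p": qs, "q": qs}, index=idx
        )

    def test_empty_significant_set(self):
        de = self._de([0.5, 0.9])
        assert len(prioritize(de, ["G0", "G1"], fdr=0.1)) == 0

    def test_intersection_with_ranked_list(self):
        de = self._de([0.01, 0.5, 0.05])
        out = prioritize(de, ["G2", "G1"], fdr=0.1)
        assert list(out.index) == ["G2"]

    def test_significant_but_unranked_excluded(self):
        de = self._de([0.01])
        assert len(prioritize(de, [], fdr=0.1)) == 0
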