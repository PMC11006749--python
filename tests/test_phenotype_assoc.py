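"""Expression normalisation/ranking and survival comparison machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from abtslc.errors import AbtslcError
from abtslc.phenotype_assoc import (ExpressionMatrix, expression_by_mutation,
                                    expression_rank, filter_low_expression,
                                    km_logrank, normalize_counts,
                                    rank_sum_test, size_factors)


def matrix(values, genes=None, samples=None, mode="raw_counts"):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            mode=mode)


class TestExpressionRank:
    def test_log2_median(self):
        tpm = matrix([[0, 0, 0], [1, 3, 7]], genes=["ZERO", "SOME"], mode="tpm")
        out = expression_rank(tpm, ["ZERO", "SOME"]).set_index("gene")
        assert out.loc["ZERO", "median_log2_tpm"] == 0
        assert out.loc["SOME", "median_log2_tpm"] == pytest.approx(2.0)

    def test_planted_ordering_recovered(self):
        rng = np.random.default_rng(3)
        medians = np.linspace(1, 40, 20)
        rows = [np.full(31, m) + rng.uniform(-0.4, 0.4, 31) for m in medians]
        genes = [f"G{i:02d}" for i in range(20)]
        tpm = matrix(np.vstack(rows), genes=genes, mode="tpm")
        out = expression_rank(tpm, genes)
        assert list(out["gene"]) == genes[::-1]  # descending planted medians

    def test_absent_gene_excluded(self):
        tpm = matrix([[1, 2]], genes=["A"], mode="tpm")
        out = expression_rank(tpm, ["A", "MISSING"])
        assert list(out["gene"]) == ["A"]

    def test_requires_tpm_mode(self):
        with pytest.raises(AbtslcError):
            expression_rank(matrix([[1, 2]]), ["G0"])


class TestFilterLowExpression:
    def test_zero_row_removed(self):
        m = matrix([[0, 0], [5, 6]])
        out = filter_low_expression(m, min_total=1)
        assert list(out.genes) == ["G1"]

    def test_min_total_zero_is_identity(self):
        m = matrix([[0, 0], [5, 6]])
        out = filter_low_expression(m, min_total=0)
        assert list(out.genes) == ["G0", "G1"]

    def test_matches_bruteforce_rowsum_scan(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(3, size=(60, 10))
        m = matrix(vals)
        out = filter_low_expression(m, min_total=30)
        expected = [f"G{i}" for i in range(60) if vals[i].sum() >= 30]
        assert list(out.genes) == expected

    def test_all_removed_is_error(self):
        with pytest.raises(AbtslcError):
            filter_low_expression(matrix([[1, 1]]), min_total=100)


class TestSizeFactors:
    def test_rank_one_matrix_recovers_column_scalars(self):
        base = np.array([10.0, 40.0, 160.0, 20.0])
        counts = np.outer(base, [1, 2, 4])
        s = size_factors(matrix(counts))
        assert np.allclose(s, [0.5, 1.0, 2.0], atol=1e-9)

    def test_single_sample_factor_one(self):
        s = size_factors(matrix([[4], [9]]))
        assert s.iloc[0] == pytest.approx(1.0)

    def test_no_all_positive_gene_is_error(self):
        with pytest.raises(AbtslcError, match="filter"):
            size_factors(matrix([[0, 5], [5, 0]]))

    def test_normalized_median_ratio_is_one(self):
        """For every sample, the median over all-positive genes of
        normalized count / geometric-mean reference equals 1."""
        rng = np.random.default_rng(8)
        mu = rng.uniform(5, 300, 40)
        s_true = np.array([0.5, 0.8, 1.0, 1.3, 2.0])
        counts = rng.poisson(np.outer(mu, s_true)) + 1
        norm = normalize_counts(matrix(counts))
        ref = np.exp(np.mean(np.log(counts), axis=1, keepdims=True))
        med = np.median(norm.values.to_numpy() / ref, axis=0)
        assert np.allclose(med, 1.0, atol=1e-9)

    def test_planted_factor_recovery(self):
        rng = np.random.default_rng(15)
        mu = rng.uniform(50, 500, 300)
        s_true = np.linspace(0.5, 2.0, 8)
        s_true /= np.exp(np.mean(np.log(s_true)))
        disp = 0.05
        n = 1 / disp
        counts = rng.negative_binomial(
            n, n / (n + np.outer(mu, s_true))) + 1
        s_hat = size_factors(matrix(counts)).to_numpy()
        assert np.all(np.abs(s_hat / s_true - 1) < 0.05)


class TestRankSum:
    def test_identical_groups_p_one(self):
        _, p, _ = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self):
        """3-vs-3 fully separated groups: enumerate all 20 assignments of
        ranks; the two most extreme give two-sided p = 0.1."""
        x, y = [1, 2, 3], [10, 11, 12]
        u_obs, p, method = rank_sum_test(x, y)
        assert method == "exact"
        pooled = sorted(x + y)
        n1 = len(x)
        u_null = []
        for combo in itertools.combinations(range(6), n1):
            vals = [pooled[i] for i in combo]
            u = sum(1 for a in vals for b in pooled
                    if b not in vals and a > b)
            u_null.append(u)
        center = len(x) * len(y) / 2
        p_enum = np.mean([abs(u - center) >= abs(u_obs - center)
                          for u in u_null])
        assert p == pytest.approx(p_enum)
        assert p == pytest.approx(0.1)

    def test_exact_agrees_with_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pooled = rng.choice(1000, size=8, replace=False).astype(float)
            x, y = pooled[:4], pooled[4:]
            u_obs, p, method = rank_sum_test(x, y)
            assert method == "exact"
            u_null = []
            for combo in itertools.combinations(range(8), 4):
                vals = pooled[list(combo)]
                rest = np.delete(pooled, list(combo))
                u_null.append(np.sum(vals[:, None] > rest[None, :]))
            center = 4 * 4 / 2
            p_enum = np.mean([abs(u - center) >= abs(u_obs - center) - 1e-9
                              for u in u_null])
            assert p == pytest.approx(p_enum)

    def test_type_one_error_nominal(self):
        """Both groups from one normal distribution: rejection at 0.05
        within +/-0.02 over 500 replicates (asymptotic mode)."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            _, p, _ = rank_sum_test(x, y)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestExpressionByMutation:
    def test_group_assignment_and_errors(self):
        m = matrix([[1, 2, 3, 4]], genes=["G"],
                   samples=["A", "B", "C", "D"], mode="normalized")
        res = expression_by_mutation(m, "G", {"A", "B"})
        assert res.n_mutant == 2 and res.n_non_mutant == 2
        with pytest.raises(AbtslcError, match="mutant"):
            expression_by_mutation(m, "G", set())
        with pytest.raises(AbtslcError, match="non-mutant"):
            expression_by_mutation(m, "G", {"A", "B", "C", "D"})
        with pytest.raises(AbtslcError, match="absent"):
            expression_by_mutation(m, "NOPE", {"A"})


def hand_logrank(times_a, events_a, times_b, events_b):
    """Independent O/E/V tabulation of the two-group log-rank statistic."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.array([0] * len(times_a) + [1] * len(times_b))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKmLogrank:
    def test_identical_groups(self):
        clin = pd.DataFrame({
            "patient": [f"P{i}" for i in range(6)],
            "time_days": [5, 10, 15, 5, 10, 15],
            "event": [1, 0, 1, 1, 0, 1],
            "cohort": "X"})
        res = km_logrank(clin, {"P0", "P1", "P2"})
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulation_fixture(self):
        """Group A events at {1, 2}, group B at {3, 4}: chi-square matches
        the hand O/E/V computation to 1e-9."""
        clin = pd.DataFrame({
            "patient": ["A1", "A2", "B1", "B2"],
            "time_days": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
            "cohort": "X"})
        res = km_logrank(clin, {"A1", "A2"})
        expected = hand_logrank(np.array([1.0, 2.0]), np.array([1, 1]),
                                np.array([3.0, 4.0]), np.array([1, 1]))
        assert res.chi_square == pytest.approx(expected, abs=1e-9)

    def test_km_curve_properties(self):
        clin = pd.DataFrame({
            "patient": [f"P{i}" for i in range(5)],
            "time_days": [2.0, 4.0, 4.0, 6.0, 9.0],
            "event": [1, 1, 0, 1, 0],
            "cohort": "X"})
        res = km_logrank(clin, {"P0"})
        curve = res.curves["non_mutant"]
        surv = curve["survival"].to_numpy()
        assert np.all(np.diff(surv) <= 1e-12)
        assert surv[0] == pytest.approx(1.0)
        # product-limit by hand for the non-mutant group {4E, 4C, 6E, 9C}:
        # S(4) = 1 - 1/4 = 0.75 ; S(6) = 0.75 * (1 - 1/2) = 0.375
        s_of = dict(zip(curve["time"], surv))
        assert s_of[4.0] == pytest.approx(0.75)
        assert s_of[6.0] == pytest.approx(0.375)

    def test_zero_events_is_error(self):
        clin = pd.DataFrame({"patient": ["A", "B"], "time_days": [1.0, 2.0],
                             "event": [0, 0], "cohort": "X"})
        with pytest.raises(AbtslcError, match="events"):
            km_logrank(clin, {"A"})

    def test_negative_times_dropped(self):
        clin = pd.DataFrame({
            "patient": ["A", "B", "C", "D"],
            "time_days": [1.0, 2.0, -5.0, np.nan],
            "event": [1, 1, 1, 1], "cohort": "X"})
        res = km_logrank(clin, {"A"})
        assert sum(res.n_by_group.values()) == 2
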