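"""Incidence counting, oncoplot summaries, ranking curves and TMB."""

import numpy as np
import pandas as pd
import pytest

from abtslc.errors import AbtslcError
from abtslc.gene_catalog import GeneSetCatalog
from abtslc.maf_io import filter_qualifying
from abtslc.mutation_landscape import (MULTI_HIT_LABEL, gene_incidence,
                                       oncoplot_summary, rank_and_accumulate,
                                       sample_tmb)
from abtslc.synthetic_data import SimConfig, simulate_maf

from conftest import make_registry, make_table


def brute_force_incidence(table, registry, genes):
    """Independent one-pass scan: gene -> set of mutated registered samples."""
    hit: dict = {g: set() for g in genes}
    registered = set(registry.samples)
    for _, row in table.df.iterrows():
        if row["gene"] in hit and row["sample"] in registered:
            hit[row["gene"]].add(row["sample"])
    return {g: len(s) for g, s in hit.items()}


class TestGeneIncidence:
    def test_direct_count(self):
        registry = make_registry([(f"S{i}", "C") for i in range(10)])
        table = make_table([("X", "S0", "C", "Missense_Mutation"),
                            ("X", "S0", "C", "Nonsense_Mutation"),
                            ("X", "S1", "C", "Missense_Mutation")])
        inc = gene_incidence(table, registry, ["X"])
        assert inc.per_gene.loc["X", "n_mutated_samples"] == 2
        assert inc.per_gene.loc["X", "n_mutations"] == 3
        assert inc.per_gene.loc["X", "incidence"] == pytest.approx(0.2)
        assert inc.set_incidence == pytest.approx(0.2)

    def test_empty_table_all_zero(self):
        registry = make_registry([("S0", "C")])
        table = make_table([])
        inc = gene_incidence(table, registry, ["X", "Y"])
        assert (inc.per_gene["incidence"] == 0).all()
        assert inc.set_incidence == 0

    def test_empty_registry_is_error(self):
        table = make_table([("X", "S0", "C", "Missense_Mutation")])
        with pytest.raises(AbtslcError):
            gene_incidence(table, make_registry([]), ["X"])

    def test_binomial_recovery_of_planted_rates(self):
        """Estimated incidence within 3 binomial SE of each planted p_g
        (no cohort burden variation, so realized rate equals p_g)."""
        config = SimConfig(seed=7, n_cohorts=4, samples_per_cohort=500,
                           cohort_sigma=0.0)
        table, registry, truth = simulate_maf(config)
        q = filter_qualifying(table, frozenset(config.classification_mix))
        inc = gene_incidence(q, registry, list(truth.gene_probs))
        n = registry.n_total
        for gene, p in truth.gene_probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(inc.per_gene.loc[gene, "incidence"] - p) <= 3 * se + 1e-12

    def test_set_incidence_bonferroni_bounds(self, sim_small):
        _, table, registry, truth = sim_small
        inc = gene_incidence(table, registry, list(truth.gene_probs))
        singles = inc.per_gene["incidence"]
        assert inc.set_incidence >= singles.max() - 1e-12
        assert inc.set_incidence <= singles.sum() + 1e-12

    def test_matches_bruteforce(self, sim_small):
        _, table, registry, truth = sim_small
        genes = list(truth.gene_probs)
        inc = gene_incidence(table, registry, genes)
        expected = brute_force_incidence(table, registry, genes)
        for g in genes:
            assert inc.per_gene.loc[g, "n_mutated_samples"] == expected[g]


class TestOncoplotSummary:
    def test_multi_hit_counted_once(self):
        registry = make_registry([("S0", "C"), ("S1", "C")])
        table = make_table([("X", "S0", "C", "Missense_Mutation"),
                            ("X", "S0", "C", "Nonsense_Mutation")])
        out = oncoplot_summary(table, ["X"], registry)
        assert out.loc["X", MULTI_HIT_LABEL] == 1
        assert out.loc["X", "n_mutated_samples"] == 1

    def test_single_record(self):
        registry = make_registry([("S0", "C"), ("S1", "C"), ("S2", "C"),
                                  ("S3", "C")])
        table = make_table([("X", "S0", "C", "Missense_Mutation")])
        out = oncoplot_summary(table, ["X"], registry)
        assert out.loc["X", "Missense_Mutation"] == 1
        assert out.loc["X", "pct_samples"] == pytest.approx(25.0)

    def test_row_sums_equal_gene_incidence(self, sim_small):
        _, table, registry, truth = sim_small
        genes = list(truth.gene_probs)
        inc = gene_incidence(table, registry, genes)
        out = oncoplot_summary(table, genes, registry)
        merged = out["n_mutated_samples"].sort_index()
        assert merged.equals(inc.per_gene["n_mutated_samples"].sort_index())
        # sorted by descending percentage
        assert (out["pct_samples"].diff().dropna() <= 1e-12).all()


class TestRankAndAccumulate:
    def _incidence(self, rows, registry, genes):
        return gene_incidence(make_table(rows), registry, genes)

    def test_single_group_curve_is_envelope(self):
        registry = make_registry([(f"S{i}", "C") for i in range(10)])
        rows = [("A", "S0", "C", "Missense_Mutation"),
                ("B", "S0", "C", "Missense_Mutation"),
                ("B", "S1", "C", "Missense_Mutation"),
                ("C", "S2", "C", "Missense_Mutation")]
        inc = self._incidence(rows, registry, ["A", "B", "C"])
        cat = GeneSetCatalog({"everything": ("A", "B", "C")})
        curves = rank_and_accumulate(inc, cat)
        assert np.allclose(curves.curves["everything"], curves.curves["all"])

    def test_single_top_gene_is_step_function(self):
        registry = make_registry([(f"S{i}", "C") for i in range(10)])
        rows = [("A", "S0", "C", "Missense_Mutation"),
                ("A", "S1", "C", "Missense_Mutation"),
                ("B", "S0", "C", "Missense_Mutation")]
        inc = self._incidence(rows, registry, ["A", "B", "Z"])
        cat = GeneSetCatalog({"top": ("A",), "rest": ("B", "Z")})
        curves = rank_and_accumulate(inc, cat)
        assert list(curves.curves["top"]) == pytest.approx([0.2, 0.2, 0.2])
        # zero-incidence gene Z keeps a trailing rank
        assert curves.ranking.loc[curves.ranking["gene"] == "Z", "rank"].iloc[0] == 3

    def test_group_totals_match_bruteforce_summation(self, sim_small, catalog):
        _, table, registry, truth = sim_small
        genes = list(truth.gene_probs)
        inc = gene_incidence(table, registry, genes)
        groups = {k: v for k, v in catalog.abt_groups().items()}
        curves = rank_and_accumulate(inc, GeneSetCatalog(groups))
        total = 0.0
        for name, members in groups.items():
            expected = sum(inc.per_gene.loc[g, "incidence"] for g in members)
            final = curves.curves[name].iloc[-1]
            assert final == pytest.approx(expected, abs=1e-12)
            total += final
        assert total <= curves.curves["all"].iloc[-1] + 1e-12

    def test_curves_monotone(self, sim_small, catalog):
        _, table, registry, truth = sim_small
        inc = gene_incidence(table, registry, list(truth.gene_probs))
        curves = rank_and_accumulate(inc, GeneSetCatalog(dict(catalog.abt_groups())))
        for col in curves.curves:
            assert (curves.curves[col].diff().dropna() >= -1e-15).all()

    def test_missing_catalog_gene_is_error(self):
        registry = make_registry([("S0", "C")])
        inc = gene_incidence(make_table([("A", "S0", "C", "Missense_Mutation")]),
                             registry, ["A"])
        with pytest.raises(AbtslcError, match="lacks"):
            rank_and_accumulate(inc, GeneSetCatalog({"g": ("A", "NOT_COVERED")}))


class TestSampleTmb:
    def test_odd_and_even_medians(self):
        registry = make_registry([("S0", "A"), ("S1", "A"), ("S2", "A"),
                                  ("S3", "B"), ("S4", "B")])
        rows = ([("G", "S0", "A", "Missense_Mutation")] * 1
                + [("G", "S1", "A", "Missense_Mutation")] * 3
                + [("G", "S2", "A", "Missense_Mutation")] * 5
                + [("G", "S3", "B", "Missense_Mutation")] * 2
                + [("G", "S4", "B", "Missense_Mutation")] * 4)
        tmb = sample_tmb(make_table(rows), registry)
        assert tmb.cohort_median["A"] == 3
        assert tmb.cohort_median["B"] == 3  # midpoint of {2, 4}

    def test_unmutated_registered_samples_count_zero(self):
        registry = make_registry([("S0", "A"), ("S1", "A")])
        tmb = sample_tmb(make_table([("G", "S0", "A", "Silent")]), registry)
        assert tmb.per_sample["S1"] == 0

    def test_negative_binomial_median_vs_monte_carlo(self):
        """Empirical cohort median within +/-1 of a brute-force sampled
        median of the same NegBin(mean 10, dispersion 1) distribution."""
        config = SimConfig(seed=3, n_cohorts=1, samples_per_cohort=500,
                           cohort_sigma=0.0, gene_probs={},
                           hotspot_fraction=0.0, protein_lengths={})
        table, registry, _ = simulate_maf(config)
        tmb = sample_tmb(table, registry)
        rng = np.random.default_rng(12345)
        n = 1.0 / config.burden_dispersion
        p = n / (n + config.burden_mean)
        reference = np.median(rng.negative_binomial(n, p, 200_000))
        assert abs(tmb.cohort_median.iloc[0] - reference) <= 1
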