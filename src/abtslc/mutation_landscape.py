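"""Per-gene incidence, oncoplot summaries, SLC ranking and mutation burden.

Incidence of a gene is the fraction of registered tumour samples carrying at
least one qualifying mutation in it; a sample is counted once per gene no
matter how many hits it carries.  The set-level incidence (any gene of a set)
is reported alongside.  Genes are ranked by descending incidence (ties broken
alphabetically) and per-group cumulative incidence curves are accumulated
along that ranking.  Tumour mutation burden (TMB) here is the count of
qualifying mutations per sample, not per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AbtslcError
from .gene_catalog import GeneSetCatalog
from .maf_io import MutationTable, SampleRegistry

MULTI_HIT_LABEL = "Multi_Hit"


@dataclass
class IncidenceTable:
    """Per-gene sample incidence plus the set-level ("any gene") incidence."""

    per_gene: pd.DataFrame  # index gene; n_mutated_samples, n_mutations, incidence
    n_total: int
    set_n_mutated: int
    set_incidence: float

    def incidence_of(self, gene: str) -> float:
        return float(self.per_gene.loc[gene, "incidence"])

    def to_tsv(self, path) -> None:
        self.per_gene.rename_axis("gene").to_csv(path, sep="\t")


@dataclass
class CumulativeCurves:
    """Global incidence ranking and per-group cumulative incidence curves.

    ``ranking`` lists every gene with its incidence and rank 1..G (descending
    incidence, alphabetical tie-break, zero-incidence genes trailing).
    ``curves`` is indexed by rank with one column per group: C_k(r) is the sum
    of incidences of that group's members with rank <= r; the ``all`` column is
    the running total over every ranked gene (the envelope).
    """

    ranking: pd.DataFrame  # columns gene, incidence, rank
    curves: pd.DataFrame   # index rank 1..G, one column per group + 'all'

    def to_tsv(self, ranking_path, curves_path) -> None:
        self.ranking.to_csv(ranking_path, sep="\t", index=False)
        self.curves.rename_axis("rank").to_csv(curves_path, sep="\t")


@dataclass
class TmbTable:
    """Qualifying mutation counts per sample and the per-cohort medians."""

    per_sample: pd.Series   # index sample, value count (0 for unmutated samples)
    cohort_median: pd.Series

    def to_tsv(self, path) -> None:
        self.per_sample.rename("tmb").rename_axis("sample").to_csv(path, sep="\t")


def gene_incidence(table: MutationTable, registry: SampleRegistry,
                   genes) -> IncidenceTable:
    """Count, per gene, distinct samples with >= 1 qualifying record.

    ``genes`` is the gene set of interest; genes absent from the table get
    incidence 0.  Records from samples not in the registry are ignored (they
    have no denominator).  Raises if the registry is empty.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise AbtslcError("gene set is empty")
    if registry.n_total == 0:
        raise AbtslcError("sample registry is empty (N_total = 0)")

    df = table.df[table.df["gene"].isin(genes)
                  & table.df["sample"].isin(registry.samples)]
    n_samples = df.groupby("gene")["sample"].nunique()
    n_muts = df.groupby("gene").size()
    per_gene = pd.DataFrame(index=pd.Index(sorted(genes), name="gene"))
    per_gene["n_mutated_samples"] = n_samples.reindex(per_gene.index).fillna(0).astype(int)
    per_gene["n_mutations"] = n_muts.reindex(per_gene.index).fillna(0).astype(int)
    per_gene["incidence"] = per_gene["n_mutated_samples"] / registry.n_total

    set_n = int(df["sample"].nunique())
    return IncidenceTable(per_gene=per_gene, n_total=registry.n_total,
                          set_n_mutated=set_n,
                          set_incidence=set_n / registry.n_total)


def oncoplot_summary(table: MutationTable, genes,
                     registry: SampleRegistry) -> pd.DataFrame:
    """Per-gene sample counts broken down by Variant_Classification.

    A sample carrying records of several classifications in one gene is
    counted once under the ``Multi_Hit`` label (oncoplot convention).  Rows
    are sorted by descending per-gene sample percentage, ties alphabetical.
    Row totals therefore equal the per-gene mutated-sample counts of
    :func:`gene_incidence`.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise AbtslcError("gene set is empty")
    if registry.n_total == 0:
        raise AbtslcError("sample registry is empty (N_total = 0)")

    df = table.df[table.df["gene"].isin(genes)
                  & table.df["sample"].isin(registry.samples)]
    per_pair = df.groupby(["gene", "sample"])["classification"].agg(
        lambda c: c.iloc[0] if c.nunique() == 1 else MULTI_HIT_LABEL)

    labels = sorted(set(per_pair.unique()) - {MULTI_HIT_LABEL})
    if (per_pair == MULTI_HIT_LABEL).any():
        labels.append(MULTI_HIT_LABEL)
    counts = (per_pair.rename("label").reset_index()
              .pivot_table(index="gene", columns="label", values="sample",
                           aggfunc="count", fill_value=0))
    counts = counts.reindex(index=sorted(genes), columns=labels, fill_value=0)
    counts = counts.astype(int)
    counts["n_mutated_samples"] = counts[labels].sum(axis=1)
    counts["pct_samples"] = 100.0 * counts["n_mutated_samples"] / registry.n_total
    counts = (counts.rename_axis("gene").reset_index()
              .sort_values(["pct_samples", "gene"], ascending=[False, True])
              .set_index("gene"))
    counts.columns.name = None
    return counts


def rank_and_accumulate(incidence: IncidenceTable,
                        catalog: GeneSetCatalog,
                        groups=None) -> CumulativeCurves:
    """Rank genes by descending incidence; accumulate per-group incidence.

    ``incidence`` must cover at least every gene appearing in the requested
    catalog groups (zero-incidence genes are retained so all group curves
    share a common x-axis).  Ties in incidence break alphabetically; genes
    with zero incidence receive trailing ranks by the same rule.
    """
    if groups is None:
        groups = list(catalog.groups)
    needed = {g for name in groups for g in catalog.genes(name)}
    have = set(incidence.per_gene.index)
    missing = needed - have
    if missing:
        raise AbtslcError(
            f"incidence table lacks {len(missing)} catalog genes, "
            f"e.g. {sorted(missing)[:5]}")

    ranking = (incidence.per_gene["incidence"].rename_axis("gene").reset_index()
               .sort_values(["incidence", "gene"], ascending=[False, True])
               .reset_index(drop=True))
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    inc = ranking["incidence"].to_numpy()
    curves = pd.DataFrame(index=pd.Index(ranking["rank"], name="rank"))
    curves["all"] = np.cumsum(inc)
    for name in groups:
        members = set(catalog.genes(name))
        mask = ranking["gene"].isin(members).to_numpy()
        curves[name] = np.cumsum(np.where(mask, inc, 0.0))
    return CumulativeCurves(ranking=ranking, curves=curves)


def sample_tmb(table: MutationTable, registry: SampleRegistry) -> TmbTable:
    """Qualifying mutation count per registered sample and cohort medians.

    Registered samples absent from the table receive count 0; cohort medians
    use the standard midpoint rule for even counts.  Records from unregistered
    samples are ignored.
    """
    if registry.n_total == 0:
        raise AbtslcError("sample registry is empty (N_total = 0)")
    counts = (table.df[table.df["sample"].isin(registry.samples)]
              .groupby("sample").size())
    per_sample = counts.reindex(registry.samples).fillna(0).astype(int)
    per_sample.index.name = "sample"
    medians = per_sample.groupby(registry.cohorts).median().sort_index()
    medians.index.name = "cohort"
    return TmbTable(per_sample=per_sample, cohort_median=medians)
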