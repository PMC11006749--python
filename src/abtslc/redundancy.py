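"""Within-sub-group co-mutation ("redundancy") statistics.

For tumours carrying at least one qualifying mutation in an ABT-SLC
sub-group, how many *additional* mutations does the same sub-group carry?
If sub-group function were essential and non-redundant, second hits should
be rare; widespread second hits suggest the sub-group tolerates (is
redundant to) a single loss.  Per sample s with m_s >= 1 sub-group mutation
records, the additional count is a_s = m_s - 1; sub-groups are compared by
one-way ANOVA on the pooled pan-cancer a_s values.

``m_s`` counts mutation records, not distinct mutated genes; a
distinct-gene mode is available behind ``count_genes=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import AbtslcError
from .gene_catalog import GeneSetCatalog
from .maf_io import MutationTable

logger = logging.getLogger(__name__)


@dataclass
class RedundancyResult:
    """Per-group additional-mutation summaries with the ANOVA across groups."""

    per_group: pd.DataFrame  # index group; n_samples, mean_additional
    f_statistic: float
    p_value: float
    values_by_group: dict

    def to_tsv(self, path) -> None:
        out = self.per_group.copy()
        out["anova_F"] = self.f_statistic
        out["anova_p"] = self.p_value
        out.rename_axis("group").to_csv(path, sep="\t")


def additional_mutation_counts(table: MutationTable, group,
                               count_genes: bool = False) -> pd.Series:
    """Per-sample additional mutation counts a_s = m_s - 1 within ``group``.

    Only samples with m_s >= 1 are returned (an empty Series means no sample
    carries a group mutation).  ``count_genes=True`` counts distinct mutated
    genes instead of mutation records.
    """
    group = set(group)
    if not group:
        raise AbtslcError("gene group is empty")
    df = table.df[table.df["gene"].isin(group)]
    if count_genes:
        m = df.groupby("sample")["gene"].nunique()
    else:
        m = df.groupby("sample").size()
    a = (m - 1).astype(int)
    a.name = "additional"
    return a


def redundancy_anova(values_by_group: dict) -> RedundancyResult:
    """One-way ANOVA of additional-mutation counts across sub-groups.

    Groups with fewer than 2 values are excluded with a warning; at least
    two groups must remain.  Identical group distributions give F ~ 0.
    """
    kept = {}
    for name, vals in values_by_group.items():
        vals = pd.Series(vals, dtype=float)
        if len(vals) < 2:
            logger.warning("redundancy_anova: group '%s' has %d value(s), excluded",
                           name, len(vals))
            continue
        kept[name] = vals
    if len(kept) < 2:
        raise AbtslcError("need >= 2 groups with >= 2 values each for ANOVA")

    f, p = stats.f_oneway(*kept.values())
    per_group = pd.DataFrame({
        "n_samples": {k: len(v) for k, v in kept.items()},
        "mean_additional": {k: float(v.mean()) for k, v in kept.items()},
    })
    per_group.index.name = "group"
    return RedundancyResult(per_group=per_group, f_statistic=float(f),
                            p_value=float(p), values_by_group=kept)


def redundancy_analysis(table: MutationTable, catalog: GeneSetCatalog,
                        count_genes: bool = False,
                        single_group_only: bool = False) -> RedundancyResult:
    """Additional-mutation ANOVA across the ABT sub-groups, pan-cancer pooled.

    ``single_group_only`` restricts to samples whose ABT mutations fall in
    exactly one sub-group (strict seed definition); by default every sample
    with >= 1 mutation in a sub-group contributes to that sub-group.
    """
    groups = catalog.abt_groups()
    values = {name: additional_mutation_counts(table, genes, count_genes)
              for name, genes in groups.items()}
    if single_group_only:
        membership = pd.DataFrame(
            {name: pd.Series(1, index=vals.index) for name, vals in values.items()})
        n_groups_hit = membership.notna().sum(axis=1)
        exclusive = set(n_groups_hit[n_groups_hit == 1].index)
        values = {name: vals[vals.index.isin(exclusive)]
                  for name, vals in values.items()}
    return redundancy_anova(values)
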