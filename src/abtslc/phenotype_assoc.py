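"""Mutation-stratified expression and overall-survival comparisons.

Expression side: raw gene-level counts are low-expression filtered, then
normalised by median-of-ratios size factors (each sample's counts divided by
the median ratio to a per-gene geometric-mean reference computed over genes
positive in every sample — the DESeq2 design ~1 normalisation).  Mutant vs
non-mutant samples are compared per gene by a two-sided Wilcoxon rank-sum
test.  TPM matrices support the per-gene median log2(TPM+1) ranking.

Survival side: overall survival of mutant vs non-mutant patients is compared
with Kaplan-Meier product-limit curves and the two-group log-rank test
(chi-square with 1 df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import AbtslcError

logger = logging.getLogger(__name__)

EXPRESSION_MODES = ("raw_counts", "tpm", "normalized")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with an explicit unit mode."""

    values: pd.DataFrame  # index genes, columns samples
    mode: str = "raw_counts"
    size_factors: pd.Series = None

    def __post_init__(self) -> None:
        if self.mode not in EXPRESSION_MODES:
            raise AbtslcError(f"unknown expression mode '{self.mode}'")
        if (self.values.to_numpy() < 0).any():
            raise AbtslcError("expression values must be non-negative")
        if self.mode == "raw_counts":
            vals = self.values.to_numpy()
            if not np.allclose(vals, np.round(vals)):
                raise AbtslcError("raw counts must be integers")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise AbtslcError("size factors must be > 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, mode: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, mode=mode)


@dataclass
class RankSumResult:
    gene: str
    n_mutant: int
    n_non_mutant: int
    median_mutant: float
    median_non_mutant: float
    statistic: float  # Mann-Whitney U of the mutant group
    p_value: float
    method: str


@dataclass
class KmLogrankResult:
    curves: dict            # group -> DataFrame(time, survival)
    chi_square: float
    p_value: float
    n_by_group: dict
    events_by_group: dict


def expression_rank(tpm: ExpressionMatrix, genes) -> pd.DataFrame:
    """Per-gene median log2(TPM+1), sorted descending (ties alphabetical)."""
    if tpm.mode != "tpm":
        raise AbtslcError("expression_rank requires a TPM matrix")
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in tpm.genes]
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.warning("expression_rank: %d genes absent from matrix: %s",
                       len(absent), absent[:5])
    med = np.log2(tpm.values.loc[present] + 1.0).median(axis=1)
    out = (med.rename("median_log2_tpm").rename_axis("gene").reset_index()
           .sort_values(["median_log2_tpm", "gene"], ascending=[False, True])
           .reset_index(drop=True))
    return out


def filter_low_expression(counts: ExpressionMatrix,
                          min_total: int = 10) -> ExpressionMatrix:
    """Drop genes whose total count across samples is below ``min_total``."""
    if counts.mode != "raw_counts":
        raise AbtslcError("filter_low_expression requires raw counts")
    keep = counts.values.sum(axis=1) >= min_total
    if not keep.any():
        raise AbtslcError("low-expression filter removed every gene")
    return ExpressionMatrix(counts.values.loc[keep], mode="raw_counts")


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (DESeq2 design ~1 convention).

    The reference is the per-gene geometric mean over samples, computed on
    genes with strictly positive counts in every sample; each sample's
    factor is the median over those genes of count / reference.
    """
    if counts.mode != "raw_counts":
        raise AbtslcError("size_factors requires raw counts")
    vals = counts.values.to_numpy(dtype=float)
    all_positive = (vals > 0).all(axis=1)
    if not all_positive.any():
        raise AbtslcError(
            "no gene has positive counts in every sample; "
            "apply a stronger low-expression filter first")
    log_vals = np.log(vals[all_positive])
    log_ref = log_vals.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_vals - log_ref, axis=0))
    return pd.Series(s, index=counts.samples, name="size_factor")


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts divided by their median-of-ratios size factors."""
    s = size_factors(counts)
    return ExpressionMatrix(counts.values / s, mode="normalized",
                            size_factors=s)


def rank_sum_test(x, y, exact_max_n: int = 20):
    """Two-sided Wilcoxon rank-sum; exact enumeration for small tie-free
    samples, normal approximation with tie correction otherwise.

    Returns ``(U_x, p, method)`` with U the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue), "asymptotic"


def expression_by_mutation(norm: ExpressionMatrix, gene: str,
                           mutant_samples) -> RankSumResult:
    """Rank-sum comparison of one gene's normalised counts, mutant vs not."""
    if gene not in norm.genes:
        raise AbtslcError(f"gene '{gene}' absent from expression matrix")
    mutant = [s for s in norm.samples if s in set(mutant_samples)]
    non_mutant = [s for s in norm.samples if s not in set(mutant_samples)]
    if not mutant:
        raise AbtslcError("mutant group is empty after intersecting samples")
    if not non_mutant:
        raise AbtslcError("non-mutant group is empty after intersecting samples")
    x = norm.values.loc[gene, mutant].to_numpy(dtype=float)
    y = norm.values.loc[gene, non_mutant].to_numpy(dtype=float)
    u, p, method = rank_sum_test(x, y)
    return RankSumResult(gene=gene, n_mutant=len(x), n_non_mutant=len(y),
                         median_mutant=float(np.median(x)),
                         median_non_mutant=float(np.median(y)),
                         statistic=u, p_value=p, method=method)


def load_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (patient, time_days, event, cohort columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str, "cohort": str})
    needed = {"patient", "time_days", "event"}
    if not needed.issubset(df.columns):
        raise AbtslcError(f"clinical table needs columns {sorted(needed)}")
    return df


def km_logrank(clinical: pd.DataFrame, mutant_patients) -> KmLogrankResult:
    """Kaplan-Meier curves and two-group log-rank test, mutant vs non-mutant.

    ``clinical`` columns: patient, time_days (overall survival or censoring
    time), event (1 = death, 0 = censored).  Patients with missing or
    negative times are dropped with a warning; both groups must be non-empty
    and at least one event must exist.
    """
    df = clinical.copy()
    bad = df["time_days"].isna() | (df["time_days"] < 0) | df["event"].isna()
    if bad.any():
        logger.warning("km_logrank: dropping %d records with missing/negative "
                       "times", int(bad.sum()))
        df = df[~bad]
    mutant_patients = set(mutant_patients)
    df["group"] = np.where(df["patient"].isin(mutant_patients),
                           "mutant", "non_mutant")
    n_by = df["group"].value_counts().to_dict()
    if n_by.get("mutant", 0) == 0 or n_by.get("non_mutant", 0) == 0:
        empty = "mutant" if n_by.get("mutant", 0) == 0 else "non_mutant"
        raise AbtslcError(f"survival group '{empty}' is empty")
    if int(df["event"].sum()) == 0:
        raise AbtslcError("no events observed; log-rank undefined")

    curves, events = {}, {}
    for name, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
        events[name] = int(sub["event"].sum())

    a = df[df["group"] == "mutant"]
    b = df[df["group"] == "non_mutant"]
    res = logrank_test(a["time_days"], b["time_days"],
                       event_observed_A=a["event"], event_observed_B=b["event"])
    return KmLogrankResult(curves=curves,
                           chi_square=float(res.test_statistic),
                           p_value=float(res.p_value),
                           n_by_group=n_by, events_by_group=events)
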