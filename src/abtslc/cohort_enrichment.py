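"""Cohort-level enrichment of gene-set mutations relative to mutation burden.

Across cancer cohorts, the percentage of samples carrying a mutation in any
gene of a set rises roughly linearly with the cohort's median tumour mutation
burden — most somatic mutations are passengers, so prevalence tracks burden.
Cohorts far above that trend are candidates for positive selection of the
gene set.  This module builds the per-cohort (median TMB, % mutated) points,
fits ordinary least squares, and flags cohorts whose standardized residual
exceeds a threshold.

A simple per-gene burden test is also provided: expected counts are
``background_rate x CDS length x n_samples`` and a two-sided exact Poisson
test (minimum-likelihood convention) is applied per gene with
Benjamini-Hochberg correction across genes.  This deliberately ignores the
covariates (replication timing, chromatin state, expression) that full
driver-detection methods model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AbtslcError, DegenerateInputError
from .maf_io import MutationTable, SampleRegistry
from .mutation_landscape import gene_incidence, sample_tmb

logger = logging.getLogger(__name__)


@dataclass
class LinearFit:
    """OLS fit of % mutated (y) on median TMB (x) with residual-based flags.

    ``points`` carries one row per cohort with x, y, residual ``e``,
    standardized residual ``z`` (e / residual SD, ddof=2) and a ``flag``
    column ('enriched' if z > tau, 'depleted' if z < -tau, '' otherwise),
    sorted by |z| descending.  ``slope_ci`` is the two-sided 95% confidence
    interval for the slope.
    """

    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    sigma: float
    tau: float
    points: pd.DataFrame
    model: object  # fitted statsmodels results (for bands/diagnostics)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.points[self.points["flag"] != ""]

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def cohort_points(table: MutationTable, registry: SampleRegistry, genes,
                  min_samples: int = 10) -> pd.DataFrame:
    """One (median TMB, % gene-set-mutated) point per cohort.

    ``y`` is on the percent scale (0-100).  Cohorts smaller than
    ``min_samples`` are flagged in ``small_cohort`` but retained.
    """
    if registry.n_total == 0:
        raise AbtslcError("sample registry is empty")
    tmb = sample_tmb(table, registry)

    set_table = table.restrict_to_genes(genes)
    mutated = set(set_table.df.loc[
        set_table.df["sample"].isin(registry.samples), "sample"].unique())
    is_mut = registry.samples.to_series().isin(mutated)
    pct = (100.0 * is_mut.groupby(registry.cohorts).mean()).sort_index()

    out = pd.DataFrame({
        "cohort": pct.index,
        "median_tmb": tmb.cohort_median.reindex(pct.index).to_numpy(dtype=float),
        "pct_mutated": pct.to_numpy(),
        "n_samples": registry.cohort_sizes.reindex(pct.index).to_numpy(dtype=int),
    }).reset_index(drop=True)
    out["small_cohort"] = out["n_samples"] < min_samples
    return out


def fit_and_flag(points: pd.DataFrame, tau: float = 1.5) -> LinearFit:
    """OLS of ``pct_mutated`` on ``median_tmb`` with residual flagging.

    Requires >= 3 points and a non-degenerate design (x not all identical).
    Standardized residual z = e / s with s the residual SD on n-2 degrees of
    freedom; |z| > tau flags a cohort as enriched (z > 0) or depleted (z < 0).
    """
    pts = points.reset_index(drop=True).copy()
    if len(pts) < 3:
        raise AbtslcError(f"need >= 3 cohort points, got {len(pts)}")
    x = pts["median_tmb"].to_numpy(dtype=float)
    y = pts["pct_mutated"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("all cohorts have identical median TMB")

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    e = res.resid
    dof = max(len(pts) - 2, 1)
    sigma = float(np.sqrt(np.sum(e ** 2) / dof))
    z = e / sigma if sigma > 0 else np.zeros_like(e)

    ci = res.conf_int(alpha=0.05)
    pts["fitted"] = res.fittedvalues
    pts["residual"] = e
    pts["z"] = z
    pts["flag"] = np.where(z > tau, "enriched", np.where(z < -tau, "depleted", ""))
    pts = pts.sort_values("z", key=np.abs, ascending=False,
                          kind="mergesort").reset_index(drop=True)
    return LinearFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
                     intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
                     sigma=sigma, tau=tau, points=pts, model=res)


def poisson_two_sided_p(observed: int, expected: float) -> float:
    """Two-sided exact Poisson p-value, minimum-likelihood convention.

    Sums Poisson(expected) probabilities of every outcome no more likely than
    the observed one.  Equals 1 when observed sits at the distribution mode.
    """
    if expected <= 0:
        raise AbtslcError("expected count must be > 0")
    k = int(observed)
    hi = int(max(k, expected + 12 * np.sqrt(expected) + 12)) + 1
    support = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(support, expected)
    p_obs = stats.poisson.pmf(k, expected)
    tol = p_obs * (1 + 1e-12)
    p = float(pmf[pmf <= tol].sum())
    if stats.poisson.pmf(hi, expected) <= tol:
        # everything beyond the enumerated support is rarer still
        p += float(stats.poisson.sf(hi, expected))
    return min(p, 1.0)


def burden_test(gene_counts: pd.Series, cds_length: pd.Series,
                background_rate: float, n_samples: int) -> pd.DataFrame:
    """Per-gene excess over a uniform background mutation rate.

    ``gene_counts``: observed qualifying mutation counts indexed by gene.
    ``cds_length``: coding length (bases) per gene; genes missing from it are
    excluded with a logged warning.  ``background_rate`` is in mutations per
    base per sample.  Returns observed, expected, two-sided exact Poisson p
    and Benjamini-Hochberg q per tested gene.
    """
    if background_rate <= 0:
        raise AbtslcError("background_rate must be > 0")
    if (cds_length <= 0).any():
        raise AbtslcError("CDS lengths must be > 0")
    missing = gene_counts.index.difference(cds_length.index)
    if len(missing):
        logger.warning("burden_test: %d genes lack CDS length, excluded: %s",
                       len(missing), list(missing[:5]))
    genes = gene_counts.index.intersection(cds_length.index)
    if len(genes) == 0:
        raise AbtslcError("no genes with both counts and CDS lengths")

    obs = gene_counts.loc[genes].astype(int)
    expected = background_rate * cds_length.loc[genes].astype(float) * n_samples
    p = np.array([poisson_two_sided_p(o, e) for o, e in zip(obs, expected)])
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"observed": obs, "expected": expected,
                        "p": p, "q": q}, index=genes)
    out.index.name = "gene"
    return out.sort_values("p", kind="mergesort")


def enrichment_analysis(table: MutationTable, registry: SampleRegistry,
                        genes, tau: float = 1.5,
                        min_samples: int = 10) -> LinearFit:
    """Convenience wrapper: cohort points then OLS fit and flagging."""
    pts = cohort_points(table, registry, genes, min_samples=min_samples)
    return fit_and_flag(pts, tau=tau)
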