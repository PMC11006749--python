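"""Synthetic MAF / expression / clinical fixtures with known ground truth.

The generator emulates the statistical structure of a pan-cancer somatic
mutation download without any sequence-level realism:

* per-sample background burden ~ negative binomial (mean 10, dispersion 1 by
  default) spread over a pool of filler genes, with heavy-tailed (lognormal)
  cross-cohort burden multipliers;
* per catalog gene g and sample, a Bernoulli hit with probability
  ``p_g x cohort multiplier x enrichment multiplier``; a hit carries
  1 + Geometric extra records so multi-hit and redundancy statistics have
  mass.  Default p_g values are spread over 0.2-2% — the range reported for
  individual acid/base-transporting SLCs in tumour cohorts;
* protein positions uniform over the gene's protein length, except a
  configurable hotspot fraction placed at one residue (default: fraction 0.5
  on SLC4A3);
* missense-dominated Variant_Classification mix; SIFT deleterious and
  PolyPhen category probabilities reflecting a deleterious excess;
* expression counts ~ NegBin(mean = s_j x mu_g x FC^{mutant}, dispersion),
  with lognormal sample size factors and a planted mutant fold change
  (default 0.5, i.e. mutants express less);
* survival times ~ Exponential(baseline hazard x HR^{mutant}) with uniform
  censoring (default HR 0.5: mutants fare better).

Every generator returns a :class:`SimTruth` carrying the planted parameters,
sufficient to recompute each expected statistic analytically, and is
byte-deterministic given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gene_catalog import builtin_abt_catalog
from .maf_io import MutationTable, SampleRegistry, write_maf

_CLASSIFICATION_MIX = {
    "Missense_Mutation": 0.66,
    "Nonsense_Mutation": 0.05,
    "Frame_Shift_Del": 0.04,
    "Frame_Shift_Ins": 0.03,
    "In_Frame_Del": 0.02,
    "Splice_Site": 0.05,
    "Silent": 0.15,
}

_POLYPHEN_PROBS = {"benign": 0.35, "possibly_damaging": 0.25,
                   "probably_damaging": 0.40}


def _default_gene_probs() -> dict:
    """Per-gene hit probabilities evenly spread over 0.2-2% (alphabetical)."""
    genes = sorted(builtin_abt_catalog(include_comparators=False).all_genes())
    probs = np.linspace(0.002, 0.02, len(genes))
    return {g: float(p) for g, p in zip(genes, probs)}


def _default_protein_lengths(genes) -> dict:
    """Deterministic pseudo-realistic protein lengths (500-1300 aa)."""
    genes = sorted(genes)
    lengths = np.linspace(500, 1300, len(genes)).round().astype(int)
    return {g: int(l) for g, l in zip(genes, lengths)}


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic pan-cancer dataset."""

    n_cohorts: int = 8
    samples_per_cohort: int = 250
    burden_mean: float = 10.0        # background mutations per sample
    burden_dispersion: float = 1.0   # NB dispersion (1/size)
    cohort_sigma: float = 0.8        # lognormal sd of cohort burden multipliers
    n_background_genes: int = 400
    gene_probs: dict = field(default_factory=_default_gene_probs)
    enrichment: dict = field(default_factory=dict)  # cohort -> multiplier
    extra_hit_rate: float = 0.2      # geometric extra-record probability
    hotspot_gene: str = "SLC4A3"
    hotspot_fraction: float = 0.5
    protein_lengths: dict = None     # gene -> aa length
    sift_deleterious_prob: float = 0.6
    sift_low_confidence_prob: float = 0.1
    polyphen_probs: dict = field(default_factory=lambda: dict(_POLYPHEN_PROBS))
    classification_mix: dict = field(
        default_factory=lambda: dict(_CLASSIFICATION_MIX))
    # expression
    expr_mean_range: tuple = (20.0, 500.0)
    expr_dispersion: float = 0.3
    size_factor_sigma: float = 0.3
    fold_change: float = 0.5
    fold_change_gene: str = "SLC4A3"
    gene_length_bp: int = 3000
    # survival
    baseline_hazard: float = np.log(2) / 1500.0  # median ~1500 days
    hazard_ratio: float = 0.5
    censor_window_days: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.gene_probs.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"gene prob out of [0,1] for {g}")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ConfigurationError("hotspot_fraction must be in [0,1]")
        if self.protein_lengths is None:
            self.protein_lengths = _default_protein_lengths(self.gene_probs)
        if self.hotspot_fraction > 0 \
                and self.hotspot_gene not in self.protein_lengths:
            raise ConfigurationError(
                f"hotspot gene '{self.hotspot_gene}' has no protein length")
        mix_sum = sum(self.classification_mix.values())
        if not np.isclose(mix_sum, 1.0):
            raise ConfigurationError("classification_mix must sum to 1")
        if not np.isclose(sum(self.polyphen_probs.values()), 1.0):
            raise ConfigurationError("polyphen_probs must sum to 1")
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ConfigurationError("hazard parameters must be > 0")

    @property
    def cohort_names(self) -> list:
        return [f"SYN-{i:02d}" for i in range(1, self.n_cohorts + 1)]


@dataclass
class SimTruth:
    """Realized ground truth emitted alongside every synthetic dataset."""

    seed: int
    gene_probs: dict = None
    cohort_multipliers: dict = None
    enriched_cohorts: list = None
    hotspot_gene: str = None
    hotspot_residue: int = None
    hotspot_fraction: float = None
    protein_lengths: dict = None
    sift_deleterious_prob: float = None
    polyphen_probs: dict = None
    classification_mix: dict = None
    expr_means: dict = None
    size_factors: dict = None
    fold_change: float = None
    fold_change_gene: str = None
    hazard_ratio: float = None
    baseline_hazard: float = None

    def to_json(self, path) -> None:
        data = {k: v for k, v in dataclasses.asdict(self).items()
                if v is not None}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True, default=float)


def _nb_draw(rng, mean, dispersion, size):
    """Negative binomial with mean/dispersion parameterisation."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if np.any(mean <= 0):
        raise ConfigurationError("negative binomial means must be > 0")
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_maf(config: SimConfig):
    """Generate (MutationTable, SampleRegistry, SimTruth) per the config.

    Deterministic for a fixed config + seed.  Samples are named
    ``<cohort>-S<k>``; background mutations land on FILLER genes so that
    burden and gene-set statistics are decoupled.
    """
    rng = np.random.default_rng(config.seed)
    cohorts = config.cohort_names
    multipliers = {c: float(m) for c, m in zip(
        cohorts, rng.lognormal(0.0, config.cohort_sigma, len(cohorts)))}
    for c in config.enrichment:
        if c not in multipliers:
            raise ConfigurationError(f"enrichment names unknown cohort '{c}'")

    samples, sample_cohort = [], []
    for c in cohorts:
        for k in range(1, config.samples_per_cohort + 1):
            samples.append(f"{c}-S{k:04d}")
            sample_cohort.append(c)
    registry = SampleRegistry(pd.Series(sample_cohort,
                                        index=pd.Index(samples, name="sample"),
                                        name="cohort"))

    class_labels = list(config.classification_mix)
    class_p = np.array([config.classification_mix[l] for l in class_labels])
    genes = sorted(config.gene_probs)
    p_g = np.array([config.gene_probs[g] for g in genes])
    lengths = config.protein_lengths
    hotspot_residue = None
    if config.hotspot_fraction > 0:
        hotspot_residue = max(1, lengths[config.hotspot_gene] // 3)

    filler = [f"FILLER{i:04d}" for i in range(config.n_background_genes)]

    rec_gene, rec_sample, rec_cohort = [], [], []
    for c in cohorts:
        cmult = multipliers[c] * config.enrichment.get(c, 1.0)
        cohort_samples = [s for s, cc in zip(samples, sample_cohort) if cc == c]
        ns = len(cohort_samples)
        # background burden over filler genes
        burden = _nb_draw(rng, config.burden_mean * multipliers[c],
                          config.burden_dispersion, (ns,))
        for s, b in zip(cohort_samples, burden):
            if b > 0:
                idx = rng.integers(0, len(filler), size=int(b))
                rec_gene.extend(filler[i] for i in idx)
                rec_sample.extend([s] * int(b))
                rec_cohort.extend([c] * int(b))
        # catalog gene hits
        hit_p = np.clip(p_g * cmult, 0.0, 0.95)
        hits = rng.random((ns, len(genes))) < hit_p
        extra = rng.geometric(1.0 - config.extra_hit_rate,
                              size=(ns, len(genes))) - 1
        counts = np.where(hits, 1 + extra, 0)
        si, gi = np.nonzero(counts)
        for a, b in zip(si, gi):
            n = int(counts[a, b])
            rec_gene.extend([genes[b]] * n)
            rec_sample.extend([cohort_samples[a]] * n)
            rec_cohort.extend([c] * n)

    n_rec = len(rec_gene)
    classification = rng.choice(class_labels, size=n_rec, p=class_p)

    gene_arr = np.array(rec_gene)
    length_arr = np.array([lengths.get(g, 0) for g in rec_gene])
    has_len = length_arr > 0
    positions = np.full(n_rec, -1, dtype=np.int64)
    positions[has_len] = rng.integers(1, length_arr[has_len] + 1)
    if hotspot_residue is not None:
        hot = (gene_arr == config.hotspot_gene) & has_len
        to_hot = hot & (rng.random(n_rec) < config.hotspot_fraction)
        positions[to_hot] = hotspot_residue

    missense = classification == "Missense_Mutation"
    sift = np.full(n_rec, None, dtype=object)
    deleterious = rng.random(n_rec) < config.sift_deleterious_prob
    low_conf = rng.random(n_rec) < config.sift_low_confidence_prob
    sift[missense] = np.where(
        deleterious,
        np.where(low_conf, "deleterious_low_confidence", "deleterious"),
        np.where(low_conf, "tolerated_low_confidence", "tolerated"))[missense]

    pp_labels = list(config.polyphen_probs)
    pp_p = np.array([config.polyphen_probs[l] for l in pp_labels])
    polyphen = np.full(n_rec, None, dtype=object)
    polyphen[missense] = rng.choice(pp_labels, size=int(missense.sum()), p=pp_p)

    df = pd.DataFrame({
        "gene": pd.array(rec_gene, dtype="string"),
        "sample": pd.array(rec_sample, dtype="string"),
        "cohort": pd.array(rec_cohort, dtype="string"),
        "classification": pd.array(classification, dtype="string"),
        "protein_pos": pd.array(
            [int(p) if p > 0 else None for p in positions], dtype="Int64"),
        "sift": pd.array(sift, dtype="string"),
        "polyphen": pd.array(polyphen, dtype="string"),
    })
    table = MutationTable(df, provenance=[f"simulate_maf(seed={config.seed})"])
    truth = SimTruth(
        seed=config.seed, gene_probs=dict(config.gene_probs),
        cohort_multipliers=multipliers,
        enriched_cohorts=sorted(config.enrichment),
        hotspot_gene=config.hotspot_gene if hotspot_residue else None,
        hotspot_residue=hotspot_residue,
        hotspot_fraction=config.hotspot_fraction if hotspot_residue else None,
        protein_lengths=dict(lengths),
        sift_deleterious_prob=config.sift_deleterious_prob,
        polyphen_probs=dict(config.polyphen_probs),
        classification_mix=dict(config.classification_mix))
    return table, registry, truth


def simulate_expression(config: SimConfig, mutant_samples,
                        samples=None, genes=None):
    """Generate raw-count and TPM matrices with a planted mutant fold change.

    ``mutant_samples`` receive ``fold_change`` on ``fold_change_gene``.
    Returns (raw ExpressionMatrix, tpm ExpressionMatrix, SimTruth).
    """
    rng = np.random.default_rng(config.seed + 1)
    if genes is None:
        genes = sorted(config.gene_probs)
    if samples is None:
        samples = [f"SYN-EXPR-S{k:04d}" for k in range(1, 601)]
    samples = list(samples)
    mutant = np.array([s in set(mutant_samples) for s in samples])

    lo, hi = config.expr_mean_range
    if lo <= 0:
        raise ConfigurationError("expression means must be > 0")
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), len(genes)))
    s_j = rng.lognormal(0.0, config.size_factor_sigma, len(samples))
    s_j /= np.exp(np.mean(np.log(s_j)))  # geometric mean 1

    mean = np.outer(mu, s_j)
    if config.fold_change_gene in genes:
        gi = genes.index(config.fold_change_gene)
        mean[gi, mutant] *= config.fold_change
    counts = _nb_draw(rng, mean, config.expr_dispersion, mean.shape)

    raw = _expression_matrix(counts, genes, samples, "raw_counts")
    rate = counts / config.gene_length_bp  # uniform gene length
    tpm_vals = rate / rate.sum(axis=0, keepdims=True) * 1e6
    tpm = _expression_matrix(tpm_vals, genes, samples, "tpm")
    truth = SimTruth(seed=config.seed,
                     expr_means={g: float(m) for g, m in zip(genes, mu)},
                     size_factors={s: float(v) for s, v in zip(samples, s_j)},
                     fold_change=config.fold_change,
                     fold_change_gene=config.fold_change_gene)
    return raw, tpm, truth


def _expression_matrix(values, genes, samples, mode):
    from .phenotype_assoc import ExpressionMatrix
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=pd.Index(samples, name="sample"))
    return ExpressionMatrix(df, mode=mode)


def simulate_survival(config: SimConfig, mutant_patients,
                      patients=None, cohort: str = "SYN-01"):
    """Exponential survival with a planted hazard ratio and uniform censoring.

    Returns (clinical DataFrame, SimTruth).  ``censor_window_days = 0``
    disables censoring (all events observed).
    """
    rng = np.random.default_rng(config.seed + 2)
    if patients is None:
        patients = [f"SYN-PT-{k:04d}" for k in range(1, 401)]
    patients = list(patients)
    mutant = np.array([p in set(mutant_patients) for p in patients])

    hazard = config.baseline_hazard * np.where(mutant, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_window_days > 0:
        t_cens = rng.uniform(0.0, config.censor_window_days, len(patients))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(patients), dtype=int)

    clinical = pd.DataFrame({
        "patient": patients,
        "time_days": time,
        "event": event,
        "cohort": cohort,
    })
    truth = SimTruth(seed=config.seed, hazard_ratio=config.hazard_ratio,
                     baseline_hazard=config.baseline_hazard)
    return clinical, truth


def simulate_cohort_panel(n_cohorts: int = 30, slope: float = 0.8,
                          intercept: float = 2.0, noise_sd: float = 1.0,
                          x_range: tuple = (2.0, 40.0),
                          enriched_cohort: str = None,
                          enriched_offset: float = 8.0,
                          seed: int = 0):
    """Per-cohort (median TMB, % mutated) points on a planted linear trend.

    One cohort may carry an additive enrichment offset above the line.
    Returns (points DataFrame compatible with fit_and_flag, truth dict).
    """
    rng = np.random.default_rng(seed)
    names = [f"SYN-{i:02d}" for i in range(1, n_cohorts + 1)]
    x = np.sort(rng.uniform(*x_range, n_cohorts))
    y = intercept + slope * x + rng.normal(0.0, noise_sd, n_cohorts)
    if enriched_cohort is not None:
        if enriched_cohort not in names:
            raise ConfigurationError(f"unknown cohort '{enriched_cohort}'")
        y[names.index(enriched_cohort)] += enriched_offset
    y = np.clip(y, 0.0, 100.0)
    points = pd.DataFrame({"cohort": names, "median_tmb": x,
                           "pct_mutated": y,
                           "n_samples": 200, "small_cohort": False})
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd,
             "enriched_cohort": enriched_cohort,
             "enriched_offset": enriched_offset, "seed": seed}
    return points, truth


def write_fixture_set(config: SimConfig, outdir) -> dict:
    """Write the full fixture family to ``outdir``; returns the file map.

    Files: maf.tsv, sample_manifest.tsv, protein_lengths.tsv,
    expression_counts.tsv, expression_tpm.tsv, clinical.tsv, simtruth.json.
    Byte-identical across runs for the same config + seed.
    """
    import os

    from .maf_io import NONSYNONYMOUS_CLASSES, filter_qualifying, patient_of

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "maf": "maf.tsv", "manifest": "sample_manifest.tsv",
        "protein_lengths": "protein_lengths.tsv",
        "counts": "expression_counts.tsv", "tpm": "expression_tpm.tsv",
        "clinical": "clinical.tsv", "truth": "simtruth.json"}.items()}

    table, registry, truth = simulate_maf(config)
    write_maf(table, paths["maf"])
    registry.to_manifest(paths["manifest"])
    with open(paths["protein_lengths"], "w") as fh:
        fh.write("gene\tlength\n")
        for g in sorted(config.protein_lengths):
            fh.write(f"{g}\t{config.protein_lengths[g]}\n")

    qualifying = filter_qualifying(table, NONSYNONYMOUS_CLASSES)
    fc_gene = config.fold_change_gene
    mutant_samples = set(
        qualifying.df.loc[qualifying.df["gene"] == fc_gene, "sample"])
    expr_samples = list(registry.samples)
    raw, tpm, expr_truth = simulate_expression(
        config, mutant_samples, samples=expr_samples)
    raw.values.round(0).astype(int).rename_axis("gene").to_csv(
        paths["counts"], sep="\t")
    tpm.values.rename_axis("gene").to_csv(
        paths["tpm"], sep="\t", float_format="%.6g")

    patients = sorted({patient_of(s) for s in registry.samples})
    mct = set(builtin_abt_catalog().genes("MCT"))
    mct_samples = set(qualifying.df.loc[qualifying.df["gene"].isin(mct),
                                        "sample"])
    mutant_patients = {patient_of(s) for s in mct_samples}
    clinical, surv_truth = simulate_survival(config, mutant_patients,
                                             patients=patients)
    clinical.to_csv(paths["clinical"], sep="\t", index=False,
                    float_format="%.6f")

    truth.expr_means = expr_truth.expr_means
    truth.size_factors = expr_truth.size_factors
    truth.fold_change = expr_truth.fold_change
    truth.fold_change_gene = expr_truth.fold_change_gene
    truth.hazard_ratio = surv_truth.hazard_ratio
    truth.baseline_hazard = surv_truth.baseline_hazard
    truth.to_json(paths["truth"])
    return paths
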