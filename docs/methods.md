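# Methods

## Scope and data model

The package analyses somatic mutation calls at gene-symbol level.  A
`MutationTable` holds one call per row with seven canonical fields (gene,
sample, cohort, Variant_Classification, protein position, SIFT category,
PolyPhen-2 category); genomic coordinates, strand and alleles are ignored
throughout.  Sample identity is the full tumour barcode; patient identity
for clinical joins is the first 12 barcode characters (configurable), the
TCGA convention.  A `SampleRegistry` supplies every denominator.  Because a
MAF cannot contain zero-mutation samples, registries can be built from an
external sample manifest whose total exceeds the barcodes present in the
MAF; when no manifest is given the denominator is the number of distinct
barcodes observed.

"Qualifying" mutations default to the nine protein-altering
Variant_Classification labels (missense, nonsense, nonstop, frame-shift
ins/del, in-frame ins/del, splice site, translation start site).
Deduplication of identical (gene, sample, classification, position) rows is
available but off by default, since recurrent identical calls can be
legitimate.

## Incidence, ranking, burden

Per-gene incidence counts a sample once regardless of the number of hits.
Ranking uses descending incidence with alphabetical tie-break; genes with
zero incidence keep trailing ranks so that all group curves share one
x-axis.  Cumulative group curves accumulate incidence *fractions*; a
raw-count mode is not provided.  Tumour mutation burden is the count of
qualifying mutations per sample (not per megabase), and cohort medians use
the midpoint rule.

## Cohort enrichment

The per-cohort points are (median TMB, % samples with ≥ 1 set mutation).
Ordinary least squares is fitted by statsmodels; the enrichment flag is a
*standardized vertical residual* `z = e / s` with `s² = SSE/(n−2)`,
threshold τ = 1.5 by default.  Externally studentized residuals were
considered and rejected for interpretability — with ~30 cohorts the two
differ little, and the vertical-residual rule is what a reader sees on the
scatter plot.  At τ = 1.96 and a true linear model with Gaussian noise the
expected flag rate is ≈ 5%, verified by simulation.

The burden test is deliberately simple: expected count = background rate ×
CDS length × number of samples, two-sided exact Poisson p-value under the
minimum-likelihood convention (outcomes no more likely than the observed
one), Benjamini–Hochberg across genes.  It models none of the covariates
(replication timing, chromatin state, expression) used by full
driver-detection methods, and is calibrated only in the sense that its
type-I error is near-nominal when counts are Poisson at the stated rate.

## Functional impact

SIFT low-confidence calls merge into their parent category by default
(toggleable), matching common MAF annotation practice.  The
deleterious/tolerated ratio applies a pseudocount c = 0.5 only when a cell
is zero, so log-ratios stay finite without biasing the typical case.
PolyPhen "unknown" is excluded from the benign-proportion denominator.
Genes need ≥ 3 records annotated by *both* tools to be classified;
otherwise they are `insufficient` — tiny denominators make the ratio
unstable.  Boundary equality (ratio exactly 2 or 1, benign proportion
exactly 0.5) maps to `intermediate`.  An optional filter restricts input to
samples carrying at least one annotated record, for cohorts where
annotation coverage is partial.

## Positional clustering

A seed is a residue with ≥ 2 mutations; a cluster is the maximal set of
mutated residues chainable to a seed through steps of ≤ 5 residues (the
published default neighbourhood of protein-hotspot cluster methods).  The
clustered fraction F is the share of positioned mutations lying on cluster
residues.  Significance uses a uniform permutation null — the observed
number of mutations scattered uniformly over 1..protein length, p =
(1 + #{F_null ≥ F_obs}) / (n_perm + 1) — rather than a synonymous-rate
background model: the uniform null is assumption-light and exactly valid,
at the cost of ignoring sequence composition.  Permutation p-values are
slightly conservative under heavy ties in F.  Protein lengths come from a
per-symbol TSV (one canonical isoform per gene).

## Redundancy

For each ABT sub-group, samples with m ≥ 1 qualifying sub-group mutations
contribute a = m − 1 "additional" mutations; m counts records, not distinct
genes (a distinct-gene mode exists behind a flag), and samples are pooled
pan-cancer.  The identity mean(a) = (total group mutations − n)/n ties the
statistic to the incidence module and is asserted in tests.  Sub-groups are
compared by classical one-way ANOVA.  A strict mode restricts to samples
whose ABT mutations fall in exactly one sub-group, for the reading in which
the seed tumour carries a single affected sub-group.

## Expression and survival

Raw counts are filtered (gene row-sum < 10 removed, configurable), then
normalised by median-of-ratios: reference = per-gene geometric mean over
samples on genes positive in every sample; size factor = per-sample median
of count/reference.  This reproduces DESeq2's design ~1 normalisation
without the dispersion machinery, which is not needed for a rank-based
two-group comparison.  The mutant vs non-mutant comparison is a two-sided
Wilcoxon rank-sum test: exact enumeration when both groups have ≤ 20
tie-free observations, otherwise the normal approximation with tie
correction (no continuity correction, so identical groups give p = 1).

Survival uses Kaplan–Meier product-limit curves and the two-group log-rank
test (χ² with 1 df), both via lifelines; tests cross-check them against
hand O/E/V tabulations.  Overall-survival time is death time if the event
occurred, else last follow-up; records with missing or negative times are
dropped with a warning.  The mutant group is defined at patient level (any
tumour sample of the patient carries a qualifying mutation in the listed
genes).

## Synthetic data

The generator emulates the statistical shape of a pan-cancer mutation
download, not its sequence content:

- **Burden**: per-sample background mutations ~ NegBin(mean 10,
  dispersion 1) over 400 filler genes; cohort burden multipliers ~
  lognormal(0, 0.8), giving the heavy-tailed cross-cohort variation that
  makes prevalence track burden.
- **Gene hits**: per gene and sample, Bernoulli(p_g × cohort multiplier ×
  optional enrichment multiplier); a hit carries 1 + Geometric(0.8) extra
  records so multi-hit and redundancy statistics have mass.  Default p_g
  values are spread evenly over 0.2–2%, the range reported for individual
  acid/base transporter genes in tumour cohorts.
- **Positions**: uniform over the gene's protein length except a hotspot
  fraction (default 0.5 on SLC4A3, echoing the ~50% clustered fraction
  reported for that gene) placed at one residue.
- **Annotations**: classification mix dominated by missense (66%, with 15%
  silent so qualifying-class filtering is non-trivial); SIFT deleterious
  probability 0.6 and PolyPhen benign probability 0.35, reflecting the
  deleterious excess and sub-50% benign share seen for most of these genes.
- **Expression**: NegBin counts with log-uniform gene means (20–500),
  dispersion 0.3, lognormal size factors (σ = 0.3, geometric mean 1), and a
  planted mutant fold change (default 0.5 — mutants express less).  TPM is
  derived with a uniform gene length, so TPM ordering mirrors count means.
- **Survival**: exponential times with baseline hazard ln2/1500 days⁻¹,
  hazard ratio for mutants (default 0.5 — mutant tumours fare better, the
  pattern reported for MCT-mutant tumours), uniform censoring over 4000
  days.

Every generator emits a `SimTruth` with the realized parameters and is
byte-deterministic given config + seed.

**What passing tests do and do not show.**  The generator plants no
correlation between genes beyond shared cohort burden, no mutational
signatures, no subclonal structure, no annotation errors, and no
confounding between expression and survival.  Recovery of planted
parameters therefore validates the *computations* (counting, fitting,
testing, normalising), not the biological conclusions one would draw on
real data, where those unmodelled features exist.  Real-data headline
figures also depend on the data release of the source portal.

## Problem sizes and numerics

Default validation sizes were chosen so the whole suite runs in well under
a minute of CPU per module: parameter recovery at 5,000 samples, null
calibrations at 500 replicates, power runs at 100–200 replicates, the
counting-oracle table at ~10⁵ records.  OLS identities hold to 1e-9;
size-factor and log-rank fixtures are asserted to 1e-9; permutation tests
use the add-one estimator, never zero.  Ties: ranking and sorting use
alphabetical tie-breaks everywhere, so all outputs are deterministic.

## Known limitations

- Burden test and clustering null are intentionally simpler than
  covariate-aware driver-detection algorithms; exact agreement with those
  tools on real data is not expected.
- One canonical protein length per symbol; isoform-level positions are not
  reconciled.
- Comparator gene groups (glucose / amino acid / nucleoside SLC families)
  follow standard family membership and are user-overridable; there is no
  authoritative published enumeration for the comparator sets.
- The catalog lists SLC9C1 among NHEs; its close paralog SLC9C2 is
  sometimes discussed in the same context but is not part of the curated
  27-gene set.
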