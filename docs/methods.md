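# Methods

## The statistic

`mutspectra` compares the germline mutation spectrum between genomic
compartments using rare polymorphisms as proxies for de novo mutations.
Every single-nucleotide variant is placed in its trinucleotide context and
collapsed with its reverse complement onto a catalog of 96 mutation types
(32 pyrimidine-centred contexts × 3 alternate alleles), grouped into six
classes (C>A, C>G, C>T, T>A, T>C, T>G).

For compartment *X* and type *i*:

- **S_i** — segregating sites of type *i* in *X*, one count per derived
  allele (a triallelic site contributes two counts with the same major
  allele);
- **O_i** — mutational opportunities: the number of sites in *X* whose
  context canonicalizes to type *i*'s context (each context count serves
  its three alternate alleles, so Σ_i O_i = 3 × Σ_ctx O_ctx; the enrichment
  ratio is invariant to this factor);
- **d_i = S_i / O_i** — per-opportunity diversity, controlling for base
  composition;
- **r_i = d_i / D**, with **D = S_tot / O_tot** — relative diversity,
  controlling for forces that scale diversity evenly across types
  (demography, linked selection).  Every emitted table satisfies
  Σ_i r_i · O_i / O_tot = 1 to floating precision.

The compartment comparison designates a *test* and a *reference*
compartment and models

    S_i^T ~ Binomial(O_i^T, p_i),   p_i = d_i^R · D^T / D^R ,

so the expected count is the reference spectrum rescaled to the test's
overall diversity and base composition.  The enrichment ratio
e_i = (d_i^T / D^T) / (d_i^R / D^R) equals S_i^T / E_i algebraically.
P-values are exact two-tailed binomial probabilities under the
minimum-likelihood convention (`scipy.stats.binomtest`); a doubled
one-tail option exists.  Confidence intervals are Clopper–Pearson on the
proportion, divided by p_i to give an interval on e_i.  Significance uses
a Bonferroni threshold α/m with m the number of *testable* types (96 for
the full catalog, 84 with CpG contexts excluded; types with zero reference
counts or opportunities are reported but untestable).

### Validity regime of the fixed-reference null

The null treats the reference spectrum as known.  That is a good
approximation when the reference holds many more variants than the test
compartment — a chromosome against all others, a window against the rest
of the genome, hotspot tiers against the non-hotspot genome.  When the two
compartments are comparable in size, the per-type statistic has roughly
twice the nominal binomial variance (both counts are equally noisy), the
z-score is inflated by ~√2, and the realized family-wise error is far
above α: with two equal compartments of ~5×10⁴ variants each we measure a
family-wise error of ~0.76 over 200 null replicates, against a nominal
0.05.  A test acknowledging reference uncertainty (e.g. the conditional
two-sample binomial) would restore calibration but is a different
statistic; we implement the fixed-reference form and restrict calibrated
use to reference ≫ test designs (a property test verifies family-wise
error control at a 40× reference).  Comparisons between similar-sized
compartments should be read as effect estimates with CIs, not as
calibrated hypothesis tests.

## Polarization

By default the most frequent allele at a site is ancestral (major-allele
rule).  Consequences implemented exactly:

- an alternate allele above 50% frequency makes the *reference* base the
  derived allele, with derived count AN − ΣAC;
- sites at exactly 50% cannot be polarized and are skipped (logged), since
  any assignment would bias directional classes;
- at multiallelic sites the major allele is taken over {reference, all
  alternates}; every other observed allele is one derived observation;
- flanking bases always come from the reference sequence; only the central
  base is replaced by the ancestral allele.

An ancestral-genome mode reads the ancestral base from a reconstructed
FASTA instead; sites whose ancestral base is not among the observed
alleles are skipped.

Variants that fail classification (N flank, missing flank, non-SNP
alleles, ambiguous polarization) are excluded from S but their positions
still count in O: opportunities are a property of the sequence alone.
Flank-truncated contig-end positions are excluded from both.

## Windows, chromosomes and regression

Window- and chromosome-level enrichment uses a leave-one-out reference:
each unit is compared against all other units combined, so pooling
per-unit counts reproduces the scope-wide spectrum exactly.  Per-class
enrichment is regressed on the unit's base-pair-weighted mean covariate
(e.g. a signed replication-timing score, positive = early) by OLS on the
raw ratio scale (log scale available as an option); R² is the squared
correlation, reported as undefined (NaN) — not zero — for a constant
covariate.  Windows with no variants or no opportunities are flagged and
dropped from fits.  Partial terminal windows are retained and identifiable
by their short width.

## Covariate matching

To compare compartments that differ in a confounding covariate, the
covariate is averaged over fixed-width windows, binned into quantile bins
computed on the test compartment's windows, and reference windows are
subsampled (seeded) so the reference bin proportions equal the test's.
Reference windows outside the test's observed covariate range are excluded
first (common support): without this, out-of-range reference windows pile
into the extreme bins and bias the matched means.  A bin occupied by test
windows but empty of reference windows raises an error naming the bin.
Diagnostics report test, unmatched- and matched-reference covariate means.

## The synthetic-data generator

The generator emulates the *statistical* structure of a large cohort's
site-level callset, not its biology:

- **Counts.** Per compartment and type, S_i ~ Poisson(O_i · rate_i ·
  multiplier_i), the low-rate limit of independent per-site mutation;
  chosen over per-site Bernoulli draws because it is orders of magnitude
  faster and gives closed-form expectations for tests.  Variants are
  placed uniformly on the compartment's opportunity sites without
  collision (an informative error suggests lowering the rate when a
  context runs out of sites).
- **Base rates.** Default per-opportunity rates have class weights
  C>A 0.10, C>G 0.09, C>T 0.42, T>A 0.06, T>C 0.24, T>G 0.09, with C>T in
  CpG contexts elevated 8-fold (methyl-cytosine deamination), normalized
  to a mean per-opportunity diversity of 0.015 — the density of a
  ~120M-SNP whole-genome callset (~0.045 segregating sites per bp).  These
  are stylized: real spectra vary by context within classes.
- **Frequency spectrum.** Derived allele counts follow a truncated power
  law P(j) ∝ j^(−α) on 1..n−1 with α = 1.8 and n = 13,860 chromosomes
  (6,930 diploid individuals).  At these values the closed-form singleton
  fraction is 0.531, matching the ~53% singleton share of such cohorts;
  the one-parameter law then puts ~15% on doubletons (real data: ~11%) and
  ~1% above 1% frequency (real data: ~10%) — a known limitation; the
  analyses exercised depend on counts and a frequency filter, not on an
  accurate tail, which is why no demographic model is used.
- **Multiallelic sites.** A configurable fraction (default 6% of
  observations) is built by co-locating pairs of independent derived
  alleles of the same context onto one position, strand-adjusted — the
  inverse of the "count derived alleles separately" accounting used in
  tabulation.
- **Covariate effects.** Class rates can be modulated per window as
  rate × (1 + β_c x_w), giving planted regression slopes; compartment
  multipliers plant enrichments.  The truth manifest records every planted
  parameter and closed-form expected count, so recovery is judged against
  ground truth.
- **Determinism.** One `numpy` Generator seeded from the config drives
  everything; identical config + seed gives byte-identical FASTA/VCF/BED.

What passing tests on this generator do **not** show: robustness to
sequencing error, coverage-dependent calling, linkage disequilibrium,
non-equilibrium demography, GC-biased gene conversion, or reference bias.
They show that the *pipeline arithmetic* — classification, normalization,
testing, matching, regression — recovers known structure at realistic
scale.

## Numerical and design choices

- Coordinates are 0-based half-open internally (BED convention); VCF
  positions are converted on read.  A variant belongs to a compartment by
  its focal position only.
- Scored interval sets must be non-overlapping (merging intervals with
  different scores is ill-defined); unscored sets are merged on
  construction.  Threshold binning uses closed inequalities (≤ low,
  ≥ high, middle discarded); quantile binning weights scores by interval
  length and sends values equal to an inner edge to the lower bin so tied
  score tiers round-trip exactly.
- O_tot sums over the 96 types (each site counted three times); relative
  diversities are invariant to this constant, verified numerically.
- p_i is clamped into [0, 1] with a logged warning (only reachable for
  extreme diversity ratios).
- Acceptance-test problem sizes are set by power analysis: e.g. the ±3%
  class-ratio band after matching requires the smallest class (~6% of
  variants) to have a ratio standard error near 1%, hence a 4-Mb test
  compartment and an 8-contig reference pool; the planted-multiplier
  check uses ≥10⁵ variants so the pooled C>A ratio's standard error is
  ~1%.
- The `pooled` class comparison of a planted within-class multiplier m
  recovers m/F with F = D^T/D^R ≈ 1 + (m−1)·s, where s is the class's
  diversity share — e.g. 1.2× on C>A (s ≈ 0.1) yields an expected relative
  ratio of ~1.18, inside the recovery band by design of the base spectrum.

## Known limitations

- The fixed-reference binomial test is anticonservative for similar-sized
  compartments (quantified above).
- The SFS tail is unrealistic (see generator notes); frequency-filter
  sensitivity analyses exercise the machinery, not realistic tail mass.
- Covariate matching equalizes bin proportions, not within-bin
  distributions; with strongly non-uniform covariate densities a residual
  within-bin mean gap of order bin-width/10 can remain (diagnostics expose
  it).
- Chromosome-level trend fits with ~10 contigs have wide R² sampling
  distributions; signs and magnitudes, not third decimals, are the
  reportable quantities.
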