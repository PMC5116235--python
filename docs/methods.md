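# Methods

This note documents the statistical model, the procedures, the defaults, and
the numerical choices implemented in `varburden`.

## Data model and assumptions

The package operates on summary-level data, never on individual genotypes:

- **Case cohorts**: per disease, a list of variants with gene, protein
  consequence, protein position, and the number of carriers observed in a
  cohort of known size. Each carrier is assumed heterozygous for one
  qualifying variant (dominant-disease assumption), so summing carrier
  counts within a gene and class estimates the number of carrier
  individuals. The sum is capped at the cohort size with a warning.
- **Reference population**: per-site allele count AC and total genotyped
  alleles AN. The reference carrier count for a gene is the sum of rare-site
  ACs, again under the one-variant-per-carrier, heterozygous assumption;
  compound heterozygosity and linkage between rare alleles are ignored
  (negligible at the frequencies involved).
- **Variant classes**: consequence terms map to `truncating`
  (nonsense/frameshift/canonical ±1–2 splice), `nontruncating`
  (missense/in-frame indels), or `excluded` (synonymous, deep intronic,
  anything else). Burden is reported for `all` (both retained classes) and
  each class separately.

## Rarity filter

A variant qualifies if its reference minor allele frequency
`MAF = AC / AN` is strictly below `rare_maf_threshold = 1e-4`. The filter is
symmetric: reference sites above threshold are also dropped from the
reference carrier sum, so both sides of the comparison count the same kind
of variation. Case variants absent from the reference have frequency 0 and
qualify. A second threshold, `polymorphism_threshold = 1e-2`, is used only
by the audit module to label reported variants that are outright
polymorphisms. Rationale: for a dominant disorder with prevalence ~1/500
spread over many genes and alleles, a truly causal allele cannot sit at
population frequency ≥ 1e-4; the threshold trades a small loss of causal
alleles for a large reduction of benign background.

## Effective reference denominator

Reference carrier frequency needs a per-gene sample size, but AN varies per
site with coverage. The package uses
`n_ref_effective = mean(AN over the gene's retained rare sites) / 2`. When a
gene has no retained sites, the fallback is `median(AN over all sites of the
gene) / 2`; with no sites at all, a gene-level AN must be supplied or an
error is raised. Mean-over-retained-sites keeps the denominator consistent
with the numerator (both reflect the same sites' callability); the median
fallback is robust to a few badly covered sites.

## Burden statistics

For each gene and class, the 2×2 table is

|            | carriers | non-carriers |
|------------|----------|--------------|
| cases      | a        | b            |
| reference  | c        | d            |

with `a` the summed case carrier count and `c = min(Σ AC, n_ref_effective)`.
Because `c` and `d` derive from a non-integer effective denominator, cells
are rounded half-away-from-zero for the exact test (which requires counts),
while frequencies, odds ratios and etiological fractions use the unrounded
cells.

- **Fisher's exact test**, two-sided by the minimum-likelihood rule: sum the
  hypergeometric probabilities of all tables (fixed margins) whose
  probability does not exceed the observed table's. Ties are accepted up to
  a relative factor of 1 + 1e-7 to absorb floating-point noise, matching the
  convention of standard implementations.
- **Multiple testing**: Bonferroni within a disease panel,
  `p < alpha / m` with `alpha = 0.05` and `m` = number of genes on the
  panel (classes within a gene are views of the same hypothesis, not extra
  tests).
- **Odds ratio**: `OR = (a·d)/(b·c)` with a Woolf (log-normal) 95% CI,
  `exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))`. If any cell is zero, the
  Haldane–Anscombe correction adds 0.5 to every cell for both the point
  estimate and the CI. A table with an empty case or reference row has no
  defined OR and raises an error.
- **Etiological fraction**: `EF = max(0, (OR − 1)/OR)`, with CI bounds
  mapped through the same transform. EF estimates the probability that a
  qualifying variant in an affected carrier is causal, assuming the excess
  of carriers among cases is entirely attributable to disease-causing
  alleles.
- **Case excess** `= a/n_cases − c/n_ref_effective` and
  **predicted pathogenic** `= max(0, excess) × n_cases`.
- **Binomial proportions** (case carrier frequency etc.) get Wilson score
  95% intervals, clamped to exactly 0 or 1 at the boundary counts.

## Mutation cluster scan (NMC)

Distinct missense residue positions within a gene are normalized by protein
length. Under the null of uniform positional distribution, with `n` distinct
positions the spacing between the `i`-th and `j`-th order statistics is
Beta(j−i, n−(j−i)+1), so `P(X_(j) − X_(i) ≤ g) = BetaCDF(g; j−i, n−j+i+1)`
is an exact p-value for the observed gap `g`. All `n(n−1)/2` pairs are
tested; Benjamini–Hochberg controls the FDR at `q = 0.05` (the pairs are
strongly positively dependent, for which BH remains valid); overlapping
significant pairs are merged into maximal clusters reported in residue
coordinates with the cluster's minimum p and its BH q. Duplicate residues
are collapsed before the scan — recurrence is burden signal, not positional
signal, and keeping duplicates would make zero gaps trivially significant.
`cluster_ef` then recomputes the EF restricted to nontruncating case
variants inside the cluster, against the gene-level reference denominator.

## Reported-variant audit

Variants reported as disease-causing (tags `DM`, `DM?`) are joined to the
reference: `absent`, `present_rare` (MAF < 1e-4), `exceeds_rare_threshold`
(1e-4 ≤ MAF ≤ 1e-2), or `polymorphism_excluded` (MAF > 1e-2). Per-disease
summaries report the cumulative reference carrier frequency of reported
variants after removing polymorphisms — an upper bound on how much of the
population would be labelled "affected" if the reported list were taken at
face value.

## Synthetic data generator

`varburden.synthetic.generate` emulates the structure of a case–reference
burden study:

- **Benign background**: each individual, in both cohorts, carries a
  qualifying benign variant in a gene with probability `background_rate`.
  Carriers draw their allele from a shared gene- and class-specific
  long-tailed (Zipf-like, exponent 0.5) catalog, so most alleles are very
  rare or private while a few recur. The catalog size is
  `max(2000, 40 × expected carriers across both cohorts)`, chosen so the
  most recurrent benign allele stays below the rarity threshold in a
  study-scale reference; this reproduces the regime the method assumes.
  Each allele has a fixed position and consequence shared across cohorts.
- **Pathogenic variants**: a fraction `pathogenic_fraction` of cases carry
  a private pathogenic allele (never present in the reference), with class
  drawn from `pathogenic_class_mix` (default 80% nontruncating, 20%
  truncating) and, optionally, nontruncating positions confined to
  `cluster_interval` to implant a hotspot.
- **Coverage**: per-site AN is `2·n_ref·depth_fraction` with multiplicative
  jitter (`coverage_model_uniform`), emulating incomplete callability.
- **Ground truth**: the generator returns the implied OR and EF computed
  from the generating probabilities (`p_case = pathogenic_fraction +
  background_rate`, `p_ref = background_rate`);
  `pathogenic_fraction_for_ef` inverts this relation (Brent root-finding)
  so experiments can target an exact true EF.

What it does **not** emulate: compound heterozygosity, relatedness,
population stratification, sequencing artifacts, gene-specific mutational
spectra, or misclassification of consequences. It is a calibration harness,
not a population-genetics simulator.

### Calibration conditions

Null-calibration and recovery experiments (tests and acceptance script) use
a study-scale reference of 60,000. At much smaller references the rarity
filter's implied AC cutoff is tiny and conditioning on the realized
reference allele count slightly depletes the reference side of the table,
inflating the null rejection rate; this is a property of applying the
method far below its intended scale, not of the implementation, and it
disappears at the scale the method targets.

## Numerical choices

- Fisher p-values are computed in-package by direct enumeration of the
  hypergeometric support using log-gamma (`gammaln`) binomial coefficients,
  vectorized over the support; this is exact to ~1e-13 against both an
  independent floating-point implementation and exact integer-arithmetic
  enumeration, and fast enough for exhaustive verification grids.
- Beta CDFs, normal quantiles: scipy. Wilson intervals and BH adjustment:
  statsmodels.
- All randomness flows from a single `numpy.random.default_rng(seed)` per
  generator call; identical seeds reproduce byte-identical outputs.

## Limitations

EF interprets the whole case excess as causal and is biased when cases and
reference differ for reasons other than disease (ancestry, platform).
Summary-level carrier counting cannot detect the same individual carrying
two variants. The NMC scan tests positional non-uniformity only; a gene
with uniformly distributed pathogenic missense has a real burden but no
cluster. Bonferroni across genes is conservative when genes are correlated
through shared patients.
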