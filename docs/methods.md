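# Methods

## Clonality model

The pipeline treats a sample's variant calls as draws from a simple mixture:
a fraction *f* of the sequenced DNA is tumor-derived ("shed" in plasma,
purity in tissue), and a variant present in a fraction *c* of tumor cells
(its cancer-cell fraction, CCF) at heterozygous single copy contributes an
expected allele fraction *c·f/2*. Clonality estimation inverts this
relationship without attempting full copy-number deconvolution:

* **ctDNA tumor fraction.** When an aneuploidy-based estimate is supplied it
  is taken at face value (the estimator itself, which requires genome-wide
  copy-number evidence, is consumed as an input, not implemented). Otherwise
  the maximum somatic allele fraction (MSAF) is used: the largest VAF among
  variants that are not germline and not clonal-hematopoiesis-associated.
  Variants with *ambiguous* somatic status are excluded by default
  (`include_ambiguous=False`) on the grounds that an unresolved call is more
  likely a germline or CH contaminant than the sample's top somatic variant;
  the flag exists because the opposite convention is defensible. CH
  filtering uses the per-variant flag plus a configurable gene list
  (default {DNMT3A, TET2, ASXL1}).
* **Tissue tumor fraction.** Per somatic variant with SGZ copy estimates,
  TF = 2·AF / (mc − AF·(wc + mc − 2)); at mc = wc = 1 this reduces to 2·AF.
  The sample estimate is the maximum over usable variants. Variants lacking
  copy estimates or with a nonpositive denominator are skipped and counted.
* **Clonal fraction and labels.** Clonal fraction = AF / TF, capped at 1
  (amplified alleles can push the raw ratio above 1; the raw value is kept
  on the call object). Labels are clonal at ≥ 0.25 (ctDNA) or ≥ 0.50
  (tissue); thresholds are inclusive and exposed for sensitivity analyses.
  The ctDNA cutoff corresponds to a heterozygous single-copy alteration
  present in about half of diploid tumor cells. Capping never flips a label
  because both thresholds are below 1.
* **Categories.** Only pathogenic (known or likely oncogenic) *PIK3CA* SNVs
  count toward multiplicity; indels, copy-number changes and rearrangements
  in the gene are reported but not counted. A sample with ≥ 2 such SNVs is
  `clonal_multiple` when at least two are clonal, else `subclonal_multiple`.
  A sample carrying a pathogenic target SNV whose label cannot be computed
  (no tumor fraction, or a countable SNV without an allele fraction) is
  `unestimable` — including the genuinely ambiguous case of one clonal plus
  one unestimable mutation, where the multiple-category split cannot be
  resolved; such samples are surfaced in the flow table rather than dropped.

## Exact tests

`fisher_exact_2x2` uses the two-sided convention that sums hypergeometric
point probabilities not exceeding the observed table's (scipy's default);
the unit suite verifies exact agreement with a brute-force enumeration
oracle for tables up to n = 200, and this convention reproduces all the
reported contingency p-values the package's tests encode.

The stratified exact conditional response test conditions on per-stratum
responder totals and group sizes; the null pmf of the total responder count
in one group is the exact convolution of per-stratum central
hypergeometrics, and the two-sided p-value applies the same
point-probability rule. Because the convolution is exact and cheap at any
realistic trial size (the support grows only additively per stratum), no
Monte-Carlo fallback is implemented. With a single stratum the
implementation delegates to `fisher_exact_2x2`, making the reduction exact
by construction. Strata with either group empty are dropped with a warning.

Confidence intervals for response rates are Clopper–Pearson, computed from
the beta-quantile form; this is the interval that yields an upper bound of
1 − 0.025^(1/5) ≈ 52% for 0 of 5 responders. Display rounding is two
significant figures on the percentage scale.

Survival machinery wraps lifelines: Kaplan–Meier product-limit curves
(median = smallest time with S(t) ≤ 0.5, absent if never crossed), the
log-rank test, and a single-covariate Cox model with Efron tie handling
(Wald 95% CI on the hazard ratio). Tie handling is configurable only by
editing the fit call; Efron is the sensible default and nothing downstream
depends on the choice at the cohort sizes involved.

## Synthetic cohorts

`SimulationConfig` defaults encode the study conditions the analysis
expects: 19.6% of samples carry multiple (≥ 2) *PIK3CA* SNVs, 71.2% of
multiples and 91.1% of singles are clonal, and 15 of 19 subclonal multiples
have exactly one clonal mutation. Shed is lognormal with median 10%
(σ = 1), truncated to (0, 1]; depth is 5000×, typical of hybrid-capture
liquid panels. Clonal CCFs are uniform on [0.40, 1.0] and subclonal on
[0.02, 0.18] — both kept clear of the 0.25 decision boundary so that truth
labels are well defined; the config validator enforces this separation
relative to the assay-mode threshold. Each sample also receives a truncal
somatic passenger (CCF = 1) that anchors MSAF — without it, a sample whose
only somatic variants are subclonal would have its top subclonal VAF
mistaken for the tumor fraction, which is exactly the failure mode the MSAF
design accepts in real data; the anchor makes recovery experiments
interpretable. CH contaminants (rate 0.25, VAF 0.2–3%) and germline
variants (rate 0.5, VAF ≈ 0.5) are added with their flags set. Pathway
co-alterations are Bernoulli per category with the RTK contrast set to
19.1% (clonal multiple) vs 47.4% (subclonal multiple) and modest or null
contrasts elsewhere. Responses are Bernoulli with per-category-and-arm
rates; PFS is Weibull with per-arm scale and per-category proportional
hazard multipliers chosen so implied medians approximate 7.6/5.1 months
(experimental) and 3.9/2.0 (control) for the multiple-mutation groups —
published medians and hazard ratios are not exactly mutually consistent
under a parametric proportional-hazards model, so medians are matched
approximately. Censoring is an independent uniform time on 1–30 months.

A single `numpy` generator seeded from `seed` drives all draws in a fixed
per-sample order (arm, category, shed, *PIK3CA* CCFs, passengers,
contaminants, pathway alterations, clinical outcome), so output tables are
byte-reproducible. Tissue mode writes mc = wc = 1 for simulated SNVs,
consistent with the heterozygous-diploid AF model.

What the generator does **not** emulate: read-level artifacts (no
FASTQ/BAM), copy-number-driven VAF distortion (every simulated SNV is
heterozygous single-copy), non-diploid tumors, correlated co-mutation
structure beyond the per-pathway Bernoulli rates, and informative
censoring. Passing recovery tests therefore demonstrate correctness of the
estimation chain under its own assumptions, not robustness to the ways real
tumors violate them — in particular, amplified-allele overestimation is
handled only by capping, mirroring the analytical choice the estimator
itself makes.

## Numerical and design choices

* Tables are UTF-8 tab-delimited with `.` for absent values; VCF ingestion
  is a convenience mapping of INFO keys (AF, SOMATIC/STATUS, CH, ONC, MC,
  WC) because VCF has no natural slots for copy numbers or the CH flag.
  Gene symbols are matched case-sensitively after trimming; protein-change
  strings are opaque labels.
* Genes altered in neither comparison group are omitted from comparison
  output, matching tile-plot semantics; no multiplicity adjustment is
  applied by default, with Benjamini–Hochberg available as an option.
* Pairwise pathway association applies the Haldane–Anscombe 0.5 correction
  to zero cells for odds ratios and flags corrected pairs.
* Default pathway gene lists are approximations over a liquid-panel-like
  universe (RTK, PI3K minus *PIK3CA*, MAPK, p53) and are user-overridable
  via JSON; analyses that depend on exact panel membership should supply
  their own lists.
* Degenerate 2×2 tables (a zero margin) return p = 1 with a warning rather
  than raising: a comparison with no signal is a valid, uninformative
  outcome in a screen over many genes.
* The recovery experiments in the test suite use cohorts of 1000–2000
  samples at 5000× depth and survival groups of 500–1500 per arm — sizes at
  which binomial and partial-likelihood sampling error is small relative to
  the tested tolerances while the full suite stays fast.

## Known limitations

* MSAF underestimates tumor fraction when the top somatic variant is
  subclonal, inflating clonal fractions of other variants; the aneuploidy
  input path exists precisely because MSAF is a proxy.
* The stratified response test requires the caller to supply strata; the
  unstratified default is a different test and can give visibly different
  p-values on small, imbalanced cohorts.
* Tissue-mode simulation covers only the heterozygous-diploid corner of the
  SGZ formula's domain; the formula itself is tested over wider mc/wc
  grids, but end-to-end tissue recovery at aberrant copy states is not
  exercised.
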