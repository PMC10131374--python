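# clonarch

Clonality estimation for *PIK3CA*-mutant cancer cohorts from ctDNA or tissue
variant calls, with downstream co-alteration and clinical-outcome analysis.

## The problem

Around a tenth of *PIK3CA*-mutant ER+/HER2− breast cancers carry **two or
more** *PIK3CA* mutations, and whether those mutations sit in essentially all
tumor cells (clonal) or only a subset (subclonal) appears to shape response
to PI3Kα inhibition. Calling that distinction from plasma requires first
estimating how much of the cell-free DNA is tumor-derived, then normalizing
each variant's allele fraction by that quantity. `clonarch` implements this
estimation chain as a reusable pipeline for translational analysts:

1. **Tumor fraction.** In ctDNA mode, an externally supplied aneuploidy-based
   estimate is used when present; otherwise the **maximum somatic allele
   fraction** (MSAF) — the largest VAF among non-germline variants after
   excluding clonal-hematopoiesis (CH) associated alterations — serves as the
   tumor-shed proxy. In tissue mode, each somatic variant with
   somatic–germline–zygosity (SGZ) copy-number estimates yields

   TF = 2·AF / (mc − AF·(wc + mc − 2)),

   with mc/wc the mutated/wild-type copy numbers, and the sample tumor
   fraction is the maximum over variants (capped at 1).
2. **Clonal fraction.** Each variant's clonal fraction is AF / TF, called
   **clonal** at ≥ 0.25 (ctDNA) or ≥ 0.50 (tissue), thresholds inclusive.
3. **Category.** Counting only pathogenic *PIK3CA* SNVs: none → `no_pik3ca`;
   one → `clonal_single`/`subclonal_single`; two or more → `clonal_multiple`
   if at least two are clonal, else `subclonal_multiple`; samples whose tumor
   fraction cannot be derived are `unestimable` and reported, not dropped.
4. **Co-alteration.** Gene- and pathway-level alteration status (≥ 1
   pathogenic alteration in a pathway gene; *PIK3CA* itself is excluded from
   the PI3K list) compared between clonality groups with two-sided Fisher
   exact tests, unadjusted.
5. **Outcomes.** Objective response rates with exact Clopper–Pearson 95%
   intervals, exact (conditionally stratified) response comparisons, and
   Kaplan–Meier / Cox (Efron ties) / log-rank PFS contrasts.

Because trial-level genomic data of this kind are not publicly shareable, the
package ships a **truth-labelled synthetic-cohort generator** that emulates
the assumed data-generating process (lognormal tumor shed, binomial
read-sampling noise at depth, CH/germline contaminants, category-dependent
co-alteration and outcome rates), so every stage is testable end to end.

## Worked example

```python
>>> from clonarch import orr_with_exact_ci, fisher_exact_2x2
>>> orr_with_exact_ci(14, 47).display()   # 14 responders of 47 patients
'30% (95% CI, 17-45)'
>>> orr_with_exact_ci(1, 19).display()
'5.3% (95% CI, 0.13-26)'
>>> fisher_exact_2x2([[9, 38], [9, 10]])  # RTK-altered: 9/47 vs 9/19 samples
0.03167158006692343
```

A full synthetic run, from cohort generation to outcome association:

```python
>>> from clonarch import SimulationConfig, run_all
>>> manifest = run_all(SimulationConfig(n_samples=300, seed=42), "demo_run")
```

which writes, among other tables, the category flow counts

```
{'clonal_multiple': 45, 'subclonal_multiple': 14, 'clonal_single': 214,
 'subclonal_single': 27, 'no_pik3ca': 0, 'unestimable': 0}
```

and the pathway comparison between the two multiple-mutation groups
(`pathway_comparisons.tsv`):

```
label  altered_a  size_a  proportion_a  altered_b  size_b  proportion_b  p_value
  RTK          7      45      0.155556          7      14      0.500000 0.013746
 PI3K          6      45      0.133333          5      14      0.357143 0.109629
 MAPK          8      45      0.177778          5      14      0.357143 0.265702
  p53         18      45      0.400000          6      14      0.428571 1.000000
```

Here 15.6% of clonal-multiple samples carry an RTK-pathway alteration versus
50% of subclonal-multiple samples (Fisher p = 0.014), the contrast the
generator encodes; the ORR summary for the same run reads
`clonal_multiple: 29% (95% CI, 16-44)` vs `subclonal_multiple: 0.0% (95% CI,
0.0-23)` with an exact p of 0.026. The same stages are available from a
shell via `clonarch simulate|categorize|coalter|outcomes|run-all`.

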