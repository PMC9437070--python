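# slco1b1 — two-SNP *SLCO1B1* star-allele cohort analysis

Pharmacogenomic analysis of the two clinically established *SLCO1B1*
variants, c.388A>G (rs2306283) and c.521T>C (rs4149056), in a cohort
stratified into ancestry groups.  The 521C allele reduces OATP1B1-mediated
hepatic statin uptake and drives simvastatin-induced myopathy risk, so the
population frequency of the 521C-bearing haplotypes is directly actionable
for dosing guidance.

The package is built around the three-group Qatari cohort (1050 exomes /
genomes: 587 Bedouin/Arab, 387 Persian/South Asian, 76 African) but every
component takes an arbitrary VCF + sample-metadata pair with any number of
groups.

## What it computes

The two SNPs define four haplotypes (star alleles):

| star allele | c.388 | c.521 | function |
|---|---|---|---|
| \*1a | A | T | normal (wild type) |
| \*1b | G | T | normal |
| \*5  | A | C | reduced |
| \*15 | G | C | reduced |

For each ancestry group and for the pooled cohort:

- **Allele frequencies and HWE** — variant-allele dosage counting from VCF
  genotypes; exact conditional Hardy–Weinberg test (tail sum of the
  conditional distribution of the heterozygote count given the allele
  counts).
- **Haplotype frequencies by EM** — gametic-phase EM under random mating.
  The only phase-ambiguous class is the double heterozygote (388 A/G +
  521 T/C), which is either \*1a/\*15 or \*1b/\*5; the E-step splits its
  count in proportion to f₁ₐf₁₅ : f₁ᵦf₅, the M-step renormalises expected
  gamete counts.  Standard errors come from the observed information.
- **Diplotypes and OATP1B1 phenotypes** — CPIC 2014 rules: 0 / 1 / 2
  reduced-function alleles (\*5, \*15) → normal / intermediate / low
  function.  Since both reduced alleles carry 521C, the phenotype equals
  the unphased 521C dosage; the diplotype route is retained and
  cross-checked.
- **Across-group tests** — Pearson chi-square (no continuity correction),
  exact 2×2 Fisher, and a seeded Monte-Carlo Fisher test for sparse r×c
  tables, chosen by a recorded policy.
- **Synthetic cohorts** — a generator that draws haplotype pairs per group
  from known frequency vectors (random mating, optional inbreeding
  coefficient F and missingness), emitting VCF + metadata + truth, so the
  whole pipeline is testable against exact generative truth.

## Worked example

```sh
slco1b1 simulate --preset maf-consistent --seed 3 --out cohort/
slco1b1 analyze --vcf cohort/cohort.vcf --metadata cohort/samples.tsv --out report/
```

`report/frequency_report.tsv` then contains (columns Total, Bedouin/Arab,
Persian/South Asian, African):

```
section                   row                Total  Bedouin/Arab  Persian/S.Asian  African  p_value  method
variant_allele_frequency  c.388A>G G allele  0.50   0.49          0.48             0.67     0.0001   chi_square
variant_allele_frequency  c.521T>C C allele  0.24   0.28          0.19             0.18     0.0000   chi_square
haplotype_frequency_pct   *1a                48.05  48.00         51.25            32.89    0.0002   chi_square
haplotype_frequency_pct   *1b                28.14  24.23         29.75            49.34    0.0000   chi_square
haplotype_frequency_pct   *5                 1.90   2.51          1.20             0.00     0.0212   fisher_mc
haplotype_frequency_pct   *15                21.90  25.26         17.79            17.76    0.0002   chi_square
phenotype_frequency_pct   normal             58.00  51.28         66.41            67.11    0.0000   chi_square
phenotype_frequency_pct   intermediate       36.38  41.91         29.20            30.26    0.0002   chi_square
phenotype_frequency_pct   low                5.62   6.81          4.39             2.63     0.1672   fisher_mc
```

i.e. roughly half of all chromosomes carry 388G and a quarter carry 521C,
so about 42% of individuals carry at least one reduced-function allele
(intermediate or low function) — and those phenotype frequencies differ
significantly across the ancestry groups, with the sparse cells (the \*5
row, the low-function row) automatically falling back from chi-square to
the seeded Monte-Carlo Fisher test.  `analysis_details.json` carries the full-precision numbers,
HWE p-values, EM diagnostics and test details; `manifest.json` records
input/output digests and seeds.

The numbered scripts under `analysis/` run the same pipeline as a narrative
study — simulate both preset cohorts, allele frequencies + HWE, EM vs
generative truth, phenotypes + tests, and the published-table
reconstruction — writing their tables under `results/`.

Because the study's genotypes are access-controlled (SRA), the shipped
presets encode the published frequency tables themselves.  The published
haplotype rows and MAF/phenotype rows are mutually inconsistent, so two
presets are provided — `hf-table` (published haplotype rows) and
`maf-consistent` (published MAFs + phenotype counts) — and a preset must be
named explicitly.

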