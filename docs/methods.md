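# Methods

## Data model

Genotypes at the two loci are carried as dosages of the cDNA variant
allele: `dosage_388` counts copies of 388G, `dosage_521` counts copies of
521C, each 0/1/2 or missing.  The cDNA-to-VCF orientation is an explicit
configuration (ancestral allele → REF, variant allele → ALT by default;
*SLCO1B1* lies on the plus strand of chromosome 12, so cDNA and genomic
alleles coincide).  A VCF record whose REF/ALT do not match the configured
orientation is a hard error — silent strand flips are the classic failure
mode of pharmacogenomic frequency reports, and no attempt is made to
recover from one.  Variants are matched by rsID first and (chrom, pos) as a
fallback; the GRCh37 coordinates shipped as defaults are configuration
data, not logic, and nothing downstream depends on their correctness.

**Missingness policy.**  A sample missing at a locus is excluded from that
locus's allele and genotype counts; a sample missing at either locus is
excluded from every two-locus computation (EM, diplotype, phenotype).  All
frequencies are therefore over chromosomes actually observed (2 × non-
missing samples), and each exclusion is tallied and surfaced.  The source
cohort's post-calling QC policy is unknown; per-computation exclusion keeps
every denominator well defined.

## Hardy–Weinberg testing

The primary test is the exact conditional test for a biallelic autosomal
SNP: conditional on the observed allele counts, the heterozygote count
n_Aa has probability ∝ 2^n_Aa · n!/(n_AA! n_Aa! n_aa!), and the p-value is
the sum of the probabilities of all configurations no more probable than
the observed one (two-sided tail-sum definition; p = 1 for monomorphic
samples, where only one configuration is attainable).  Weights are
computed in log space and normalised; ties are admitted with 1e-12
relative slack.  A chi-square goodness-of-fit variant (df = 1) is
available behind a separate function but is not the default — the exact
test is well defined at every group size here and is verifiable by
enumeration.  Equilibrium is declared at p ≥ 0.05, the analysis's global
significance convention.  No mid-p variant, no multi-allelic or X-linked
support.

## Haplotype EM

With haplotypes h ∈ {\*1a, \*1b, \*5, \*15} and frequencies f, genotype
classes are multinomial with random-mating probabilities (f_h² for
homozygous pairs, 2f_h f_k otherwise).  Eight of the nine two-locus
classes determine their gamete pair; the double heterozygote is
\*1a/\*15 with probability f₁ₐf₁₅/(f₁ₐf₁₅ + f₁ᵦf₅) in the E-step, and the
M-step sets each f to its expected gamete count over 2N.  Consequences
used as test invariants: the marginal allele frequencies f₁ᵦ+f₁₅ and
f₅+f₁₅ equal the observed 388G and 521C frequencies at *every* iterate,
and the log-likelihood is non-decreasing.

Numerical choices:

- **Initialisation** — linkage-equilibrium start (product of observed
  allele frequencies).  Deterministic; no RNG anywhere in inference.  The
  two-locus likelihood restricted to the margin-preserving ridge is
  one-dimensional and well behaved, and a dense grid-search oracle in the
  test suite guards against local-optimum pathologies.
- **Convergence** — max |Δf| < 1e-10 or 10,000 iterations; both far below
  reporting precision (2 dp percentages).
- **Degenerate inputs** — if only double heterozygotes are observed the
  likelihood is flat along the phase split; this is detected structurally,
  flagged as non-identifiable, and the initialisation point is reported
  with `converged = True` rather than iterating on a ridge.  A zero E-step
  denominator with double heterozygotes present (possible only from a
  user-supplied boundary initialisation) splits 50/50 for that iteration
  and warns.
- **Standard errors** — observed information: numerical Hessian of the
  log-likelihood in the three free coordinates (central differences, step
  1e-5), inverted; the \*15 variance follows by the delta method.
  Undefined (and refused) at boundary estimates.

Diplotypes are reported as the most probable phase with its posterior
attached (tie → \*1a/\*15), not fractionally.  Phenotype calls never
depend on this choice — see below.

## Phenotype calling

CPIC 2014 simvastatin rules: the OATP1B1 phenotype is determined by the
number of reduced-function alleles (\*5, \*15) in the diplotype — 0 →
normal, 1 → intermediate, 2 → low function.  Both reduced alleles carry
521C and both functional alleles carry 521T, so the reduced-allele count
equals the unphased 521C dosage; phenotypes are therefore called from the
dosage directly, making the headline outputs independent of phase
inference.  The diplotype route is retained and the equivalence is
asserted over all nine genotype classes × random frequency vectors.  The
2014 normal/intermediate/low labels are the primary surface (matching the
era of the guideline used); a mapping to the later
normal/decreased/poor nomenclature ships alongside.  An identity used as a
test: (n_intermediate + 2·n_low)/(2·n_classified) equals the 521C
frequency on the classified samples, exactly.

## Across-group testing

Pearson chi-square without continuity correction (the reconstructed \*5
carriage table reproduces the published p = 0.1195 only without
correction); exact two-sided 2×2 Fisher with integer hypergeometric
weights (ties exact, no float tolerance); and for sparse r×c tables a
Monte-Carlo Fisher test — tables drawn from the conditional null given
both margins by sequential hypergeometric fill (the `r2dtable` scheme),
p̂ = (1 + hits)/(n_draws + 1) with its binomial SE, fully determined by
the seed.  The selection policy (chi-square iff all expected cells ≥ 5,
else exact 2×2 Fisher, else Monte Carlo) is recorded in every result.  Raw
p-values at α = 0.05, no multiplicity adjustment, matching the original
analysis.  The 388-vs-521 frequency comparison treats the two loci as
independent samples even though they are paired within individuals —
deliberately mirroring the published treatment — and its output is flagged
accordingly.  The Freeman–Halton exact r×c algorithm and any regression
adjustment are out of scope.

## Published-table reconstruction

Every published percentage sits over a known denominator (587/387/76
samples; 1174/774/152 chromosomes), so counts are recovered as
round(pct·N/100) (half away from zero) with a residual report; a residual
> 0.5 marks a cell that cannot have come from an integer count.  Pooling
the per-group counts reproduces the published Total column at printed
precision for all phenotype and haplotype rows, and the phenotype counts
imply the published 521C frequencies (0.24 pooled, 0.27 Bedouin/Arab).
Two caveats are handled explicitly rather than glossed over:

- The published African intermediate-function cell prints 7.11% where the
  row forces 13/76 = 17.11%; intermediate counts are always derived by
  subtraction (group size − normal − low) and that cell is flagged as a
  known irreconcilable value, never used.
- The published haplotype rows imply marginal allele frequencies
  (388G ≈ 0.73, 521C ≈ 0.42) that contradict the published MAFs
  (0.49, 0.24) for the same cohort, while the phenotype counts are exactly
  consistent with the MAFs.  The two row-sets are therefore treated as
  separate reference fixtures; no computation asserts their joint
  consistency from one dataset.

## Synthetic cohorts

The generator draws, per sample, two haplotypes from the group's frequency
4-vector — identical by descent (one draw duplicated) with probability F,
the inbreeding coefficient — derives dosages, and masks each locus missing
independently at the configured rate.  One root seed; group k uses the
child stream `SeedSequence(seed, spawn_key=(k,))`, so adding a group never
perturbs earlier groups.  Outputs are VCF v4.2 (GT-only), a
`sample_id/group` TSV, and a truth JSON with the config and every sample's
haplotype pair.

Two presets encode the study cohort at its published group sizes
(587/387/76), one per published row-set (see caveats above).  The
`maf-consistent` preset's per-group 521C mass is the phenotype-implied
frequency and its 388G mass the printed MAF; the one degree of freedom the
marginals leave open — the \*5/\*15 split — follows the published
per-group \*5:\*15 ratio.  Defaults are F = 0 and no missingness: the real
cohort passed HWE, and although its slight low-function excess is
consistent with consanguinity, modelling that is left to the user via F.

What the generator emulates: group structure, random mating with optional
consanguinity, per-locus missingness, exact two-SNP truth.  What it does
not: genotyping error, admixed individuals, linkage to other *SLCO1B1*
star alleles (\*14, \*17, …), read-level evidence.  Passing
parameter-recovery tests therefore demonstrates correctness of the
inference under the stated model, not robustness to artefacts real exome
pipelines can produce.

## Problem sizes in the test suite

Oracle-equivalence checks run the EM against a dense simplex grid (step
0.01 with three ten-fold local refinements, i.e. 1e-5 resolution at the
optimum) on 100 random tables of N ≤ 200; Fisher 2×2 against exact
enumeration for every table with N ≤ 40; the HWE test against exact
enumeration for every genotype table with n ≤ 50.  Parameter recovery uses
20 seeds at n = 5000 per group (3-SE coverage ≥ 95% per parameter) and the
phenotype check 5 seeds at the study's own group sizes.  These sizes make
the full suite run in well under a minute while keeping every estimate's
Monte-Carlo error far below the tested tolerances.

## Known limitations

Two-SNP star-allele system only — increased-function phenotypes (which
need alleles outside this system) cannot be assigned; no phasing from
reads; no variant calling (the pipeline starts at a called VCF); the
Monte-Carlo Fisher p is an estimator, and results carry its SE so
borderline calls near α can be re-run at higher draw counts.
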