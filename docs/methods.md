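# Methods

This note documents the statistical procedures, conventions, default
parameters, and design choices of `haplobiva`, and what the synthetic-data
generator does and does not emulate.

## Coordinates and genotype representation

All genomic coordinates are 1-based and inclusive on both ends; an interval's
length is `end − start + 1` (the convention under which the two sequenced
amplicons, 17:3596108–3596806 and 17:3571903–3572410, have lengths 699 and
508 bp). VCF POS is used as-is; no half-open conversion. Alleles are
reported on the positive strand; no reverse-complement logic exists.

Genotypes are unphased alt-allele dosages in {0, 1, 2} with a missing
sentinel. Only biallelic SNVs enter the dosage matrix; multiallelic records
and indels are skipped with a logged count. A parallel *allele-pair table*
(Sanger-style TSV: one column per rsID, cells like `G/C`) carries arbitrary
allele characters; diplotype calling reads this table because a
per-amplicon genotyping workflow can legitimately observe a third allele at
a site — in the shipped block definitions, the rare H1-c haplotype makes
rs73303325 triallelic (a = C, b = T, c = G), which a biallelic matrix cannot
represent. The dosage path and the allele path agree exactly wherever both
are defined (tested by round-trip).

## Screening statistics

* **MAF** — min(p, 1−p) of the alt-allele frequency over non-missing
  alleles at a site (per-site complete cases).
* **F<sub>ST</sub>** — two estimators. The default `weir_cockerham` is the
  Weir & Cockerham (1984) single-locus θ̂ = a/(a+b+c) with the full
  variance components including observed heterozygosity; this is what
  PLINK-style per-SNP `--fst` screening actually computes even when
  described with Wright's symbols. `hudson` is the uncorrected
  1 − H<sub>w</sub>/H<sub>b</sub> with H<sub>w</sub> = p₁q₁ + p₂q₂ and
  H<sub>b</sub> = p₁q₂ + p₂q₁, chosen without finite-sample correction so
  that identical frequencies give exactly 0 and a fixed difference exactly
  1. Negative estimates are reported as computed and flagged, never
  clipped. Descriptive divergence classes use the conventional 0.15
  (moderate) and 0.25 (high) cuts; no multiple-testing correction is
  applied at the screening stage.
* **LD** — the two-locus haplotype frequency p<sub>AB</sub> is estimated by
  EM over the double-heterozygote phase ambiguity (all other dosage pairs
  resolve deterministically), started from linkage equilibrium, tolerance
  1e−12. D = p<sub>AB</sub> − p<sub>A</sub>p<sub>B</sub>;
  D′ = |D|/D<sub>max</sub> with the sign-dependent D<sub>max</sub>;
  r² = D²/(p<sub>A</sub>q<sub>A</sub>p<sub>B</sub>q<sub>B</sub>).
  Pairwise-complete genotypes; monomorphic sites are undefined, not zero.
* **LD blocks** — maximal runs of ≥ 2 position-consecutive variants in which
  *every* within-run pair has D′ > 0.75 and r² > 0.75. Singletons are not
  blocks. This all-pairs/contiguous rule is deliberately conservative and
  order-based; its known limitation is that a weakly linked SNP physically
  interleaved between block members splits the run. The pipeline therefore
  detects blocks on the SNP subset that passed the F<sub>ST</sub> screen
  (divergence > 0.15), mirroring the screen-then-cluster order of the
  original two-stage procedure; with the default synthetic SNP layout one
  interleaved divergent SNP (rs73303327) still splits H1, so the block
  report for that layout lists the sub-runs rather than a single 5-SNP
  block. A layout without interleaved non-members recovers both planted
  blocks exactly.
* **Tajima's D** — (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
  a₁ = Σ1/i, a₂ = Σ1/i², b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1)),
  c₁ = b₁ − 1/a₁, c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁², e₁ = c₁/a₁,
  e₂ = c₂/(a₁²+a₂). π is computed from per-site allele counts as
  Σ 2i(n−i)/(n(n−1)), which equals the exhaustive all-pairs enumeration
  (verified to 1e−9 by a property sweep). Haplotype (0/1) input is exact;
  unphased diploid input contributes two sequences per individual, which is
  identical for π (frequency-based) and documented as the supported
  approximation. S = 0 yields an undefined (None) D, never 0.

## Haplotype blocks and diplotype calling

Block definitions (tag-SNP order plus per-haplotype allele states) ship as
YAML; the built-in file encodes the two *TRPV1* blocks: H1 with three
haplotypes (a, b, c) over five tag SNPs and H2 with two haplotypes over
three tag SNPs. The exonic SNP inside the H2 span (rs877610) is not in
linkage with the block and is excluded from calling.

Calling assumes same phase: the call is the unordered pair of defined
haplotypes whose site-wise allele multiset equals the observed genotype at
every tag SNP. If no pair fits, the call is INCONSISTENT; if more than one
fits, or any tag SNP is missing, it is AMBIGUOUS with the candidate list —
no frequency-weighted guessing, because a silent guess would fabricate
data. With the shipped 3+2 haplotypes every complete genotype is uniquely
resolvable (the six H1 pairs are distinguished at rs73303325 alone).
Subjects with unresolved calls are excluded from association with a logged
count.

Grouping schemes: `raw` diplotype labels; `merge_c_into_b` (the rare c
haplotype, observed in two subjects in the motivating data, is pooled with
its near-identical sibling b before pairing); `carrier_vs_aa` (binary aa
vs. any non-a carrier). Additive genotype coding counts non-a copies, so c
counts with b.

## Specific BIVA

Segment areas use the circle model C²/(4π) — the closed form consistent
with circumference inputs and the convention of the specific-BIVA method.
A = 0.45·arm + 0.10·waist + 0.45·calf (cm²); L = 1.1·height (cm);
Rsp = R·A/L, Xcsp = Xc·A/L. The phase angle is computed with atan2 and is
invariant under standardization since A/L cancels in Xc/R.

Ellipses: a **tolerance** ellipse describes population variability, so its
squared Mahalanobis radius is the χ²₂ quantile at coverage 0.50/0.75/0.95
(fixed menu mirroring BIVA practice). A **confidence** ellipse describes
uncertainty in the sample mean: shape matrix = sample covariance / n,
squared radius = 2(n−1)/(n−2)·F(2, n−2; 0.95), exact in small samples;
n < 4 or a zero-variance coordinate is an error ("sample too small"), not a
silent result. The boundary is closed, with a 1e−12 relative epsilon so
constructed boundary points are contained.

Hotelling: T² = (n₁n₂/n)·d′S<sub>pooled</sub>⁻¹d;
F = T²(n−3)/(2(n−2)) on (2, n−3) df (two-sided by construction);
D = √(T²·n/(n₁n₂)) from the pooled covariance. The published-table
consistency of these conversions is exercised as a fixture test; one
tabulated row produced by a sample-duplication workaround is irreconcilable
with the conversion under any rounding and is excluded from the fixture.
"Non-overlapping 95% confidence ellipses" is reported as the boolean
p < 0.05.

Plots put Rsp on x and Xcsp on y, equal aspect, ohm·cm. The reference
population file format is CSV-like (name, n, means, SDs, correlation); the
package ships only synthetic reference parameters — the real NHANES-derived
and Italo-Spanish reference values are not published in usable form, so no
claim is made about them.

## Perception

Dilution series: swab k holds stock/f^(n−k); defaults stock = 2.243 µg/mL,
f = 2, n = 10, so swab 1 ≈ 0.004, swab 5 ≈ 0.07, swab 9 ≈ 1.12 µg/mL and
swab 10 is the stock bit-exactly. The threshold phenotype is the ordinal
swab index (1–10), treated as a 10-category phenotype downstream. PROP
classification: taster iff LMS ≥ 50 (closed lower bound), partitioning
[0, 100] with no gap. Molarity conversion mg/mL = mM·(g/mol)/1000.

## Association

Within-sex z-scores use the sample SD (ddof = 1); zero within-sex SD is an
error. The pooled regression uses additive coding (copies of the
non-reference haplotype), the conventional reading of a linear genotype
model, with carrier coding exposed because the group-wise tables use aa vs.
b-carrier; sex enters as a female indicator. OLS is fitted through
statsmodels and verified against a from-scratch normal-equations oracle to
1e−9. Group tests are classical pooled-variance Student t (not Welch),
matching the tabulated procedure; strata with fewer than two observations
per group are reported N/A rather than dropped. Missing phenotypes are
deleted listwise per model with `n_used` reported. Raw p-values are primary;
Bonferroni adjustment exists only as a clearly labelled extension.

With a female-restricted effect and no interaction term, the sex-adjusted
additive β targets the genotype-variance-weighted average of the
sex-specific slopes; the parameter-recovery tests score the 95% CI against
that target, where coverage is exact under the model.

## Synthetic-data generator

One seeded `numpy` Generator drives the whole study; identical seeds give
byte-identical output. Defaults are fixed to the motivating study's
conditions: cohort sizes 34 M + 12 F (African-ancestry, "SSA") and
20 M + 25 F (European-ancestry, "ITA" — 45 total, the split forced by the
published comparison sample sizes); H1 haplotype frequencies in SSA
a/b/c = 0.545/0.433/0.022 and H2 a/b = 0.556/0.444, with ITA fixed for a;
non-block SNPs drawn independently at their observed cohort frequencies.

Bioimpedance: per (ancestry, sex) bivariate normal baselines on
(Rsp, Xcsp) with correlation 0.65. Female baselines are anchored so the
marginal vector length and phase angle approximate the published female
summaries (ITA_F Zsp ≈ 407 ohm·cm, PhA ≈ 5.7°; SSA_F Zsp ≈ 502 ohm·cm,
PhA ≈ 6.2°); male baselines are not published and are set once to plausible
shorter-vector, larger-angle positions. The default effect model adds
(+45, +3) ohm·cm per H2 b-copy in females only — lengthening the vector and
reducing the phase angle, the direction reported for b-carrier women; the
magnitude is configuration, not an estimate. Anthropometry comes from
sex-specific normals (means ~176/162 cm, 76/62 kg), rounded to 0.1 at draw
time so the written files reproduce A/L exactly; raw (R, Xc) are obtained
by inverting the standardization, making synthetic studies
indistinguishable from real input at the file interface. Capsaicin
thresholds follow a categorical distribution that decays after swab 5 and
is zero from swab 9 (means ≈ 3.7); PROP LMS ~ N(63, 18) clipped to
[0, 100] (≈ 22% non-tasters).

What the generator does **not** emulate: linkage between blocks or with
flanking variation (haplotype pairs are drawn independently per block),
recombination and coalescent genealogy, Hardy–Weinberg departures,
measurement error in R/Xc, anthropometric covariance structure, or any
realistic demography. Passing tests therefore demonstrate correctness of
the estimators and the end-to-end plumbing under the stated generating
model — not robustness to the violations real data can show.

The neutral-region generator provides three stylized haplotype samples for
the neutrality statistic: all-singleton (D < 0), two balanced classes
(D > 0), and a 1/i frequency spectrum for which E[π] = E[θ<sub>W</sub>]
per site, centering D near zero (calibration checked over 200 replicates).

## Pipeline and outputs

Stages run in the order screen → blocks → diplotype → biva → association;
every output table carries a provenance comment (version, config hash,
coordinate convention) and the JSON run summary records seed and per-stage
counts. Errors abort with the stage name; exit codes: 0 success, 2 config
error, 3 data error. Thresholds (F<sub>ST</sub> 0.15/0.25, LD 0.75,
α = 0.05, PROP cut 50) are config fields with those defaults.

## Problem sizes in tests

The property suites use sizes chosen for tight statistical bounds at modest
cost: 400 random matrices for the Tajima oracle sweep, 10⁵ draws for
tolerance-ellipse coverage, 1000 replicates for confidence-ellipse
coverage, 2000 null replicates for Hotelling type-I error, 500 generated
cohorts for effect-recovery CI coverage, and 5000-subject cohorts for
Hardy–Weinberg and frequency-recovery checks.

## Known limitations

* The contiguous-run block rule cannot represent a block interrupted by a
  physically interleaved non-member SNP (see above).
* Tajima's D on unphased diploids is exact for π but treats 2N chromosomes
  as the sample; no missing data are allowed on that path.
* The EM LD estimator assumes random mating within the analysed sample; it
  is biased under strong substructure (compute LD within groups instead).
* STR variation inside the H1 amplicon (a known tetranucleotide repeat) is
  not modelled; calling uses SNP states only.
* Confidence-ellipse and Hotelling inference assume bivariate normality;
  with the motivating study's smallest strata (n < 4) no statistic is
  produced at all rather than an unreliable one.
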