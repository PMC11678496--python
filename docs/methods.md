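# Methods

## Reference-standard model

The evaluation assumes two pure genomes and their mixtures. DNA1 is fully
homozygous (the hydatidiform-mole situation: every allele paternal, no
heterozygotes), DNA2 is ordinary diploid. For a site with allele dosages
d₁, d₂ ∈ {0, 1, 2} in the two genomes, a mixture with DNA1 mass fraction
f₁ presents the variant at

    eVAF = f₁·d₁/2 + (1 − f₁)·d₂/2 .

Informative (N–H) pairs are the special case where one side has dosage 0
and the other dosage 2, so eVAF is exactly f₁ or 1 − f₁ and every mixture
in the series probes one known allele fraction. Everything downstream —
detection rates, probit sensitivity, trimming — rests on this arithmetic
and on nothing caller-specific.

Thresholds are taken boundary-inclusive exactly as stated throughout:
null means VAF ≤ 0.05, homozygous VAF ≥ 0.95, depth requirements are
"at least" (depth exactly 10 passes DP10), trim removals are "at or above"
(VAF exactly 0.7 is removed), and cutoff conditions treat a call below the
threshold as null. Single-nucleotide variants only; multi-allelic records
are split per alternate base; chromosome names are normalized to the
prefix-free form; informative pairs are restricted to autosomes 1–22.

## Pair selection and trimming

Selection requires the null side to be reference-only **at the site**
(no allele above 0.05 anywhere at that chrom/pos, an uncalled site counting
as VAF 0), not merely for the specific alt — a genome homozygous for a
different alt at the same position is not null. Both pure-sample depths
must be ≥ `dp_min` (default 10) *where assessable*: depth at an uncalled
site cannot come from a VCF, so each sample may carry a per-base coverage
table. A missing table makes the check "not assessable"; the pair is then
retained with a warning (lenient, default) or dropped (`strict` mode). An
unknown depth is represented as `None` and is never conflated with zero
coverage.

Trimming removes non-specific calls that cannot be diluted true variants:
pairs with depth < `dp_min` in any mixture expecting the variant nearly
undiluted (eVAF ≥ 0.8 — for the canonical series this is the CH5/CH10/CH20
mixtures of an N–Ho pair and CH80/CH90/CH95 of a Ho–N pair), and pairs
showing VAF ≥ 0.7 in any mixture with eVAF ≤ 0.2 or VAF ≥ 0.8 where
0.2 < eVAF < 0.8 (eVAF 0.5 in the canonical series). Stating the rules in
terms of eVAF bands rather than fixed sample names generalizes them to
non-canonical designs while reproducing the canonical behaviour exactly.
Trimming recomputes observations from the mixture call sets, so it is
idempotent by construction; surviving observations carry V-group labels
`V{round(100·eVAF)}`.

## Detection and probit sensitivity

An observation is detected under condition (dp_cut, vaf_cut) iff VAF > 0
and VAF ≥ vaf_cut and depth ≥ dp_cut. VAF cutoff 0 therefore still
requires presence in the call set: "no cutoff" means no *extra*
thresholding. Unknown depth passes the depth test vacuously (absence of
coverage information is not evidence of low coverage).

Group-level detected/total counts are fit as Binomial with success
probability Φ(a + b·eVAF) by IRLS maximum likelihood (a GLM with probit
link; group-level binomial totals give the identical likelihood to
per-observation rows). The sensitivity estimate is
(Φ⁻¹(target) − a)/b with target 0.95 by default, reported both as an eVAF
and as a percentage rounded to two decimals. Numerical edge cases:

* groups with zero observations are dropped; fewer than two usable groups
  is an error;
* if every used group already has rate ≥ target the fit would extrapolate
  below the observed data; the smallest observed eVAF is returned with a
  `saturated` flag instead;
* a fitted slope ≤ 10⁻⁶ (flat dose–response) or non-convergence raises an
  explicit error naming the condition;
* fully detected upper groups produce a quasi-separated likelihood — the
  associated statsmodels warning is suppressed because the slope remains
  identified by the partially detected groups;
* `max_fit_evaf` optionally restricts the fit to the lower groups. The
  default fits all groups: the saturated upper groups carry almost no
  likelihood weight, so estimates move little either way, but the choice
  is exposed because on real data partial fits can shift results slightly.

## FP error typing

A mixture allele passing the cutoff condition is a false positive iff that
base is absent from both pure samples at the site; a pure-sample allele at
or below the null threshold (0.05) is itself noise and does not shield a
matching mixture call. Sites are classed R–R / V–V / R–V from the pure
samples' alleles above the null threshold: a sample "has the reference
base" unless it is homozygous-variant (VAF ≥ 0.95), so V–V requires both
samples homozygous for a variant and every other mixed configuration is
R–V. Heterozygous parents therefore fall in R–V, the literal reading of
the three class definitions. Only called mixture alleles need enumerating
(an uncalled allele cannot be a false positive), which keeps the R–R
universe implicit. Per cutoff condition the grid reports per-class counts
per mixture and the median across the design's mixtures, both per class
and for per-sample totals; V–V and R–V counts are computed but secondary,
as their magnitudes are typically small. Fold differences between
conditions or pipelines are reported as ratios rounded half-up to two
decimals.

## Concordance statistics

Two pair sets built against the same pure samples are matched on
(variant key, pair orientation) and partitioned into common / A-specific /
B-specific. VAF variability per eVAF group is summarized by Q1/median/Q3
with linear interpolation between order statistics (type 7 — the
convention is not dictated by the problem, and exact IQRs can shift
slightly between conventions, so it is fixed and recorded here);
IQR = Q3 − Q1. Group IQRs of two categories are compared with the
two-sided Wilcoxon matched-pairs signed-rank test pairing groups of equal
eVAF, using the exact null distribution up to 25 non-zero differences
(seven uniformly signed pairs give p = 2/2⁷ = 0.015625) and the normal
approximation beyond; all-zero differences return p = 1. Depth and GC
comparisons use the two-sided Mann–Whitney U test (exact for small
tie-free samples). GC content is computed over a window (default 101 bp,
a round "variant ± 50 bp" choice; the window is a free parameter and
exposed) centered on the variant, truncated at contig edges, with N bases
excluded from the denominator. The median-centered "adjusted VAF" display
shifts a group's quartiles so the median sits at 0.5 for plotting
comparability; it never feeds statistics.

## Synthetic experiments

The simulator emulates the call-level structure of the mixture experiment,
not reads: per sample and site, depth ~ NegBin(mean 100, size 4; CV ≈ 0.5,
mimicking exome capture non-uniformity) or fixed for analytic tests; reads
are allocated to alleles multinomially at their eVAFs; each read is
corrupted with probability ε (default 0.001, a typical Illumina
substitution scale) uniformly to one of the three other bases; a threshold
caller (min alt reads, default 3; optional min VAF and min depth,
including high-VAF presets that reproduce aggressive in-house filtering)
emits VCF records with GT/AD/DP. Truth genotypes are drawn to hit
requested counts of N–Ho, Ho–N, R–R, V–V and R–V sites exactly (defaults
300/300/400/50/100 on two 50 kb contigs — large enough for stable group
rates, small enough for second-scale tests); DNA1 is never heterozygous.
Everything is deterministic under the config seed, including the on-disk
VCF/FASTA/TSV realization and the manifest that feeds `mixsense evaluate`.

`analytic_detection` provides the closed-form companion: the probability
that a site at a given eVAF is emitted equals a binomial tail
P(X ≥ t | depth, p_eff) with p_eff = eVAF·(1−ε) + (1−eVAF)·ε/3 and t the
caller's alt-read threshold, marginalized over the depth distribution
(negative-binomial tail truncated at mass 10⁻⁹). `analytic_lod` inverts it
by root-finding. These oracles never share code with the pipeline they
check.

What passing simulation-based tests shows — and what it does not: the
simulator reproduces binomial allele sampling, coverage dispersion,
uniform substitution errors and threshold calling, so it validates the
selection/trimming/regression machinery end to end. It does not model
mapping artefacts, strand or GC bias, capture dropout correlated across
samples, contamination, or caller-specific heuristics; sensitivity numbers
from real service-provider data can differ for those reasons even when
every test here passes.

## Test problem sizes

The end-to-end recovery test uses 5,000 informative sites at fixed depth
100 (probit estimate within one percentage point of the analytic 95%
point); probit recovery uses 20 replicates of 500 observations per group,
comparing the mean estimate at ±0.01 eVAF since the single-replicate
sampling SE is ≈ 0.005; brute-force equivalence runs 100 random toy
datasets of ≤ 250 sites; calibration checks (VAF concentration, FP
injection) use 2,000-site batches against 3σ binomial bounds. These sizes
keep the full suite in the seconds-to-a-minute range while leaving the
stochastic tolerances comfortably above sampling noise.

## Known limitations

* SNVs only — indels, MNVs and symbolic alleles are skipped on ingest.
* No genotype-likelihood modelling; pair status is purely threshold-based.
* No confidence intervals on the sensitivity estimate.
* gVCF input and BAM-level analyses are out of scope; depth at uncalled
  sites must come from a coverage table.
* The Wilcoxon/Mann–Whitney implementations defer to SciPy; exact p-values
  switch to approximations in the presence of ties/zeros beyond what the
  exact method supports.
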