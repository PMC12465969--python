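# Methods

This note documents the models behind `canidnm`, the choices made where
the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## DNM calling model

A candidate de novo SNV is accepted when, within a trio, the offspring
is heterozygous (0/1) and both parents homozygous reference (0/0); the
parents jointly carry at most one alternate-allele read; the offspring
genotype quality is ≥ 40; every trio member's depth DP satisfies
DP ≥ 12 and 0.5·indDP < DP < 2·indDP, where indDP is that individual's
genome-wide mean autosomal depth; and the offspring allele balance
alt/(ref+alt) lies strictly in (0.25, 0.75). On the X-unique region of
a male offspring the depth thresholds are halved (the offspring and
sire are hemizygous there) and the allele balance must instead exceed
0.75; pseudoautosomal (PAR) sites keep autosomal thresholds. Only
single-nucleotide changes are eligible. Boundary strictness follows the
stated inequalities: GQ and the DP floor are inclusive, the
mean-relative depth bounds and the allele-balance bounds strict, and
the halved X thresholds inherit the same strictness. The GQ rule
applies to the offspring only (configurable to all samples, since the
narrower reading is ambiguous). Missing genotype evidence fails closed
with a dedicated `MISSING_EVIDENCE` code. All rules are evaluated
independently, so the verdict cannot depend on evaluation order.

A read-level post-check mimics a manual alignment review: at most one
"incorrect" read is tolerated (a parental read not matching the
reference, or an offspring read matching neither reference nor the DNM
allele), and the offspring read-level allele balance must lie in
[0.25, 0.75].

Cohort-level QC removes trios with any individual mean depth below
24×. Multi-allelic records are decomposed into bi-allelic candidates
on ingest, each alternate evaluated independently.

## Callable accounting and rates

A position is callable for a trio when both parents are homozygous
reference and all three members pass the same depth rules as calling
(halved on the male X-unique region). Callable *sites* (bp) become the
callable *size* — the rate denominator — by a ploidy factor: 2
everywhere except the X-unique region of a male offspring, where 1.
The per-generation rate is the pooled ratio ΣDNMs/Σcallable size
(ratio of sums, not the mean of per-trio rates: pooling is what the
trio-resampling bootstrap below recomputes per round; per-trio rates
are also reported). Confidence intervals are percentile bootstrap over
trios, 10,000 rounds by default, seeded.

Per-class rates correct for mutational opportunity: the callable size
of a region is multiplied by the fraction of bases that can host the
class — A/T sites for T>\* classes, C/G sites outside CpG dinucleotides
for C>\* classes, CpG-dinucleotide sites for CpG>TpG. Mutation classes
are strand-collapsed to the pyrimidine strand; C>T with a 3′ G on
either strand is CpG>TpG. The classifier accepts the triplet context
given on either strand and is exactly strand-symmetric (tested
exhaustively over all 4×3×16 combinations).

Two closed forms support the X-chromosome analysis. With α the
male-to-female mutation ratio (α = paternal/maternal phased counts),
the expected X/autosome rate ratio is 2(2+α)/(3(1+α)), from males
carrying one X to the females' two. The PAR male recombination rate is
the obligate 100-cM male map over the PAR physical length; the
sex-averaged rate is the mean of the male and female rates.

The recombination-mutagenesis accounting takes the observed
hypomethylated-CGI DNM count O and the composition-corrected
enrichment fold F: expected = O/F under the genome-wide rate, excess =
O − O/F, reported per trio and as a fraction of the mean per-trio DNM
count, with a one-sided Poisson tail p for the enrichment.

## Parental-age models

Phased counts are modelled as count ~ Poisson((b0 + b1·age)·E) on the
identity scale — the reported slopes are additive per-year effects in
mutations/bp/year, which a log link would not give. The exposure E of
a phased fit is the trio's haploid autosomal callable size (half the
diploid callable size); unphased DNMs are excluded from phased fits.
Whether the haploid or diploid convention matches the original
analyses is not decidable from the reported quantities; both are
available, haploid is the default. Note that fitting
incompletely-phased counts estimates the phased-count slope, which is
the full per-parent slope attenuated by the phasing fraction; fits on
fully-phased (truth) counts recover the generative slope directly.

Maximum likelihood uses Nelder–Mead on the exact log-likelihood with a
−∞ barrier wherever a fitted mean would go negative (no silent
clipping), started from a weighted least-squares moment estimate; Wald
intervals come from the observed information. The Bayesian variant
samples the same likelihood under independent half-normal priors
scaled to 10× a crude moment estimate (weakly informative,
nonnegative), using an affine-invariant ensemble sampler (emcee, 16
walkers, 2000 steps, 500 burn-in) with a cross-walker R-hat warning
gate at 1.05; intervals are highest-density. ML and Bayes agree within
2% on well-conditioned cohorts (tested), and the ML fit matches
statsmodels' identity-link Poisson GLM (independent oracle in the test
suite).

McFadden's R² is 1 − ll_model/ll_null with the intercept-only Poisson
null on the same data, both likelihoods exact. Downsampling thins
per-trio counts binomially with keep probability target/total, which
preserves the Poisson structure and scales both coefficients by the
keep probability in expectation. Breed-size strata (small /
intermediate / large) are fit independently plus pooled. An all-zero
count vector returns a flagged boundary fit (b0 = b1 = 0).

The yearly rate is reported two ways, both labelled approximations:
the per-generation per-bp rate at the mean parental ages divided by
the mean generation interval, and the slope-sum (b1p + b1m)/2 — the
rate added per diploid bp when both parental ages advance one year.

## Spectrum, sharing, hypermutation

Cross-cohort class tests are two-sided Fisher exact tests on the 2×2
table (in-class vs not, cohort A vs B), Bonferroni-controlled across 8
tests (the 7 base classes plus the CGI-overlap class), significance
strictly below 0.05/8 = 0.00625. Paternal-age spectrum trends are
weighted least squares of per-age-bin class fractions on age with bin
totals as weights.

Shared (early embryonic) mutations are DNMs at the same position with
the same alternate allele in ≥ 2 offspring sharing at least one
parent; allele identity is required on top of position to avoid
coincidental collisions. Groups whose members share no parent are
flagged `RECURRENT_UNRELATED` and excluded. The sharing fraction is
pair-based: Σ shared / Σ unique over all full-sib pairs (triples
contribute all constituent pairs); half-sib sharing is reported but
excluded from the fraction. Its CI is a 1000-round percentile
bootstrap over pairs.

Hypermutator flagging compares each trio's count to the cohort
excluding itself: fold over the median, and an upper Poisson tail at
the cohort mean, Bonferroni-adjusted across trios, flagged below 0.05.
Flagged trios are excluded from rate and age analyses by default. The
phase-balance binomial test of shared-mutation origins defaults to an
expected paternal fraction of 0.5 (equal-sex accrual of early
mutations); the cohort-wide 0.7505 is available as an alternative
null, since either could be intended.

## Crossovers and PRDM9 dating

Haplotype blocks are runs of ≥ 500 consecutive informative markers
with the same grandparental origin; shorter runs are treated as
phasing noise and masked (they neither split blocks nor create
breakpoints), and adjacent same-origin blocks merge. Each boundary
between different-origin blocks yields a breakpoint at the midpoint of
the flanking markers. The DNM–breakpoint proximity expectation is
trio-matched: each trio contributes n_dnm · n_breakpoints · 2w/G for
window w and genome size G — the only accounting whose cohort-scale
value matches the headline expectation — with a cohort-pooled variant
available for comparison.

Dating the *PRDM9* loss uses paired trees estimated from
hypomethylated-CGI and whole-autosome alignments with identical
topologies. Per branch, the ratio of HMR to autosomal length measures
the relative substitution rate; branches are assigned roles: *full*
(entirely post-loss; pooled into r1), *pre* (PRDM9 still functional;
pooled into r0), and the *transition* branch carrying the loss.
Pooling is length-weighted (Σhmr/Σauto). With the transition branch
spanning ages [T_young, T_old] and observed ratio r_obs, the loss time
t solves the time-weighted mixture

    r_obs·(T_old − T_young) = r1·(t − T_young) + r0·(T_old − t),

i.e. the elevated regime applies to the part of the branch younger
than the loss; r_obs = r1 places the loss at the branch's oldest
point. An r_obs outside [r0, r1] is clamped and flagged. The exact
interpolation the assumption set implies is this linear mixture; the
solver is the exact inverse of the bundled tree generator at zero
noise (round-trip identity to 1e-9 My, tested). Uncertainty comes from
1000 resamples: either user-supplied bootstrap tree pairs (one HMR and
one autosome tree drawn independently per round) or, at desk scale,
independent multiplicative log-normal noise on every branch of each
tree — a parametric stand-in for alignment-bootstrap replicates, which
require the alignments themselves. Loss-time draws are clamped to the
branch span; the CI is the 2.5/97.5 percentile interval.

## Synthetic-data generator

`SimulationConfig` defaults encode the study conditions: 390 trios,
paternal/maternal slopes 3.25×10⁻¹⁰ and 9.64×10⁻¹¹ mutations/bp/year,
a cohort rate of 4.89×10⁻⁹/bp/generation with a 75.05% paternal share
of phased mutations (intercepts are solved from these at the mean
age), 31.11% phasing, a 2.34-fold hypomethylated-CGI enrichment over a
30.68-Mb HMR span in a 2.28-Gb autosomal genome with a 6.8-Mb PAR,
mean litter size 2.4, a 0.45% target pair-shared fraction, and 43.3×
mean depth. Values the study does not print were fixed once at
realistic levels: parental ages truncated-normal (mean 5 y, sd 2.2 y,
bounds 1–12 y — the usual dog breeding span), per-site depths negative
binomial (size 8) around each individual's mean, a representative
transition-rich spectrum, and per-trio callable fractions near 96.5%.

Counts are generated per parent as Poisson((b0 + b1·age)·G) with G the
trio's haploid autosomal callable size. Early (sibling-shareable)
mutations are drawn per litter and duplicated across littermates, with
parental origin split 0.5/0.5; the per-offspring early fraction is
2s/(1+s) so the pair-based estimator's expectation equals the
configured shared fraction s. Genomic placement is uniform within
strata, with the HMR stratum chosen at probability
fold·f/(1 − f + fold·f) for HMR autosome fraction f. Per-size-class
slope overrides re-solve the class intercept so the paternal rate at
the mean age is unchanged (slower-but-earlier versus faster-but-later
accumulation, matching the observed stability of per-generation rates
across sizes).

The generator emulates genotype evidence (negative-binomial depth,
binomial heterozygote allele balance, optional parental error reads,
VCF emission with byte-determinism), not read alignments or
base-calling errors; the synthetic genome's CpG "islands" are coarse
blocks whose total spans are correct, not kb-scale islands; breeds are
a fixed six-breed rotation rather than 43 breeds with realistic
pedigree depth. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model — Poisson counts, uniform
placement, independent trios — not robustness to alignment artifacts,
mapping bias, or cryptic relatedness in real data.

## Problem sizes and numerics

The default test suite simulates cohorts of 40–390 trios, with 20
replicate cohorts for the slope-recovery and size-class-ordering
checks, bootstrap rounds reduced to 100–2000 inside tests (10,000 and
1000 remain the analysis defaults), and 10⁵–10⁶-marker crossover
tracks. Bootstrap and MCMC seeds are mandatory arguments — there is no
hidden global state — and all reported intervals are percentile-based,
so results are reproducible bit-for-bit given a seed. Degenerate
inputs reject loudly (zero callable size, zero age variance, empty
cohorts, saturating proximity windows) rather than returning NaNs.
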