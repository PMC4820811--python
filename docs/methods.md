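# Methods

`omicscreen` implements a cross-omics candidate-gene discovery pipeline of
the kind used to find downstream targets of a disease-associated
transcription factor: an over-expression screen read out at both the
transcript and the protein level, intersected into a short
direction-consistent candidate list, with a parametric linkage stage for
the genetic localization that precedes such screens and small
validation-assay computations (qPCR, dual reporter, flow-count folds)
around them.  This note describes the models, the defaults and why, what
the synthetic data do and do not emulate, and the numerical choices.

## Transcriptome stage

**Design.** Three conditions — non-transfected control, wild-type
construct, mutant construct — with 8 biological replicates each.  The
control is treated as shared background: its normalized expression is
subtracted from both transfected conditions before fold changes are
formed.

**Normalization.** Expression is RPKM,
`1e9 * count / (library_total * length_bp)`.  RPKM is scale-invariant per
sample (multiplying a library's counts by a constant changes nothing),
which is the property the tests pin down.  No TPM/CPM alternatives are
offered; they are out of scope.

**The s.d.-about-zero statistic.** Differential thresholds are multiples
of sigma, defined as the root mean square of the valid log2 fold changes
about zero — the deviation from an assumed mean of "no change" — not the
sample s.d. about the empirical mean.  The RMS about zero dominates the
s.d. about the mean (they coincide only when the mean is exactly 0); both
are reported.  A comparison is *valid* iff both background-subtracted
condition means are positive, the minimal rule that keeps log2FC finite at
pseudocount 0.  The k-sigma rule flags `|log2FC| > k*sigma` strictly, so a
value lying exactly on the threshold is not a hit, and k = 6 hits nest
inside k = 3 hits by construction.  Under an approximately Gaussian null
the two-sided 3-sigma flag rate is 2\*Phi(-3) ~ 0.27%, which the
acceptance suite verifies by simulation.

**Detection routes.**

1. *Subtractive route*: per-replicate RPKM minus the control condition
   mean (clamped at 0), log2 with a pseudocount of 0.5 (needed because
   clamped replicate values can be 0; the condition-mean path uses
   pseudocount 0 with validity masking instead), two-sided pooled-variance
   Student's t, hit iff p <= 0.05 and mean fold >= 1.5.
2. *Sigma route*: the k-sigma rule above on the log2FC of
   background-subtracted condition means, at k = 3 and k = 6.
3. *Count route*: a deliberately simplified two-step negative-binomial
   test on raw counts, in the spirit of DESeq but not equivalent to it:
   median-of-ratios size factors against the geometric-mean reference;
   per-gene dispersion pooled across the two tested conditions by method
   of moments (`d = max(0, (var - mu) / mu^2)`), a Wald statistic on the
   log2 ratio of condition means with a delta-method standard error.  The
   statistic is referred to a t distribution with the pooled degrees of
   freedom rather than the normal: the dispersion is itself estimated from
   8 replicates, and the normal reference proved anti-conservative
   (planted-fixture false discovery proportion ~0.18 against a nominal
   0.05 Benjamini-Hochberg level; the t reference brings it to ~0.06 at
   ~0.94 recall).  Step 1 screens wild-type against control and keeps
   genes with BH q < 0.05 that sit at least 1 log2 unit above background;
   step 2 tests mutant against wild-type on those survivors at BH
   q < 0.05.  All-zero genes are excluded before size factors.

**Consensus** is the intersection of any chosen routes with an identical
direction everywhere; the default triple is subtractive + 3-sigma + count
route.  The 6-sigma route is computed and reported but not part of the
default consensus: on the default fixture its threshold (~2.9 log2 units
once planted effects inflate sigma) exceeds the planted effect sizes, and
requiring it would gut recall, exactly as raising stringency is meant to.

**Sequencing QC.** Derived columns from raw per-sample read counts in
millions: % mapped without PCR duplicates = 100 \* wo_dup / total;
% properly paired = 100 \* properly_paired / wo_dup; sequenced Mb =
properly paired reads (10^6) x read length (default 100 bp, pairs counted
as two reads); coverage = sequenced Mb / transcriptome size, default 65 Mb
— a value inferred from the bundled table's own coverage column rather
than stated anywhere, and exposed as a parameter.  The bundled run summary
ships in two fixtures: per-sample rows, and the published per-lane totals
as printed.  The published totals were computed before the per-sample
values were rounded to two decimals, so summing the printed per-sample
rows reproduces the printed lane totals only to ~0.3; the combined run
totals are therefore defined, as in the source table, as the sum of the
per-lane totals.

## Proteome stage

One row per peptide-spectrum match with 8 reporter channels (3 wild-type,
3 mutant, 2 non-transfected control).  The pipeline is:

1. *Filter*: isolation interference strictly < 30% (the conventional
   "<30%" phrasing is a strict bound), identification q <= 0.01 (a "1% FDR
   cutoff" is conventionally inclusive), rank-1 assignments only.
   Relaxing any threshold can only grow the survivor set (tested as a
   property).  Proteins whose every PSM is filtered out are dropped, not
   imputed.
2. *Aggregate*: per protein per channel, the median over surviving
   spectra; even counts average the two central values.  The median is
   permutation-invariant and bounded by the contributing values, and the
   generator plants effects at the protein level with spectrum-level noise
   precisely so that the median is the right de-noiser.
3. *Quantile normalization* across all 8 channels (controls ride along but
   are excluded from testing): each column's rank r is replaced by the
   mean of the r-th order statistics across columns, ties receiving the
   mean of the reference values their average rank spans.  Column means
   become equal and the map is idempotent.  Proteins with a missing or
   non-positive channel after aggregation are dropped from normalization
   and testing rather than imputed.  An optional median-centering after
   quantile normalization exists behind a flag and is off by default;
   only quantile normalization is part of the standard path.
4. *Test*: log2, two-sided pooled-variance Student's t of the 3 mutant
   against the 3 wild-type channels, BH q-values attached.  Degenerate
   zero-variance proteins get p = 1 when the group means agree.
5. *Detect*: the same k-sigma rule as the transcriptome stage (k = 3) on
   the protein log2FC vector.
6. *Concordance*: proteins hit on both labelling platforms with the same
   direction are concordant; opposite directions are reported separately
   as discordant, never silently merged.

A known and deliberate limitation inherited from the normalization choice:
rank-based quantile normalization cannot represent values below (or above)
the shared reference range, so fold changes of proteins at the abundance
floor are compressed — a planted 5.7-fold effect on a 1st-percentile
protein can measure as ~2-fold.  This mirrors the ratio compression real
isobaric quantification suffers and shapes the truth-recovery fixtures
(below).

## Cross-omics intersection

Identifier spaces are aligned explicitly (`map_ids`): a one-to-one mapping
table or identity; unmapped ids on either side are reported, never
silently dropped; duplicate mappings are an error.  A candidate must be in
the transcript consensus and hit on all proteome platforms (default; a
mode relaxes this to any platform) with one direction of change across
every supporting screen.  Direction consistency can be relaxed by flag for
exploratory use but is on by default — a candidate that goes up in one
screen and down in another is no candidate.  The report carries per-screen
effect sizes so the final table reads like the figure such studies print.

## Linkage stage

Two-point parametric likelihood of affection statuses and marker genotypes
under a disease model (allele frequency plus penetrance triple, indexed by
copies of the disease allele: default 0.001 and (0, 0, 1), the fully
penetrant autosomal recessive model) linked to a codominant marker with
user-supplied allele frequencies at a single sex-averaged recombination
fraction theta.  Founders follow Hardy-Weinberg proportions with linkage
equilibrium between the loci; transmissions use the standard
recombination-fraction haplotype probabilities over ordered two-locus
genotypes ((2m)^2 states for an m-allele marker).

The engine is generalized Elston-Stewart peeling implemented as factor-
graph variable elimination with a greedy minimum-degree order.  Because
variable elimination is exact on arbitrary factor graphs, consanguineous
(looped) pedigrees are handled by the same code with no loop breaking and
no separate enumeration fallback; a full-joint brute-force enumeration is
nevertheless exposed (`enumerate_likelihood`) as an independent reference
for small pedigrees and serves as the oracle in the tests (pedigrees of
3-6 members; the joint array is 16^n states, so 7+ members would need
gigabytes).  Intermediate factors are rescaled by their maximum with the
log of the normalizers accumulated, keeping the arithmetic in log domain
end to end; impossible data return -inf.  The likelihood of a single
untyped founder of unknown affection is exactly 1, elimination order does
not change the result, and at theta = 0.5 the likelihood factorizes into
disease-only and marker-only parts — all tested.

LOD: Z(theta) = log10 L(theta) - log10 L(0.5), profiled over
{0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5} by default, Z(0.5) = 0 exactly
and Z(0) = -inf in the presence of an obligate recombinant.  A phase-known
double backcross (affected grandparent homozygous 1/1, unaffected
grandmother 2/2, so the affected parent is an obligate disease-1/wild-2
double heterozygote) with n non-recombinant meioses gives
Z(0) = n\*log10(2) exactly, which the acceptance suite checks to 1e-9 for
n = 5, 10, 15.  Marker allele frequencies are user inputs; sex-specific
theta, multipoint analysis and liability classes are out of scope.

## Synthetic data: what it emulates, what it does not

All generators take independent, explicitly seeded streams (a fixed
per-generator offset mixed with the master seed), so enlarging the gene
panel does not perturb a pedigree simulated from the same seed, and
identical configurations are bitwise reproducible.

**RNA-seq counts.** Negative binomial with `var = mu + d*mu^2` (default
dispersion d = 0.05, moderate for cell-line replicates), gene means
log-normal (natural-log mean 6.0 ~ 400 counts, s.d. 1.0), lengths uniform
on 200-10,000 bp, per-sample log-normal depth jitter (s.d. 0.1; the real
replicate depths vary by ~±15%).  A gene is *transfection-responsive* with
probability `responsive_fraction` (default 0.3): its mean splits into a
background share (`background_fraction`, default 0.25) present identically
in every condition — alone constituting the control mean — and a signal
share carrying the planted mutant effect multiplicatively.  Non-responsive
genes are expressed at the full mean in all three conditions, as most of a
real transcriptome is.  This split matters: if *every* gene's control mean
were a fixed fraction of its expression, the control library would be a
global rescale of the wild-type library and depth normalization would
exactly undo it, leaving the background-subtraction step with nothing to
subtract.  With a responsive subset, subtraction cancels the shared
endogenous expression and the valid comparisons are the responsive genes,
matching how such screens actually behave.  Planted features are always
responsive.  The truth table records each feature's planted log2 effect
and tier.

**PSM tables.** Per protein 1-10 peptides with 1-5 spectra each; spectrum
intensity = channel mean x a log-normal per-spectrum ionization factor x
log-normal channel noise (s.d. 0.25 log2 units by default); planted
effects multiply the mutant channel means; control channels carry the
background fraction of the abundance.  Configurable fractions of rows
exceed the interference threshold (10%), the q cutoff (5%) or carry rank 2
(5%), calibrated so the filter retains roughly the share of PSMs such
experiments keep.  Not emulated: isotope impurity cross-talk, co-isolation
ratio compression at the spectrum level, shared peptides between proteins,
or missing channels within a spectrum — so passing tests say nothing about
protein-inference ambiguity on real data.

**Joint fixtures** assign tiers (both / transcript-only / protein-only /
null, 6 each by default) with one signed effect per feature (±2.5 log2 by
default) applied in every layer its tier names.  Protein base abundances
are drawn once per fixture and shared by both platform runs — two
chemistries measuring the same lysates — with platform-independent noise.
Effects are planted on mid-abundance (10th-90th percentile) proteins
because, per the compression property above, truth planted at the
abundance floor is unrecoverable by *any* analysis of quantile-normalized
data; the recovery tests are about the intersection logic, not about the
floor.  For the same reason the low-noise recovery fixtures set the
filter-failure fractions to zero: a single-spectrum protein would
otherwise vanish from a platform with probability ~0.19, failing recovery
for data-availability rather than method reasons (the filter path has its
own tests).  The low-noise condition used by the recovery tests is
dispersion 0.01, no depth jitter, background fraction 0.1, spectrum noise
0.15.

**Pedigrees.** Gene-drop: founder haplotypes from population frequencies
under linkage equilibrium, transmissions recombining with probability
theta, affection drawn from the penetrance vector (deterministic under 0/1
penetrances), all individuals genotyped.  The generator exposes the raw
haplotypes for meiosis-level assertions (no recombinants at theta = 0;
locus independence at theta = 0.5 by chi-squared on >10^4 meioses).

**Ct tables.** Gaussian noise on the Ct scale (the standard qPCR
assumption); a group with true fold F has target Ct = calibrator Ct -
log2(F) + noise, reference Ct around its own mean.  Undetected expression
(Ct > 40) is encoded as missing, never as the number 40.

## Assay computations

Delta-delta-Ct: per-record dCt = Ct_target - Ct_reference, per-group ddCt
against the calibrator mean, fold = 2^-ddCt, dispersion propagated as the
conventional fold range 2^-(ddCt ± s.d.).  The fold is invariant to adding
a constant to every Ct of a run, and the noiseless generator round-trips
exactly.  Reporter normalization: luciferase over phosphatase, fold
against the control pair; invariant to rescaling both channels together.
Percent-positive folds: fold of mean replicate percentages with a
two-sided Student's t on the percentages; swapping groups inverts the
fold.  Amplification-efficiency (Pfaffl) correction and cell-cycle model
fitting are out of scope.

## Problem sizes

The test suite and the acceptance script use: 2,000 genes x 24 samples
with 20 planted effects over 10 seeds for consensus recovery; 400 proteins
(~7,000 PSMs) for the proteome stages; 800-gene/400-protein joint fixtures
over 10 seeds for intersection recovery; 20 x 10,000 Gaussian nulls for
sigma calibration; 30-100 random 3-6-member pedigrees for the
peeling-vs-enumeration oracle plus the closed-form families; 100 seeds of
6-replicate Ct tables.  These sizes make every stochastic check
well-resolved (binomial standard errors a few 1e-4) while the whole suite
runs in about a minute.
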