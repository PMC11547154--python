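# Methods

This note documents the models and procedures implemented in `lncmeth`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Quantification

**ΔΔCt expression.** Replicate wells are averaged arithmetically
(triplicates are the norm; a replicate spread above 0.5 cycles is flagged
but kept — a common qPCR QC convention).  ΔCt = Ct_target − Ct_reference
per sample; the calibrator ΔCt is either the mean over a calibrator
sample set or, in paired mode, the matched sample of the same patient;
fold = 2^−ΔΔCt.  Reference genes may be a list, in which case the mean
reference Ct is used (small-RNA assays normalised to the mean of RNU48
and RNU6 fall out of this rule).  Changes within twofold of the
calibrator are classified *retained*, with the boundary inclusive
(|ΔΔCt| ≤ 1 → retained; ΔΔCt > 1 → down; ΔΔCt < −1 → up): reference-gene
variability makes sub-twofold calls unreliable.

**qMSP methylation.** The methylation-specific assay is quantified as
PMR (percent of methylated reference) against a fully methylated control
DNA; this is the standard quantity when the assay design names a
100%-methylation control but no explicit formula.  Conversion
completeness is checked with an ACTB assay specific to the *unconverted*
template: amplification below a Ct floor (default 35 cycles) flags the
sample and excludes it from group statistics by default.  Degenerate
inputs follow explicit conventions: an undetermined Ct at the
methylated-specific locus with a valid converted-ACTB assay is PMR = 0
(below detection) rather than missing, preserving the sample for group
comparisons; PMR above 150 (possible with efficiency differences between
loci) is capped and flagged.

## Cohort statistics

The Mann–Whitney U is exact (full enumeration) when n₁+n₂ ≤ 20 with no
ties, otherwise normal approximation with midrank tie correction and
continuity correction.  Tests are two-sided throughout.  BH-FDR is
applied per comparison design across the gene panel (one family of ten
tests per design, matching per-figure reporting granularity) rather than
globally; the family is a parameter.  Significance tiers follow the
figure-caption convention: \* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001,
\# p < 0.0001.  Spearman correlation uses midranks and the t-distribution
approximation; with zero rank variance the coefficient is reported as
undefined (NaN), not zero.

Comparison designs: T vs N and T vs D (unpaired — the normal and donor
sets are smaller than the tumor set), PM vs T restricted to patients
contributing both samples (paired by patient key), stage I+II vs III+IV,
T1–T2 vs T3, G1–G2 vs G3–G4, and one design per metastasis flag
(lymphatic via nodal status, distant via M stage, peritoneal, omental),
ascites, and any-metastasis.

**Binary hypermethylation call.** No consensus cutoff exists for calling
a tumor "hypermethylated"; the call here is PMR above the 95th percentile
of the pooled normal + donor reference distribution for that gene, with
the percentile a parameter.  This call feeds the survival stratification
and the marker panel.

## Sequence analysis

**Smith–Waterman.** Standard local dynamic programming with linear gap
penalty (the simplest scheme; affine adds parameters without changing
the site metrics) and deterministic traceback: ties prefer the diagonal
move, then the vertical, then the horizontal, and the best cell is the
first in row-major order, so re-runs are bit-identical.
*Complementarity mode* reverse-complements the subject before the DP, so
a "match" is a Watson–Crick pair on the original strands; subject
coordinates are mapped back afterwards.  G:U wobble scoring is available
but off by default — the site metrics count strict complementary
identities in DNA space (U→T on input).  Default scores match = +2,
mismatch = −3, gap = −5, chosen so that planted biological-scale sites
dominate the random background (checked by the null simulations in the
test suite: spurious exact complementary runs between 500–1000-nt random
sequences stay below 15 nt).

**Site enumeration.** Iterative best-site extraction: after accepting a
site its footprint is masked (N) on both sequences and the DP repeats
until the score drops below `min_site_score` (default 12) or `max_sites`
is reached.  Accepted sites therefore never overlap.  The two reported
pair metrics are the summed count of complementary nucleotides over all
sites (gaps and mismatches excluded) and that count divided by the
subject (mRNA) length — the full transcript length, not the CDS.

**Seed taxonomy.**  Site types are defined by pairing of miRNA positions
1–8 against the target, written 5′→3′ on the target so the base opposite
position 1 sits at the site's 3′ end: 6mer (positions 2–7), 7mer-A1
(2–7 + target A opposite position 1, recognised as A regardless of the
miRNA base), 7mer-m8 (2–8), 8mer (2–8 + the A), and a bulged variant
"7mer-m8 g-bulged" read as positions 2–8 paired with exactly one
unpaired G bulged on the target side strictly inside the span.  When one
location satisfies several types the strongest under a configurable
priority is reported and weaker contained calls are suppressed.

## ceRNA assembly

Triplets are a relational join over three screened edge lists under the
ceRNA sign pattern (lncRNA–miRNA negative, miRNA–mRNA negative,
lncRNA–mRNA positive).  Default bounds: lnc–miR r_s ≤ −0.3 with p < 0.05,
miR–mRNA r_s ≤ −0.4, lnc–mRNA r_s ≥ +0.3.  Seed-site evidence is
attached when present and *advisory by default* — correlation-only
triplets are hypotheses, and any mRNA positively coupled to a sponging
lncRNA inherits a negative correlation with the miRNA, so enforcement
(`require_seed_on_lnc` / `require_seed_on_mrna`) is the gate that
separates direct targets from riders.  Output is ordered by the weakest
edge's |r_s|, strongest-supported triplet first.

## Survival and the marker panel

Kaplan–Meier estimation and the log-rank test go through lifelines
(product-limit with simultaneous tied events; censored subjects leave
the risk set just after their time; Greenwood variance attached).  The
Cox fit for cumulative risk of several binary methylation factors is a
partial-likelihood Newton maximisation written in-package with Breslow
handling of ties, converging when the score norm falls below 1e-8, so
the score can be inspected at the optimum; non-convergence and
(quasi-)separation raise instead of returning a bad fit.  The in-package
fit agrees with lifelines' `CoxPHFitter` to 1e-5 on shared problems
(checked in the tests; lifelines is the cross-check, not the
implementation).

The metastasis marker panel predicts a positive when at least k of n
binary hypermethylation calls fire (default k = 4 of the six-gene panel
*GAS5*, *KCNK15-AS1*, *MEG3*, *SEMA3B-AS1*, *ZEB1-AS1*, *ZNF667-AS1*).
Because the only score is a marker count, the ROC is the discrete sweep
of k from n+1 (predict nobody) to 0 (predict everybody) — n+2 operating
points — and AUC is the trapezoid under it.  k is a first-class
parameter and the full sweep is always reported.

## The synthetic cohort generator

The generator is the package's stand-in for the clinical study design:
140 primary tumors (96 with some metastasis), 123 matched normals, 59
peritoneal metastases paired by patient key to primary tumors of the
same patients, 18 cancer-free donor ovaries; clinical covariates drawn
to match the marginal composition of such a cohort (76% serous; stage,
extent, grade and ascites coupled to the metastasis flags so that
stage/grade comparisons inherit signal).

Methylation is beta-distributed on the 0–100 PMR scale (mean m,
concentration c = 8, i.e. Beta(mc, (1−m)c) × 100); the distributional
form is an assumption — cohort methylation data are bounded and skewed,
which the beta captures with two parameters.  Defaults: normal/donor
mean 0.10; tumor shift +0.30 for all ten genes; additional +0.12 for
(gene, metastasis-type) pairs — lymphatic: *HAND2-AS1*; peritoneal:
*KCNK15-AS1*, *MEG3*, *SEMA3B-AS1*; omental: *MEG3*, *SEMA3B-AS1*,
*ZNF667-AS1* — and a −0.20 reversal applied to PM samples for *MEG3*,
*SEMA3B-AS1*, *SSTR5-AS1*, *ZEB1-AS1*, *ZNF667-AS1*.  Expression is
log2-scale: intercept + slope × methylation-fraction + Gaussian noise
(slope −4, noise SD 1), which lands the methylation–expression Spearman
r_s in the −0.4…−0.8 band at the default cohort size.

Survival is exponential with per-patient hazard = baseline ×
∏ HR_g over genes called methylation-positive in the tumor (HR = 2 for
*SEMA3B-AS1*, *SSTR5-AS1*, *ZNF667-AS1*; baseline 8e-4/month), censored
by a uniform administrative mechanism over a 180-month follow-up
(censoring rate 0.3) — the simplest model under which the KM/log-rank/
Cox stages can recover the planted effect.  The generative
methylation-positive threshold (PMR > 30) sits near the reference-tissue
95th percentile so the generative call and the analysis call coincide.
The baseline yields on the order of 35–45 deaths per 140 patients.

Raw Ct tables are back-computed from the planted levels (triplicates
with symmetric ±0.1-cycle offsets; qMSP anchored to a `FULLY_METH`
control two cycles above ACTB; expression against a fixed reference Ct),
so quantification round-trips to the planted values to ~1e-15 relative
error — an end-to-end consistency check between the generator and the
quantification module.

Planted expression networks use a Gaussian copula: a partner is built
from its source with the Pearson coefficient ρ = 2 sin(π r_s / 6) that
yields the requested Spearman r_s under bivariate normality; edges may
chain, which induces the transitive correlations a real regulatory
cascade produces (and is how the ceRNA triplet's positive lnc–mRNA edge
arises).  Sequence fixtures are uniform-random DNA with planted
reverse-complement segments (exactly complementary by construction) and
seed sites built to their declared type.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: probe- or read-level measurement (no
bisulfite reads, no microarray CEL processing), realistic genome
coordinates or sequence composition (uniform base frequencies, no CpG
islands), between-gene correlation of methylation within a patient,
batch and plate effects, non-proportional hazards, and informative
censoring.  Recovery of planted effects demonstrates that the analysis
chain detects what it claims to detect at the stated effect sizes and
sample sizes; it does not validate the biological effect sizes
themselves.

## Numerical choices and problem sizes

Exact Mann–Whitney switches to the corrected normal approximation above
pooled n = 20 or with ties; BH q-values are step-up with monotone
enforcement and clipping at 1.  The Cox Newton iteration caps at 50
steps and declares separation when |β| exceeds 15.  Alignment oracle
checks run full enumeration up to length 12 and an independent aligner
up to length 30.  Monte-Carlo suites use 100–400 replicates: large
enough that the binomial band around a 5% rate is ±2–3 points, small
enough that the whole test suite completes in a couple of minutes.
Percentages intended for tables are rounded to two significant figures,
round-half-to-even.

## Known limitations

Screening p-values use the same t-approximation as the cohort
statistics; at very small n (miRNA profiling designs) the approximation
is rough and the r_s bound, not p, does the work.  The site-enumeration
"number of complementary nucleotides" metric depends on the scoring
scheme; with the default threshold, random background between kilobase
transcripts does contribute small sites alongside planted ones (the
planted site is always the top-scoring extraction).  The aligner is a
readable O(nm) Python DP, adequate for transcript pairs up to a few
kilobases, not for genome-scale screening.  The panel is evaluated on
the cohort that defines the calls (no held-out validation), matching how
single-cohort operating points are usually reported.
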