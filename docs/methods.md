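# Methods

`finehap` re-implements, as a tested library, the statistical pipeline used
to fine-map a case-control disease locus and probe the pleiotropy of its
causal variants: stepwise conditional logistic association, EM haplotype
models with omnibus tests, rare-variant collapsing tests under permutation
nulls, an EMR-style phenome scan with fixed-effect meta-analysis, and
analytic power / liability-variance calculations.  Because the cohorts the
original analyses used are access-restricted, the package ships a
synthetic-cohort generator that reproduces the locus's statistical
structure, and every downstream claim is exercised against it.

## The locus model and disease simulation

A locus is a pool of haplotypes over a small set of biallelic variants.
In *distinct-background* mode each causal variant's minor allele sits on
exactly one haplotype, so the implied per-variant MAF equals that
haplotype's frequency and the three signals are statistically independent
— the structure the fine-mapped locus exhibits.  Defaults plant three
protective missense variants at MAFs 0.034 / 0.008 / 0.080 with per-allele
odds ratios 0.66 / 0.53 / 0.86 (`preset="results"`); a second preset
(`"power"`: 0.034 / 0.007 / 0.087) carries the frequencies used by the
power calculations, which were quoted slightly differently — both are
exposed rather than reconciled.

A common benign tag variant (MAF 0.23, the V362F analogue) is placed on a
configurable fraction `tag_ld` of every causal-carrier haplotype (default
1.0 — the causal alleles arose on the tag background) plus a tag-only
haplotype absorbing the remaining tag frequency.  This makes the tag's
marginal association a pure LD artefact while the tag-only haplotype has
OR 1 by construction.  Null common variants (default four, MAFs 0.10-0.40)
enter in linkage equilibrium.

Disease status is logistic in the haplotype-borne allele dosages — not a
liability-threshold model — so the planted odds ratios are the direct
estimands of the downstream logistic fits.  The baseline log-odds default
is logit(0.2); under case-control ascertainment only the intercept is
affected.  Exact case/control counts are obtained by rejection sampling in
batches (capped at 200 batches; a diplotype reaching disease probability
0.999 is rejected as pathological).  Covariates (age, sex, PCs) are drawn
independent of genotype and status: they exercise the adjustment code
without confounding.

The rare background appends MAF < 0.5% missense/nonsense variants with
predictor labels; a configurable fraction are singletons (default 5/7,
matching the reported kinase-domain cluster of 7 variants with 5
singletons).  Enrichment mode places all appended variants in a stated
CDS interval with damaging labels and draws carriers with odds `weight`
(default 6) toward one arm — the device used to regenerate the
damaging-in-controls domain cluster.

What the generator deliberately does not emulate: population structure
(PCs are pure noise), genotyping error and cluster-separation artefacts,
LD decay beyond the single locus, age/sex effects on disease, and coded
diagnoses with realistic temporal structure.  Tests passing here therefore
validate the statistical machinery, not robustness to those features of
real data.

## Association and the conditional scan

`fit_logistic` is a Newton/IRLS maximum-likelihood fit (gradient
sup-norm < 1e-8, at most 100 iterations, steps damped to length 10 on the
separation path).  Missing dosages are mean-imputed within the fitted
stratum, preserving row alignment with covariates.  Separation — a fitted
probability within 1e-8 of 0/1 with |linear predictor| > 15 — flags the
result and substitutes the likelihood-ratio p for the meaningless Wald p.
The implementation is cross-checked in the tests against the 2x2
closed form and against an independent maximum-likelihood fit from
statsmodels.

The conditional scan is forward selection: round k refits every remaining
variant with the k-1 selected dosages appended to the covariates and
selects the minimum-p candidate while p < `stop_p` (default 0.01, the
stopping rule of the original scan).  No MAF floor is applied.  Ties break
on genomic position then variant id; candidates whose dosage is (numerically)
in the span of the selected design are skipped with a note.  Fixed-effect
meta-analysis is inverse-variance weighting with allele-label harmonisation
enforced.

## Haplotype model

Phasing is an EM over all 2^k haplotypes (k <= 10), grouped by distinct
genotype pattern; missing sites are marginalised in the diplotype
enumeration.  Initialisation is the linkage-equilibrium product of allele
frequencies, making the fit deterministic; the log-likelihood is asserted
non-decreasing and convergence is Δlog-lik < 1e-8.  Haplotypes below the
pooling floor (default 0.1% frequency) are dropped and the remaining
frequencies and per-subject posterior dosages renormalised.

The regression is haplotype-trend regression on posterior-mean dosages
(propagating phase uncertainty rather than committing to a best guess),
with one column per non-reference haplotype; the reference is the most
frequent haplotype (ties: lexicographically smallest allele vector).  The
omnibus test is the LRT against the covariate-only model on
(#haplotypes - 1) df; a score-type omnibus would be asymptotically
equivalent, and the LRT was chosen for its exact equivalence to the
single-variant LRT at k = 1 (tested).

## Rare-variant tests

The qualifying-variant mask defaults to missense/nonsense with combined
case+control MAF < 0.5%.  The two-predictor damaging rule: any "benign"
call from either predictor makes the variant benign; otherwise it is
potentially damaging.

One-sided statistics are standardized trend-type scores of a collapsed
count: unweighted (burden), weighted by 1/sqrt(n q(1-q)) with the
control-based +1 pseudo-count frequency estimate (WT), and maximised over
all observed MAF thresholds (VT).  Each runs in both orientations
("case" and "control" arms).  Their p-values are purely empirical:
case/control labels are permuted (covariates stay attached to subjects)
and p = (r+1)/(B+1), bounded below by 1/(B+1).  Gene and domain tests
default to B = 10,000; the sliding-window scan defaults to B = 1,000 with
an override to 10,000, since the two figures were both quoted for
window tests.

SKAT is the weighted quadratic form of null-model score residuals with
Beta(MAF; 1, 25)-density weights; its analytic p-value evaluates the
survival of the eigenvalue mixture of chi-squares by a Lugannani-Rice
saddlepoint approximation, with four-moment (Liu-type) matching as the
fallback in the immediate neighbourhood of the mixture mean where the
saddlepoint degenerates.  Moment matching alone proved inadequate: with
the skewed spectra rare-variant kernels produce it can return p = 1.0
where the true survival is ~0.93.  The saddlepoint is an analytic
approximation, not an exact characteristic-function inversion; exact
(Davies-type) inversion remains out of scope.  SKAT-O takes the minimum
p over the canonical 8-point rho grid of burden/SKAT mixtures and
computes the combined p by the standard one-dimensional integration over
the shared burden component (with the cross-term variance adjustment),
clipped to its Bonferroni-valid range [T, 8T].  Both are also available
under permutation, which is the default route for set-level inference:
at singleton-level minor-allele counts the permutation null visibly
departs from any asymptotic mixture, so the analytic p is trusted only
in moderately-powered regimes (the analytic-vs-permutation agreement is
tested at n = 2,000 with per-variant MAF 0.005-0.03).

Window coordinates are 1-based on the strand-resolved concatenated CDS;
a window of width w centred on position x contains variants within
± w/2 inclusive, so a variant participates in w+1 window positions.
Identical variant subsets across positions are tested once and shared.

## Phenome scan

A subject is a case for a phenotype with >= 2 mapped events of its code
group, a control with 0 events, and — by default — excluded with exactly
1 event (the original rule defines only the case side; exclusion is the
standard guard against misclassification, and "treat-as-control" is
available).  Phenotypes must exceed 1% case prevalence in every cohort and
fall inside the code inclusion range (integer parts 1-779).  Per-cohort
logistic fits use the package's own engine; cohorts may carry extra
adjustments (e.g. disease status for a cohort ascertained on it); the
meta-analysis pools whichever cohorts are testable.  Significance uses the
hard threshold alpha = 1e-4 with no FDR layer, matching the original
design.  The "consistency" flag on a row requires agreeing effect signs
and a meta p below each cohort p — a pure function of the row.

Quantitative traits: LDL uses each subject's first measurement, excludes
subjects with a statin prescription strictly before it, and adjusts for
age at measurement, measurement year, and covariates (beta in mg/dL per
allele).  WBC uses the per-subject mean of all measurements with the
measurement count as a covariate (dropped with a warning when constant).
Both are ordinary least-squares fits (statsmodels).

## Power and variance explained

The analytic power model is the allele-count two-proportion normal
approximation: control risk-allele frequency q0, case frequency
q1 = q0·OR/(1-q0+q0·OR), allele counts 2·n_case and 2·n_control, pooled
null standard error, two-sided alpha.  It is validated against the
empirical rejection rate of the package's own logistic test.  Protective
alleles can be entered from either side (RAF or 1-RAF).  Minimum
detectable OR scans an ascending grid (default 1.1-3.0 by 0.1) for the
first OR with power >= 0.80; required cases inverts power by integer
bisection with a fixed control:case ratio.

Variance explained converts each (MAF p, OR) pair to a liability-scale
effect beta = ln(OR)·K(1-K)/phi(Phi^-1(1-K)) under the liability-threshold
model at prevalence K (preset 0.005) and sums 2p(1-p)·beta^2 across
variants, reported in percent.  The conversion is itself validated by
simulating the liability-threshold model forward and recovering the input
odds ratio.

## Problem sizes used by the test suite

The acceptance-level simulations run at the motivating cohort scales: 50 seeds of 7,222/15,870 for scan and haplotype
recovery; 200 replicates of 3,053/13,687 for the tag-deflation property;
500 replicates of 1,000/1,000 with 40 rare variants at B = 1,000 for
type-I calibration (sized so the discrete permutation distributions are
near-continuous — tie-counting empirical p-values are conservative on
sparse designs, which would sit below the nominal level by construction); 100 sets at n = 2,000 with B = 10,000 for the SKAT
analytic-vs-permutation cross-check; phenome-scan null calibration on six
5,000-subject EMR draws.  These sizes were chosen so each property is
measured with useful precision while the whole suite stays desk-scale.

## Known limitations

* The per-seed success rate of "exactly the three planted variants" in
  the conditional scan is ~88-89% under the planted effect sizes: the
  third variant's conditional power at the 0.01 stopping threshold is
  ~93% at this cohort size, and four null common variants contribute a
  few percent of spurious selections.  This is a property of the study
  design itself, not of the estimator.
* Analytic SKAT p-values are asymptotic; for singleton-heavy sets use the
  permutation p (the default for set-level inference).
* The EM phaser enumerates 2^k haplotypes and is meant for small variant
  sets (k <= 10), not genome-scale phasing.
* Pi-hat uses the idealised method-of-moments IBS decomposition without
  small-sample allele-frequency corrections; it is intended for flagging
  duplicates and close relatives, not precise kinship estimation.
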