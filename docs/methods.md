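# Methods

`evsmall` implements, as a tested offline pipeline, an analysis chain for
profiling plasma extracellular-vesicle (EV) small non-coding RNAs across a
healthy / iRBD (idiopathic REM-sleep behavior disorder) / Parkinson's disease
(PD) cohort: read-level sncRNA quantification, moderated differential
expression, biomarker-panel classification, trajectory clustering over the
disease hierarchy, and phenoconversion survival analysis. A synthetic cohort
generator supplies ground truth for every stage.

## sncRNA quantification

**Trimming and filtering.** The 3' adapter is located by exact prefix match:
the longest adapter prefix occurring at read position ≥ 17 wins, ties broken
toward the earliest position, with a minimum 3-nt overlap so that 1–2 nt of
chance suffix agreement cannot clip adapterless reads. Reads without an
adapter occurrence are discarded (configurable for pre-trimmed input), as are
reads shorter than 17 nt after trimming. Identical sequences are collapsed to
(sequence, multiplicity) records; annotation operates on collapsed reads.

**miRNA counting rule.** A read counts toward a mature miRNA iff (a) its
first nucleotide aligns exactly to the mature 5' start site on the precursor
and it matches the precursor with no internal mismatches, and (b) its 3' end
lies within ±3 nt of the annotated mature 3' end. 3' extensions must copy the
precursor downstream sequence (templated isomiRs only); non-templated tails
are rejected. Because the 3' end is a single offset δ ∈ [−3, +3], a deletion
and an addition cannot co-occur. Matching is implemented as a dictionary
probe on the 12-nt anchored prefix plus one string comparison; a brute-force
positional enumeration over all precursor substrings serves as the test
oracle.

**Annotation priority.** Non-miRNA classes match by exact substring
containment (mismatch tolerance configurable, default 0). Reads with
candidates in several classes are assigned to the highest-priority class:
miRNA > ysRNA > tsRNA > rsRNA > snRNA > snoRNA > lncRNA > mRNA; unmatched
reads are "others". Within the winning class, multi-mapped reads are split
1/k across the k matched features, which preserves the read-conservation
identity (annotated totals + others = total collapsed multiplicity) that the
test suite relies on.

**Normalization.** Size factors are median-of-ratios: s_j = median_i
x_ij / g_i with g_i the geometric mean of feature i over samples, restricted
to features positive in every sample, then rescaled to geometric mean 1.
Size factors are defined only up to a common constant; fixing that gauge
makes the estimator exactly equivariant on factor ratios and an exact fixed
point under renormalization, and leaves the small worked examples unchanged.
The expressed-miRNA filter keeps features with mean normalized count
strictly > 1 detected in strictly > 25% of samples.

## Differential expression

Expression is y = log2(normalized + 1); the offset keeps zeros finite and the
transform monotone. Per feature, ordinary least squares is fit on an
intercept, a contrast indicator, and optional covariate columns (sex for
PD-involving contrasts, batch whenever present with more than one level).
The contrast coefficient is the log2 fold change; residual variances s²_g
with shared residual df d are shrunk toward a scaled-inverse-chi-square prior
fitted by method of moments on z = log s²_g using the digamma/trigamma
identities (prior df d0 via a trigamma inverse solved by Newton iteration;
prior variance s0² from the first moment). The moderated t is
coef / (ŝ_g · SE_unscaled) with ŝ²_g = (d0 s0² + d s²_g)/(d0 + d) and
d0 + d degrees of freedom. When the observed variances are *less* dispersed
than pure chi-square noise the prior df is infinite; in that branch the prior
variance is the pooled mean of the observed variances, which makes moderation
an exact no-op when all variances are equal (the natural d0 → ∞ limit).

Calls use the raw-p rule p < 0.05 together with fold change strictly > 1.4
(both boundaries strict); BH-adjusted p values are reported alongside, and a
configuration switch allows calling on adjusted p instead. All tests are
two-sided.

## Biomarker classifier

Samples are split 60/40 per class (seed-deterministic, at least one sample of
each class on each side). Feature selection is all-relevant (Boruta-style):
each run appends an independently shuffled shadow copy of every feature, fits
a 500-tree random forest, and scores a hit for features whose importance
exceeds the maximum shadow importance; two-sided binomial tests on hit counts
(Bonferroni-corrected over the undecided features) move features to
confirmed/rejected, and leftover tentatives are resolved by comparing median
importance with the median per-run maximum shadow importance. The importance
oracle is the forest's impurity (Gini) importance: with shadow copies
restoring exchangeability under irrelevance, it supports the same hit
statistic as permutation importance at a small fraction of the cost.

One calibration caveat is inherent to all-relevant selection and documented
here because the tests are designed around it: on a *fixed* dataset, a noise
feature whose accidental correlation with the labels is large for that
dataset (the maximum over k features is ≈ 2.3 standard errors regardless of
n) is genuinely informative *for that dataset* and will be confirmed
consistently. The null-calibration test therefore residualizes noise features
against the labels, which isolates the machinery's intrinsic false-confirm
behavior (zero confirmations across seeded replicates).

Classification is a maximum-margin SVM (linear kernel by default — n ≪ p
favors linear margins; RBF available), with features z-scored using training
statistics only and the cost parameter chosen from {0.01, 0.1, 1, 10, 100} by
stratified 5-fold cross-validation accuracy; the final model is refit on the
full training set and continuous decision scores are kept for ROC analysis.
AUC is the Mann–Whitney probability with ties counted ½; confidence intervals
are percentile bootstrap with class-stratified resampling (100 iterations by
default), and AUC comparisons use the bootstrap distribution of the paired
difference. When selection confirms no feature (null-like cohorts) the
classifier falls back to all input features and flags the result, so
chance-level behavior remains measurable.

## Trajectory clustering

Features passing a Kruskal–Wallis screen (tie-corrected H, chi-square p with
2 df, strict p < 0.05 across the three groups) are summarized as 3-point
group-mean profiles over (healthy, iRBD, PD), standardized to mean 0 and
population sd 1 (constant profiles are excluded). Fuzzy c-means with
Euclidean distance, k = 8 and fuzzifier m = 2 (both configurable) alternates
membership and center updates from random initializations, keeps the best of
10 restarts by final objective, and converges when the maximum center shift
falls below 1e-8. A point coincident with a center takes membership 1 there
(the limit convention). Clusters whose centers are strictly ordered along
the hierarchy are labeled increasing/decreasing; features are hardened to
their maximum-membership cluster. Per-sample clustering, automatic selection
of k, and data-driven fuzzifier estimation are out of scope.

## Conversion survival

Each miRNA is screened with a univariate Cox proportional-hazards model
adjusted for age and sex (Efron tie handling via lifelines), the feature
standardized to unit SD so hazard ratios are per SD of expression; monotone
likelihoods fall back to a small ridge penalty and are flagged unreliable.
Candidates (Wald p strictly < 0.05, ascending) are dichotomized at the
maximally selected log-rank statistic: candidate cutpoints are midpoints
between consecutive distinct values whose low-group proportion lies in
[0.1, 0.9], and the cutpoint maximizing |standardized log-rank z| wins.
The log-rank statistic and the Kaplan–Meier product-limit estimator are
implemented in-package (the cutpoint search needs the standardized form) and
cross-checked against lifelines. The p value reported at the selected
cutpoint is not adjusted for the maximal selection and is anti-conservative;
the test suite asserts this known inflation on null cohorts rather than
pretending nominal calibration. Competing risks are pooled into a single
conversion endpoint.

## Synthetic cohort generator

The generator emulates the study conditions: group sizes 60/56/53
(healthy/iRBD/PD), a female-skewed PD group (25 M / 28 F) with an 18-of-53
PD-iRBD overlap flag, ~3.3-year follow-up with roughly 8 converters among 56
iRBD patients, miRNA reads of 17–24 nt with templated 3' isomiR variation in
±3 nt, and class-specific read lengths (ysRNA 25–33, tsRNA 30–33, rsRNA
17–20 nt); the per-class read-fraction composition of a real library is not
constrained by these summaries and is a free parameter here. References are
random sequences over the DNA alphabet (U→T on
ingestion): precursors of 60–90 nt contain their 18–23 nt mature sequence
with ≥ 3 nt downstream so every templated +3 extension exists.

Counts are negative-binomial (variance μ + αμ², default α = 0.15, default
depth 2×10⁴) around baseline × library size × group effect, with mild
(1.15-fold) sex and batch effects on random 10% feature subsets so covariate
correction is testable but not dominant. Planted differential features
default to 2-fold effects (validated ≥ the 1.4-fold call floor) and cycle
through up-monotone (1, √f, f), down-monotone, and non-monotone shapes
(peak/dip/step patterns), giving fuzzy clustering distinguishable shapes; the
per-contrast ground truth lists features whose planted ratio for that
contrast exceeds 1.4. Conversion times are exponential with hazard
baseline × exp(β·z + 0.02(age−64) + 0.1·male), administratively censored at
the horizon; β = log hazard ratio per SD.

Two generator details exist to make exact round-trips possible: the isomiR
shift δ is constrained so trimmed reads never drop below 17 nt, and
cross-class ambiguous sequences (a mature miRNA embedded in a ysRNA
reference, for priority testing) are created only when decoys are explicitly
requested. The generator does not model sequencing errors, quality-score
realism, or UMIs — so passing round-trip tests demonstrate correctness of
the counting logic, not robustness to base-calling noise.

## Numerical choices and problem sizes

Deterministic seeding throughout (NumPy `default_rng`); identical seeds give
byte-identical outputs, which the pipeline manifest verifies by SHA-256
checksums of every stage output (wall-clock timings are recorded but excluded
from determinism comparisons). Fuzzy c-means tie-break: best-of-restarts by
objective; coincident point/center takes membership 1. Degenerate inputs:
all-tied features get Kruskal–Wallis p = 1; constant profiles are excluded
from clustering with a logged reason; all-censored survival tables and
zero-variance features are rejected with errors.

Tests and the acceptance script run on deliberately desk-scale problems —
cohorts of up to 300 samples, 150–2000 features, 10–40 replicates for
calibration checks, 100 randomized bundles for the counting-rule oracle —
chosen so the full suite completes in a few minutes while leaving the
statistical assertions (recovery rates, calibration bands) comfortably
powered. The null-AUC band check uses a 150/150 cohort because the sampling
sd of a chance-level AUC at validation n ≈ 120 (~0.074) must sit well inside
the ±0.15 band for the ≥90%-of-replicates property to be a statement about
the pipeline rather than about small-sample noise.

## Known limitations

- The annotation engine is exact (default 0 mismatches); mapped-read
  fractions will therefore differ from pipelines built on mismatch-tolerant
  genome aligners.
- Boruta's familywise false-confirm rate on fixed datasets is not controlled
  at alpha (see above); only the machinery-level calibration is.
- The post-cutpoint log-rank p is anti-conservative by construction.
- Several conventions are genuinely open choices in this kind of analysis —
  calling on raw vs BH-adjusted p, fold-averaged vs refit CV metrics, and
  which class counts as "positive" for sensitivity; all are configuration
  switches here, with the defaults stated above.
- Headline numbers from any real cohort (AUCs, specific DE counts, a specific
  conversion-miRNA panel) depend on the underlying patient data; synthetic
  cohorts reproduce the procedures and their statistical behavior, not a
  particular dataset's values.
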