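# Methods

`morphnet` implements a morphological brain-network analysis pipeline for a
patient/control cohort — the kind of study that asks how regional
gray-matter volume (GMV) differs in a disease group, how inter-regional
covariance is reorganized, in what order regions are drawn into the
atrophic process, how dynamic functional states change, and whether
baseline features predict treatment response. Because such studies run on
private clinical MRI, every stage here is validated against *synthetic
cohorts with planted ground truth*: the generator writes the effect in, the
stage must read it back out.

## Synthetic cohorts (`morphnet.synthetic`)

`GroundTruth` holds every generative parameter; all generators are
deterministic functions of its seed.

**Subjects.** Ages ~ N(63.4, 6.7²) y, sex ~ Bernoulli(½) in both groups
(balanced in expectation), TIV ~ N(1.45, 0.12²)·10⁶ mm³. Patient disease
duration is lognormal with arithmetic mean 8.34 y and sd 5.34 y — a
right-skewed shape typical of duration data; the lognormal is a modeling
choice, only the two moments are constrained. Clinical scores (MDS-UPDRS
III on/off, tremor and postural sub-scores, H&Y, MMSE, MoCA, HAM-A/D, VHI,
LED) are drawn with cohort-typical means and dispersions; the tremor/PIGD
sub-scores are drawn so the simulated cohort is tremor-dominant.

**GMV matrix.** Per parcel: positive baseline + linear covariate effects
(age −0.02/y, sex 0.3, TIV 0.5 per sd — all on the unit-noise scale,
configurable) + Gaussian noise (sd 1 by default, per-parcel overridable).
Three effect families are then superimposed:

* *atrophy*: a group mean shift in sd units on named parcels;
* *covariance slopes*: within group g, target += β·z(seed), creating
  group-dependent structural covariance;
* *causal edges*: with patients sorted by (duration, id), target at
  duration rank r gains β·z(source at rank r−1). Edges apply sequentially,
  so chains propagate. With zero innovation noise on the target, lag-1
  regression of the raw target on the standardized lagged source recovers β
  *exactly* — the closed-form oracle used in tests.

**Component time series.** A hidden Markov chain over k=5 connectivity
states (uniform initial state) emits zero-mean Gaussians with
state-specific covariances. Default states carry three signature ±0.8
correlations each on disjoint component pairs (state 5 is weakly coupled);
the default self-transition probability is 0.99 (mean dwell ≈ 100 samples).
The slow-switching default is deliberate: windowed correlation estimates
use 22-sample windows, and a process that switches every ~10–20 samples
leaves most windows straddling a transition, making state recovery
ill-posed for *any* window-based method. Real resting-state dynamics switch
faster; what the recovery tests certify is the clustering machinery, not
temporal resolution beyond the window length.

**DBS outcomes.** Improvement% = 35 + 15·(Σ effectᵢ·z(featureᵢ) +
confound·z(total VTA) + ε), ε ~ N(0,1), clipped to [−50, 100]; VTA
subregion volumes are lognormal (mean 60 mm³). Efficacy labels follow the
<30% rule. Baselines ~ N(45, 16²); post = baseline·(1 − improvement/100).

**What the generator does not emulate:** MRI physics, registration error,
spatial autocorrelation between parcels, non-Gaussian score distributions,
site effects, missing data. Passing tests demonstrate correct *estimation
and inference given the model*, not robustness to those real-data features.

## Group morphometry (`morphnet.morphostats`)

Mass-univariate OLS per parcel/voxel: y = β₀ + β_g·group + βᵀ·(age, sex,
TIV) + ε; t = β_g/SE with df = n − rank(X), two-sided p. Patients are coded
1, so negative β_g means lower volume in patients. Smoothing is Gaussian
with σ = FWHM/(2√(2 ln 2)) and nearest-replicate boundaries.

Voxel-level inference uses permutation cluster-FWE instead of random-field
theory: clusters are 26-connected components (configurable 6/18/26) of the
|t| map above the voxel-forming threshold (p < 0.001 two-sided by default);
the null is the maximum cluster size over Freedman–Lane permutations
(residuals of the covariates-only model are permuted and the reduced fit
added back), and FWE p = (1 + #{null ≥ obs})/(1 + n_perm), so 1/(n_perm+1)
is the floor. Under exchangeability this is exact up to the discreteness of
the size statistic: on *unsmoothed* white noise nearly all suprathreshold
clusters are single voxels, ties dominate, and the test is markedly
conservative — calibration should always be assessed on smoothed maps,
which is also the only regime morphometry uses.

Other primitives: Benjamini–Hochberg FDR (statsmodels), partial Pearson
correlation (residualize both variables on covariates, df = n − #cov − 2),
and Mann–Whitney U with full enumeration of group assignments when both
samples have ≤ 8 observations (valid under ties) and the tie-corrected
normal approximation otherwise.

## Structural covariance (`morphnet.scn`)

Within-group: target ~ seed + covariates; the seed slope and partial r
(sign-matched, r = t/√(t²+df)) describe morphological synchronization. The
group comparison fits the pooled model target ~ seed + group + seed×group +
covariates per target; the interaction Wald z (negative ⇒ patient
covariance lower) is BH-corrected across targets. The pooled-model
interaction was chosen over two separate fits because it yields a single
well-defined test under a common error variance; the two approaches agree
within ~10% on planted data (tested).

## Pseudotime causality (`morphnet.cascn`)

Patients sorted by (duration, id) — ties broken by id for reproducibility —
form a pseudotime series; each parcel is residualized on age/sex/TIV and
standardized (zero-variance parcels are dropped with a warning). The
bivariate signed-path-coefficient Granger model is

    y_t = b₀ + b₁·y_{t−1} + β·x_{t−1} + e_t,

estimated by OLS; β is the signed path coefficient, z = β/SE (Wald),
two-sided normal p. Lag 1 is the default and the only order sensible for
~60 pseudotime points; the autoregressive term can be switched off
(`include_ar=False`) for sensitivity. Standardization upstream makes β
comparable across pairs. Seed-to-map and ROI-network analyses retain
*positive* coefficients only (the progression-forecasting convention),
apply BH-FDR across the retained tests (per seed, or jointly across ROI
pairs), binarize at q < 0.05 and report out-/in-degrees. Interpretation
caveat: the subject axis is a cross-sectional ordering, not time; permuting
it destroys the planted edges (tested), which is precisely why the ordering
carries the causal claim.

## Dynamic connectivity (`morphnet.dfnc`)

Sliding-window correlation per component pair with window 22 samples, step
1, and a taper built by convolving the rectangle with a Gaussian of sd 3
samples (weights normalized to sum 1; these defaults are the common
toolbox convention and fully configurable), Fisher z-transformed. Windows
pooled over subjects are clustered by k-means with cityblock distance
(median centroid update; euclidean optional), best of n_init random
restarts, k = 5 by default; an inertia-over-k helper exists but is never
applied automatically. Labels are canonicalized by descending occupancy.
Dwell statistics per subject/state: mean length of maximal runs (windows),
occupancy fraction (sums to 1 exactly), visit counts; states never entered
have undefined dwell and are excluded from group tests. Group comparison:
Mann–Whitney per state with BH across states. Dwell is expressed in
windows; seconds = windows × TR × step is left to the caller.

## Outcome prediction (`morphnet.prediction`)

Improvement rates are first residualized on all VTA subregion volumes
(OLS, mean-preserving; collinear columns dropped with a warning), removing
the stimulation-geometry confound before labels are formed. Feature
selection: bootstrapped L1 logistic regression repeated n times; the
penalty is chosen per repeat by 3-fold cross-validated binomial deviance
with the one-standard-error rule (the glmnet convention) — accuracy-based
selection is too noisy to shrink on null data and lets sample-specific
noise features reach high selection frequencies. Features are ranked by
selection frequency; the top ceil(0.30·p) are retained (ties broken by
name). Evaluation: per iteration a stratified 3:1 split, standardization
fitted on the training portion, linear-kernel SVM, AUC from decision values
on the held-out quarter; the report carries all AUCs, their median and the
2.5/97.5 percentiles. Selection can run per split (leakage-free), pooled
over all data (a deliberately leaky variant kept for demonstrating the
inflation it causes), or be skipped. `permute_labels=True` gives the
randomization null: labels are shuffled each iteration, centering the AUC
at chance independent of accidental feature–label correlation in the fixed
sample — a fixed 60-subject null table can sit anywhere around chance by
dataset luck, which is a property of small-sample evaluation, not of the
classifier.

## Numerical choices

* OLS everywhere via explicit normal equations with `inv(XᵀX)`; designs are
  small and well-conditioned by construction, and tests pin equality to
  independent solves at 1e-10.
* Zero-variance guards are relative (1e-12 of the data scale), not exact
  zero, so float residue cannot mask a constant column.
* Fisher z clips |r| at 1 − 1e-7; exact ±1 correlations map to large finite
  z rather than infinity.
* Perfect model fits (zero residual variance in the Granger regression)
  report z = ±inf, p = 0 rather than NaN.
* All RNG flows through `numpy.random.SeedSequence` children of a single
  seed; identical seeds give byte-identical outputs.

## Problem sizes in tests

Recovery rates use 200 seeds; error calibration uses 500 replicates of 200
permutations on a 16³ grid with n = 20; state recovery uses 20 seeds × 100
subjects × 160 samples; prediction ensembles use 100–200 iterations (the
library default is 1000). These sizes were chosen so the full suite
completes in a few minutes on one CPU while keeping Monte-Carlo error well
inside the asserted margins.

## Known limitations

* Parcel-level only for covariance/causality (voxel-level seed maps are out
  of scope); voxel operations exist for group morphometry.
* Bivariate (not conditional) Granger causality: an A→B→C chain can induce
  an apparent A→C edge; degree summaries, not individual edges, are the
  robust readout.
* The permutation FWE test assumes exchangeability of covariate-adjusted
  residuals across subjects.
* k-means state counts are fixed by the analyst; the elbow helper is
  descriptive only.
* Small-cohort AUC estimates carry wide percentile bands; the median over
  many splits is the only summary the package endorses.
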