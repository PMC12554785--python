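# morphnet

Morphological brain-network analysis for patient/control neuroimaging
cohorts: group morphometry with permutation cluster inference, seed-based
structural covariance networks, duration-ordered causal structural
covariance (signed-path-coefficient Granger causality), sliding-window
dynamic connectivity states with dwell-time statistics, and prediction of
deep-brain-stimulation (DBS) outcomes — together with a synthetic-cohort
generator that plants every structure the analyses assume, so the whole
pipeline is verifiable by parameter recovery without patient data.

It is written for neuroimaging methodologists who want the statistical
machinery of a volumetric case–control study (e.g. tremor-dominant
Parkinson's disease vs controls) as tested, importable Python rather than
a GUI toolbox chain.

## Core methods

**Group morphometry.** Per parcel or voxel, OLS with covariates:
y = β₀ + β_g·group + βᵀ(age, sex, TIV) + ε, t = β_g/SE. Voxel maps are
thresholded at p < 0.001 and clusters tested by permutation FWE
(Freedman–Lane residual permutation, max-cluster-size null, p < 0.05).

**Structural covariance (SCN).** Across subjects, target ~ seed +
covariates within group; the group contrast is the pooled interaction model
target ~ seed + group + seed×group + covariates, whose Wald z (negative ⇒
lower covariance in patients) is BH-FDR corrected across targets.

**Causal SCN.** Patients sorted by disease duration form a pseudotime
series; after residualizing age/sex/TIV and standardizing, each directed
pair is scored by the bivariate Granger model
y_t = b₀ + b₁y_{t−1} + β x_{t−1} + e with β the signed path coefficient.
Positive β are retained, FDR-thresholded at q < 0.05, and each region's
out-/in-degree summarizes whether it drives or follows the atrophic
progression.

**Dynamic connectivity (dFNC).** Tapered 22-sample sliding-window
correlations among component time series, pooled k-means (cityblock, k = 5)
into connectivity states; per-subject mean dwell time per state compared
between groups by Mann–Whitney tests under FDR.

**Outcome prediction.** Improvement rates residualized on stimulation
volumes (VTA) per subthalamic subregion, dichotomized at 30% improvement;
features selected by 1000× bootstrapped L1 logistic regression (deviance +
one-SE penalty rule, top 30% by selection frequency); performance is the
median AUC of a linear SVM over 1000 stratified 3:1 train/test splits with
a 2.5–97.5 percentile band.

## Worked example

`examples/04_causal_network.py` generates 61 patients whose gray-matter
volumes carry a planted causal chain PAL.L → PCUN.L → ITG.L (path
coefficient 0.6 at each link) and asks the causal-network stage to recover
it:

```
$ python examples/04_causal_network.py
pseudotime series: 61 patients ordered by duration, 12 parcels residualized for ['age', 'sex', 'tiv']

seed-to-map influence of PAL.L (positive coefficients, BH-FDR):
  PAL.L -> PAL.R: beta 0.055, z 0.42, q 0.865
  PAL.L -> PCUN.L: beta 0.562, z 5.22, q 0.000 *
  PAL.L -> FFG.L: beta 0.160, z 1.20, q 0.687
  ...

ROI network degrees (directed edges at q<0.05):
        out  in
PAL.L     1   0
PCUN.L    1   1
ITG.L     0   1
highest out-degree = earliest driver of the planted progression chain
```

The seed-to-map coefficient 0.562 recovers the planted 0.6 within sampling
error, and the degree table reads the chain's direction: the pallidum only
sends (out 1, in 0), the temporal target only receives (out 0, in 1).
`examples/06_predict_dbs_outcome.py` shows the prediction stage on a
planted three-feature signal: after VTA residualization the
improvement–VTA correlation drops from 0.19 to ~0, the repeated LASSO
retains all three signal features, and the SVM ensemble reports a median
AUC of 0.955 [0.884, 0.996]. The other examples cover simulation, group
morphometry, covariance interaction, dynamic states and the full pipeline
driver (`run_pipeline`, also exposed as the `morphnet` command line).

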