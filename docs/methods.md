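# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the limitations of `rehonorm`.

## ReHo as Kendall's W

Regional homogeneity scores the temporal synchrony of a voxel with its
spatial neighborhood. For K time series over n time points, ranks are
computed within each series (midranks for ties), R_i is the rank sum
across series at time point i, and

    W = (Σ_i R_i² − n·R̄²) / ((1/12) K² (n³ − n)) ∈ [0, 1].

Choices: no tie-correction factor (matching the classic ReHo convention);
a fully constant series contributes flat midranks, and an all-constant
neighborhood yields W = 0 — degenerate voxels must not look synchronized.
The default neighborhood is 27 voxels (center + faces + edges + corners);
7 and 19 are also supported. A voxel needs at least two in-mask neighbors,
otherwise its value is absent (NaN) and logged. The voxel grid is treated
as isotropic and no smoothing or other preprocessing is performed here.
Regional reduction is the arithmetic mean of valid voxels per atlas label;
an empty region yields NaN with a warning.

## ComBat harmonization

Multi-site data carry additive and multiplicative site effects per
site × region. We implement the canonical parametric empirical-Bayes
location/scale model: features are standardized by the covariate fit
(age, sex; optionally diagnosis) and pooled variance; per-site location
γ and scale δ estimates are shrunk toward across-region normal and
inverse-gamma priors by the standard iterative conditional scheme; data
are rescaled with the shrunken estimates and the covariate fit restored.

The EB iteration stops when the maximum relative change of γ*, δ* falls
below 1e-4 (max 100 iterations). That is the convergence criterion the
widely used reference implementations hard-code, and keeping it makes our
output agree with them to machine precision; a stricter tolerance is
available via the `tol` argument. Diagnosis is *not* protected by
default (the pipeline harmonizes HC and patients jointly with age and sex
as preserved covariates); `protect_diagnosis` switches it on.
Harmonizing a single site is refused rather than silently skipped.

## GP normative model

Each region gets an independent GP regression of (harmonized) ReHo on
[age, sex] fitted to healthy controls:

- kernel: C·RBF(length-scales over standardized age and the 0/1 sex code)
  + DotProduct + WhiteKernel. The RBF captures smooth nonlinear age
  trends, the linear term global trends and the sex offset, the white
  term the noise variance σ²_n.
- age is standardized to zero mean/unit variance inside the model, the
  target likewise; predictions are mapped back. Hyperparameters maximize
  the log marginal likelihood with seeded multi-restart (L-BFGS).
- predictions return the posterior mean μ and the *function* variance
  σ²_f with the noise returned separately, so deviations use the full
  predictive variance: Z = (y − μ)/√(σ²_f + σ²_n). Covariates outside
  the training age range are flagged as extrapolations.

Extreme deviations use a strict inequality |Z| > 2.6 (two-sided normal
tail p < 0.005); a value of exactly 2.6 is not extreme.

Model accuracy is assessed by k-fold cross-validation (default 10):
SMSE = test MSE / test-target variance (1 ≈ predicting the mean), and
MSLL = mean Gaussian negative log predictive density minus the same loss
under the trivial model using the training fold's mean and variance
(0 ≈ trivial, negative is better). Held-out HC Z-scores double as the HC
deviation map; patient deviations come from models trained on *all* HC.
On calibrated synthetic HC data the held-out Z-scores are close to
standard normal and the |Z| > 2.6 rate close to its analytic 0.93% — the
test suite checks both.

Regional age trajectories (posterior mean curves on an age grid, per sex)
are standardized and 2-means clustered into increasing/decreasing
patterns; the cluster with positive mean end-minus-start difference is
labeled "increasing". All-identical curves raise an error.

## Deviation statistics

Per-subject indices are mean-based: overall = mean Z over regions,
positive = mean of max(Z, 0), negative = mean of min(Z, 0), giving the
exact identity overall = positive + negative. This scale-free definition
was chosen because the analysis reports signed group differences on all
three indices; counts of extreme regions accompany them. Overlap maps
give per-region percentages of subjects with extreme positive/negative
deviations; prevalence summaries give per-cohort percentages of subjects
(and regions) with at least one extreme.

Group comparisons default to Welch's t (site-driven variance
heterogeneity) with pooled-SD Cohen's d as the effect size; one-way
ANOVA and type-III ANCOVA (sum-to-zero factor coding) report partial η²;
contingency tables report Cramér's V; multiplicity is handled by
Benjamini–Hochberg step-up q-values.

## Subtyping and k selection

Clustering operates on the region-level Z maps (246 features) with
Euclidean k-means (k-means++ initialization, 50 restarts by default,
lowest within-cluster SS wins, fixed seed). Network aggregation (mean Z
over member regions of 8 canonical networks) is used for description,
not for clustering.

The number of clusters comes from a majority vote over eleven validity
indices — silhouette, Calinski–Harabasz, Davies–Bouldin (minimized),
Dunn, gap statistic (Tibshirani's one-SE rule, uniform-box references),
Hartigan (smallest k with H ≤ 10, else largest drop), Krzanowski–Lai,
C-index (minimized), McClain–Rao (minimized), Ratkowsky–Lance, Ball–Hall
(largest successive drop). Each index votes for its optimal k over the
candidate range (default 2–8); the modal k wins, ties going to the
smallest k. The battery is a documented stand-in of the same character
as the larger index collections used in R's NbClust.

Stability validation: (a) per-site clustering, (b) leave-one-site-out
reclustering, (c) subgroup reruns (male, female, young/old at the cohort
median age — the split point was an open choice — and FEDN / recurrent /
medicated when present). Every rerun is aligned to the primary labels by
optimal assignment on the confusion matrix (exact for any k) and scored
by the percentage overlap and the adjusted Rand index. Sites below a
patient-count threshold can be dropped (`site_filters`) before
reclustering. A fold whose clustering degenerates is recorded as failed,
never silently dropped.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions the package targets.

- **Regions**: 246 regions partitioned over FPCN, VAN, DMN, LN, DAN,
  SMN, VN, SUB (≥10 each). Normative means are quadratic in age (decades,
  centered at 40 y) with a sex intercept offset — the simplest form with
  the nonlinearity a GP must capture. Slopes ±0.005–0.03 per decade,
  intercepts 0.8–1.2, sex offsets ±0.02 (ReHo units).
- **Cohorts**: defaults 1011 HC, 1101 MDD, 22 sites, ages 18–65, 60%
  female. Tests and the acceptance script run reduced sizes (e.g. 600
  patients over 6 sites, 500 HC) chosen as the package's desk-scale
  working points.
- **Site effects** follow the ComBat generative model exactly — additive
  N(0, 0.05) and multiplicative U(0.8, 1.25) per site × region — so
  harmonization is testable against its own generative assumptions.
- **Subtypes**: patients are subtype 1 with probability 0.36. Deviations
  carry a network-level shift of ±d/2 per network (signed d defaults:
  FPCN −1.75, VAN −1.00, DMN −0.70, LN −0.40, DAN +0.52, SMN +1.81,
  VN +1.00, SUB 0; subtype 2 reversed). Within-network deviations are
  equicorrelated (ρ = 0.5), and the shift is scaled by the within-subtype
  SD of the network mean so that the *network-level* Cohen's d matches
  the configured value exactly while each region's marginal variance
  stays 1 (preserving extreme-rate calibration). A fixed region-level
  jitter (SD 0.4, centered within each network so network-level d is
  untouched) makes the planted pattern region-specific, as empirical
  subtype deviation maps are; without it, a purely network-constant
  pattern caps the achievable label recovery well below what the
  analysis's own stability figures imply.
- **Clinical variables**: truncated normals on valid ranges (HAMD-17
  0–52, anxiety/somatization factor, insight item 0–2, illness duration
  ≥ 0.1 y) with configured between-subtype effects (age d −0.19, HAMD
  d 0.17, insight d −0.25, anxiety/somatization d −0.15, medication
  Cramér's V 0.09 via a rate offset computed from the subtype mixing).
  The duration–severity correlation (−0.21) is induced through a shared
  latent factor in subtype 1 only.
- **Voxel fixtures**: disjoint 3³ blocks per region; each parcel's voxels
  share a latent signal with weight √synchrony plus independent noise, so
  parcel ReHo is monotone in the synchrony parameter.

Everything descends from one integer seed (site effects from a dedicated
stream keyed by the same seed so HC and MDD cohorts share them), and the
same seed reproduces cohorts bitwise.

What the generator does **not** emulate: BOLD physiology, head motion,
preprocessing artifacts, realistic site demographics, spatial
autocorrelation beyond the network block structure, or non-Gaussian
deviation tails. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure under the stated
assumptions — not performance on real rs-fMRI data.

## Numerical choices and degenerate inputs

- ComBat EB tolerance 1e-4 / 100 iterations (see above); zero pooled
  variance, single sites, sites with < 2 subjects, rank-deficient
  designs, and unseen site ids raise errors.
- GP fits require n ≥ 20 and nonzero age variance; a constant target is
  handled by leaving the target scale trivial and letting the white term
  absorb it. Function variance is clipped at 0 when subtracting the noise
  term.
- k-means ties broken by lowest within-cluster SS across restarts;
  k selection tie broken toward the smallest k; difference-based indices
  use the k−1 and k+1 solutions at the range boundaries (W at k = 1 is
  the total SS).
- Label alignment uses optimal assignment, so it reduces to the best
  swap at k = 2 and stays exact for any k.
- Deviation maps must be finite; p-values outside [0, 1] are rejected.

## Problem sizes

Default test and acceptance workloads: subtyping targets at n = 600
patients / 6 sites / 246 regions; normative-model calibration at n = 500
HC with 4 regions under 10-fold CV; the end-to-end pipeline exercised at
80–100 subjects per group with 80 regions; the full-scale pipeline
default (200 HC / 220 MDD / 6 sites / 246 regions) completes in roughly
ten minutes on a single core. These sizes are the package's chosen
desk-scale working points; the statistical checks (calibration,
planted-parameter recovery) are sized so their Monte-Carlo tolerances are
meaningful.

## Known limitations

- Per-region GPs are independent; no multi-task sharing, no warped or
  non-Gaussian likelihoods, no transfer/federated normative modeling.
- Only parametric-prior ComBat; no nonparametric or longitudinal variants.
- The validity-index battery is a stand-in; R's NbClust offers more
  indices and different tie conventions.
- Inference is classical; no permutation or spatial-autocorrelation-aware
  nulls.
- The model-set serialization uses pickle and is not portable across
  incompatible sklearn versions.
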