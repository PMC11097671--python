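# Methods

This note documents the models and procedures `cerebgrad` implements, the
design decisions taken where conventions differ across labs, the synthetic
cohort generator's assumptions, and the package's numerical choices and
limitations.

## Quality control and volume censoring (`cerebgrad.qc`)

Framewise displacement is the Power-style sum of absolute backward
differences of the six rigid-body parameters, FD(t) = Σᵢ₌₁⁶ |dᵢ(t) −
dᵢ(t−1)|, with the three rotations (radians) converted to arc length on a
sphere of radius 50 mm (configurable; 50 mm is the common adult convention
and conservative for a neonatal head). The first volume's FD is defined as
0. Intensity outliers use a robust per-voxel rule: a voxel is an outlier at
volume t when |x(t) − median| > k·MAD with raw MAD (no 1.4826 consistency
factor) and k = 3.5 by default; voxel rows with zero temporal variance are
excluded from the denominator. A volume is censored when FD > 0.2 mm *or*
the outlier fraction > 0.10 (both strict inequalities: values exactly at
threshold are retained), and a scan is excluded when fewer than 120 clean
volumes remain (4 min at TR = 2 s; 119 fails, 120 passes). Censored
volumes are dropped and the retained volumes concatenated before FC;
neighboring volumes are not additionally censored.

## Connectome (`cerebgrad.connectome`)

FC is the Pearson correlation between voxel time series over retained
volumes (raw r; no Fisher transform before PCA). The strict upper triangle
is vectorized row-major — (0,1), (0,2), …, (0,V−1), (1,2), … — and this
order is fixed package-wide so connection-level loadings can be mapped
back to voxel pairs unambiguously. Voxel indexing is 0-based internally.
At least 3 retained volumes are required and any zero-variance retained
row is an error naming the voxel.

## Functional gradients (`cerebgrad.gradients`)

Gradients are principal components of the C × S group matrix after
per-connection mean-centering across subjects (no variance scaling:
connections are already on the common correlation scale, and
centering-only yields the expected rank of S − 1). The eigendecomposition
is performed on the S × S Gram matrix XcᵀXc — mathematically identical to
the C × C covariance route and cheap at C = 52,650. PCA signs are
arbitrary, so each component is flipped to make its largest-|value|
loading positive; this makes fitted models, reports and tests
deterministic. K = 10 components are retained by default (configurable).
Requesting k > S − 1, or more than the effective rank, is an error, as is
a group matrix that is degenerate after centering.

Projection of new subjects always uses the *stored training means* — never
the new data's own means — so the same code path is leakage-safe inside
cross-validation folds, and projecting the training set reproduces the
stored coefficients exactly.

Localization selects the floor(0.05·C) connections with largest absolute
loading (positive and negative pooled by magnitude, signs reported; ties
broken by lower linear index), maps each to its two voxels, and ranks ROIs
by summed voxel incidence. Incidence counts therefore total twice the
number of selected connections.

## Association statistics (`cerebgrad.stats`)

Each (feature, domain) cell fits OLS `score ~ feature + sex + pma_weeks +
birthweight_g` on complete cases and reports the feature coefficient's t
statistic with a two-sided p on n − 5 degrees of freedom. BH-FDR
(step-up, adjusted p = min over higher ranks of p·m/rank, capped at 1) is
applied per outcome domain across features: for a 10-gradient table this
makes a family of 10 tests per domain, which is the scope under which the
published worked examples reproduce exactly (0.032·10/1 = 0.32;
0.015·10/1 = 0.15; 0.042·10/2 = 0.21). A `global` scope (one family over
all cells) is available as an option. Volume growth is the per-ROI Pearson
correlation of volume with PMA, reported with percent variance explained
(100·r²) and BH across the 8 ROIs.

## Prediction (`cerebgrad.predict`)

Per repeat, subjects are partitioned into n_folds (default 10) by a seeded
shuffle followed by contiguous near-equal blocks. For functional features
the gradient basis is re-fitted on the training columns of each fold (k
capped at n_train − 1) and both sets are projected with training means;
anatomical features are the 8 ROI volumes; the combined set concatenates
both blocks with each column standardized on training statistics.
Non-imaging covariates are deliberately excluded from the predictor set.
An OLS model (intercept + features, `numpy.linalg.lstsq`) is fitted per
fold and held-out predictions pooled, so every subject is predicted
exactly once per repeat.

Performance per repeat is the Pearson r between pooled out-of-fold
predictions and actual scores (per-fold r would be unstable with ~6
subjects per fold), Fisher-transformed to z = atanh(r); the summary is
mean z ± SE over repeats. The permutation null shuffles the scores once
per permutation and runs a single full CV cycle (not the full repeat
schedule — one cycle per shuffle keeps thousands of permutations
tractable while sampling the same statistic); the one-sided p-value uses
the add-one rule p = (1 + #{null ≥ observed})/(1 + N) so p is never 0.
By default the observed statistic is the mean z over repeats; a
`single`-cycle observed statistic is available by configuration. An exact
|r| = 1 makes z infinite and raises an error with guidance rather than
propagating infinities.

## Atlas reduction (`cerebgrad.atlas`)

The fine newborn cerebellar parcellation distinguishes 28 regions; for
lobe-level analysis these collapse to 8: left/right anterior lobe (lobules
I–IV, V), left/right central lobe (VI, Crus I/II, VIIb, VIIIa, VIIIb, IX),
left/right posterior lobe (X), central vermis (vermal VI–IX) and posterior
vermis (vermal X). Because published descriptions list the lobule
membership of the 8 lobes but not a canonical 28-name roster, the package
ships a default 28-name table (10 lateral lobules × 2 hemispheres + 8
vermal subdivisions) implementing that membership; the grouping is an
ordinary mapping argument and fully user-editable. Voxel counts are
conserved by construction and unmapped labels are an error.

## Synthetic cohort generator (`cerebgrad.synth`)

The generator emulates the *data structure* of a neonatal cerebellar
rs-fMRI study after preprocessing, with every planted parameter exposed as
ground truth.

**Latent connectivity model.** Each subject's BOLD matrix is
X_s = M·diag(w_s)·Z_s + σ·E, with V × L spatial maps M fixed across
subjects, per-subject source strengths w_s, unit-variance temporal sources
Z_s regenerated per subject from the seed, and i.i.d. Gaussian noise
(σ = noise_sd = 1.0 by default, giving a comfortable but not trivial
voxel-level SNR for L = 6 sources of O(1) amplitude). Each source loads
strongly (weight ≈ 1.6, random sign) on two "home" ROIs and weakly
(SD 0.25) elsewhere, plus voxel-level scatter (SD 0.3): sources are
spatially clustered, as empirical gradients are, and their connection-level
signatures are near-orthogonal. Subject strengths are log-normal around 1
(no sign flips, smoothly varying FC) with a *decaying* per-source log-SD
profile — 1.6× the base (0.5) for the first source, then a linear taper
from 0.5 to 0.25. The decay mirrors the sharply decreasing variance
spectra of empirical FC gradients (a dominant first component, then a long
tail) and is what makes individual sources identifiable by PCA: with equal
source variances the component basis is rotationally degenerate and no
single component need align with any single source. The outcome-coupled
source is the dominant one by default (configurable).

**Outcomes.** The four domain t-scores are 50 + 10·value. The coupled
domain's value is r·z + √(1−r²)·ε with z the standardized planted
strength, ε independent noise and r = coupling_r (default 0.42), so the
population correlation between planted strength and coupled score is
exactly r. The remaining domains are correlated noise with pairwise ≈ 0.3
among the three problem domains (Externalizing/Internalizing/
Dysregulation) and an independent Competence domain, mirroring the
instrument's typical inter-domain structure and giving the multiple-testing
stage realistic behavior. Covariates: PMA ~ truncated normal
42.00 ± 1.91 weeks on [38.57, 47.43]; birthweight ~ truncated normal
3303 ± 432 g on [2280, 4184]; sex ~ Bernoulli(0.5).

**Motion.** Traces are six-parameter series with small i.i.d. jitter
(0.01 mm; rotational jitter scaled to the same arc length) and persistent
position steps of spike_mm (default 0.5 mm) at Bernoulli(spike_rate)
volumes, so each spike censors exactly one volume. The default
spike_rate = 0.02 censors ~4 volumes/scan for motion; the intensity
rule censors a further ~9 (volumes where a strong common source excursion
makes >10% of voxels deviate jointly — the synthetic analogue of global
signal events), leaving ≈ 187 usable volumes of 200 on average, always
above the 120-volume exclusion floor.

**ROI volumes.** volume = intercept + slope·PMA + ε per ROI, with slopes
0.08–0.35 cm³/week and near-term baselines 2.5–6.5 cm³. The noise SD is
solved analytically from r² = s²·var(PMA)/(s²·var(PMA) + σ²) so the
volume–PMA correlation equals target_r (default 0.74, the midpoint of the
0.65–0.81 calibration band; target_r = 1 gives the exact noiseless case).

**Reproducibility.** All randomness flows through named, subject-tagged
`numpy.random.SeedSequence` streams: outputs are bit-identical for a given
seed, and any single subject's BOLD or motion trace can be regenerated in
isolation.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: hemodynamic response dynamics and
autocorrelated BOLD noise, spatial autocorrelation of voxel noise, scanner
artifacts and slow drifts, registration/segmentation error, non-linear or
interaction effects of covariates, item-level questionnaire structure and
age-/sex-norming, and missing-data mechanisms other than
missing-completely-at-random.

## Problem sizes used in the validation suite

The test suite exercises the statistical guarantees at sizes chosen to
make Monte-Carlo assertions stable: planted-coupling recovery uses 50
cohorts of 64 subjects × 120 voxels × 150 volumes; permutation-test
calibration under the null uses 200 replicates of 61 subjects with 199
permutations each on anatomical features (the permutation machinery is
identical across feature sets, and the anatomical path makes 40,000 CV
cycles affordable); the power check uses 20 cohorts of 61 subjects at
coupling 0.6 with 500 permutations on functional features at 40 voxels.
The acceptance script runs the full default geometry (72 × 325 × 200)
end to end.

## Known limitations

- Within-fold PCA makes component *identity* fold-dependent: component 7
  of one fold need not match component 7 of another. Prediction uses the
  full k-dimensional coefficient block, so this does not affect the
  predictive model, but per-component interpretation across folds is not
  meaningful.
- The permutation test permutes scores only; covariate-outcome structure
  is not preserved under the null (covariates are excluded from the
  predictor set, so this matches the prediction model's assumptions).
- Complete-case handling assumes scores are missing completely at random.
- Atlas reduction ships a plausible default 28-region roster; users with a
  different fine parcellation must supply their own grouping table.
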