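# Methods

## The Scaled Subprofile Model

Uptake images are treated as log-multiplicative: scanner gain, injected
dose and global metabolic level scale a scan multiplicatively, while
disease reorganizes the *relative* regional topography. Taking natural
logs (the base is a pure rescaling of all profiles; base *e* is fixed
throughout) and removing each subject's mean over the in-mask voxels
and then the voxelwise group mean profile (GMP) leaves the subject
residual profile (SRP):

```
SRP_iv = log I_iv − mean_v(log I_iv) − GMP_v
```

With the GMP derived from the same cohort, the SRP matrix is doubly
centered (row and column means zero to 1e-10); the reconstruction
`log I = offsets ⊕ GMP ⊕ SRP` is exact. Multiplying any scan by a
positive constant leaves its SRP — and hence every downstream score —
unchanged; this is asserted to 1e-8 in the tests.

The GMP is the voxelwise mean of the row-centered log data over the
pooled derivation cohort (controls and patients). A controls-only GMP
is available via `DeriveConfig.gmp_group`; pooling is the default
because the pattern's contrast should live in the residuals, not in the
reference profile, and because prospective scoring subtracts the stored
derivation GMP regardless.

## Masking and vectorization

The brain mask keeps a voxel iff, for every subject, its intensity
exceeds `mask_threshold` (default 0.35) of that subject's maximum — a
relative-threshold intersection that removes out-of-brain voxels
before the log transform. The threshold is configurable; the
intersection makes the mask conservative under subject-wise dropout.
Voxels are linearized in row-major (C) order over the grid, so masks,
patterns and weight maps are portable. In-mask nonpositive intensities
are a hard error (the log is meaningless there), never clamped.
Volumes must share grid shape and affine (elementwise tolerance 1e-4);
spatial normalization is assumed done upstream and is out of scope.

## PCA in voxel space

Because voxels far outnumber subjects, the covariance PCA of the SRPs
is computed in the dual: eigendecompose the subject × subject Gram
matrix and map eigenvectors to unit-norm voxel loadings. This equals a
dense voxel-space eigendecomposition (the test oracle) to 1e-8. No
voxel standardization or rotation is applied. At most `n−1` components
are retained (the centered Gram has a null space), eigenvalues are
reported as variances (Gram eigenvalue / (n−1)), and each component is
oriented so the patient-minus-control mean subject score is
nonnegative (ties broken by making the largest-magnitude loading
positive), which removes sign ambiguity before regression and
bootstrap alignment. Component indices are 0-based throughout the API.

## Component selection and combination

Candidates are the smallest prefix of components whose cumulative
variance fraction reaches `cum_var_threshold` (default 0.5, at least
one component). Their subject scores enter a forward-only stepwise
logistic regression of patient status: starting from the intercept,
the addition minimizing AIC = 2k − 2 log L is accepted until no
addition lowers AIC. Perfect separation — likely at n≈40 — has no
finite MLE; the fit then falls back to an L2 penalty of 1e-4 on the
slopes, the flag is recorded, and AIC uses the unpenalized
log-likelihood with probabilities clipped at 1e-12. If selection keeps
nothing, derivation falls back to PC1 alone and flags it.

The pattern is `Σ_k c_k · loading_k`, normalized to unit Euclidean norm
and oriented so derivation patients score higher; the signed
normalization scalar is stored so derivation subject scores remain
recoverable from the PCA scores. Unit norm is a convention (no
canonical scale exists); raw-score scale differences are absorbed by
the downstream z-transformation.

Forward stepwise selection is *not* best-subset search: for three or
more candidates the greedy path can end at a model with higher AIC
than the exhaustive optimum, and with ~10+ flat-spectrum candidates at
n = 40 it regularly admits components whose group separation is pure
chance (the best of m null t-statistics grows like √(2 log m), and any
|t| > √2 lowers AIC). Because raw-scale logistic coefficients scale
inversely with a component's score spread, such chance components
enter the linear combination with weights comparable to the disease
component's and dilute the recovered topography. The PC1-only variant
(`derive_pattern_pc1`) is immune to this and is the recommended mode
when topographic fidelity matters more than in-sample discrimination;
the package reports both.

## Bootstrap stability

`bootstrap_stability` resamples subjects with replacement within each
group (group sizes preserved), re-runs the *full* derivation (PCA,
variance selection, stepwise) inside the original analysis mask, aligns
each replicate pattern's sign to the original (flip when negatively
correlated), and takes per-voxel percentiles of the aligned weights.
A voxel is stable when its one-sided CI at `ci_level` (default 0.90,
1000 replicates) excludes zero: 10th percentile > 0 or 90th < 0.
Replicates where stepwise keeps no component are counted as failures
and skipped (the PC1 fallback is deliberately disabled inside the
bootstrap so selection variability is visible); more than 20% failures
warns, or errors under `strict_failures`. Replicate r draws from the
deterministic child stream `(seed, r)`, so results are bit-reproducible
and independent of replicate ordering.

## Scoring and z-transformation

A new scan is scored without refitting anything: its offset is its log
mean over the pattern's mask, the pattern's stored GMP is subtracted,
and the residual is projected onto the weights (all mask voxels
contribute). Scores are z-transformed against a designated control
group scanned on the same camera, using the sample standard deviation
(n−1; control groups are small). Camera batches are never mixed; a
batch containing patients without ≥2 controls is a configuration error
naming the batch, while a batch holding only a third diagnostic group
(e.g. atypical parkinsonism) may be referenced to a designated
control batch via `fallback_camera`.

## Validation statistics

AUC is the Mann–Whitney probability that a random patient outscores a
random control (ties half); the group comparison is the
pooled-variance Student t (Welch behind a flag), two-sided, flagged
significant at p < 0.05 uncorrected; correlations are Pearson's r with
t-distribution p-values. Region weights are unweighted voxel means of
pattern weights within each atlas region intersected with the mask;
regions without in-mask voxels are reported missing, not zero. The
bundled 30-region atlas is a synthetic stand-in (labeled ellipsoids
generated programmatically); any labeled integer NIfTI atlas is
accepted for real use.

## Synthetic cohorts

`generate_cohort` draws, for subject *i* on camera *c*:

```
I_iv = exp( baseline_v + camera_cv + o_i + s_i · P_v + ε_iv )
```

with planted pattern `P` (signed Gaussian blobs, unit norm over the
brain support, default topography mimicking the parkinsonian pattern:
deep-nuclear/pontocerebellar/motor hypermetabolism co-varying with
parieto-occipital and frontal hypometabolism), expression
`s_i ~ N(0, 1)` for controls and `N(2, 1)` for patients, offsets
`o_i ~ N(0, 0.2²)`, optional smooth per-camera gain fields, and white
voxel noise `ε ~ N(0, 0.05²)` in log units. The default grid is
20×24×20 with a superellipsoid brain support of ~6.2k voxels — large
enough for stable PCA at n = 40, small enough that a full derivation
takes well under a second. In the noise-free, offset-free limit the
SSM residual of subject *i* is exactly `(s_i − s̄)(P − P̄)`, which the
tests assert to 1e-8; this analytic pass-through is what makes
parameter recovery a fair end-to-end check.

What the generator does *not* emulate: structured inter-subject
anatomical covariance. Real cohorts show smoothly decaying residual
spectra (first component ≈ 2× the second, roughly six components to
half the variance); under the default white-noise model the non-signal
spectrum is flat, with the noise floor spread evenly over all n−1 dual
components. Consequently the top-50% rule admits ~17 candidates here
versus ~6 on real data, making the stepwise mode's chance-admission
behavior *more* pronounced than in practice, and passing recovery
tests say nothing about anatomical confounds. An optional
`nuisance_mode_sds` setting adds shared smooth covariance modes with a
chosen eigenvalue profile for experiments that need realistic spectra;
it is off by default so the reference model stays minimal. Attenuation,
scatter and PET reconstruction physics are out of scope.

## Reference experiment and problem sizes

`reference_recovery_experiment` generates, per seed, an independent
derivation and validation cohort (20+20 each), derives patterns in
both modes, and reports truth–weight correlation, truth–score
correlation and held-out AUC, with medians over seeds (ten by
default). The acceptance script adds a 5-seed null (effect size 0), a
200-replicate bootstrap on a high-SNR cohort (noise sd 0.005), and the
numerical invariants; the whole script runs in well under a minute on
one core. Under the reference conditions the measured medians are
≈ 0.90 (weights) and ≈ 0.999 (scores) for PC1-only derivation and
≈ 0.57 / 0.87 for the stepwise mode, with held-out AUC ≈ 0.94 for both
— the quantitative face of the fit-versus-generality trade-off above.

## Known limitations

* The stepwise mode's selection is greedy; its AIC path is exported
  (`derivation["aic_trace"]`) so alternative paths can be audited, but
  backward elimination is not implemented.
* Scores are computed on inputs as given; equalizing smoothing across
  cameras is the user's responsibility.
* Longitudinal modelling, multi-pattern differential diagnosis and
  spatial normalization are out of scope.
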