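# ssmpca

Spatial covariance analysis of metabolic brain images with the Scaled
Subprofile Model and principal component analysis (SSM PCA).

Neurodegenerative diseases such as Parkinson's disease alter glucose
metabolism in distributed brain networks rather than in isolated
regions. Given FDG-PET scans of controls and patients (spatially
normalized to a common grid), this package derives a disease-related
covariance pattern — a voxel-weight map of co-varying relative hyper-
and hypometabolism — and quantifies its expression in any new scan as
a single subject score. It is aimed at imaging researchers who need
pattern derivation, prospective scoring, bootstrap stability maps and
cross-cohort validation in one reproducible pipeline.

## Model

A scan is modelled log-multiplicatively. For subject *i* and voxel *v*:

```
log I_iv = o_i + GMP_v + SRP_iv
```

* `o_i` — subject's global offset (mean of the log image), absorbing
  scanner gain and injected dose;
* `GMP` — group mean profile of the derivation cohort;
* `SRP` — subject residual profile, invariant to global scaling.

PCA of the SRP matrix in voxel space (computed in the subject-space
dual form) yields spatial covariance components. The components
covering the top 50% of total variance are candidates; their subject
scores enter a forward stepwise logistic regression on the
control/patient labels with AIC (`2k − 2 log L`) as the selection
criterion, and the selected components, weighted by their logistic
coefficients, are combined into a unit-norm pattern oriented so
patients score higher. A PC1-only variant derives component 1 in
isolation. Voxel stability is assessed by bootstrap resampling of
subjects (full re-derivation per replicate; a voxel is stable when the
one-sided 90% percentile CI of its aligned weights excludes zero).

Expression in a new scan is the inner product of that scan's residual
profile (formed with the *pattern's* GMP) with the pattern weights,
z-transformed against controls scanned on the same camera. Validation
uses Student's t and ROC AUC on the z-scores; patterns are compared via
Pearson correlation of subject z-scores and of mean weights over a
volume-of-interest atlas.

A synthetic-cohort generator (`ssmpca.synthetic_data`) draws scans from
exactly this generative model with a known planted pattern, so every
stage is testable without clinical data.

## Worked example

```python
import numpy as np
from ssmpca import (SyntheticCohortSpec, generate_cohort, derive_pattern,
                    derive_pattern_pc1, score_cohort, discrimination_report)

vs, truth = generate_cohort(SyntheticCohortSpec(seed=2))   # 20+20 subjects

for name, derive in [("stepwise", derive_pattern), ("PC1-only", derive_pattern_pc1)]:
    pattern = derive(vs).pattern
    r = np.corrcoef(pattern.weights, truth.pattern_in_mask(pattern.mask))[0, 1]
    vs_val, _ = generate_cohort(SyntheticCohortSpec(seed=3))  # held-out cohort
    scores = score_cohort(vs_val, pattern)["cam0"]
    report = discrimination_report(scores.z, scores.group_labels)
    print(f"{name:9s} components={pattern.component_indices.tolist()} "
          f"truth r={r:+.3f}  validation AUC={report.auc:.3f}  "
          f"t={report.t_statistic:.2f} p={report.p_value:.2g}")
```

prints

```
stepwise  components=[0, 1, 4, 9] truth r=+0.489  validation AUC=0.943  t=6.27 p=2.4e-07
PC1-only  components=[0] truth r=+0.882  validation AUC=0.943  t=6.26 p=2.5e-07
```

Both derivations discriminate patients from controls in the held-out
cohort (AUC ≈ 0.94, patients z-scored against the validation controls).
The stepwise combination additionally pulls in small components that
help the in-sample logistic fit but dilute the recovered topography
(truth correlation 0.49 vs 0.88 for PC1 alone) — the familiar
fit-versus-generality trade-off of multi-component patterns, discussed
further in `docs/methods.md`.

The same workflow is available from the shell:

```sh
ssmpca simulate --out cohort --seed 3
ssmpca derive   --scans cohort/manifest.tsv --out pattern --seed 3
ssmpca score    --pattern pattern --scans cohort/manifest.tsv --out scores.tsv
ssmpca validate --pattern pattern --scans cohort/manifest.tsv --out report.json
ssmpca bootstrap --scans cohort/manifest.tsv --pattern pattern --out boot --reps 1000
```

Each command writes a `run_manifest.json` (config echo, seed, input
hashes, package version) sufficient to reproduce the run.

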