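"""Discrimination and similarity statistics for pattern validation.

Within-cohort validation asks whether patients express a pattern more
strongly than controls (Student's t on z-scores, ROC AUC); cross-cohort
comparison asks whether two patterns agree, via Pearson correlation of
their subject z-scores in a common dataset and of their mean weights
over a volume-of-interest atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import DegenerateDataError
from .pattern_derivation import CovariancePattern
from .scoring import cohort_scores_frame, score_cohort
from .volume_io import VOIAtlas, VolumeSet

#: uncorrected significance threshold used in report flags
P_SIGNIFICANT = 0.05


@dataclass
class DiscriminationReport:
    auc: float
    n_controls: int
    n_patients: int
    t_statistic: float
    p_value: float
    control_mean: float
    control_sd: float
    patient_mean: float
    patient_sd: float
    significant: bool


@dataclass
class SimilarityReport:
    region_weight_correlation: float
    region_weight_p: float
    n_regions: int
    score_correlation: float | None = None
    score_p: float | None = None


def _split(z: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    controls = z[labels == "control"]
    patients = z[labels == "patient"]
    if controls.size == 0 or patients.size == 0:
        raise ValueError("need both controls and patients")
    return controls, patients


def roc_auc(z_scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(random patient outscores random control), ties counted 1/2."""
    controls, patients = _split(z_scores, labels)
    y = np.concatenate([np.zeros(controls.size), np.ones(patients.size)])
    return float(roc_auc_score(y, np.concatenate([controls, patients])))


def group_compare(
    z_scores: np.ndarray, labels: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample Student's t (pooled variance by default; Welch optional).

    Sign convention: positive t means patients score higher.
    """
    controls, patients = _split(z_scores, labels)
    if controls.size < 2 or patients.size < 2:
        raise ValueError("need >= 2 subjects per group")
    if np.ptp(controls) == 0 and np.ptp(patients) == 0 and controls[0] == patients[0]:
        # identical constant samples: no evidence of difference
        return 0.0, 1.0
    res = stats.ttest_ind(patients, controls, equal_var=equal_var)
    if not np.isfinite(res.statistic):
        raise DegenerateDataError("zero pooled variance in t test")
    return float(res.statistic), float(res.pvalue)


def discrimination_report(z_scores: np.ndarray, labels: np.ndarray) -> DiscriminationReport:
    controls, patients = _split(z_scores, labels)
    t, p = group_compare(z_scores, labels)
    return DiscriminationReport(
        auc=roc_auc(z_scores, labels),
        n_controls=int(controls.size),
        n_patients=int(patients.size),
        t_statistic=t,
        p_value=p,
        control_mean=float(controls.mean()),
        control_sd=float(controls.std(ddof=1)),
        patient_mean=float(patients.mean()),
        patient_sd=float(patients.std(ddof=1)),
        significant=bool(p < P_SIGNIFICANT),
    )


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlate needs equal-length vectors of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance input to correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def voi_region_weights(pattern: CovariancePattern, atlas: VOIAtlas) -> pd.Series:
    """Mean pattern weight per named atlas region (in-mask voxels only).

    Regions with zero in-mask overlap are omitted (missing, not zero).
    """
    if atlas.labels.shape != pattern.mask.shape:
        raise ValueError("atlas grid does not match pattern grid")
    in_mask_labels = atlas.labels[pattern.mask]
    means: dict[str, float] = {}
    for label, name in atlas.names.items():
        sel = in_mask_labels == label
        if sel.any():
            means[name] = float(pattern.weights[sel].mean())
    if not means:
        raise ValueError("no atlas region overlaps the pattern mask")
    return pd.Series(means, name=pattern.pattern_id)


def compare_patterns(
    pattern_a: CovariancePattern,
    pattern_b: CovariancePattern,
    atlas: VOIAtlas,
    scored_dataset: VolumeSet | None = None,
) -> SimilarityReport:
    """Topographic and expression similarity of two patterns.

    Region-weight correlation is Pearson's r over atlas regions present
    in both patterns' masks; if ``scored_dataset`` is given, both
    patterns are scored on it (per-camera z-referencing) and the
    z-score vectors correlated.
    """
    wa = voi_region_weights(pattern_a, atlas)
    wb = voi_region_weights(pattern_b, atlas)
    common = wa.index.intersection(wb.index)
    if common.size < 3:
        raise ValueError(f"only {common.size} atlas regions common to both patterns")
    r_w, p_w = correlate(wa[common].to_numpy(), wb[common].to_numpy())
    r_s = p_s = None
    if scored_dataset is not None:
        fa = cohort_scores_frame(score_cohort(scored_dataset, pattern_a)).set_index("subject_id")
        fb = cohort_scores_frame(score_cohort(scored_dataset, pattern_b)).set_index("subject_id")
        fb = fb.loc[fa.index]
        r_s, p_s = correlate(fa["z"].to_numpy(), fb["z"].to_numpy())
    return SimilarityReport(
        region_weight_correlation=r_w,
        region_weight_p=p_w,
        n_regions=int(common.size),
        score_correlation=r_s,
        score_p=p_s,
    )
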