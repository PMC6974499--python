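"""Pattern expression scoring (topographic profile rating).

A subject's raw score is the inner product of their residual profile
with a fixed pattern's voxel weights, where the residual profile is
formed with the *pattern's* group mean profile — scoring a new scan
never refits anything.  Raw scores depend on camera and reconstruction
details, so they are z-transformed against a designated control group
scanned on the same camera; per-camera batches are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError, DimensionError
from .pattern_derivation import CovariancePattern
from .ssm_core import ssm_transform
from .volume_io import VolumeSet, apply_mask


@dataclass
class SubjectScores:
    """Raw projection scores and control-referenced z-scores."""

    subject_ids: list[str]
    group_labels: np.ndarray
    camera_labels: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    reference_group: str
    reference_mean: float
    reference_sd: float
    pattern_id: str = "pattern"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.group_labels,
                "camera": self.camera_labels,
                "raw": self.raw,
                "z": self.z,
                "pattern_id": self.pattern_id,
                "reference_group": self.reference_group,
            }
        )


def _conform(vs: VolumeSet, pattern: CovariancePattern) -> VolumeSet:
    if vs.grid_shape != tuple(pattern.mask.shape):
        raise DimensionError(
            f"scan grid {vs.grid_shape} does not match pattern grid {pattern.mask.shape}"
        )
    if vs.mask.all():
        return apply_mask(vs, pattern.mask)
    if np.array_equal(vs.mask, pattern.mask):
        return vs
    raise DimensionError("scan mask differs from pattern mask")


def score_subjects(vs: VolumeSet, pattern: CovariancePattern) -> np.ndarray:
    """Raw pattern-expression score per subject.

    The subject mean (global offset) is computed over the pattern's
    mask voxels, the pattern's GMP is removed, and the residual is
    projected onto the pattern weights.  All mask voxels contribute.
    Pure function of the stored pattern bundle: nothing is refit.
    """
    vs = _conform(vs, pattern)
    rp = ssm_transform(vs, reference_gmp=pattern.gmp)
    return rp.srp @ pattern.weights


def z_transform(
    raw: np.ndarray,
    reference_raw: np.ndarray,
    subject_ids: list[str] | None = None,
    group_labels: np.ndarray | None = None,
    camera_labels: np.ndarray | None = None,
    reference_group: str = "control",
    pattern_id: str = "pattern",
) -> SubjectScores:
    """Standardize raw scores against a reference control sample.

    Uses the sample standard deviation (n-1 denominator); reference
    control groups are typically small, so this matters.
    """
    raw = np.asarray(raw, dtype=float)
    reference_raw = np.asarray(reference_raw, dtype=float)
    if reference_raw.size < 2:
        raise DegenerateDataError("z-transform needs >= 2 reference subjects")
    mu = float(reference_raw.mean())
    sd = float(reference_raw.std(ddof=1))
    if sd == 0:
        raise DegenerateDataError("reference scores have zero standard deviation")
    n = raw.size
    return SubjectScores(
        subject_ids=list(subject_ids) if subject_ids is not None else [f"s{i}" for i in range(n)],
        group_labels=np.asarray(group_labels if group_labels is not None else ["other"] * n, dtype=object),
        camera_labels=np.asarray(camera_labels if camera_labels is not None else ["cam0"] * n, dtype=object),
        raw=raw,
        z=(raw - mu) / sd,
        reference_group=reference_group,
        reference_mean=mu,
        reference_sd=sd,
        pattern_id=pattern_id,
    )


def score_cohort(
    vs: VolumeSet,
    pattern: CovariancePattern,
    reference_group: str = "control",
    fallback_camera: str | None = None,
) -> dict[str, SubjectScores]:
    """Score a cohort with per-camera z-referencing.

    Each camera batch is z-transformed against its own subjects of
    ``reference_group``.  A batch lacking >= 2 such subjects is an
    error — unless it contains *only* non-control, non-patient subjects
    (e.g. a third diagnostic group) and ``fallback_camera`` designates
    the batch whose controls should serve as reference, or unless
    ``fallback_camera`` is given explicitly for it.
    """
    raw_all = score_subjects(vs, pattern)
    cameras = list(dict.fromkeys(vs.camera_labels.tolist()))
    ref_raw_by_cam = {
        cam: raw_all[(vs.camera_labels == cam) & (vs.group_labels == reference_group)]
        for cam in cameras
    }
    out: dict[str, SubjectScores] = {}
    for cam in cameras:
        sel = vs.camera_labels == cam
        ref = ref_raw_by_cam[cam]
        if ref.size < 2:
            if fallback_camera is not None and ref_raw_by_cam.get(fallback_camera, np.empty(0)).size >= 2:
                ref = ref_raw_by_cam[fallback_camera]
            else:
                raise ConfigurationError(
                    f"camera batch {cam!r} has no usable {reference_group!r} "
                    "reference subjects (and no fallback_camera given)"
                )
        out[cam] = z_transform(
            raw_all[sel],
            ref,
            subject_ids=[sid for sid, s in zip(vs.subject_ids, sel) if s],
            group_labels=vs.group_labels[sel],
            camera_labels=vs.camera_labels[sel],
            reference_group=reference_group,
            pattern_id=pattern.pattern_id,
        )
    return out


def cohort_scores_frame(scores: dict[str, SubjectScores]) -> pd.DataFrame:
    """Concatenate per-camera scores into one tidy table."""
    return pd.concat([s.to_frame() for s in scores.values()], ignore_index=True)
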