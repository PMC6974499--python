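"""The Scaled Subprofile Model transform and voxel-space PCA.

The SSM treats an uptake image as log-multiplicative: a per-subject
global scaling, a shared regional mean profile, and a residual
covariance profile.  Taking logs and removing the subject mean and the
group mean profile (GMP) leaves the subject residual profile (SRP),
which is invariant to global scaling of the raw scan.  PCA of the SRP
matrix in voxel space yields spatial covariance components; their
subject scores are the raw material for disease-pattern derivation.

Because voxels vastly outnumber subjects, the PCA is computed in the
dual (subject-space) form: eigendecompose the subject x subject Gram
matrix of the SRPs and map eigenvectors back to unit-norm voxel
loadings.  A dense voxel-space eigendecomposition gives identical
results on small problems and serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, DimensionError
from .volume_io import VolumeSet

#: eigenvalues below this fraction of the largest are treated as null space
_RANK_RTOL = 1e-10


@dataclass
class ResidualProfiles:
    """Log-transformed, doubly centered scan matrix plus the pieces
    needed to score new scans against the same reference.

    ``srp[i] = log(data[i]) - subject_offsets[i] - gmp`` identically.
    """

    srp: np.ndarray            # (n_subjects, n_voxels), log units
    gmp: np.ndarray            # (n_voxels,) group mean profile, log units
    subject_offsets: np.ndarray  # (n_subjects,) per-subject log means
    subject_ids: list[str]
    group_labels: np.ndarray
    camera_labels: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.srp.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.srp.shape[1]


@dataclass
class PCAResult:
    """Voxel-space PCA of residual profiles.

    ``components`` rows are mutually orthogonal unit-norm voxel
    loadings; ``subject_scores[:, k]`` are the derivation subjects'
    expressions of component ``k``; ``srp ≈ subject_scores @ components``.
    Components are oriented so the patient-minus-control mean score is
    nonnegative (ties: largest-magnitude loading positive).
    """

    components: np.ndarray        # (n_components, n_voxels)
    eigenvalues: np.ndarray       # descending, variance units
    variance_fractions: np.ndarray
    subject_scores: np.ndarray    # (n_subjects, n_components)
    subject_ids: list[str]
    group_labels: np.ndarray
    camera_labels: np.ndarray


def ssm_transform(
    vs: VolumeSet,
    reference_gmp: np.ndarray | None = None,
    gmp_group: str | None = None,
) -> ResidualProfiles:
    """Log-transform and doubly center a cohort.

    Parameters
    ----------
    vs
        Masked cohort; every in-mask intensity must be > 0.
    reference_gmp
        Group mean profile from a derivation cohort.  When given (the
        prospective-scoring case) it is subtracted as-is; when absent,
        the GMP is the voxelwise mean of the row-centered log data of
        this cohort.
    gmp_group
        Restrict the self-derived GMP to one group (e.g. ``"control"``).
        Default pools all subjects.  Ignored when ``reference_gmp`` is
        given.
    """
    if np.any(vs.data <= 0):
        raise ValueError(
            "nonpositive in-mask intensity: the log transform requires "
            "strictly positive values (re-mask or check the input volumes)"
        )
    log_data = np.log(vs.data)
    offsets = log_data.mean(axis=1)
    centered = log_data - offsets[:, None]
    if reference_gmp is not None:
        gmp = np.asarray(reference_gmp, dtype=float)
        if gmp.shape != (vs.n_voxels,):
            raise DimensionError(
                f"reference GMP has {gmp.shape[-1] if gmp.ndim else 0} voxels, "
                f"data has {vs.n_voxels}"
            )
    else:
        if gmp_group is None:
            gmp = centered.mean(axis=0)
        else:
            sel = vs.group_labels == gmp_group
            if not sel.any():
                raise ValueError(f"no subjects in gmp_group={gmp_group!r}")
            gmp = centered[sel].mean(axis=0)
    return ResidualProfiles(
        srp=centered - gmp,
        gmp=gmp,
        subject_offsets=offsets,
        subject_ids=list(vs.subject_ids),
        group_labels=vs.group_labels.copy(),
        camera_labels=vs.camera_labels.copy(),
    )


def _orient_components(
    components: np.ndarray, scores: np.ndarray, group_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flip component signs so patients express each one at least as
    strongly as controls (ties: largest-|loading| voxel positive)."""
    is_pat = group_labels == "patient"
    is_con = group_labels == "control"
    for k in range(components.shape[0]):
        if is_pat.any() and is_con.any():
            diff = scores[is_pat, k].mean() - scores[is_con, k].mean()
        else:
            diff = 0.0
        if diff < 0:
            flip = True
        elif diff > 0:
            flip = False
        else:
            flip = components[k, np.argmax(np.abs(components[k]))] < 0
        if flip:
            components[k] = -components[k]
            scores[:, k] = -scores[:, k]
    return components, scores


def fit_pca(rp: ResidualProfiles) -> PCAResult:
    """Covariance PCA of residual profiles via the subject-space dual.

    Eigenvalues are reported as variances (Gram eigenvalues divided by
    ``n_subjects - 1``); variance fractions use the full trace, so the
    fractions of the retained (nonzero) components sum to 1 up to the
    discarded null space.
    """
    S = rp.srp
    n = S.shape[0]
    if n < 2:
        raise DegenerateDataError("PCA needs at least 2 subjects")
    # residuals are log-unit quantities; anything at float-noise level
    # carries no signal (e.g. globally constant volumes)
    if np.abs(S).max() < 1e-12:
        raise DegenerateDataError("residual profiles are identically zero")
    gram = S @ S.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise DegenerateDataError("residual profiles are identically zero")
    keep = evals > _RANK_RTOL * evals[0]
    keep[n - 1:] = False  # a centered n-subject set has at most n-1 components
    if not keep.any():
        raise DegenerateDataError("residual profiles are identically zero")
    evals_k = evals[keep]
    evecs_k = evecs[:, keep]
    # map dual eigenvectors u to unit-norm voxel loadings v = S^T u / sqrt(l)
    components = (S.T @ evecs_k / np.sqrt(evals_k)).T
    scores = evecs_k * np.sqrt(evals_k)
    components, scores = _orient_components(
        components.copy(), scores.copy(), rp.group_labels
    )
    return PCAResult(
        components=components,
        eigenvalues=evals_k / (n - 1),
        variance_fractions=evals_k / total,
        subject_scores=scores,
        subject_ids=list(rp.subject_ids),
        group_labels=rp.group_labels.copy(),
        camera_labels=rp.camera_labels.copy(),
    )


def select_top_variance_components(
    variance_fractions: np.ndarray, cumulative_threshold: float = 0.5
) -> np.ndarray:
    """Smallest prefix of components whose cumulative variance fraction
    reaches ``cumulative_threshold`` (always at least one component).

    Returns 0-based component indices ``[0, 1, ..., m-1]``.
    """
    fractions = np.asarray(variance_fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty variance_fractions")
    if np.any(np.diff(fractions) > 1e-12):
        raise ValueError("variance_fractions must be sorted descending")
    if fractions.sum() > 1 + 1e-8:
        raise ValueError("variance_fractions sum exceeds 1")
    if not (0.0 < cumulative_threshold <= 1.0):
        raise ValueError("cumulative_threshold must lie in (0, 1]")
    cum = np.cumsum(fractions)
    idx = int(np.searchsorted(cum, cumulative_threshold - 1e-12))
    idx = min(idx, fractions.size - 1)
    return np.arange(idx + 1)
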