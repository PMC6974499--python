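"""Disease-pattern derivation: component selection, combination, bootstrap.

A derivation cohort (controls + patients) is SSM-transformed, its
residual profiles decomposed by PCA, and the components explaining the
top 50% of total variance become candidates.  Their subject scores
enter a forward stepwise logistic regression with the Akaike
information criterion (AIC = 2k - 2 log L) as the selection rule; the
selected components, weighted by their logistic coefficients, are
linearly combined into a single unit-norm covariance pattern oriented
so patients score higher than controls.

Voxel stability is assessed by bootstrap resampling of subjects
(stratified within group), re-running the full derivation per
replicate and keeping voxels whose one-sided percentile confidence
interval of aligned weights excludes zero.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from . import __version__ as _pkg_version
from .config import DeriveConfig
from .exceptions import DegenerateDataError, DimensionError
from .ssm_core import (
    PCAResult,
    ResidualProfiles,
    fit_pca,
    select_top_variance_components,
    ssm_transform,
)
from .volume_io import (
    VolumeSet,
    apply_mask,
    compute_brain_mask,
    export_weight_map,
    load_weight_map,
)

logger = logging.getLogger(__name__)

#: L2 coefficient penalty used when the logistic likelihood has no
#: finite maximizer (perfectly separated groups)
SEPARATION_PENALTY = 1e-4

_PROB_EPS = 1e-12


@dataclass
class CovariancePattern:
    """A unit-norm voxel-weight map with its derivation provenance.

    ``weights = (sum_k coefficients[k] * PC_k loadings) / normalization``
    where the signed ``normalization`` scalar enforces unit norm and the
    patients-score-higher orientation, keeping derivation subject scores
    recoverable from the PCA subject scores.
    """

    weights: np.ndarray            # (n_voxels,), unit norm
    mask: np.ndarray               # bool 3D grid
    affine: np.ndarray
    gmp: np.ndarray                # derivation group mean profile (log units)
    component_indices: np.ndarray  # 0-based, strictly increasing
    coefficients: np.ndarray       # logistic coefficients per included PC
    intercept: float
    variance_fractions: np.ndarray  # of the included PCs
    normalization: float
    pattern_id: str = "pattern"
    derivation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights.shape != (int(self.mask.sum()),):
            raise DimensionError("weights length must equal mask voxel count")
        if not np.isclose(np.linalg.norm(self.weights), 1.0, atol=1e-8):
            raise ValueError("pattern weights must have unit norm")
        idx = np.asarray(self.component_indices)
        if idx.size == 0 or np.any(np.diff(idx) <= 0):
            raise ValueError("component_indices must be nonempty, strictly increasing")


@dataclass
class StepwiseResult:
    selected: np.ndarray        # 0-based candidate indices, ascending
    coefficients: np.ndarray    # per selected candidate, final model
    intercept: float
    aic_trace: list[dict]
    separation: bool


@dataclass
class BootstrapResult:
    n_replicates: int
    ci_level: float
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    stable_mask: np.ndarray      # bool per voxel
    replicate_failures: int
    pattern: CovariancePattern
    replicate_weights: np.ndarray | None = None


@dataclass
class DerivationResult:
    pattern: CovariancePattern
    pca: PCAResult
    residuals: ResidualProfiles


@dataclass
class _LogisticFit:
    coef: np.ndarray
    intercept: float
    llf: float
    aic: float
    separated: bool


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), _PROB_EPS, 1 - _PROB_EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> _LogisticFit:
    """Maximum-likelihood logistic fit with a penalized fallback.

    When the groups are perfectly separated the MLE diverges; we then
    refit with a small L2 penalty (``SEPARATION_PENALTY``) so the
    relative component weighting stays finite and meaningful, and
    report the (clipped) unpenalized log-likelihood.
    """
    n = len(y)
    if X.shape[1] == 0:
        p = y.mean()
        llf = _loglik(y, np.full(n, np.log(p / (1 - p)) if 0 < p < 1 else np.sign(p - 0.5) * 50))
        return _LogisticFit(np.empty(0), float(np.log(p / (1 - p))) if 0 < p < 1 else 0.0,
                            llf, 2 * 1 - 2 * llf, False)
    X1 = np.column_stack([np.ones(n), X])
    separated = False
    params = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, X1).fit(disp=0, method="newton", maxiter=200)
        params = np.asarray(res.params)
        if (
            not np.all(np.isfinite(params))
            or np.abs(params).max() > 1e3
            or not res.mle_retvals.get("converged", True)
        ):
            separated = True
    except Exception:
        separated = True
    if separated:
        # alpha * ||w||^2 penalty  <=>  sklearn C = 1 / (2 * alpha)
        clf = LogisticRegression(
            C=1.0 / (2.0 * SEPARATION_PENALTY), solver="lbfgs",
            max_iter=2000, tol=1e-10,
        ).fit(X, y)
        params = np.concatenate([clf.intercept_, clf.coef_[0]])
    llf = _loglik(y, X1 @ params)
    k = X1.shape[1]
    return _LogisticFit(params[1:], float(params[0]), llf, 2 * k - 2 * llf, separated)


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if not {"control", "patient"} <= classes:
        raise ValueError("labels must contain both 'control' and 'patient'")
    extra = classes - {"control", "patient"}
    if extra:
        raise ValueError(f"stepwise selection accepts only control/patient labels, got {extra}")
    return (labels == "patient").astype(float)


def stepwise_logistic_aic(
    subject_scores: np.ndarray, labels: np.ndarray
) -> StepwiseResult:
    """Forward stepwise logistic regression minimizing AIC.

    Starts from the intercept-only model; at each step adds the
    candidate component whose inclusion lowers AIC the most, stopping
    at the first step where no addition improves AIC.  May select no
    component (all candidates useless: the +2 parameter penalty is
    never repaid).
    """
    X = np.asarray(subject_scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("subject_scores must be (n_subjects, n_candidates), >=1 candidate")
    y = _binary_labels(labels)
    base = _fit_logistic(X[:, :0], y)
    current: list[int] = []
    current_aic = base.aic
    trace = [{"step": 0, "added": None, "aic": current_aic, "candidates": {}}]
    separation = False
    remaining = list(range(X.shape[1]))
    while remaining:
        fits = {j: _fit_logistic(X[:, sorted(current + [j])], y) for j in remaining}
        best_j = min(fits, key=lambda j: fits[j].aic)
        cand_aics = {j: fits[j].aic for j in remaining}
        if fits[best_j].aic < current_aic:
            current.append(best_j)
            current_aic = fits[best_j].aic
            separation |= fits[best_j].separated
            remaining.remove(best_j)
            trace.append(
                {"step": len(trace), "added": best_j, "aic": current_aic,
                 "candidates": cand_aics}
            )
        else:
            trace.append(
                {"step": len(trace), "added": None, "aic": current_aic,
                 "candidates": cand_aics}
            )
            break
    selected = np.array(sorted(current), dtype=int)
    if selected.size:
        final = _fit_logistic(X[:, selected], y)
        separation |= final.separated
        coef, intercept = final.coef, final.intercept
    else:
        coef, intercept = np.empty(0), base.intercept
    return StepwiseResult(selected, coef, float(intercept), trace, separation)


def combine_pattern(
    pca: PCAResult,
    selected: Sequence[int],
    coefficients: Sequence[float],
    gmp: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    intercept: float = 0.0,
    pattern_id: str = "pattern",
    derivation: dict | None = None,
) -> CovariancePattern:
    """Linearly combine selected components into a unit-norm pattern.

    Raw weights are ``sum_k coef_k * loading_k``; the signed
    normalization scalar makes the result unit norm and orients it so
    derivation patients have the higher mean raw score.
    """
    selected = np.asarray(sorted(selected), dtype=int)
    coefficients = np.asarray(coefficients, dtype=float)
    if selected.size == 0 or coefficients.shape != (selected.size,):
        raise ValueError("need one coefficient per selected component")
    raw = coefficients @ pca.components[selected]
    norm = np.linalg.norm(raw)
    if norm == 0:
        raise DegenerateDataError("coefficients combine to an all-zero pattern")
    scores = pca.subject_scores[:, selected] @ coefficients
    is_pat = pca.group_labels == "patient"
    is_con = pca.group_labels == "control"
    sign = 1.0
    if is_pat.any() and is_con.any():
        if scores[is_pat].mean() < scores[is_con].mean():
            sign = -1.0
    normalization = sign * norm
    return CovariancePattern(
        weights=raw / normalization,
        mask=mask,
        affine=affine,
        gmp=np.asarray(gmp, dtype=float),
        component_indices=selected,
        coefficients=coefficients,
        intercept=float(intercept),
        variance_fractions=pca.variance_fractions[selected],
        normalization=float(normalization),
        pattern_id=pattern_id,
        derivation=derivation or {},
    )


def _prepare(vs: VolumeSet, config: DeriveConfig) -> VolumeSet:
    if vs.mask.all():
        mask = compute_brain_mask(vs, config.mask_threshold)
        vs = apply_mask(vs, mask)
    return vs


def derive_pattern(
    vs: VolumeSet,
    config: DeriveConfig | None = None,
    allow_pc1_fallback: bool = True,
    pattern_id: str = "pattern",
) -> DerivationResult:
    """Full derivation: mask -> SSM -> PCA -> variance selection ->
    stepwise logistic (AIC) -> weighted component combination.

    If stepwise selection keeps no component the pattern falls back to
    PC1 alone (flagged in the derivation summary) unless
    ``allow_pc1_fallback`` is False, in which case a
    :class:`DegenerateDataError` is raised (the bootstrap uses this to
    count degenerate replicates).
    """
    config = config or DeriveConfig()
    groups = set(vs.group_labels.tolist())
    if not {"control", "patient"} <= groups:
        raise ValueError("derivation cohort must contain both controls and patients")
    vs = _prepare(vs, config)
    rp = ssm_transform(vs, gmp_group=config.gmp_group)
    pca = fit_pca(rp)
    candidates = select_top_variance_components(
        pca.variance_fractions, config.cum_var_threshold
    )
    step = stepwise_logistic_aic(pca.subject_scores[:, candidates], vs.group_labels)
    fallback = False
    if step.selected.size:
        selected = candidates[step.selected]
        coefficients = step.coefficients
        intercept = step.intercept
    else:
        if not allow_pc1_fallback:
            raise DegenerateDataError("stepwise selection kept no component")
        logger.warning("stepwise selection kept no component; falling back to PC1")
        fallback = True
        pc1_fit = _fit_logistic(pca.subject_scores[:, :1], _binary_labels(vs.group_labels))
        selected = np.array([0])
        coefficients = np.array([pc1_fit.coef[0] if pc1_fit.coef[0] != 0 else 1.0])
        intercept = pc1_fit.intercept
    n_con = int((vs.group_labels == "control").sum())
    n_pat = int((vs.group_labels == "patient").sum())
    derivation = {
        "n_controls": n_con,
        "n_patients": n_pat,
        "mode": "stepwise",
        "pc1_fallback": fallback,
        "separation": step.separation,
        "aic_trace": step.aic_trace,
        "candidate_components": candidates.tolist(),
        "software_version": _pkg_version,
    }
    pattern = combine_pattern(
        pca, selected, coefficients, rp.gmp, vs.mask, vs.affine,
        intercept=intercept, pattern_id=pattern_id, derivation=derivation,
    )
    return DerivationResult(pattern, pca, rp)


def derive_pattern_pc1(
    vs: VolumeSet, config: DeriveConfig | None = None, pattern_id: str = "pattern_pc1"
) -> DerivationResult:
    """Derivation variant using principal component 1 in isolation.

    The pattern is PC1's unit-norm loadings, oriented so patients score
    higher; the logistic fit of PC1 alone is retained only for
    reporting (its coefficient does not rescale the pattern).
    """
    config = config or DeriveConfig()
    groups = set(vs.group_labels.tolist())
    if not {"control", "patient"} <= groups:
        raise ValueError("derivation cohort must contain both controls and patients")
    vs = _prepare(vs, config)
    rp = ssm_transform(vs, gmp_group=config.gmp_group)
    pca = fit_pca(rp)
    fit = _fit_logistic(pca.subject_scores[:, :1], _binary_labels(vs.group_labels))
    derivation = {
        "n_controls": int((vs.group_labels == "control").sum()),
        "n_patients": int((vs.group_labels == "patient").sum()),
        "mode": "pc1",
        "pc1_logistic_coefficient": float(fit.coef[0]),
        "pc1_logistic_intercept": float(fit.intercept),
        "separation": fit.separated,
        "software_version": _pkg_version,
    }
    pattern = combine_pattern(
        pca, [0], [1.0], rp.gmp, vs.mask, vs.affine,
        intercept=fit.intercept, pattern_id=pattern_id, derivation=derivation,
    )
    return DerivationResult(pattern, pca, rp)


def stability_from_replicates(
    replicate_weights: np.ndarray, ci_level: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bounds and stability mask from aligned replicate weights.

    One-sided level ``ci_level``: a voxel is stable when its
    ``(1-ci_level)`` quantile is > 0 (consistently positive weight) or
    its ``ci_level`` quantile is < 0 (consistently negative).
    """
    if not (0.5 < ci_level < 1.0):
        raise ValueError("ci_level must lie in (0.5, 1)")
    lower = np.percentile(replicate_weights, 100 * (1 - ci_level), axis=0)
    upper = np.percentile(replicate_weights, 100 * ci_level, axis=0)
    stable = (lower > 0) | (upper < 0)
    return lower, upper, stable


def bootstrap_stability(
    vs: VolumeSet,
    config: DeriveConfig | None = None,
    n_replicates: int = 1000,
    ci_level: float = 0.90,
    seed: int | None = None,
    keep_replicates: bool = False,
    resample: bool = True,
    max_failure_fraction: float = 0.2,
    strict_failures: bool = False,
) -> BootstrapResult:
    """Bootstrap voxel stability of the derived pattern.

    Subjects are resampled with replacement within each group (group
    sizes preserved); the full derivation re-runs per replicate inside
    the original analysis mask; each replicate pattern's sign is
    aligned to the original (flipped if negatively correlated).
    Replicates where stepwise keeps no component are counted as
    failures and skipped.  ``resample=False`` is a test hook that reuses
    the original subjects each replicate.
    """
    config = config or DeriveConfig()
    vs = _prepare(vs, config)
    original = derive_pattern(vs, config)
    w0 = original.pattern.weights
    rng_seed = seed if seed is not None else config.seed
    groups = vs.group_labels
    group_rows = {g: np.flatnonzero(groups == g) for g in dict.fromkeys(groups)}
    weights_list = []
    failures = 0
    for r in range(n_replicates):
        rng = np.random.default_rng([0 if rng_seed is None else rng_seed, r])
        if resample:
            rows = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in group_rows.values()]
            )
        else:
            rows = np.arange(vs.n_subjects)
        rep_vs = vs.subset(rows, subject_ids=[f"b{r}_{i}" for i in range(rows.size)])
        try:
            rep = derive_pattern(rep_vs, config, allow_pc1_fallback=False)
        except DegenerateDataError:
            failures += 1
            continue
        w = rep.pattern.weights
        if np.corrcoef(w, w0)[0, 1] < 0:
            w = -w
        weights_list.append(w)
    if failures > max_failure_fraction * n_replicates:
        msg = (
            f"{failures}/{n_replicates} bootstrap replicates degenerate "
            f"(> {max_failure_fraction:.0%})"
        )
        if strict_failures:
            raise DegenerateDataError(msg)
        warnings.warn(msg, stacklevel=2)
    if not weights_list:
        raise DegenerateDataError("all bootstrap replicates failed")
    W = np.vstack(weights_list)
    lower, upper, stable = stability_from_replicates(W, ci_level)
    return BootstrapResult(
        n_replicates=n_replicates,
        ci_level=ci_level,
        lower_bound=lower,
        upper_bound=upper,
        stable_mask=stable,
        replicate_failures=failures,
        pattern=original.pattern,
        replicate_weights=W if keep_replicates else None,
    )


# ---------------------------------------------------------------------------
# pattern bundle serialization

def save_pattern(pattern: CovariancePattern, directory: str | Path) -> Path:
    """Write a pattern bundle: weights/gmp/mask NIfTIs + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    export_weight_map(pattern.weights, pattern.mask, pattern.affine, directory / "weights.nii.gz")
    export_weight_map(pattern.gmp, pattern.mask, pattern.affine, directory / "gmp.nii.gz")
    import nibabel as nib

    nib.Nifti1Image(pattern.mask.astype(np.uint8), pattern.affine).to_filename(
        str(directory / "mask.nii.gz")
    )
    sidecar = {
        "pattern_id": pattern.pattern_id,
        "component_indices": pattern.component_indices.tolist(),
        "coefficients": np.asarray(pattern.coefficients).tolist(),
        "intercept": pattern.intercept,
        "variance_fractions": np.asarray(pattern.variance_fractions).tolist(),
        "normalization": pattern.normalization,
        "derivation": pattern.derivation,
    }
    (directory / "pattern.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_pattern(directory: str | Path) -> CovariancePattern:
    directory = Path(directory)
    import nibabel as nib

    mask_img = nib.load(str(directory / "mask.nii.gz"))
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    affine = np.asarray(mask_img.affine)
    weights = load_weight_map(directory / "weights.nii.gz", mask)
    gmp = load_weight_map(directory / "gmp.nii.gz", mask)
    meta = json.loads((directory / "pattern.json").read_text())
    return CovariancePattern(
        weights=weights / np.linalg.norm(weights),  # guard float round-trip drift
        mask=mask,
        affine=affine,
        gmp=gmp,
        component_indices=np.asarray(meta["component_indices"], dtype=int),
        coefficients=np.asarray(meta["coefficients"], dtype=float),
        intercept=float(meta["intercept"]),
        variance_fractions=np.asarray(meta["variance_fractions"], dtype=float),
        normalization=float(meta["normalization"]),
        pattern_id=meta.get("pattern_id", "pattern"),
        derivation=meta.get("derivation", {}),
    )
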