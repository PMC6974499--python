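"""Stepwise component selection, pattern combination and the bootstrap."""

import numpy as np
import pytest

from ssmpca import (
    apply_mask,
    combine_pattern,
    compute_brain_mask,
    derive_pattern,
    derive_pattern_pc1,
    bootstrap_stability,
    fit_pca,
    load_pattern,
    save_pattern,
    score_subjects,
    ssm_transform,
    stepwise_logistic_aic,
)
from ssmpca.exceptions import DegenerateDataError
from ssmpca.pattern_derivation import stability_from_replicates
from ssmpca.scoring import score_cohort
from ssmpca.validation import roc_auc
from tests.conftest import small_spec
from ssmpca import generate_cohort


def _labels(n_con, n_pat):
    return np.array(["control"] * n_con + ["patient"] * n_pat, dtype=object)


class TestStepwiseLogisticAIC:
    def test_useless_candidate_not_selected(self):
        """A candidate identical across groups costs +2 AIC with no
        likelihood gain, so the intercept-only model wins."""
        labels = _labels(10, 10)
        scores = np.ones((20, 1))
        result = stepwise_logistic_aic(scores, labels)
        assert result.selected.size == 0
        assert result.coefficients.size == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_forward_path_matches_exhaustive_search(self, seed):
        """One strongly separating candidate among noise: the greedy
        forward path lands on the exhaustive subset-AIC optimum."""
        rng = np.random.default_rng(seed)
        labels = _labels(20, 20)
        y = (labels == "patient").astype(float)
        X = rng.standard_normal((40, 4))
        X[:, 1] += 2.0 * y  # strong group shift on candidate 1
        X = (X - X.mean(0)) / X.std(0)
        result = stepwise_logistic_aic(X, labels)
        from tests.oracles import exhaustive_best_subset

        oracle_set, oracle_aic = exhaustive_best_subset(X, y)
        assert set(result.selected.tolist()) == oracle_set
        assert result.aic_trace[-1]["aic"] == pytest.approx(oracle_aic, abs=1e-4)

    def test_perfect_separation_flagged_and_handled(self):
        labels = _labels(10, 10)
        x = np.concatenate([np.linspace(-2, -1, 10), np.linspace(1, 2, 10)])
        result = stepwise_logistic_aic(x[:, None], labels)
        assert result.separation
        assert 0 in result.selected.tolist()
        # penalized fallback preserves the monotone score ordering
        assert result.coefficients[0] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stepwise_logistic_aic(np.random.default_rng(0).standard_normal((8, 2)),
                                  np.array(["control"] * 8, dtype=object))


def _toy_pca(n_voxels=40, n_subjects=10, seed=0):
    """PCAResult-like object with orthonormal loadings for combination tests."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_voxels, 3)))
    components = q.T
    scores = rng.standard_normal((n_subjects, 3))
    from ssmpca.ssm_core import PCAResult

    return PCAResult(
        components=components,
        eigenvalues=np.array([3.0, 2.0, 1.0]),
        variance_fractions=np.array([0.5, 0.33, 0.17]),
        subject_scores=scores,
        subject_ids=[f"s{i}" for i in range(n_subjects)],
        group_labels=_labels(5, 5),
        camera_labels=np.array(["cam0"] * n_subjects, dtype=object),
    )


def _combine(pca, selected, coefs):
    mask = np.ones((5, 4, 2), dtype=bool)
    return combine_pattern(pca, selected, coefs, np.zeros(40), mask, np.eye(4))


class TestCombinePattern:
    def test_single_component_reproduces_loadings(self):
        pca = _toy_pca()
        pattern = _combine(pca, [0], [2.5])
        assert abs(abs(pattern.weights @ pca.components[0]) - 1) < 1e-10

    def test_zero_coefficient_component_is_inert(self):
        pca = _toy_pca()
        a = _combine(pca, [0], [2.5])
        b = _combine(pca, [0, 1], [2.5, 0.0])
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_pythagorean_combination(self):
        """Coefficients (3, 4) on orthonormal loadings combine with norm
        5; the unit pattern is (3/5, 4/5) of the two loadings."""
        pca = _toy_pca()
        pattern = _combine(pca, [0, 1], [3.0, 4.0])
        expected = 0.6 * pca.components[0] + 0.8 * pca.components[1]
        sign = np.sign(pattern.weights @ expected)
        np.testing.assert_allclose(pattern.weights, sign * expected, atol=1e-10)
        assert abs(pattern.normalization) == pytest.approx(5.0, abs=1e-10)

    def test_positive_rescaling_leaves_pattern_unchanged(self):
        pca = _toy_pca()
        a = _combine(pca, [0, 2], [1.0, -0.5])
        b = _combine(pca, [0, 2], [7.0, -3.5])
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_all_zero_combination_rejected(self):
        with pytest.raises((DegenerateDataError, ValueError)):
            _combine(_toy_pca(), [0], [0.0])


class TestDerivePattern:
    def test_recovers_truth_in_low_noise_limit(self):
        vs, truth = generate_cohort(small_spec(voxel_noise_sd=0.001, seed=21))
        pattern = derive_pattern(vs).pattern
        r = np.corrcoef(pattern.weights, truth.pattern_in_mask(pattern.mask))[0, 1]
        assert abs(r) >= 0.99

    def test_orientation_and_norm(self, small_cohort, small_pattern):
        vs, _ = small_cohort
        assert np.linalg.norm(small_pattern.weights) == pytest.approx(1.0, abs=1e-8)
        raw = score_subjects(vs, small_pattern)
        is_pat = vs.group_labels == "patient"
        assert raw[is_pat].mean() >= raw[~is_pat].mean()

    def test_permuted_labels_yield_chance_discrimination(self):
        """With group labels shuffled, whatever pattern emerges should
        not discriminate on an independent cohort."""
        vs, _ = generate_cohort(small_spec(seed=31))
        rng = np.random.default_rng(5)
        perm = vs.subset(rng.permutation(vs.n_subjects))
        perm = perm.__class__(
            data=vs.data, mask=vs.mask, affine=vs.affine,
            subject_ids=vs.subject_ids,
            group_labels=perm.group_labels,  # shuffled labels, original data
            camera_labels=vs.camera_labels,
        )
        pattern = derive_pattern(perm).pattern
        vs_val, _ = generate_cohort(small_spec(seed=32))
        scored = score_cohort(vs_val, pattern)
        z = np.concatenate([s.z for s in scored.values()])
        labels = np.concatenate([s.group_labels for s in scored.values()])
        assert 0.2 <= roc_auc(z, labels) <= 0.8

    def test_duplicating_subjects_preserves_component_subspace(self, small_cohort):
        vs, _ = small_cohort
        masked = apply_mask(vs, compute_brain_mask(vs))
        pca = fit_pca(ssm_transform(masked))
        dup = masked.subset(
            np.repeat(np.arange(masked.n_subjects), 2),
            subject_ids=[f"d{i}" for i in range(2 * masked.n_subjects)],
        )
        pca_dup = fit_pca(ssm_transform(dup))
        originals = pca_dup.subject_scores[::2]
        for k in range(3):
            r = np.corrcoef(originals[:, k], pca.subject_scores[:, k])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)


class TestDerivePatternPC1:
    def test_matches_stepwise_when_pc1_carries_the_signal(self):
        vs, _ = generate_cohort(small_spec(voxel_noise_sd=0.001, seed=41))
        full = derive_pattern(vs).pattern
        pc1 = derive_pattern_pc1(vs).pattern
        r = np.corrcoef(full.weights, pc1.weights)[0, 1]
        assert abs(r) >= 0.99

    def test_unit_norm_and_orientation(self, small_cohort):
        vs, _ = small_cohort
        pattern = derive_pattern_pc1(vs).pattern
        assert np.linalg.norm(pattern.weights) == pytest.approx(1.0, abs=1e-8)
        raw = score_subjects(vs, pattern)
        is_pat = vs.group_labels == "patient"
        assert raw[is_pat].mean() >= raw[~is_pat].mean()
        np.testing.assert_array_equal(pattern.component_indices, [0])


class TestBootstrapStability:
    def test_disabled_resampling_collapses_bounds(self, small_cohort):
        vs, _ = small_cohort
        result = bootstrap_stability(vs, n_replicates=2, resample=False, seed=0)
        np.testing.assert_allclose(result.lower_bound, result.upper_bound, atol=1e-12)
        np.testing.assert_allclose(result.lower_bound, result.pattern.weights, atol=1e-12)
        expected_stable = result.pattern.weights != 0
        np.testing.assert_array_equal(result.stable_mask, expected_stable)

    def test_stable_mask_independent_of_subject_ids(self, small_cohort):
        vs, _ = small_cohort
        renamed = vs.subset(np.arange(vs.n_subjects),
                            subject_ids=[f"x{i}" for i in range(vs.n_subjects)])
        a = bootstrap_stability(vs, n_replicates=6, seed=3)
        b = bootstrap_stability(renamed, n_replicates=6, seed=3)
        np.testing.assert_array_equal(a.stable_mask, b.stable_mask)

    def test_determinism(self, small_cohort):
        vs, _ = small_cohort
        a = bootstrap_stability(vs, n_replicates=5, seed=9)
        b = bootstrap_stability(vs, n_replicates=5, seed=9)
        np.testing.assert_array_equal(a.stable_mask, b.stable_mask)
        np.testing.assert_array_equal(a.lower_bound, b.lower_bound)

    def test_stability_antimonotone_in_ci_level(self, small_cohort):
        vs, _ = small_cohort
        result = bootstrap_stability(vs, n_replicates=24, seed=2, keep_replicates=True)
        previous = None
        for ci in (0.80, 0.90, 0.95):
            _, _, stable = stability_from_replicates(result.replicate_weights, ci)
            if previous is not None:
                assert not np.any(stable & ~previous), "raising CI level added voxels"
            previous = stable


class TestPatternBundleIO:
    def test_save_load_round_trip(self, small_pattern, tmp_path):
        save_pattern(small_pattern, tmp_path / "bundle")
        loaded = load_pattern(tmp_path / "bundle")
        np.testing.assert_allclose(loaded.weights, small_pattern.weights, atol=1e-6)
        np.testing.assert_allclose(loaded.gmp, small_pattern.gmp, atol=1e-6)
        np.testing.assert_array_equal(loaded.mask, small_pattern.mask)
        np.testing.assert_array_equal(loaded.component_indices,
                                      small_pattern.component_indices)
        assert loaded.normalization == pytest.approx(small_pattern.normalization)
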