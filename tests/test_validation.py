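"""Discrimination statistics (AUC, t test, correlation) and VOI comparison."""

import numpy as np
import pytest

from ssmpca import compare_patterns, correlate, group_compare, roc_auc, voi_region_weights
from ssmpca.exceptions import DegenerateDataError
from ssmpca.pattern_derivation import CovariancePattern
from ssmpca.volume_io import VOIAtlas


def _labels(n_con, n_pat):
    return np.array(["control"] * n_con + ["patient"] * n_pat, dtype=object)


def _pair_count_auc(controls, patients):
    """Oracle: count control-patient pairs the patient wins (+ half ties)."""
    wins = sum(
        1.0 if p > c else 0.5 if p == c else 0.0
        for c in controls
        for p in patients
    )
    return wins / (len(controls) * len(patients))


class TestRocAuc:
    def test_perfect_separation(self):
        z = np.array([0.0, 1.0, 2.0, 3.0])
        assert roc_auc(z, _labels(2, 2)) == 1.0

    def test_all_ties_give_half(self):
        z = np.full(6, 1.5)
        assert roc_auc(z, _labels(3, 3)) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        # coarse rounding induces ties
        z = np.round(rng.standard_normal(16), 1)
        labels = _labels(8, 8)
        expected = _pair_count_auc(z[:8], z[8:])
        assert roc_auc(z, labels) == pytest.approx(expected, abs=1e-12)

    def test_negation_complements(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(14)  # ties almost surely absent
        labels = _labels(7, 7)
        assert roc_auc(z, labels) + roc_auc(-z, labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(12)
        labels = _labels(6, 6)
        assert roc_auc(np.exp(3 * z), labels) == pytest.approx(roc_auc(z, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(4), np.array(["control"] * 4, dtype=object))


class TestGroupCompare:
    def test_identical_distributions(self):
        z = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        t, p = group_compare(z, _labels(3, 3))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(12)
        labels = _labels(6, 6)
        t1, p1 = group_compare(z, labels)
        t2, p2 = group_compare(z, labels[::-1].copy())
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_pooled_variance_formula(self):
        """Textbook pooled-variance Student t evaluated directly."""
        controls = np.array([1.0, 2.0, 3.0, 4.0])
        patients = np.array([3.0, 5.0, 6.0, 8.0])
        z = np.concatenate([controls, patients])
        t, _ = group_compare(z, _labels(4, 4))
        n1, n2 = 4, 4
        sp2 = ((n1 - 1) * controls.var(ddof=1) + (n2 - 1) * patients.var(ddof=1)) / (n1 + n2 - 2)
        expected = (patients.mean() - controls.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert t == pytest.approx(expected, abs=1e-12)

    def test_zero_pooled_variance_rejected(self):
        z = np.array([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(DegenerateDataError):
            group_compare(z, _labels(2, 2))


class TestCorrelate:
    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = correlate(x, -x)
        assert r2 == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 20))
        r, _ = correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            correlate(np.ones(5), np.arange(5.0))

    def test_length_contract(self):
        with pytest.raises(ValueError):
            correlate(np.ones(2), np.ones(2))


def _pattern_from_weights(weights, mask):
    return CovariancePattern(
        weights=weights / np.linalg.norm(weights), mask=mask, affine=np.eye(4),
        gmp=np.zeros(int(mask.sum())), component_indices=np.array([0]),
        coefficients=np.array([1.0]), intercept=0.0,
        variance_fractions=np.array([1.0]), normalization=1.0,
    )


class TestVOIRegionWeights:
    def _atlas(self, grid=(4, 4, 4)):
        labels = np.zeros(grid, dtype=np.int16)
        labels[:2, :2, :] = 1
        labels[2:, :2, :] = 2
        labels[:, 3, 0] = 3
        return VOIAtlas(labels=labels, names={1: "a", 2: "b", 3: "c"})

    def test_constant_pattern_gives_constant_weights(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        pattern = _pattern_from_weights(np.ones(64), mask)
        weights = voi_region_weights(pattern, self._atlas())
        c = pattern.weights[0]
        assert all(w == pytest.approx(c) for w in weights)

    def test_single_voxel_region(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        rng = np.random.default_rng(0)
        pattern = _pattern_from_weights(rng.standard_normal(64), mask)
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[1, 2, 3] = 9
        atlas = VOIAtlas(labels=labels, names={9: "pin"})
        w = voi_region_weights(pattern, atlas)
        vol = np.zeros((4, 4, 4))
        vol[mask] = pattern.weights
        assert w["pin"] == pytest.approx(vol[1, 2, 3])

    def test_matches_bruteforce_label_averaging(self):
        rng = np.random.default_rng(1)
        mask = rng.uniform(size=(4, 4, 4)) > 0.3
        pattern = _pattern_from_weights(rng.standard_normal(int(mask.sum())), mask)
        atlas = self._atlas()
        got = voi_region_weights(pattern, atlas)
        vol = np.zeros((4, 4, 4))
        vol[mask] = pattern.weights
        for label, name in atlas.names.items():
            sel = (atlas.labels == label) & mask
            if sel.any():
                assert got[name] == pytest.approx(vol[sel].mean(), abs=1e-12)
            else:
                assert name not in got.index

    def test_region_outside_mask_reported_missing(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        mask[:, 3, 0] = False  # removes region "c" entirely
        rng = np.random.default_rng(2)
        pattern = _pattern_from_weights(rng.standard_normal(int(mask.sum())), mask)
        weights = voi_region_weights(pattern, self._atlas())
        assert "c" not in weights.index and {"a", "b"} <= set(weights.index)


class TestComparePatterns:
    def _setup(self):
        rng = np.random.default_rng(7)
        mask = np.ones((5, 5, 4), dtype=bool)
        labels = (rng.integers(0, 6, size=(5, 5, 4))).astype(np.int16)
        atlas = VOIAtlas(labels=labels, names={k: f"r{k}" for k in range(1, 6)})
        a = _pattern_from_weights(rng.standard_normal(100), mask)
        b = _pattern_from_weights(rng.standard_normal(100), mask)
        return a, b, atlas

    def test_self_similarity_is_one(self):
        a, _, atlas = self._setup()
        report = compare_patterns(a, a, atlas)
        assert report.region_weight_correlation == pytest.approx(1.0)

    def test_negation_similarity_is_minus_one(self):
        a, _, atlas = self._setup()
        neg = _pattern_from_weights(-a.weights, a.mask)
        report = compare_patterns(a, neg, atlas)
        assert report.region_weight_correlation == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        a, b, atlas = self._setup()
        ab = compare_patterns(a, b, atlas)
        ba = compare_patterns(b, a, atlas)
        assert ab.region_weight_correlation == pytest.approx(
            ba.region_weight_correlation, abs=1e-12
        )
        assert ab.n_regions == ba.n_regions
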