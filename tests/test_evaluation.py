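"""Similarity metrics, ROI metrics and paired statistics against
independent oracles (hand evaluation, exhaustive enumeration, brute force)."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from rpgdwi import (
    AP,
    ROIMask,
    Volume,
    average_hausdorff,
    bland_altman,
    centroid_distance,
    dice,
    evaluate_dataset,
    mutual_information,
    structural_reference,
    wilcoxon_signed_rank,
)


def _vol(arr):
    return Volume(np.asarray(arr, dtype=float), (1, 1, 1))


def _mask(arr, spacing=(1, 1, 1)):
    return ROIMask(np.asarray(arr, dtype=bool), "m", spacing)


class TestMutualInformation:
    def test_hand_computed_two_bin_table(self):
        """Joint counts {(0,0):2,(0,1):1,(1,0):1,(1,1):2} give
        MI = 2*(2/6)ln((2/6)/(1/4)) + 2*(1/6)ln((1/6)/(1/4)) = 0.0566 nats."""
        a = _vol(np.array([0, 0, 0, 1, 1, 1]).reshape(1, 1, 6))
        b = _vol(np.array([0, 0, 1, 0, 1, 1]).reshape(1, 1, 6))
        expected = 2 * (2 / 6) * np.log((2 / 6) / 0.25) + 2 * (1 / 6) * np.log((1 / 6) / 0.25)
        assert mutual_information(a, b, n_bins=2) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0566, abs=5e-5)

    def test_self_information_is_entropy(self, rng):
        data = rng.integers(0, 8, (12, 12, 4)).astype(float)
        v = _vol(data)
        counts = np.bincount(data.astype(int).ravel(), minlength=8)
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(v, v, n_bins=8) == pytest.approx(entropy, abs=1e-12)

    def test_independent_images_near_zero(self, rng):
        # histogram-MI bias is ~(bins-1)^2 / (2 n); with 32 bins at 32^3
        # voxels the estimate of independent images must be close to zero
        a = _vol(rng.random((32, 32, 32)))
        b = _vol(rng.random((32, 32, 32)))
        mi = mutual_information(a, b, n_bins=32)
        assert 0 <= mi < 0.05
        # and it shrinks toward 0 as the sample grows
        c = _vol(rng.random((48, 48, 48)))
        d = _vol(rng.random((48, 48, 48)))
        assert mutual_information(c, d, n_bins=32) < mi

    def test_symmetry(self, rng):
        a = _vol(rng.random((10, 10, 5)))
        b = _vol(rng.normal(size=(10, 10, 5)))
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a), abs=1e-12)

    def test_constant_image_warns_zero(self, rng):
        a = _vol(np.ones((4, 4, 4)))
        b = _vol(rng.random((4, 4, 4)))
        with pytest.warns(UserWarning):
            assert mutual_information(a, b) == 0.0


class TestMaskMetrics:
    def test_dice_identical_disjoint_half(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:3, 1:3, 1] = True  # 4 voxels
        other = np.zeros_like(m)
        other[1:3, 1, 1] = True
        other[4, 4, 4] = True
        other[5, 5, 5] = True  # |B| = 4, overlap 2
        assert dice(_mask(m), _mask(m)) == 1.0
        assert dice(_mask(m), _mask(np.roll(m, 3, axis=0))) == 0.0
        assert dice(_mask(m), _mask(other)) == 0.5

    def test_dice_both_empty_rejected(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            dice(_mask(empty), _mask(empty))

    def test_centroid_distance_spacing_aware(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros_like(a)
        a[2, 2, 2] = True
        b[5, 2, 2] = True  # 3 voxels, 2 mm spacing -> 6 mm
        assert centroid_distance(_mask(a, (2, 2, 2)), _mask(b, (2, 2, 2))) == pytest.approx(6.0)

    def test_centroid_matches_bruteforce(self, rng):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros_like(a)
        a[tuple(rng.integers(0, 10, (3, 10)))] = True
        b[tuple(rng.integers(0, 10, (3, 10)))] = True
        sp = (1.5, 2.0, 3.0)
        ca = np.mean(np.argwhere(a), axis=0) * sp
        cb = np.mean(np.argwhere(b), axis=0) * sp
        assert centroid_distance(_mask(a, sp), _mask(b, sp)) == pytest.approx(
            float(np.linalg.norm(ca - cb))
        )

    def test_avd_identical_and_two_points(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:4, 2:4, 2:4] = True
        assert average_hausdorff(_mask(m), _mask(m)) == 0.0
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros_like(a)
        a[1, 1, 1] = True
        b[1, 1, 6] = True  # 5 voxels apart at 1 mm
        assert average_hausdorff(_mask(a), _mask(b)) == pytest.approx(5.0)

    def test_avd_matches_bruteforce_on_blobs(self, rng):
        """AVD equals the O(n^2) exhaustive surface-distance computation."""
        a = np.zeros((12, 12, 12), dtype=bool)
        b = np.zeros_like(a)
        a[3:6, 3:6, 3:6] = True
        b[5:9, 4:8, 5:8] = True
        sp = (2.0, 1.0, 3.0)

        def surface(m):
            pts = []
            for idx in np.argwhere(m):
                for ax in range(3):
                    for dd in (-1, 1):
                        j = idx.copy()
                        j[ax] += dd
                        if (j < 0).any() or (j >= 12).any() or not m[tuple(j)]:
                            pts.append(idx)
                            break
                    else:
                        continue
                    break
            return np.asarray(pts) * sp

        sa, sb = surface(a), surface(b)
        d_ab = np.mean([min(np.linalg.norm(p - q) for q in sb) for p in sa])
        d_ba = np.mean([min(np.linalg.norm(p - q) for q in sa) for p in sb])
        expected = 0.5 * (d_ab + d_ba)
        assert average_hausdorff(_mask(a, sp), _mask(b, sp)) == pytest.approx(expected)

    def test_metric_symmetry(self, rng):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros_like(a)
        a[2:5, 2:5, 2:5] = True
        b[4:8, 3:6, 4:7] = True
        ma, mb = _mask(a, (1, 2, 1)), _mask(b, (1, 2, 1))
        assert dice(ma, mb) == dice(mb, ma)
        assert centroid_distance(ma, mb) == centroid_distance(mb, ma)
        assert average_hausdorff(ma, mb) == average_hausdorff(mb, ma)


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1, 2, 3], [1, 2, 3])
        assert res["bias"] == 0 and res["loa_low"] == 0 and res["loa_high"] == 0

    def test_constant_offset_orientation(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x + 5.0)
        assert res["bias"] == pytest.approx(-5.0)
        assert res["loa_high"] - res["loa_low"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # diffs {1,2,3}: bias 2, sd 1, LoA (0.04, 3.96)
        res = bland_altman([2, 4, 6], [1, 2, 3])
        assert res["bias"] == pytest.approx(2.0)
        assert res["loa_low"] == pytest.approx(0.04)
        assert res["loa_high"] == pytest.approx(3.96)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])


def _enumerate_wilcoxon_p(diffs):
    """Independent oracle: exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    for v in np.unique(absd):
        tie = absd == v
        if tie.sum() > 1:
            ranks[tie] = ranks[tie].mean()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    count = sum(
        1
        for signs in itertools.product((0, 1), repeat=n)
        if min((s := np.dot(ranks, signs)), total - s) <= w_obs + 1e-12
    )
    return count / 2.0**n


class TestWilcoxon:
    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res["p_two_sided"] == 1.0

    def test_all_positive_n6(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        assert res["W"] == 0.0
        assert res["p_two_sided"] == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        # continuous values: no ties, exact path applies
        diffs = rng.normal(size=n) * 3
        res = wilcoxon_signed_rank(diffs)
        assert res["p_two_sided"] == pytest.approx(_enumerate_wilcoxon_p(diffs), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_path_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        ours = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, mode="exact", alternative="two-sided")
        assert ours["p_two_sided"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.8, size=40) + 0.3
        ours = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, correction=True, mode="approx", alternative="two-sided")
        assert ours["p_two_sided"] == pytest.approx(ref.pvalue, rel=0.02)

    def test_p_in_unit_interval_with_ties(self):
        res = wilcoxon_signed_rank([1, 1, 1, -1, 2, 2, -2, 3, 3, 3, -3, 4, 4, 5])
        assert 0.0 <= res["p_two_sided"] <= 1.0


@pytest.fixture(scope="module")
def report_identical_conditions(tiny_truth, tiny_acquisition):
    """Corrected inputs identical to the uncorrected ones: all ADC
    differences must vanish and the paired test must be degenerate."""
    ap = [s for s in tiny_acquisition if s.polarity is AP]
    structural = structural_reference(tiny_truth, upsample_inplane=1.0)
    rois = {
        name: tiny_truth.labels == lab
        for lab, name in tiny_truth.label_names.items()
        if lab >= 2
    }
    with pytest.warns(UserWarning):  # DC-b50 missing -> partial report
        report = evaluate_dataset(
            ap, ap, None, structural, masks={}, adc_rois=rois,
            n_overlap=tiny_truth.cfg.n_overlap,
        )
    return report, ap, rois


class TestEvaluateDataset:
    def test_identical_conditions_zero_delta_and_p_one(self, report_identical_conditions):
        report, _, _ = report_identical_conditions
        deltas = report.values("dADC_mean", "DC-b0")
        assert deltas and all(v == 0.0 for v in deltas.values())
        adc_tests = [t for t in report.test_results if t["comparison"].startswith("ADC")]
        assert adc_tests and all(t["p_value"] == 1.0 for t in adc_tests)

    def test_record_count_bookkeeping(self, report_identical_conditions):
        report, ap, rois = report_identical_conditions
        n_stations = len(ap)
        n_conditions = 2  # NC and DC-b0 present
        n_rois = len(rois)
        expected = (
            n_stations * n_conditions          # MI rows
            + n_rois * n_conditions            # ADC_mean rows
            + n_rois                           # dADC rows (one comparison)
        )
        assert len(report.records) == expected

    def test_mi_equal_for_identical_conditions(self, report_identical_conditions):
        report, _, _ = report_identical_conditions
        assert report.values("MI", "NC") == report.values("MI", "DC-b0")
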