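"""Metrics: DSC arithmetic and symmetry, confusion-matrix metrics on
hand-counted toys, stage aggregation rules and the sensitivity matrix layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastoseg.evaluate import (ImageEvaluation, SENSITIVITY_COLUMNS,
                                SENSITIVITY_ROWS, all_regions_dsc, dsc,
                                region_metrics, sensitivity_analysis,
                                stage_report)
from blastoseg.preprocess import Micrograph


class TestDSC:
    def test_identical_nonempty_masks_score_one(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2], b[8:] = True, True
        assert dsc(a, b) == 0.0

    def test_half_overlap_scores_half(self):
        # |a| = |b| = 100 with 50 shared pixels -> 2*50 / 200 = 0.5
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        empty = np.zeros((5, 5), bool)
        assert dsc(empty, empty) == 1.0
        assert dsc(empty, empty, both_empty=0.0) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        d1, d2 = dsc(a, b), dsc(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0
        if np.array_equal(a, b):
            assert d1 == 1.0


class TestRegionMetrics:
    def test_perfect_prediction(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[3:7, 3:7] = 2
        m = region_metrics(gt, gt, "TE")
        assert (m.dsc, m.sensitivity, m.specificity, m.precision, m.accuracy) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_complement_has_zero_sensitivity(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[:5] = 2
        pred = np.where(gt == 2, 0, 2).astype(np.uint8)
        m = region_metrics(pred, gt, "TE")
        assert m.sensitivity == 0.0

    def test_hand_counted_confusion(self):
        """TP=30, FP=10, FN=20, TN=40 on a 10x10 grid."""
        gt = np.zeros(100, dtype=np.uint8)
        pred = np.zeros(100, dtype=np.uint8)
        gt[:50] = 2                       # 50 positives
        pred[:30] = 2                     # 30 of them predicted
        pred[50:60] = 2                   # 10 false positives
        m = region_metrics(pred.reshape(10, 10), gt.reshape(10, 10), "TE")
        assert (m.tp, m.fp, m.fn, m.tn) == (30, 10, 20, 40)
        assert m.precision == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.dsc == pytest.approx(2 / 3)

    def test_counts_cover_grid(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 5, (12, 12)).astype(np.uint8)
        gt = rng.integers(0, 5, (12, 12)).astype(np.uint8)
        m = region_metrics(pred, gt, "ICM")
        assert m.tp + m.fp + m.fn + m.tn == 144

    def test_undefined_ratio_is_missing_not_zero(self):
        gt = np.zeros((6, 6), dtype=np.uint8)      # no ICM anywhere
        pred = np.zeros((6, 6), dtype=np.uint8)
        m = region_metrics(pred, gt, "ICM")
        assert m.sensitivity is None
        assert m.precision is None


class TestStageReport:
    def make_eval(self, image_id, stage, icm_present, icm_after, all_after=0.9):
        per = {"BG": 0.9, "ZP": 0.8, "TE": 0.7, "BC": 0.85, "ICM": icm_after,
               "All": all_after}
        return ImageEvaluation(image_id=image_id, stage=stage,
                               icm_present=icm_present,
                               dsc_before=dict(per), dsc_after=dict(per))

    def test_single_perfect_image(self):
        per = {k: 1.0 for k in ("BG", "ZP", "TE", "BC", "ICM", "All")}
        e = ImageEvaluation("a", "expansion", True, dict(per), dict(per))
        report = stage_report([e])
        assert (report["all_mean"] == 1.0).all()
        assert (report["all_std"] == 0.0).all()

    def test_icm2_excludes_missing_ground_truth(self):
        evals = [self.make_eval("a", "expansion", False, 0.0),
                 self.make_eval("b", "expansion", True, 0.8)]
        report = stage_report(evals)
        assert report.loc["ICM", "all_mean"] == pytest.approx(0.4)
        assert report.loc["ICM2", "all_mean"] == pytest.approx(0.8)

    def test_empty_group_omitted_with_warning(self):
        evals = [self.make_eval("a", "expansion", True, 0.5),
                 self.make_eval("b", "expansion", True, 0.6),
                 self.make_eval("c", "hatching", True, 0.7)]
        with pytest.warns(UserWarning, match="hatched"):
            report = stage_report(evals)
        assert "hatched_mean" not in report.columns
        assert "hatching_mean" in report.columns

    def test_means_within_value_range(self):
        evals = [self.make_eval(str(i), "expansion", True, 0.2 + 0.1 * i)
                 for i in range(5)]
        report = stage_report(evals)
        icm_vals = [0.2 + 0.1 * i for i in range(5)]
        assert min(icm_vals) <= report.loc["ICM", "all_mean"] <= max(icm_vals)


class TestSensitivityMatrix:
    @pytest.fixture(scope="class")
    def table(self, expansion_phantom):
        """A model-free segmenter (intensity thresholds) exercises the full
        harness quickly."""
        image, _ = expansion_phantom

        def segment(img):
            labels = np.zeros(img.shape, dtype=np.uint8)
            labels[img > 100] = 2
            labels[img > 180] = 1
            return labels

        m = Micrograph(intensities=image, pixel_size_um=1.0)
        return sensitivity_analysis([m], segment)

    def test_layout(self, table):
        assert isinstance(table, pd.DataFrame)
        assert list(table.index) == list(SENSITIVITY_ROWS)
        assert list(table.columns) == list(SENSITIVITY_COLUMNS)
        assert table.shape == (15, 6)                 # reference + 14 variants

    def test_identity_row_is_all_ones(self, table):
        assert (table.loc["0D"] == 1.0).all()

    def test_geometric_rows_near_one_for_equivariant_segmenter(self, table):
        # a pointwise-threshold segmenter commutes with rotations/flips
        for row in ("90D", "180D", "270D", "H-", "V-", "HV-"):
            assert table.loc[row, "All"] == pytest.approx(1.0)

    def test_values_bounded(self, table):
        assert ((table.values >= 0) & (table.values <= 1)).all()


def test_all_regions_dsc_is_agreement_fraction():
    rng = np.random.default_rng(0)
    pred = rng.integers(0, 5, (16, 16)).astype(np.uint8)
    gt = rng.integers(0, 5, (16, 16)).astype(np.uint8)
    assert all_regions_dsc(pred, gt) == pytest.approx((pred == gt).mean())
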