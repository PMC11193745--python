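"""Confusion metrics, degenerate conventions, and stratified estimators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import croplandsyn as cs
from croplandsyn.accuracy import Stratum, StratifiedDesign

from conftest import make_grid

counts = st.integers(min_value=0, max_value=500)


def sklearn_metrics(tp, fp, fn, tn):
    """Independent re-derivation of the five scores via scikit-learn."""
    from sklearn.metrics import (accuracy_score, f1_score, matthews_corrcoef,
                                 precision_score, recall_score)
    y = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
    yh = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
    return dict(oa=accuracy_score(y, yh),
                pa=recall_score(y, yh, zero_division=0),
                ua=precision_score(y, yh, zero_division=0),
                f1=f1_score(y, yh, zero_division=0),
                mcc=matthews_corrcoef(y, yh))


class TestMetrics:
    def test_against_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 60, 4))
            m = cs.metrics(cs.ConfusionCounts(tp, fp, fn, tn))
            ref = sklearn_metrics(tp, fp, fn, tn)
            for k, v in ref.items():
                assert abs(getattr(m, k) - v) <= 1e-12, (k, tp, fp, fn, tn)

    def test_perfect_classifier(self):
        m = cs.metrics(cs.ConfusionCounts(7, 0, 0, 13))
        assert (m.oa, m.pa, m.ua, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_degenerate_conventions(self):
        # no true positives and no mapped positives: PA, F1, MCC fall back to 0
        m = cs.metrics(cs.ConfusionCounts(0, 0, 5, 20))
        assert m.pa == 0 and m.f1 == 0 and m.mcc == 0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            cs.metrics(cs.ConfusionCounts(0, 0, 0, 0))

    def test_error_complements(self):
        m = cs.metrics(cs.ConfusionCounts(30, 10, 20, 40))
        assert m.oe == pytest.approx(1 - m.pa)
        assert m.ce == pytest.approx(1 - m.ua)

    @given(counts, counts, counts, counts)
    def test_mcc_and_oa_invariant_under_class_swap(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        a = cs.metrics(cs.ConfusionCounts(tp, fp, fn, tn))
        b = cs.metrics(cs.ConfusionCounts(tn, fn, fp, tp))  # swap classes
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.oa == pytest.approx(b.oa, abs=1e-12)

    @given(counts, counts, counts, counts)
    def test_pa_ua_swap_under_transpose(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        a = cs.metrics(cs.ConfusionCounts(tp, fp, fn, tn))
        b = cs.metrics(cs.ConfusionCounts(tp, fn, fp, tn))  # transpose matrix
        assert a.pa == pytest.approx(b.ua, abs=1e-12)
        assert a.ua == pytest.approx(b.pa, abs=1e-12)


class TestConfusionFromSamples:
    def test_single_sample_at_pixel_center(self):
        g = make_grid(np.ones((2, 2)))
        x, y = g.spec.cell_center(0, 0)
        cm = cs.confusion_from_samples(g, ([x], [y], [1]))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 0)

    def test_all_commission_on_all_one_map(self):
        g = make_grid(np.ones((4, 4)))
        rows, cols = np.divmod(np.arange(10), 4)
        x, y = g.spec.cell_center(rows, cols)
        cm = cs.confusion_from_samples(g, (x, y, np.zeros(10)))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 10, 0, 0)

    def test_matches_brute_force_loop(self, small_scene, labeled_pool):
        g = small_scene.products[0]
        cm = cs.confusion_from_samples(g, labeled_pool)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for _, p in labeled_pool.df.iterrows():
            col = int((p.x - g.spec.origin_x) // g.spec.pixel_size)
            row = int((g.spec.origin_y - p.y) // g.spec.pixel_size)
            pred = g.labels[row, col]
            if pred == g.nodata_code:
                continue
            key = ("t" if pred == p.label else "f") + ("p" if pred == 1 else "n")
            tally[key] += 1
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"])

    def test_out_of_extent_samples_dropped(self):
        g = make_grid(np.ones((2, 2)))
        x0, y0 = g.spec.cell_center(0, 0)
        cm = cs.confusion_from_samples(g, ([x0, 1e6], [y0, 1e6], [1, 1]))
        assert cm.total == 1


class TestAdjustedEstimates:
    def two_strata(self):
        # map-class strata: cropland W=0.3 (40/50 agree), non-crop W=0.7 (45/50)
        crop = Stratum(1, 0.3, ((0, 0), (10, 40)))
        non = Stratum(0, 0.7, ((45, 5), (0, 0)))
        return StratifiedDesign((non, crop))

    def test_hand_computed_adjusted_oa(self):
        est = cs.adjusted_estimates(self.two_strata(), total_area=100.0)
        assert est.oa == pytest.approx(0.3 * 0.8 + 0.7 * 0.9)

    def test_hand_computed_area_proportion(self):
        est = cs.adjusted_estimates(self.two_strata(), total_area=100.0)
        # cropland share: 0.3*(40/50) + 0.7*(5/50) = 0.31
        assert est.p_hat[1] == pytest.approx(0.31)
        assert est.area[1] == pytest.approx(31.0)
        assert est.p_hat[0] + est.p_hat[1] == pytest.approx(1.0)
        # stratified SE, by hand
        se = np.sqrt(0.3**2 * 0.8 * 0.2 / 49 + 0.7**2 * 0.1 * 0.9 / 49)
        assert est.se_p[1] == pytest.approx(se)
        assert est.ci95_area(1) == pytest.approx(1.96 * se * 100.0)

    def test_single_stratum_equals_raw(self):
        cm = cs.ConfusionCounts(30, 10, 20, 40)
        design = StratifiedDesign(
            (Stratum(0, 1.0, ((cm.tn, cm.fn), (cm.fp, cm.tp))),))
        est = cs.adjusted_estimates(design, 1.0)
        raw = cs.metrics(cm)
        assert est.oa == pytest.approx(raw.oa)
        assert est.ua[1] == pytest.approx(raw.ua)
        assert est.pa[1] == pytest.approx(raw.pa)

    def test_equal_weight_design_reduces_to_raw_oa(self):
        # W_i = n_i / n makes the stratified OA collapse to the raw OA exactly
        s1 = Stratum(1, 60 / 110, ((2, 3), (15, 40)))
        s0 = Stratum(0, 50 / 110, ((35, 5), (4, 6)))
        est = cs.adjusted_estimates(StratifiedDesign((s0, s1)), 1.0)
        raw_oa = (2 + 40 + 35 + 6) / 110
        assert est.oa == pytest.approx(raw_oa, abs=1e-15)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            StratifiedDesign((Stratum(0, 0.5, ((5, 5), (5, 5))),))

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError, match="n="):
            StratifiedDesign((Stratum(0, 1.0, ((1, 0), (0, 0))),))


class TestZonesAndErrors:
    def test_single_zone_equals_global(self, small_scene, labeled_pool):
        g = small_scene.products[0]
        zones = np.ones(g.spec.shape, dtype=int)
        tab = cs.per_zone_metrics(g, labeled_pool, zones)
        cm = cs.confusion_from_samples(g, labeled_pool)
        glob = cs.metrics(cm)
        assert len(tab) == 1
        assert tab.loc[0, "OA"] == pytest.approx(glob.oa)
        assert tab.loc[0, "MCC"] == pytest.approx(glob.mcc)

    def test_zone_confusions_sum_to_pooled(self, small_scene, labeled_pool):
        g = small_scene.products[0]
        tab = cs.per_zone_metrics(g, labeled_pool, small_scene.zones)
        cm = cs.confusion_from_samples(g, labeled_pool)
        for part in ("TP", "FP", "FN", "TN"):
            assert tab[part].sum() == getattr(cm, part.lower())

    def test_empty_zone_flagged_not_dropped(self, small_scene, labeled_pool):
        g = small_scene.products[0]
        tab = cs.per_zone_metrics(g, labeled_pool, small_scene.zones,
                                  zone_ids=[1, 999])
        row = tab[tab["zone"] == 999].iloc[0]
        assert row["flag"] == "no_samples"
        assert np.isnan(row["OA"])

    def test_error_sample_counts_match_confusion(self, small_scene, labeled_pool):
        g = small_scene.products[0]
        cm = cs.confusion_from_samples(g, labeled_pool)
        err = cs.error_samples(g, labeled_pool)
        assert (err["flag"] == "commission").sum() == cm.fp
        assert (err["flag"] == "omission").sum() == cm.fn

    def test_perfect_map_has_no_error_samples(self, small_scene, labeled_pool):
        err = cs.error_samples(small_scene.truth, labeled_pool)
        assert len(err) == 0
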