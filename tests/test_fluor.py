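"""MFI, Mann-Whitney comparisons, ROC/cutoff, binarization and overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fme import fluor, synthetic
from fme.fluor import BiopsyRecord, OverlapStats


def _record(fluorescence, tissue=None, target=None, label="ESCC"):
    fl = np.asarray(fluorescence, dtype=float)
    tissue = np.ones_like(fl, dtype=bool) if tissue is None else np.asarray(tissue, bool)
    target = np.zeros_like(fl, dtype=bool) if target is None else np.asarray(target, bool)
    return BiopsyRecord("b1", "p1", label, fl, tissue, target)


def _table(pos, neg, pos_label="ESCC", neg_label="normal"):
    vals = list(pos) + list(neg)
    labels = [pos_label] * len(pos) + [neg_label] * len(neg)
    return pd.DataFrame(
        {"biopsy_id": [f"b{i}" for i in range(len(vals))], "label": labels, "mfi": vals}
    )


class TestMFI:
    def test_constant_image(self):
        assert fluor.mean_fluorescence(_record(np.full((4, 4), 7.0))) == 7.0

    def test_small_grid_mean(self):
        rec = _record([[1.0, 2.0], [3.0, 4.0]])
        assert fluor.mean_fluorescence(rec) == 2.5

    def test_single_pixel_mask(self):
        tissue = np.zeros((2, 2), bool)
        tissue[0, 0] = True
        rec = _record([[9.0, 2.0], [3.0, 4.0]], tissue=tissue)
        assert fluor.mean_fluorescence(rec) == 9.0

    def test_empty_tissue_mask_rejected(self):
        with pytest.raises(ValueError, match="empty tissue"):
            fluor.mean_fluorescence(_record(np.ones((2, 2)), tissue=np.zeros((2, 2), bool)))

    def test_include_background_flag(self):
        tissue = np.zeros((2, 2), bool)
        tissue[0] = True
        rec = _record([[4.0, 4.0], [0.0, 0.0]], tissue=tissue)
        assert fluor.mean_fluorescence(rec) == 4.0
        assert fluor.mean_fluorescence(rec, include_background=True) == 2.0


class TestMannWhitney:
    def test_identical_groups(self):
        t = _table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        _, p = fluor.compare_mfi_groups(t, "ESCC", "normal")
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_enumeration_small_design(self):
        # (1,2) vs (3,4): U = 0; 1 of 6 orderings as or more extreme each
        # tail -> exact two-sided p = 2/6
        t = _table([1.0, 2.0], [3.0, 4.0])
        u, p = fluor.compare_mfi_groups(t, "ESCC", "normal")
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_composite_groups(self):
        t = synthetic.simulate_mfi_cohort(synthetic.published_biopsy_config(seed=0))
        u, p = fluor.compare_mfi_groups(t, ("HGD", "ESCC"), ("LGD", "normal"))
        assert 0 <= p <= 1

    def test_empty_group_rejected(self):
        t = _table([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            fluor.compare_mfi_groups(t, "ESCC", "LGD")

    def test_separated_groups_usually_significant(self):
        # HGD vs LGD+normal under published group parameters
        hits = 0
        for s in range(100):
            t = synthetic.simulate_mfi_cohort(synthetic.published_biopsy_config(seed=s))
            _, p = fluor.compare_mfi_groups(t, ("HGD",), ("LGD", "normal"))
            hits += p < 0.01
        assert hits >= 90


class TestROC:
    def test_perfect_separation(self):
        roc = fluor.roc_auc(_table([10.0, 11.0], [1.0, 2.0]))
        assert roc.auc == 1.0

    def test_pair_counting_oracle(self):
        # positives (3,5), negatives (2,4): 3 of 4 pairs concordant
        roc = fluor.roc_auc(_table([3.0, 5.0], [2.0, 4.0]))
        assert roc.auc == pytest.approx(0.75)

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for trial in range(20):
            pos = rng.normal(1.0, 1.0, size=8).clip(0.01)
            neg = rng.normal(0.5, 1.0, size=6).clip(0.01)
            if trial % 3 == 0:  # force ties
                pos = np.round(pos, 1)
                neg = np.round(neg, 1)
            roc = fluor.roc_auc(_table(pos, neg))
            y = np.r_[np.ones(8), np.zeros(6)]
            assert roc.auc == pytest.approx(
                float(roc_auc_score(y, np.r_[pos, neg])), abs=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 20), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 20), min_size=1, max_size=8),
    )
    def test_rank_auc_equals_trapezoid_area(self, pos, neg):
        # roc_auc asserts rank/trapezoid agreement internally on every call
        roc = fluor.roc_auc(_table([float(v) for v in pos], [float(v) for v in neg]))
        assert 0.0 <= roc.auc <= 1.0

    def test_sens_spec_lie_on_the_curve(self):
        rng = np.random.default_rng(1)
        t = _table(rng.uniform(0, 10, 7), rng.uniform(0, 10, 5))
        roc = fluor.roc_auc(t)
        for thr, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            se2, sp2 = fluor.sens_spec_at_cutoff(t, thr)
            assert (se2, sp2) == (se, sp)


class TestCutoff:
    def test_cutoff_below_everything(self):
        se, sp = fluor.sens_spec_at_cutoff(_table([3.0, 5.0], [2.0, 4.0]), -1.0)
        assert (se, sp) == (1.0, 0.0)

    def test_direct_count(self):
        se, sp = fluor.sens_spec_at_cutoff(
            _table([3000.0, 2000.0], [1000.0, 2500.0]), 2355.0
        )
        assert (se, sp) == (0.5, 0.5)

    def test_youden_matches_brute_force(self):
        t = _table([3.0, 5.0, 6.0], [2.0, 4.0])
        roc = fluor.roc_auc(t)
        chosen = fluor.choose_cutoff(roc)
        vals = np.unique(t["mfi"])
        best_j, best_c = -np.inf, None
        for c in vals:
            se, sp = fluor.sens_spec_at_cutoff(t, c)
            j = se + sp - 1
            if j > best_j + 1e-12:
                best_j, best_c = j, c
        assert chosen == best_c

    def test_perfectly_separated_returns_smallest_qualifying(self):
        roc = fluor.roc_auc(_table([10.0, 11.0], [1.0, 2.0]))
        assert fluor.choose_cutoff(roc) == 2.0

    def test_degenerate_all_equal(self):
        roc = fluor.roc_auc(_table([5.0, 5.0], [5.0, 5.0]))
        assert fluor.choose_cutoff(roc) == 5.0


class TestBinarize:
    def test_bimodal_recovers_signal_region(self):
        img = np.full((10, 10), 1000.0)
        img[:5] = 3000.0
        rec = _record(img)
        tm = fluor.binarize_fluorescence(rec, rule="otsu")
        assert np.array_equal(tm.mask, img == 3000.0)

    def test_fixed_rule(self):
        rng = np.random.default_rng(2)
        rec = _record(rng.uniform(0, 5000, (8, 8)))
        tm = fluor.binarize_fluorescence(rec, rule="fixed", value=2355.0)
        assert np.array_equal(tm.mask, (rec.fluorescence > 2355.0) & rec.tissue_mask)
        assert tm.threshold == 2355.0

    def test_percentile_100_empty(self):
        rng = np.random.default_rng(3)
        rec = _record(rng.uniform(0, 10, (6, 6)))
        tm = fluor.binarize_fluorescence(rec, rule="percentile", percentile=100.0)
        assert not tm.mask.any()

    def test_constant_image_warns_all_negative(self, caplog):
        import logging

        rec = _record(np.full((4, 4), 5.0))
        with caplog.at_level(logging.WARNING, logger="fme.fluor"):
            tm = fluor.binarize_fluorescence(rec, rule="otsu")
        assert not tm.mask.any() and tm.threshold is None


class TestOverlap:
    def test_identical_masks(self):
        target = np.zeros((4, 4), bool)
        target[:2] = True
        rec = _record(np.ones((4, 4)), target=target)
        ov = fluor.pixel_overlap(target, rec)
        assert (ov.sensitivity, ov.specificity) == (1.0, 1.0)

    def test_set_arithmetic(self):
        # tissue {a,b,c,d}; target+ = {a,b}; tracer+ = {b,c}
        tissue = np.zeros((2, 2), bool)
        tissue[:] = True
        target = np.array([[True, True], [False, False]])
        tracer = np.array([[False, True], [True, False]])
        rec = _record(np.ones((2, 2)), tissue=tissue, target=target)
        ov = fluor.pixel_overlap(tracer, rec)
        assert (ov.sensitivity, ov.specificity) == (0.5, 0.5)

    def test_empty_tracer(self):
        target = np.zeros((3, 3), bool)
        target[0] = True
        rec = _record(np.ones((3, 3)), target=target)
        ov = fluor.pixel_overlap(np.zeros((3, 3), bool), rec)
        assert (ov.sensitivity, ov.specificity) == (0.0, 1.0)

    def test_undefined_denominators_are_nan(self):
        rec = _record(np.ones((3, 3)))  # no target-positive pixels
        ov = fluor.pixel_overlap(np.zeros((3, 3), bool), rec)
        assert np.isnan(ov.sensitivity) and ov.specificity == 1.0
        all_target = _record(
            np.ones((3, 3)), target=np.ones((3, 3), bool)
        )
        ov2 = fluor.pixel_overlap(np.ones((3, 3), bool), all_target)
        assert ov2.sensitivity == 1.0 and np.isnan(ov2.specificity)

    def test_invariant_under_pixel_relabeling(self):
        rng = np.random.default_rng(4)
        tissue = rng.random((6, 6)) < 0.8
        target = tissue & (rng.random((6, 6)) < 0.4)
        tracer = tissue & (rng.random((6, 6)) < 0.5)
        rec = _record(np.ones((6, 6)), tissue=tissue, target=target)
        ov = fluor.pixel_overlap(tracer, rec)
        perm = rng.permutation(36)
        shuf = lambda a: a.ravel()[perm].reshape(6, 6)
        rec_s = _record(np.ones((6, 6)), tissue=shuf(tissue), target=shuf(target))
        ov_s = fluor.pixel_overlap(shuf(tracer), rec_s)
        assert (ov.sensitivity, ov.specificity) == (ov_s.sensitivity, ov_s.specificity)


class TestCohortOverlap:
    def test_single_biopsy_median_is_itself(self, biopsy_records):
        one = fluor.cohort_overlap_summary(biopsy_records[:1])
        tm = fluor.binarize_fluorescence(biopsy_records[0])
        ov = fluor.pixel_overlap(tm.mask, biopsy_records[0])
        assert one["median_sensitivity"] == pytest.approx(ov.sensitivity)
        assert one["median_specificity"] == pytest.approx(ov.specificity)

    def test_median_is_order_statistic(self):
        recs = []
        rng = np.random.default_rng(5)
        for i, f in enumerate([0.1, 0.2, 0.9]):
            tissue = np.ones((20, 20), bool)
            target = np.zeros((20, 20), bool)
            target[:10] = True
            img = np.where(target, 3000.0, 1000.0)
            # corrupt tracer signal to hit sensitivity f: keep a fraction of
            # the bright area bright
            n_keep = int(round(f * target.sum()))
            bright = np.argwhere(target)
            img[tuple(bright[n_keep:].T)] = 1000.0
            recs.append(BiopsyRecord(f"b{i}", f"p{i}", "ESCC", img, tissue, target))
        out = fluor.cohort_overlap_summary(recs, rule="fixed", value=2000.0)
        assert out["median_sensitivity"] == pytest.approx(0.2)

    def test_undefined_stats_excluded_from_median_and_n(self):
        tissue = np.ones((4, 4), bool)
        target_all = np.ones((4, 4), bool)
        target_none = np.zeros((4, 4), bool)
        recs = [
            BiopsyRecord("b0", "p0", "ESCC", np.ones((4, 4)), tissue, target_all),
            BiopsyRecord("b1", "p1", "ESCC", np.ones((4, 4)), tissue, target_none),
        ]
        out = fluor.cohort_overlap_summary(recs, rule="fixed", value=0.5)
        assert out["n_sensitivity"] == 1  # b1 has no target-positive area
        assert out["n_specificity"] == 1  # b0 has no target-negative area

    def test_noise_free_signal_on_target_gives_perfect_overlap(self):
        # tumor-localization property: signal exactly on target+, Otsu splits
        cfg = synthetic.BiopsyCohortConfig(
            groups={"ESCC": synthetic.BiopsyGroup(3, 4309.0, 2657.0, positive_fraction=0.3)},
            image_shape=(32, 32), edge_artifact=False, noise_sd=0.0, seed=8,
        )
        recs = synthetic.simulate_biopsy_set(cfg)
        out = fluor.cohort_overlap_summary(recs, rule="otsu")
        assert out["median_sensitivity"] == 1.0
        assert out["median_specificity"] == 1.0


class TestAnalyzeCohort:
    def test_report_schema_and_consistency(self, biopsy_records):
        out = fluor.analyze_cohort(biopsy_records, cutoff=2355.0)
        assert out["n_biopsies"] == len(biopsy_records)
        assert 0.0 <= out["auc"] <= 1.0
        table = out["mfi_table"]
        se, sp = fluor.sens_spec_at_cutoff(table, 2355.0)
        assert out["sens_at_cutoff"] == se and out["spec_at_cutoff"] == sp
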