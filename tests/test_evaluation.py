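"""Accuracy metrics (JCD, RDD/RCD, Δr), case taxonomy, summaries and
the interobserver statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from spheroidseg.evaluation import (
    delta_r,
    dunn_bonferroni,
    evaluate_image,
    friedman_test,
    interobserver_matrix,
    jcd,
    relative_deviation,
    summarize,
)
from spheroidseg.postprocess import extract_spheroid

from conftest import random_blob, rasterized_disk


def seg_from(mask):
    """SegmentationResult from a boolean mask via the standard chain."""
    return extract_spheroid(np.where(mask, 1.0, 0.0))


class TestJcd:
    def test_perfect_overlap(self):
        t = rasterized_disk(10)
        assert jcd(t, t) == 0.0

    def test_disjoint(self):
        p = np.zeros((20, 20), bool)
        p[0:3, 0:3] = True
        t = np.zeros((20, 20), bool)
        t[10:13, 10:13] = True
        assert jcd(p, t) == 1.0

    def test_shifted_square_half(self):
        p = np.zeros((5, 6), bool)
        p[1:4, 1:4] = True
        t = np.zeros((5, 6), bool)
        t[1:4, 2:5] = True
        assert jcd(p, t) == 0.5

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            jcd(np.zeros((3, 3), bool), np.zeros((3, 3), bool))

    def test_symmetric_and_bounded_against_set_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random((32, 32)) < 0.3
            t = rng.random((32, 32)) < 0.3
            if not t.any() or not p.any():
                continue
            ps = set(zip(*np.nonzero(p)))
            ts = set(zip(*np.nonzero(t)))
            expect = 1 - len(ps & ts) / len(ps | ts)
            assert jcd(p, t) == expect
            assert jcd(t, p) == jcd(p, t)
            assert 0 <= jcd(p, t) <= 1


class TestRelativeDeviation:
    def test_closed_forms(self):
        assert relative_deviation(5.0, 5.0) == 0.0
        assert relative_deviation(10.0, 5.0) == 1.0

    def test_disks_of_different_radii(self):
        d_p = 2 * math.sqrt(rasterized_disk(10).sum() / math.pi)
        d_t = 2 * math.sqrt(rasterized_disk(20).sum() / math.pi)
        assert relative_deviation(d_p, d_t) == pytest.approx(0.5, abs=0.02)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            relative_deviation(1.0, 0.0)


class TestDeltaR:
    def test_perfect_prediction_zero(self):
        t = rasterized_disk(20)
        assert delta_r(t, t)[0] == 0.0

    def test_empty_prediction_closed_form(self):
        t = rasterized_disk(25)
        d_t = 2 * math.sqrt(t.sum() / math.pi)
        dr_px, _ = delta_r(np.zeros_like(t), t)
        assert dr_px == pytest.approx(d_t * (1 / math.sqrt(2) - 0.5), rel=1e-6)

    def test_concentric_disks_give_radial_gap(self):
        size = 64
        yy, xx = np.mgrid[0:size, 0:size]
        rho2 = (yy - 32) ** 2 + (xx - 32) ** 2
        t = rho2 <= 20**2
        p = rho2 <= 25**2
        dr_px, dr_um = delta_r(p, t, pixel_size=2.0)
        assert dr_px == pytest.approx(5.0, rel=0.02)
        assert dr_um == pytest.approx(2.0 * dr_px)

    def test_monotone_in_shrinking_nested_prediction(self):
        size = 80
        yy, xx = np.mgrid[0:size, 0:size]
        rho2 = (yy - 40) ** 2 + (xx - 40) ** 2
        t = rho2 <= 30**2
        last = -1.0
        for r_p in (28, 24, 18, 10):
            dr, _ = delta_r(rho2 <= r_p**2, t)
            assert dr > last
            last = dr

    def test_exceeds_radial_error_implied_by_diameters(self):
        # surplus and missing areas do not compensate in Δr: a shifted
        # disk of equal radius has RDD ≈ 0 (diameters agree) yet a
        # substantial Δr from the two mismatched crescents
        size = 100
        yy, xx = np.mgrid[0:size, 0:size]
        t = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        for shift in (6, 12, 20):
            p = (yy - 50) ** 2 + (xx - 50 - shift) ** 2 <= 30**2
            dr, _ = delta_r(p, t)
            d_p = 2 * math.sqrt(p.sum() / math.pi)
            d_t = 2 * math.sqrt(t.sum() / math.pi)
            rdd_implied = abs(d_p - d_t) / 2
            assert rdd_implied < 0.1  # diameters nearly identical
            assert dr > 10 * rdd_implied and dr > 1.0


class TestEvaluateImage:
    def test_correct_single_spheroid(self):
        t = rasterized_disk(12)
        rec = evaluate_image(seg_from(t), t, pixel_size=2.04)
        assert not rec.invalid and not rec.ambiguous
        assert rec.jcd == 0.0 and rec.rdd == 0.0 and rec.rcd == 0.0
        assert rec.delta_r_px == 0.0

    def test_extra_blob_counts_ambiguous_not_invalid(self):
        t = np.zeros((60, 60), bool)
        t[10:30, 10:30] = True
        pred = t.copy()
        pred[45:50, 45:50] = True  # nonexistent extra spheroid
        rec = evaluate_image(seg_from(pred), t, pixel_size=1.0)
        assert rec.ambiguous and not rec.invalid
        assert rec.jcd == 0.0  # largest component matches the target

    def test_disjoint_prediction_invalid(self):
        t = np.zeros((40, 40), bool)
        t[5:15, 5:15] = True
        pred = np.zeros((40, 40), bool)
        pred[25:35, 25:35] = True
        rec = evaluate_image(seg_from(pred), t, pixel_size=1.0)
        assert rec.invalid and not rec.ambiguous
        assert rec.jcd == 1.0 and rec.rdd == 1.0 and rec.rcd == 1.0
        # Δr against the empty prediction
        d_t = 2 * math.sqrt(t.sum() / math.pi)
        assert rec.delta_r_px == pytest.approx(d_t * (1 / math.sqrt(2) - 0.5), rel=1e-6)

    def test_empty_prediction_invalid(self):
        t = rasterized_disk(8)
        rec = evaluate_image(seg_from(np.zeros_like(t)), t, pixel_size=1.0)
        assert rec.invalid and rec.jcd == 1.0


class TestSummarize:
    def test_all_perfect(self):
        t = rasterized_disk(10)
        recs = [evaluate_image(seg_from(t), t, 1.0) for _ in range(5)]
        s = summarize(recs)
        assert s.mean["jcd"] == 0.0 and s.isf == 0.0 and s.asf == 0.0
        assert s.isf_se == 0.0 and s.asf_se == 0.0

    def test_binomial_standard_error(self):
        t = rasterized_disk(10)
        good = evaluate_image(seg_from(t), t, 1.0)
        bad = evaluate_image(seg_from(np.zeros_like(t)), t, 1.0)
        s = summarize([bad] + [good] * 99)
        assert s.isf == pytest.approx(0.01)
        assert s.isf_se == pytest.approx(math.sqrt(0.01 * 0.99 / 100), rel=1e-9)

    def test_single_record_zero_sd(self):
        t = rasterized_disk(6)
        s = summarize([evaluate_image(seg_from(t), t, 1.0)])
        assert all(v == 0.0 for v in s.sd.values())

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        recs = []
        t = rasterized_disk(15)
        for _ in range(9):
            blob = random_blob(rng, shape=t.shape)
            recs.append(evaluate_image(seg_from(blob | t), t, 1.0))
        s = summarize(recs)
        vals = sorted(r.jcd for r in recs)
        assert s.median["jcd"] == vals[len(vals) // 2]


class TestInterobserver:
    def _panel(self, n_raters=5, n_images=4):
        rng = np.random.default_rng(8)
        base = rasterized_disk(15)
        panel = {}
        for r in range(n_raters):
            name = f"H{r}"
            masks = []
            for i in range(n_images):
                from spheroidseg.synth import perturb_as_rater

                masks.append(perturb_as_rater(base, 2.0, seed=100 * r + i))
            panel[name] = masks
        return panel

    def test_pair_count_five_raters_ten_pairs(self):
        table = interobserver_matrix(self._panel())
        assert table.shape == (4, 10)
        assert list(table.columns) == [
            f"{a}~{b}" for a, b in itertools.combinations([f"H{r}" for r in range(5)], 2)
        ]

    def test_duplicated_rater_zero_column(self):
        panel = self._panel(n_raters=2)
        panel["H2"] = [m.copy() for m in panel["H0"]]
        table = interobserver_matrix(panel)
        assert (table["H0~H2"] == 0).all()

    def test_mismatched_counts_rejected(self):
        panel = self._panel(n_raters=2)
        panel["H1"] = panel["H1"][:-1]
        with pytest.raises(ValueError, match="differing"):
            interobserver_matrix(panel)


class TestFriedman:
    def test_forced_ranks_statistic_six(self):
        # ranks always (1, 2, 3) over 3 blocks:
        # 12/(3·3·4)·(9 + 36 + 81) − 3·3·4 = 6
        table = np.array([[1.0, 2.0, 3.0]] * 3)
        stat, p = friedman_test(table)
        assert stat == pytest.approx(6.0, abs=1e-12)
        assert 0 < p < 1

    def test_identical_groups_zero(self):
        table = np.ones((5, 3))
        stat, p = friedman_test(table)
        assert stat == 0.0 and p == 1.0

    def test_agrees_with_scipy_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            table = rng.random((10, 4))
            stat, p = friedman_test(table)
            ref_stat, ref_p = stats.friedmanchisquare(*table.T)
            assert stat == pytest.approx(ref_stat, abs=1e-9)
            assert p == pytest.approx(ref_p, abs=1e-9)


class TestDunnBonferroni:
    def test_identical_groups_all_p_one(self):
        out = dunn_bonferroni(np.ones((6, 3)))
        assert (out["p_adjusted"] == 1.0).all()

    def test_adjusted_never_below_unadjusted(self):
        rng = np.random.default_rng(11)
        out = dunn_bonferroni(rng.random((12, 4)))
        assert (out["p_adjusted"] >= out["p_unadjusted"] - 1e-15).all()

    def test_dominated_group_significant(self):
        rng = np.random.default_rng(12)
        table = rng.random((30, 3))
        table[:, 2] += 10.0  # always worst rank
        out = dunn_bonferroni(table, ["a", "b", "c"])
        worst = out[(out.group_a == "c") | (out.group_b == "c")]
        assert (worst["p_adjusted"] < 0.005).all()
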