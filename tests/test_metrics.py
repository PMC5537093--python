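"""Overlap metrics, border distances, volumetry and Bland-Altman."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkdseg.grids import BinaryMask3D, GeometryError
from pkdseg import metrics as M
from .conftest import random_mask


def brute_force_confusion(ref, pred):
    """Independent per-voxel enumeration oracle (pure Python loops)."""
    tp = fp = fn = tn = 0
    r, p = ref.values, pred.values
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            for k in range(r.shape[2]):
                if r[i, j, k] and p[i, j, k]:
                    tp += 1
                elif not r[i, j, k] and p[i, j, k]:
                    fp += 1
                elif r[i, j, k] and not p[i, j, k]:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, fn, tn


class TestConfusionCounts:
    def test_identity_and_complement(self, rng):
        m = random_mask(rng)
        c = M.confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0 and c.tp == m.voxel_count()
        comp = BinaryMask3D(1 - m.values, m.spacing_mm)
        c2 = M.confusion_counts(m, comp)
        assert c2.tp == 0 and c2.tn == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            a, b = random_mask(rng, (8, 8, 8)), random_mask(rng, (8, 8, 8))
            c = M.confusion_counts(a, b)
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_confusion(a, b)
            assert c.total == 8**3

    def test_geometry_mismatch_rejected(self, rng):
        a = random_mask(rng, (8, 8, 8))
        b = random_mask(rng, (8, 8, 7))
        with pytest.raises(GeometryError):
            M.confusion_counts(a, b)


class TestOverlapFormulas:
    def test_hand_computed_example(self):
        c = M.ConfusionCounts(tp=4, fp=1, fn=1, tn=10)
        assert M.dice(c) == pytest.approx(0.8)
        assert M.jaccard(c) == pytest.approx(4 / 6)
        # Dice-Jaccard identity on the same counts
        j = M.jaccard(c)
        assert M.dice(c) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_perfect_agreement_gives_ones(self, rng):
        m = random_mask(rng)
        c = M.confusion_counts(m, m)
        for fn in (M.dice, M.jaccard, M.sensitivity, M.specificity, M.precision):
            assert fn(c) == 1.0

    def test_no_overlap_gives_zero(self):
        c = M.ConfusionCounts(tp=0, fp=3, fn=2, tn=5)
        assert M.dice(c) == 0.0
        assert M.jaccard(c) == 0.0

    def test_zero_denominator_is_nan_not_zero(self):
        empty = M.ConfusionCounts(tp=0, fp=0, fn=0, tn=10)
        assert math.isnan(M.dice(empty))
        assert math.isnan(M.sensitivity(empty))
        assert math.isnan(M.precision(empty))
        all_fg = M.ConfusionCounts(tp=10, fp=0, fn=0, tn=0)
        assert math.isnan(M.specificity(all_fg))

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(derandomize=True, max_examples=100)
    def test_dice_jaccard_identity_property(self, tp, fp, fn):
        c = M.ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=7)
        d, j = M.dice(c), M.jaccard(c)
        if not math.isnan(d):
            assert abs(d - 2 * j / (1 + j)) < 1e-9


class TestBoundaryDistance:
    def brute_force_slice_distance(self, ref, pred, spacing2d):
        """All-pairs directed-max border distances, symmetrized, per slice."""
        from scipy import ndimage

        per_slice = []
        for z in range(ref.shape[2]):
            r, p = ref.values[:, :, z].astype(bool), pred.values[:, :, z].astype(bool)
            if not (r.any() and p.any()):
                continue
            rb = np.argwhere(r & ~ndimage.binary_erosion(r, border_value=0))
            pb = np.argwhere(p & ~ndimage.binary_erosion(p, border_value=0))
            sc = np.asarray(spacing2d)

            def directed(A, B):
                return max(
                    min(math.dist(a * sc, b * sc) for b in B) for a in A
                )

            per_slice.append(max(directed(rb, pb), directed(pb, rb)))
        return float(np.mean(per_slice))

    def test_identical_masks_give_zero(self, rng):
        m = random_mask(rng, (12, 12, 4))
        d, mssd = M.boundary_distance_mean(m, m)
        assert d == 0.0 and mssd == 0.0

    def test_offset_squares_match_all_pairs_oracle(self):
        ref = np.zeros((20, 20, 1), dtype=np.uint8)
        pred = np.zeros((20, 20, 1), dtype=np.uint8)
        ref[4:10, 4:10, 0] = 1
        pred[6:12, 6:12, 0] = 1  # offset by 2 voxels at 1.5 mm
        a = BinaryMask3D(ref, (1.5, 1.5, 3.0))
        b = BinaryMask3D(pred, (1.5, 1.5, 3.0))
        d, _ = M.boundary_distance_mean(a, b)
        assert d == pytest.approx(self.brute_force_slice_distance(a, b, (1.5, 1.5)))

    def test_random_masks_match_all_pairs_oracle(self, rng):
        a = random_mask(rng, (10, 10, 3), p=0.4)
        b = random_mask(rng, (10, 10, 3), p=0.4)
        d, _ = M.boundary_distance_mean(a, b)
        assert d == pytest.approx(self.brute_force_slice_distance(a, b, (1.5, 1.5)))

    def test_scales_linearly_with_spacing(self):
        ref = np.zeros((20, 20, 1), dtype=np.uint8)
        pred = np.zeros((20, 20, 1), dtype=np.uint8)
        ref[4:10, 4:10, 0] = 1
        pred[6:12, 6:12, 0] = 1
        d1, _ = M.boundary_distance_mean(
            BinaryMask3D(ref, (1.5, 1.5, 3.0)), BinaryMask3D(pred, (1.5, 1.5, 3.0))
        )
        d2, _ = M.boundary_distance_mean(
            BinaryMask3D(ref, (3.0, 3.0, 3.0)), BinaryMask3D(pred, (3.0, 3.0, 3.0))
        )
        assert d2 == pytest.approx(2 * d1)

    def test_empty_mask_is_undefined(self, rng):
        m = random_mask(rng, (8, 8, 2))
        empty = BinaryMask3D(np.zeros((8, 8, 2), dtype=np.uint8), m.spacing_mm)
        d, mssd = M.boundary_distance_mean(m, empty)
        assert math.isnan(d) and math.isnan(mssd)


class TestVolumetry:
    def test_closed_form_tkv(self):
        vals = np.zeros((20, 20, 20), dtype=np.uint8)
        vals.flat[:1000] = 1
        m = BinaryMask3D(vals, (1.5, 1.5, 3.0))
        assert M.total_volume(m) == pytest.approx(6.75)

    def test_empty_is_zero_and_thickness_linear(self):
        empty = BinaryMask3D(np.zeros((4, 4, 4), dtype=np.uint8), (1.5, 1.5, 3.0))
        assert M.total_volume(empty) == 0.0
        vals = np.ones((4, 4, 4), dtype=np.uint8)
        v1 = M.total_volume(BinaryMask3D(vals, (1.5, 1.5, 3.0)))
        v2 = M.total_volume(BinaryMask3D(vals, (1.5, 1.5, 6.0)))
        assert v2 == pytest.approx(2 * v1)

    def test_additive_over_disjoint_masks(self, rng):
        a = random_mask(rng, (10, 10, 4), p=0.3)
        b_vals = ((rng.random((10, 10, 4)) < 0.3) & ~a.values.astype(bool)).astype(np.uint8)
        b = BinaryMask3D(b_vals, a.spacing_mm)
        union = BinaryMask3D(a.values | b.values, a.spacing_mm)
        assert M.total_volume(union) == pytest.approx(
            M.total_volume(a) + M.total_volume(b)
        )

    def test_percent_difference(self):
        assert M.percent_volume_difference(505, 500) == pytest.approx(1.0)
        assert M.percent_volume_difference(500, 500) == 0.0
        assert M.percent_volume_difference(460, 500) == pytest.approx(-8.0)
        with pytest.raises(ValueError):
            M.percent_volume_difference(100, 0)


class TestBlandAltman:
    def test_closed_forms(self):
        ba = M.bland_altman([0.0, 0.0, 0.0])
        assert ba.mean_diff == 0 and ba.sd_diff == 0
        assert ba.lower_limit == 0 and ba.upper_limit == 0
        ba2 = M.bland_altman([-1.0, 1.0])
        assert ba2.mean_diff == 0
        assert ba2.sd_diff == pytest.approx(math.sqrt(2))
        assert ba2.upper_limit == pytest.approx(1.96 * math.sqrt(2))
        assert ba2.lower_limit == pytest.approx(-1.96 * math.sqrt(2))

    def test_against_direct_reimplementation(self, rng):
        for _ in range(100):
            d = rng.normal(size=rng.integers(2, 30))
            ba = M.bland_altman(d)
            mean = sum(d) / len(d)
            sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (len(d) - 1))
            assert ba.mean_diff == pytest.approx(mean)
            assert ba.sd_diff == pytest.approx(sd)
            assert ba.upper_limit - ba.lower_limit == pytest.approx(2 * 1.96 * sd)

    def test_shift_invariance_of_interval_width(self, rng):
        d = rng.normal(size=12)
        ba = M.bland_altman(d)
        ba_shift = M.bland_altman(d + 5.0)
        assert ba_shift.mean_diff == pytest.approx(ba.mean_diff + 5.0)
        assert ba_shift.sd_diff == pytest.approx(ba.sd_diff)
        assert ba_shift.lower_limit == pytest.approx(ba.lower_limit + 5.0)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            M.bland_altman([1.0])


class TestCohortEvaluation:
    def test_single_perfect_case(self, rng):
        m = random_mask(rng, (10, 10, 4))
        cohort = M.evaluate_cohort([(m, m)])
        row = cohort.per_case.iloc[0]
        assert row["dice"] == 1.0 and row["jaccard"] == 1.0
        assert row["pct_diff"] == 0.0
        assert cohort.summary.loc["dice", "mean"] == 1.0

    def test_min_max_bracket_cases(self, rng):
        ref = random_mask(rng, (10, 10, 4), p=0.4)
        noisy = ref.values.copy()
        noisy[0:2] = 0
        pred = BinaryMask3D(noisy, ref.spacing_mm)
        cohort = M.evaluate_cohort([(ref, ref), (ref, pred)])
        for stat in ("dice", "jaccard"):
            vals = cohort.per_case[stat]
            assert cohort.summary.loc[stat, "min"] == vals.min()
            assert cohort.summary.loc[stat, "max"] == vals.max()

    def test_summary_matches_recomputation_from_per_case(self, rng):
        pairs = []
        for _ in range(6):
            ref = random_mask(rng, (10, 10, 4), p=0.4)
            pred = random_mask(rng, (10, 10, 4), p=0.4)
            pairs.append((ref, pred))
        cohort = M.evaluate_cohort(pairs)
        # independent recomputation from the per-case table
        for stat in ("dice", "jaccard", "pct_diff"):
            col = cohort.per_case[stat].dropna()
            assert cohort.summary.loc[stat, "mean"] == pytest.approx(col.mean())
            assert cohort.summary.loc[stat, "sd"] == pytest.approx(col.std(ddof=1))
        ba = cohort.bland_altman
        diffs = cohort.per_case["pct_diff"].dropna()
        assert ba.mean_diff == pytest.approx(diffs.mean())

    def test_formatted_rows_style(self, rng):
        m = random_mask(rng, (10, 10, 4))
        cohort = M.evaluate_cohort([(m, m), (m, m)])
        text = cohort.formatted()["dice"]
        assert "±" in text and "[" in text and "/" in text
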