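"""Overlap, repeatability error metrics, Bland-Altman, Spearman, rating maps."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from myometry import reliability as rel
from myometry import composition as comp
from myometry import phantom as ph
from myometry.core import MuscleLabel, MuscleLabelMap
from myometry.errors import DomainError, InsufficientDataError, UndefinedOverlapError


def _map_from(mask, code=1):
    return MuscleLabelMap(labels=mask.astype(np.int32) * code,
                          dictionary={code: MuscleLabel("m", "left")}, spacing=(1, 1, 1))


class TestOverlap:
    def test_identical_labels_give_unity(self):
        mask = np.zeros((4, 4, 2), bool)
        mask[1:3, 1:3, :] = True
        r = rel.overlap(_map_from(mask), _map_from(mask), 1)
        assert r.dice == 1.0 and r.jaccard == 1.0

    def test_disjoint_labels_give_zero(self):
        a = np.zeros((4, 4, 2), bool)
        b = np.zeros((4, 4, 2), bool)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        r = rel.overlap(_map_from(a), _map_from(b), 1)
        assert r.dice == 0.0 and r.jaccard == 0.0

    def test_partial_overlap_brute_force(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[:2, :4, 0] = True  # 8 voxels
        b[1:3, :4, 0] = True  # 8 voxels, 4 shared
        r = rel.overlap(_map_from(a), _map_from(b), 1)
        assert r.jaccard == pytest.approx(4 / 12)
        assert r.dice == pytest.approx(0.5)

    def test_dice_jaccard_identity_on_random_masks(self, rng):
        for _ in range(100):
            a = rng.random((6, 6, 3)) > 0.6
            b = rng.random((6, 6, 3)) > 0.6
            if not (a.any() or b.any()):
                continue
            r = rel.overlap(_map_from(a), _map_from(b), 1)
            # brute-force voxel counting oracle
            inter = sum(1 for idx in np.ndindex(a.shape) if a[idx] and b[idx])
            union = sum(1 for idx in np.ndindex(a.shape) if a[idx] or b[idx])
            assert r.jaccard == pytest.approx(inter / union)
            assert r.dice == pytest.approx(2 * inter / (a.sum() + b.sum()))
            assert r.dice == pytest.approx(2 * r.jaccard / (1 + r.jaccard))
            assert r.jaccard <= r.dice + 1e-15

    def test_empty_in_both_raises(self):
        empty = np.zeros((3, 3, 1), bool)
        with pytest.raises(UndefinedOverlapError):
            rel.overlap(_map_from(empty), _map_from(empty), 1)


class TestPairedErrors:
    def test_volume_error_examples(self):
        assert rel.abs_volume_error(100, 100) == 0.0
        assert rel.abs_volume_error(95, 105) == pytest.approx(10.0)

    def test_volume_error_symmetry(self, rng):
        for _ in range(25):
            a, b = rng.uniform(1, 1e5, 2)
            assert rel.abs_volume_error(a, b) == pytest.approx(rel.abs_volume_error(b, a))

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            rel.abs_volume_error(0.0, 10.0)

    def test_ff_difference_examples(self):
        assert rel.abs_ff_difference(20, 20) == 0.0
        assert rel.abs_ff_difference(12.5, 15.0) == pytest.approx(2.5)

    def test_ff_difference_triangle_inequality(self):
        values = [0.0, 12.5, 33.0, 50.0, 97.5, 100.0]
        for a, b, c in itertools.permutations(values, 3):
            assert rel.abs_ff_difference(a, c) <= (
                rel.abs_ff_difference(a, b) + rel.abs_ff_difference(b, c) + 1e-12)

    def test_out_of_range_ff_rejected(self):
        with pytest.raises(DomainError):
            rel.abs_ff_difference(-1.0, 50.0)


class TestBlandAltman:
    def test_identical_pairs_zero_bias_and_slope(self, rng):
        a = rng.uniform(10, 100, 20)
        r = rel.bland_altman(list(zip(a, a)))
        assert r.bias == 0.0 and r.slope == 0.0
        assert r.degenerate  # zero variance: no t statistic
        assert np.isnan(r.t_fixed)

    def test_constant_offset_recovered(self, rng):
        a = rng.uniform(10, 100, 15)
        r = rel.bland_altman(list(zip(a, a + 5.0)))
        assert r.bias == pytest.approx(5.0)
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.df_fixed == 14 and r.df_slope == 13

    def test_proportional_bias_matches_regression_oracle(self, rng):
        a = rng.uniform(10, 100, 30)
        b = 1.1 * a
        r = rel.bland_altman(list(zip(a, b)))
        diff, mean = b - a, (a + b) / 2
        slope_oracle = np.polyfit(mean, diff, 1)[0]  # closed-form least squares
        assert r.slope == pytest.approx(slope_oracle, rel=1e-9)
        # b = 1.1a -> diff = 0.1a, mean = 1.05a -> slope = 0.1/1.05 exactly
        assert r.slope == pytest.approx(0.1 / 1.05, rel=1e-9)
        assert r.p_slope < 1e-6

    def test_noisy_fixed_bias_t_matches_scipy(self, rng):
        a = rng.uniform(10, 100, 40)
        b = a + rng.normal(2.0, 1.0, 40)
        r = rel.bland_altman(list(zip(a, b)))
        t, p = sps.ttest_1samp(b - a, 0.0)
        assert r.t_fixed == pytest.approx(t)
        assert r.p_fixed == pytest.approx(p)
        assert r.loa_low == pytest.approx(r.bias - 1.96 * r.sd)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            rel.bland_altman([(1.0, 2.0), (2.0, 3.0)])


def _exact_perm_oracle(x, y):
    """Independent enumeration: two-sided p of |rho| under permutation."""
    def rho_of(a, b):
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        return np.corrcoef(ra, rb)[0, 1]
    obs = rho_of(x, y)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(rho_of(x, perm)) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


class TestSpearman:
    def test_perfect_monotone(self):
        r = rel.spearman([1, 2, 3, 4, 5], [10, 20, 25, 70, 71])
        assert r.rho == pytest.approx(1.0)

    def test_perfect_reversed(self):
        r = rel.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("x,y", [
        ([1, 1, 2, 2, 3, 3], [0.5, 1.0, 0.7, 2.0, 1.8, 2.2]),  # tied ordinal
        ([1, 2, 2, 3, 4, 4], [4, 4, 3, 3, 2, 1]),
        ([0, 1, 0, 1, 2, 2], [3.3, 1.1, 2.2, 5.5, 4.4, 6.6]),
    ])
    def test_tied_cases_match_exact_permutation_oracle(self, x, y):
        r = rel.spearman(x, y)
        rho_o, p_o = _exact_perm_oracle(np.asarray(x, float), np.asarray(y, float))
        assert r.exact
        assert r.rho == pytest.approx(rho_o)
        assert r.p == pytest.approx(p_o)

    def test_large_n_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.8, size=30)
        r = rel.spearman(x, y)
        rho_s, p_s = sps.spearmanr(x, y)
        assert not r.exact
        assert r.rho == pytest.approx(rho_s)
        assert r.p == pytest.approx(p_s, rel=1e-6)

    def test_constant_input_flagged_undefined(self):
        r = rel.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not r.defined and np.isnan(r.rho)


class TestRatingMaps:
    @pytest.mark.parametrize("ff,expected", [(0, 1), (4.9, 1), (5, 2), (14.9, 2),
                                             (15, 3), (29.9, 3), (30, 4), (45, 4),
                                             (59.9, 4), (60, 5), (84.9, 5), (85, 6),
                                             (100, 6)])
    def test_fat_rating_bins(self, ff, expected):
        assert rel.fat_rating_from_ff(ff) == expected

    @pytest.mark.parametrize("pct,expected", [(0, 0), (0.5, 0), (1, 2), (29.9, 2),
                                              (30, 3), (60, 3), (60.1, 4), (70, 4),
                                              (100, 4)])
    def test_stir_grade_bins(self, pct, expected):
        assert rel.stir_grade_from_fraction(pct) == expected

    def test_mild_diffuse_is_grade_one(self):
        assert rel.stir_grade_from_fraction(0.0, mild_diffuse=True) == 1

    def test_fat_rating_monotone_over_sweep(self):
        ratings = [rel.fat_rating_from_ff(ff) for ff in np.linspace(0, 100, 201)]
        assert all(b >= a for a, b in zip(ratings, ratings[1:]))


class TestReliabilityReport:
    def _runs(self, ds, ds2=None):
        t1 = {m.code: m for m in comp.composition_table(ds.water, ds.fat, ds.labelmap)}
        if ds2 is None:
            return [t1, dict(t1)]
        t2 = {m.code: m for m in comp.composition_table(ds2.water, ds2.fat, ds2.labelmap)}
        return [t1, t2]

    def test_identical_runs_all_zero_and_dice_one(self, minimal_ds):
        report = rel.reliability_report(
            self._runs(minimal_ds), "intra_observer",
            label_maps=[minimal_ds.labelmap, minimal_ds.labelmap])
        assert (report.per_muscle["abs_volume_error_mean"] == 0).all()
        assert (report.per_muscle["abs_ff_difference_mean"] == 0).all()
        assert (report.per_muscle["dice_mean"] == 1.0).all()
        assert report.volume_agreement.bias == 0.0

    def test_row_count_equals_shared_codes(self, minimal_ds):
        report = rel.reliability_report(self._runs(minimal_ds), "scan_rescan")
        assert len(report.per_muscle) == len(minimal_ds.labelmap.codes_present())

    def test_rescan_with_jitter_small_errors(self):
        spec = ph.large_muscle_spec(noise_sd=0.02, seed=2)
        a = ph.generate(spec)
        b = ph.generate(ph.rescan_spec(spec))
        report = rel.reliability_report(self._runs(a, b), "scan_rescan")
        assert (report.per_muscle["abs_volume_error_mean"] < 2.0).all()
        assert (report.per_muscle["abs_ff_difference_mean"] < 1.0).all()

    def test_unknown_design_rejected(self, minimal_ds):
        with pytest.raises(DomainError):
            rel.reliability_report(self._runs(minimal_ds), "nonsense")

    def test_insufficient_shared_muscles_rejected(self, minimal_ds):
        runs = self._runs(minimal_ds)
        runs[1] = {99: runs[0][1]}
        with pytest.raises(InsufficientDataError):
            rel.reliability_report(runs, "scan_rescan")
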