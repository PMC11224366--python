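"""Slice-wise CSA decomposition and length normalization."""

import numpy as np
import pytest

from myometry import composition as comp
from myometry import phantom as ph
from myometry import profiles as prof
from myometry.core import MuscleLabel, MuscleLabelMap, VolumetricImage
from myometry.errors import AlignmentError, EmptyMuscleError, ParameterError


def _uniform_muscle(nx=8, ny=5, nz=4, ff=25.0, spacing=(1.0, 1.0, 3.0)):
    shape = (nx, ny, nz)
    water = VolumetricImage(np.full(shape, 100.0 - ff), spacing)
    fat = VolumetricImage(np.full(shape, ff), spacing)
    lmap = MuscleLabelMap(labels=np.ones(shape, dtype=np.int32),
                          dictionary={1: MuscleLabel("ta", "left")}, spacing=spacing)
    return water, fat, lmap


def _slices_from_csa(csa_values, dz=3.0):
    return [
        prof.SliceMetrics(index=i, position_mm=i * dz, boundary_csa=c,
                          lean_csa=0.75 * c, fat_csa=0.25 * c, area_ff=25.0)
        for i, c in enumerate(csa_values)
    ]


class TestSliceMetrics:
    def test_uniform_slice_arithmetic(self):
        # 40 voxels/slice at (1,1) mm in-plane, FF 25% -> 40 / 10 / 30 mm^2
        water, fat, lmap = _uniform_muscle()
        slices = prof.slice_metrics(water, fat, lmap, 1)
        assert len(slices) == 4
        for s in slices:
            assert s.boundary_csa == pytest.approx(40.0)
            assert s.fat_csa == pytest.approx(10.0)
            assert s.lean_csa == pytest.approx(30.0)
            assert s.area_ff == pytest.approx(25.0)

    def test_single_slice_muscle(self):
        water, fat, lmap = _uniform_muscle(nz=1)
        assert len(prof.slice_metrics(water, fat, lmap, 1)) == 1

    def test_empty_muscle_raises(self):
        water, fat, lmap = _uniform_muscle()
        with pytest.raises(EmptyMuscleError):
            prof.slice_metrics(water, fat, lmap, 5)

    def test_integral_consistency_with_boundary_volume(self, minimal_noisy_ds):
        ds = minimal_noisy_ds
        for code in ds.labelmap.codes_present():
            slices = prof.slice_metrics(ds.water, ds.fat, ds.labelmap, code)
            vol = sum(s.boundary_csa for s in slices) * ds.labelmap.spacing[2]
            m = comp.muscle_composition(ds.water, ds.fat, ds.labelmap, code)
            assert vol == pytest.approx(m.boundary_volume, rel=0, abs=0)

    def test_cone_csa_matches_analytic_within_discretization(self):
        spec = ph.minimal_spec()
        spec.muscles = [ph.MuscleSpec(
            code=1, name="cone", side="left", center_mm=(39.0, 39.0),
            radii_mm=(12.0, 12.0), z_extent_mm=(8.0, 88.0),
            taper="linear", taper_min=0.2,
            ff_pattern=ph.FFPattern(kind="homogeneous", ff_const=30.0))]
        ds = ph.generate(spec)
        m = spec.muscles[0]
        h = max(spec.spacing[:2])
        for s in prof.slice_metrics(ds.water, ds.fat, ds.labelmap, 1):
            u = (s.index * spec.spacing[2] - 8.0) / 80.0
            analytic = float(m.csa_mm2(u))
            r_eff = m.radii_mm[0] * float(m.scale(u))
            bound = 2.0 * np.pi * r_eff * h + 4.0 * h * h  # boundary-cell bound
            assert abs(s.boundary_csa - analytic) <= bound


class TestNormalizeProfile:
    def test_two_slices_linear_interpolation(self):
        profile = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        assert profile.boundary_csa[0] == pytest.approx(10.0)
        assert profile.boundary_csa[100] == pytest.approx(20.0)
        assert profile.boundary_csa[50] == pytest.approx(15.0)
        assert len(profile.percent) == 101

    def test_eleven_slices_closed_form(self):
        profile = prof.normalize_profile(_slices_from_csa(list(range(11))))
        np.testing.assert_allclose(profile.boundary_csa, profile.percent / 10.0, atol=1e-12)

    def test_single_slice_constant_profile(self):
        profile = prof.normalize_profile(_slices_from_csa([42.0]))
        assert np.all(profile.boundary_csa == 42.0)

    def test_endpoints_equal_terminal_slices(self, minimal_ds):
        ds = minimal_ds
        slices = prof.slice_metrics(ds.water, ds.fat, ds.labelmap, 2)
        profile = prof.normalize_profile(slices)
        assert profile.boundary_csa[0] == pytest.approx(slices[0].boundary_csa)
        assert profile.boundary_csa[-1] == pytest.approx(slices[-1].boundary_csa)

    def test_closure_preserved_at_every_grid_point(self, minimal_noisy_ds):
        ds = minimal_noisy_ds
        profile = prof.muscle_profile(ds.water, ds.fat, ds.labelmap, 2)
        np.testing.assert_allclose(profile.lean_csa + profile.fat_csa,
                                   profile.boundary_csa, rtol=1e-9)

    def test_storage_direction_invariance(self, minimal_ds):
        ds = minimal_ds
        profile = prof.muscle_profile(ds.water, ds.fat, ds.labelmap, 2)
        flip = lambda a: np.flip(a, axis=2)
        water_f = VolumetricImage(flip(ds.water.data), ds.water.spacing,
                                  superior_direction=-1)
        fat_f = VolumetricImage(flip(ds.fat.data), ds.fat.spacing, superior_direction=-1)
        lmap_f = MuscleLabelMap(labels=flip(ds.labelmap.labels),
                                dictionary=ds.labelmap.dictionary,
                                spacing=ds.labelmap.spacing, superior_direction=-1)
        profile_f = prof.muscle_profile(water_f, fat_f, lmap_f, 2)
        np.testing.assert_allclose(profile.boundary_csa, profile_f.boundary_csa, atol=1e-9)
        np.testing.assert_allclose(profile.area_ff, profile_f.area_ff, atol=1e-9)


class TestTrimAndDelta:
    def test_default_trim_keeps_81_points(self):
        profile = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        trimmed = prof.trim_profile(profile)
        assert len(trimmed.percent) == 81
        assert trimmed.percent[0] == 10.0 and trimmed.percent[-1] == 90.0
        assert trimmed.untrimmed is profile

    def test_full_range_trim_is_identity(self):
        profile = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        trimmed = prof.trim_profile(profile, 0, 100)
        np.testing.assert_array_equal(trimmed.boundary_csa, profile.boundary_csa)

    def test_invalid_bounds_rejected(self):
        profile = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        with pytest.raises(ParameterError):
            prof.trim_profile(profile, 60, 40)

    def test_identical_profiles_zero_delta(self):
        p = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        delta = prof.profile_delta(p, p)
        for arr in delta.values():
            assert np.all(arr == 0.0)

    def test_delta_antisymmetry(self):
        a = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        b = prof.normalize_profile(_slices_from_csa([12.0, 25.0]))
        d_ab = prof.profile_delta(a, b)
        d_ba = prof.profile_delta(b, a)
        for key in d_ab:
            np.testing.assert_allclose(d_ab[key], -d_ba[key], atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = prof.normalize_profile(_slices_from_csa([10.0, 20.0]))
        b = prof.trim_profile(a)
        with pytest.raises(AlignmentError):
            prof.profile_delta(a, b)

    def test_programmed_progression_localizes_in_transition_zone(self):
        # +dFF concentrated where |d(truth FF)/dz| is largest: the logistic
        # transition of a high_distal muscle, i.e. mid-length
        spec = ph.minimal_spec()
        spec.progression_dff = {2: 10.0}
        base = ph.generate(spec)
        follow = ph.make_followup(base)
        p_base = prof.muscle_profile(base.water, base.fat, base.labelmap, 2)
        p_follow = prof.muscle_profile(follow.water, follow.fat, follow.labelmap, 2)
        delta = prof.profile_delta(p_base, p_follow)["area_ff"]
        mid = np.abs(delta[40:61]).max()
        ends = max(np.abs(delta[:20]).max(), np.abs(delta[81:]).max())
        assert mid > 5.0 * max(ends, 1e-6)
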