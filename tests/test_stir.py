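"""STIR+ segmentation, rigid registration and content quantification."""

import numpy as np
import pytest

from myometry import phantom as ph
from myometry import stir as st
from myometry.core import MuscleLabel, MuscleLabelMap, VolumetricImage
from myometry.errors import AlignmentError, ParameterError


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        t = st.RigidTransform.from_euler((10, -5, 30), (4, -7, 2), (10, 20, 30))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.matrix, np.eye(3), atol=1e-9)
        pts = np.array([[0, 0, 0], [5, 5, 5], [-3, 8, 100.0]])
        np.testing.assert_allclose(ident.apply(pts), pts, atol=1e-9)

    def test_compose_matches_sequential_application(self):
        a = st.RigidTransform.from_euler((5, 0, 10), (1, 2, 3), (4, 4, 4))
        b = st.RigidTransform.from_euler((0, 7, -3), (-2, 0, 5), (9, 1, 0))
        pts = np.array([[1.0, 2.0, 3.0], [10.0, -4.0, 7.0]])
        np.testing.assert_allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9)

    def test_sitk_roundtrip_preserves_action(self):
        t = st.RigidTransform.from_euler((3, 2, -4), (6, -1, 9), (20, 20, 40))
        back = st.RigidTransform.from_sitk(t.to_sitk())
        pts = np.array([[0.0, 0.0, 0.0], [15.0, 25.0, 35.0]])
        np.testing.assert_allclose(back.apply(pts), t.apply(pts), atol=1e-9)

    def test_dict_roundtrip(self):
        t = st.RigidTransform.from_euler((3, 2, -4), (6, -1, 9), (20, 20, 40))
        back = st.RigidTransform.from_dict(t.to_dict())
        np.testing.assert_allclose(back.matrix, t.matrix, atol=1e-12)
        np.testing.assert_allclose(back.translation, t.translation, atol=1e-12)


class TestLimbMask:
    def test_phantom_limb_recovered(self, minimal_noisy_ds):
        ds = minimal_noisy_ds
        mask = st.limb_mask(ds.stir)
        inter = np.count_nonzero(mask & ds.limb)
        dice = 2 * inter / (mask.sum() + ds.limb.sum())
        assert dice >= 0.98

    def test_background_volume_gives_empty_mask(self):
        vol = VolumetricImage(np.zeros((8, 8, 4)), (1, 1, 3))
        assert not st.limb_mask(vol).any()


class TestSegmentStir:
    def test_noiseless_bimodal_recovered_exactly(self, minimal_ds):
        ds = minimal_ds
        mask = st.segment_stir(ds.stir, st.limb_mask(ds.stir))
        assert np.array_equal(mask.mask, ds.truth_stir.mask)

    def test_constant_intensity_yields_empty_mask(self):
        data = np.zeros((24, 24, 4))
        xx, yy = np.mgrid[:24, :24]
        limb2d = ((xx - 12) ** 2 + (yy - 12) ** 2) <= 100
        data[limb2d, :] = 100.0
        vol = VolumetricImage(data, (2, 2, 4))
        limb = np.repeat(limb2d[:, :, None], 4, axis=2)
        mask = st.segment_stir(vol, limb)
        assert not mask.mask.any()

    def test_noisy_phantom_dice_above_095(self):
        ds = ph.generate(ph.minimal_spec(stir_noise_sd=10.0, seed=42))
        mask = st.segment_stir(ds.stir, st.limb_mask(ds.stir))
        inter = np.count_nonzero(mask.mask & ds.truth_stir.mask)
        dice = 2 * inter / (mask.mask.sum() + ds.truth_stir.mask.sum())
        assert dice >= 0.95

    def test_bad_region_fraction_rejected(self, minimal_ds):
        with pytest.raises(ParameterError):
            st.segment_stir(minimal_ds.stir, st.limb_mask(minimal_ds.stir),
                            region_fraction=0.0)
        with pytest.raises(ParameterError):
            st.segment_stir(minimal_ds.stir, st.limb_mask(minimal_ds.stir),
                            region_fraction=0.02)  # windows below 9 px^2

    def test_ff_veto_removes_fat_candidates(self, minimal_ds):
        ds = minimal_ds
        ff = np.zeros(ds.stir.shape)
        ff[ds.truth_stir.mask] = 80.0  # pretend every lesion voxel is fat
        mask = st.segment_stir(ds.stir, st.limb_mask(ds.stir), ff_on_stir=ff)
        assert not mask.mask.any()


class TestRegistration:
    def test_self_registration_is_identity(self, minimal_ds):
        rec = st.register_rigid(minimal_ds.water, minimal_ds.water, metric="mse", seed=1)
        assert rec.rotation_angle_deg <= 0.1
        assert np.abs(rec.apply(np.array([39.0, 39.0, 46.0])) -
                      np.array([39.0, 39.0, 46.0])).max() <= 0.1

    def test_known_offset_recovered(self):
        center = (47.25, 47.25, 70.5)
        truth = st.RigidTransform.from_euler((0, 0, 3.0), (4.0, -2.0, 0.0), center)
        ds = ph.generate(ph.five_pattern_spec(stir_noise_sd=5.0, seed=8,
                                              dixon_to_stir=truth))
        rec = st.register_rigid(ds.water, ds.stir, seed=8)
        drot = rec.matrix @ truth.matrix.T
        angle = np.degrees(np.arccos(np.clip((np.trace(drot) - 1) / 2, -1, 1)))
        assert angle <= 0.5
        err = np.abs(rec.apply(np.array(center)) - truth.apply(np.array(center)))
        assert err[0] <= 0.75 and err[1] <= 0.75 and err[2] <= 1.5  # half voxel per axis

    def test_composition_invariance(self):
        # registering a pre-transformed moving image recovers the composed map
        center = (47.25, 47.25, 70.5)
        truth = st.RigidTransform.from_euler((0, 0, 2.0), (3.0, 1.0, 0.0), center)
        ds = ph.generate(ph.five_pattern_spec(stir_noise_sd=5.0, seed=9,
                                              dixon_to_stir=truth))
        rec = st.register_rigid(ds.water, ds.stir, seed=9)
        recovered_identity = rec.compose(truth.inverse())
        assert recovered_identity.rotation_angle_deg <= 0.5
        c = np.array(center)
        assert np.abs(recovered_identity.apply(c) - c).max() <= 1.5


class TestResampleLabels:
    def test_identity_transform_is_voxel_identical(self, minimal_ds):
        ds = minimal_ds
        out = st.resample_labels(ds.labelmap, st.RigidTransform.identity(), ds.stir)
        assert np.array_equal(out.labels, ds.labelmap.labels)

    def test_pure_translation_shifts_by_one_voxel(self, minimal_ds):
        ds = minimal_ds
        dx = ds.labelmap.spacing[0]
        t = st.RigidTransform(np.eye(3), np.array([dx, 0.0, 0.0]))
        out = st.resample_labels(ds.labelmap, t, ds.stir)
        # transform maps reference point p to p+dx in label space: content shifts -x
        np.testing.assert_array_equal(out.labels[:-1, :, :], ds.labelmap.labels[1:, :, :])

    def test_resampled_codes_subset_of_original(self, minimal_ds):
        ds = minimal_ds
        t = st.RigidTransform.from_euler((0, 0, 5), (3, 3, 2), (39, 39, 46))
        out = st.resample_labels(ds.labelmap, t, ds.stir)
        assert set(out.codes_present()) <= set(ds.labelmap.codes_present())


class TestStirContent:
    def _grid(self, n_stir=720, n_total=1000):
        # muscle of 1000 voxels with 720 STIR+: content 72.0%
        labels = np.zeros((12, 12, 10), dtype=np.int32)
        labels[1:11, 1:11, :] = 1
        mask = np.zeros_like(labels, dtype=bool)
        flat = np.flatnonzero(labels)
        mask.flat[flat[:n_stir]] = True
        lmap = MuscleLabelMap(labels=labels, dictionary={1: MuscleLabel("ta", "left")},
                              spacing=(1, 1, 1))
        return st.StirMask(mask=mask, spacing=(1, 1, 1), provenance="external"), lmap

    def test_720_of_1000_is_72_percent(self):
        mask, lmap = self._grid()
        content = st.stir_content(mask, lmap, erode_first=False)
        assert content[0].stir_pct == pytest.approx(72.0)
        assert content[0].stir_voxels == 720 and content[0].total_voxels == 1000

    def test_empty_mask_gives_zero_for_all(self, minimal_ds):
        ds = minimal_ds
        empty = st.StirMask(mask=np.zeros(ds.stir.shape, bool), spacing=ds.stir.spacing)
        for c in st.stir_content(empty, ds.labelmap):
            assert c.stir_pct == 0.0

    def test_grid_mismatch_rejected(self, minimal_ds):
        ds = minimal_ds
        bad = st.StirMask(mask=np.zeros((2, 2, 2), bool), spacing=(1, 1, 1))
        with pytest.raises(AlignmentError):
            st.stir_content(bad, ds.labelmap)

    def test_phantom_fraction_recovered_within_two_points(self, minimal_noisy_ds):
        ds = minimal_noisy_ds
        mask = st.segment_stir(ds.stir, st.limb_mask(ds.stir))
        for c in st.stir_content(mask, ds.labelmap):
            truth = 100.0 * ds.truth_stir_fraction_eroded[c.code]
            assert c.stir_pct == pytest.approx(truth, abs=2.0)

    def test_enlarging_lesion_never_decreases_content(self):
        # programmed lesion growth -> monotone recovered percentage
        pcts = []
        for frac in (0.1, 0.3, 0.5, 0.7):
            spec = ph.minimal_spec(stir_noise_sd=5.0, seed=21)
            spec.muscles[0] = ph.MuscleSpec(
                **{**vars(spec.muscles[0]), "stir_fraction": frac})
            ds = ph.generate(spec)
            mask = st.segment_stir(ds.stir, st.limb_mask(ds.stir))
            content = {c.code: c.stir_pct for c in st.stir_content(mask, ds.labelmap)}
            pcts.append(content[1])
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))
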