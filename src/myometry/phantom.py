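"""Synthetic limb phantoms with known ground truth.

The generator emulates what the quantification pipeline assumes about a
lower-limb Dixon/STIR acquisition: a roughly cylindrical limb with a
subcutaneous fat ring, several non-overlapping tube-shaped muscles with
tapering elliptical cross-sections, a voxelwise fat-fraction (FF) field
following one of five archetypal spatial patterns (homogeneous, high
distal, high proximal, high at both ends, high in the centre), Dixon
water/fat signals generated from that field,

    water = S0 (1 - FF/100)(1 + eps_w),   fat = S0 (FF/100)(1 + eps_f),

a STIR volume with known hyperintense lesions in a possibly offset frame,
and an optional follow-up timepoint whose FF increase concentrates in the
axial transition zones between high and low FF.

Because muscle cross-sections are analytic ellipses with sinusoidal or
linear taper, CSA(z) and the per-muscle mean FF have closed forms, and in
noiseless mode the entire downstream pipeline must reproduce every
programmed quantity to numerical precision — the phantoms are the oracles
for the analysis modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .core import MuscleLabel, MuscleLabelMap, VolumetricImage, ClinicalRatings
from .errors import SpecError
from .morphology import ErosionSpec, erode_labels
from .reliability import fat_rating_from_ff, stir_grade_from_fraction
from .stir import RigidTransform, StirMask

logger = logging.getLogger("myometry")

PATTERN_KINDS = ("homogeneous", "high_distal", "high_proximal", "high_ends", "high_center")


@dataclass(frozen=True)
class FFPattern:
    """Fat-fraction profile along normalized muscle length u in [0, 1].

    u = 0 is the inferior (distal) end. ``ff_low``/``ff_high`` are the
    plateau values (%); logistic kinds transition at ``center`` with scale
    ``width``; Gaussian-bump kinds use ``sigma``. Homogeneous muscles take
    the constant ``ff_const``.
    """

    kind: str = "homogeneous"
    ff_const: float = 20.0
    ff_low: float = 10.0
    ff_high: float = 70.0
    center: float = 0.5
    width: float = 0.08
    sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise SpecError(f"unknown FF pattern kind {self.kind!r}")
        for v in (self.ff_const, self.ff_low, self.ff_high):
            if not 0 <= v <= 100:
                raise SpecError(f"FF pattern values must lie in [0, 100], got {v}")

    def __call__(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        lo, hi = self.ff_low, self.ff_high
        if self.kind == "homogeneous":
            return np.full_like(u, self.ff_const)
        if self.kind == "high_distal":
            return lo + (hi - lo) / (1.0 + np.exp((u - self.center) / self.width))
        if self.kind == "high_proximal":
            return lo + (hi - lo) / (1.0 + np.exp(-(u - self.center) / self.width))
        bump = np.exp(-((u - 0.5) ** 2) / (2.0 * self.sigma**2))
        if self.kind == "high_center":
            return lo + (hi - lo) * bump
        return hi - (hi - lo) * bump  # high_ends


@dataclass(frozen=True)
class MuscleSpec:
    """Geometry and truth fields for one tube-shaped muscle."""

    code: int
    name: str
    side: str
    center_mm: tuple[float, float]  # in-plane axis position
    radii_mm: tuple[float, float]  # elliptical semi-axes at full scale
    z_extent_mm: tuple[float, float]
    ff_pattern: FFPattern = FFPattern()
    taper: str = "sine"  # none | linear | sine
    taper_min: float = 0.5  # cross-section scale at the tapered end(s)
    curve_amp_mm: float = 0.0  # lateral bow of the tube axis
    stir_fraction: float = 0.0  # target STIR+ fraction of the muscle's voxels
    stir_lesion_center: float = 0.5  # normalized-length position of the lesion slab
    stir_mild: bool = False  # grade-1 style diffuse lift instead of lesions

    def scale(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.taper == "none":
            return np.ones_like(u)
        if self.taper == "linear":
            return self.taper_min + (1.0 - self.taper_min) * u
        if self.taper == "sine":
            return self.taper_min + (1.0 - self.taper_min) * np.sin(np.pi * u)
        raise SpecError(f"unknown taper {self.taper!r}")

    def csa_mm2(self, u) -> np.ndarray:
        """Analytic cross-sectional area pi a(u) b(u) in mm^2."""
        s = self.scale(u)
        return np.pi * self.radii_mm[0] * self.radii_mm[1] * s * s

    def axis_xy(self, u) -> tuple[np.ndarray, np.ndarray]:
        u = np.asarray(u, dtype=float)
        cx = self.center_mm[0] + self.curve_amp_mm * np.sin(np.pi * u)
        cy = np.full_like(u, self.center_mm[1])
        return cx, cy


@dataclass
class PhantomSpec:
    """Full phantom description; fixed seed implies bit-reproducible output."""

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    limb_radius_mm: float = 45.0
    fat_thickness_mm: float = 6.0
    muscles: list[MuscleSpec] = field(default_factory=list)
    s0: float = 1000.0
    noise_sd: float = 0.0  # Dixon channel noise, fraction of s0
    noise_model: str = "gaussian"  # gaussian | rician
    intermuscular_ff: float = 15.0
    subcut_ff: float = 90.0
    stir_muscle_signal: float = 100.0
    stir_lesion_signal: float = 300.0
    stir_fat_signal: float = 40.0
    stir_mild_lift: float = 0.15  # fractional whole-muscle intensity lift, grade 1
    stir_noise_sd: float = 0.0  # absolute intensity units on the STIR volume
    dixon_to_stir: RigidTransform = field(default_factory=RigidTransform.identity)
    stir_slab: tuple[int, int] | None = None  # slice range of the STIR grid
    progression_dff: dict[int, float] = field(default_factory=dict)  # points per muscle
    progression_concentration: float = 2.0  # gradient-weight exponent
    seed: int = 0

    @property
    def limb_center_mm(self) -> tuple[float, float]:
        return (
            (self.shape[0] - 1) * self.spacing[0] / 2.0,
            (self.shape[1] - 1) * self.spacing[1] / 2.0,
        )


@dataclass
class PhantomDataset:
    """Generated volumes plus every piece of ground truth the tests need."""

    spec: PhantomSpec
    water: VolumetricImage
    fat: VolumetricImage
    stir: VolumetricImage
    labelmap: MuscleLabelMap
    truth_ff: np.ndarray  # voxelwise FF (%), NaN outside the limb
    limb: np.ndarray  # limb mask on the Dixon grid
    truth_stir_dixon: np.ndarray  # lesion mask, Dixon frame
    truth_stir: StirMask  # lesion mask on the STIR grid
    truth_transform: RigidTransform  # STIR-frame point -> Dixon-frame point
    stir_origin: tuple[float, float, float]  # physical origin of the STIR grid
    truth_stir_fraction: dict[int, float]  # per-muscle lesion voxel fraction (0-1)
    truth_stir_fraction_eroded: dict[int, float]  # same, over one-layer-eroded labels
    # (the quantity the STIR pathway reports with its default border erosion)
    analytic_mean_ff: dict[int, float]  # exact voxel-mean of the truth field
    ratings: ClinicalRatings
    clipped_ff_mass: float = 0.0  # percent-points x voxels lost to clipping at 100


def _coords(spec: PhantomSpec):
    sx, sy, sz = spec.spacing
    x = np.arange(spec.shape[0]) * sx
    y = np.arange(spec.shape[1]) * sy
    z = np.arange(spec.shape[2]) * sz
    return x, y, z


def _rasterize(spec: PhantomSpec):
    """Voxelize limb, subcutaneous ring and muscles; return masks + truth FF."""
    x, y, z = _coords(spec)
    cx0, cy0 = spec.limb_center_mm
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r2 = (xx - cx0) ** 2 + (yy - cy0) ** 2
    limb2d = r2 <= spec.limb_radius_mm**2
    inner2d = r2 <= (spec.limb_radius_mm - spec.fat_thickness_mm) ** 2
    limb = np.repeat(limb2d[:, :, None], spec.shape[2], axis=2)
    subcut = np.repeat((limb2d & ~inner2d)[:, :, None], spec.shape[2], axis=2)

    labels = np.zeros(spec.shape, dtype=np.int32)
    truth_ff = np.full(spec.shape, np.nan)
    truth_ff[limb] = spec.intermuscular_ff
    truth_ff[subcut] = spec.subcut_ff

    for m in spec.muscles:
        z0, z1 = m.z_extent_mm
        if z1 <= z0:
            raise SpecError(f"muscle {m.code}: empty z extent {m.z_extent_mm}")
        for k, zk in enumerate(z):
            if not (z0 <= zk <= z1):
                continue
            u = (zk - z0) / (z1 - z0)
            s = float(m.scale(u))
            if s <= 0:
                continue
            acx, acy = (float(v) for v in m.axis_xy(u))
            a, b = m.radii_mm[0] * s, m.radii_mm[1] * s
            inside = ((xx - acx) / a) ** 2 + ((yy - acy) / b) ** 2 <= 1.0
            clash = inside & (labels[:, :, k] != 0)
            if clash.any():
                other = int(labels[:, :, k][clash].flat[0])
                raise SpecError(f"muscle geometry overlap between codes {other} and {m.code}")
            if (inside & ~inner2d).any():
                logger.warning("muscle %d extends into the subcutaneous ring", m.code)
            labels[:, :, k][inside] = m.code
            truth_ff[:, :, k][inside] = float(m.ff_pattern(u))
    return limb, subcut, labels, truth_ff


def _muscle_u(spec_m: MuscleSpec, z_mm: np.ndarray) -> np.ndarray:
    z0, z1 = spec_m.z_extent_mm
    return (z_mm - z0) / (z1 - z0)


def _lesion_mask(spec: PhantomSpec, labels: np.ndarray) -> tuple[np.ndarray, dict[int, float]]:
    """Full-cross-section axial slabs sized to hit each target STIR fraction."""
    _, _, z = _coords(spec)
    lesions = np.zeros(spec.shape, dtype=bool)
    fractions: dict[int, float] = {}
    for m in spec.muscles:
        mask = labels == m.code
        total = int(mask.sum())
        if total == 0 or m.stir_fraction <= 0 or m.stir_mild:
            fractions[m.code] = 0.0
            continue
        counts = mask.sum(axis=(0, 1))
        occ = np.flatnonzero(counts)
        u = _muscle_u(m, z[occ])
        center_i = int(np.argmin(np.abs(u - m.stir_lesion_center)))
        chosen = {center_i}
        acc = int(counts[occ[center_i]])
        lo = hi = center_i
        target = m.stir_fraction * total
        last_added = None
        while acc < target and (lo > 0 or hi < len(occ) - 1):
            # grow the slab toward whichever side keeps it centred
            if hi - center_i <= center_i - lo and hi < len(occ) - 1:
                hi += 1
                last_added = hi
            elif lo > 0:
                lo -= 1
                last_added = lo
            else:
                hi += 1
                last_added = hi
            chosen.add(last_added)
            acc += int(counts[occ[last_added]])
        # the final slice may overshoot; keep whichever slab is closer to target
        if last_added is not None and len(chosen) > 1:
            without = acc - int(counts[occ[last_added]])
            if abs(without - target) < abs(acc - target):
                chosen.discard(last_added)
                acc = without
        for i in chosen:
            lesions[:, :, occ[i]] |= mask[:, :, occ[i]]
        fractions[m.code] = acc / total
    return lesions, fractions


def _stir_scene(spec: PhantomSpec, limb, subcut, labels, lesions) -> np.ndarray:
    scene = np.zeros(spec.shape)
    scene[limb] = spec.stir_fat_signal  # intermuscular + subcutaneous: fat-suppressed
    muscle_any = labels != 0
    scene[muscle_any] = spec.stir_muscle_signal
    for m in spec.muscles:
        if m.stir_mild:
            scene[labels == m.code] *= 1.0 + spec.stir_mild_lift
    scene[lesions] = spec.stir_lesion_signal
    return scene


def _dixon_noise(spec: PhantomSpec, clean: np.ndarray, limb: np.ndarray, rng) -> np.ndarray:
    """Channel noise: multiplicative Gaussian ``clean * (1 + eps)`` with
    fractional SD ``noise_sd`` (so the SD never exceeds that fraction of the
    base signal S0), clipped at zero; Rician optionable."""
    if spec.noise_sd <= 0:
        return clean
    if spec.noise_model == "rician":
        sd = spec.noise_sd * spec.s0
        out = np.hypot(clean + rng.normal(0.0, sd, clean.shape),
                       rng.normal(0.0, sd, clean.shape))
        return np.where(limb, out, 0.0)
    out = np.clip(clean * (1.0 + rng.normal(0.0, spec.noise_sd, clean.shape)), 0.0, None)
    return np.where(limb, out, 0.0)


def _resample_to_stir(
    scene: np.ndarray, spec: PhantomSpec, transform: RigidTransform,
    origin_z: float, n_slices: int, nearest: bool = False,
) -> np.ndarray:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(scene.astype(float), (2, 1, 0))))
    img.SetSpacing(tuple(spec.spacing))
    ref = sitk.Image(spec.shape[0], spec.shape[1], n_slices, sitk.sitkFloat64)
    ref.SetSpacing(tuple(spec.spacing))
    ref.SetOrigin((0.0, 0.0, origin_z))
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(img, ref, transform.to_sitk(), interp, 0.0)
    return np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0))


def generate(spec: PhantomSpec) -> PhantomDataset:
    """Build the phantom: deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    limb, subcut, labels, truth_ff = _rasterize(spec)

    ff = np.nan_to_num(truth_ff, nan=0.0)
    water_clean = np.where(limb, spec.s0 * (1.0 - ff / 100.0), 0.0)
    fat_clean = np.where(limb, spec.s0 * (ff / 100.0), 0.0)
    water_data = _dixon_noise(spec, water_clean, limb, rng)
    fat_data = _dixon_noise(spec, fat_clean, limb, rng)

    water = VolumetricImage(water_data, spec.spacing)
    fat = VolumetricImage(fat_data, spec.spacing)
    dictionary = {m.code: MuscleLabel(m.name, m.side) for m in spec.muscles}
    labelmap = MuscleLabelMap(labels=labels, dictionary=dictionary, spacing=spec.spacing)

    lesions, fractions = _lesion_mask(spec, labels)
    eroded = erode_labels(labelmap, ErosionSpec(mode="one_layer"))
    fractions_eroded = {
        m.code: (
            float(np.count_nonzero(lesions & eroded.mask(m.code)) / eroded.voxel_count(m.code))
            if eroded.voxel_count(m.code) else 0.0
        )
        for m in spec.muscles
    }
    scene = _stir_scene(spec, limb, subcut, labels, lesions)

    slab = spec.stir_slab or (0, spec.shape[2])
    n_slices = slab[1] - slab[0]
    origin_z = slab[0] * spec.spacing[2]
    identity = np.allclose(spec.dixon_to_stir.matrix, np.eye(3)) and np.allclose(
        spec.dixon_to_stir.translation, 0
    )
    if identity and spec.stir_slab is None:
        stir_data = scene.copy()
        stir_truth = lesions.copy()
    else:
        stir_data = _resample_to_stir(scene, spec, spec.dixon_to_stir, origin_z, n_slices)
        stir_truth = (
            _resample_to_stir(lesions.astype(float), spec, spec.dixon_to_stir,
                              origin_z, n_slices, nearest=True) > 0.5
        )
    if spec.stir_noise_sd > 0:
        stir_data = np.clip(stir_data + rng.normal(0, spec.stir_noise_sd, stir_data.shape), 0, None)
    stir_img = VolumetricImage(stir_data, spec.spacing)

    analytic_mean = {
        m.code: float(np.mean(truth_ff[labels == m.code])) for m in spec.muscles
        if (labels == m.code).any()
    }
    ratings = ClinicalRatings(
        fat_rating={c: fat_rating_from_ff(v) for c, v in analytic_mean.items()},
        stir_grade={
            m.code: stir_grade_from_fraction(
                100.0 * fractions.get(m.code, 0.0), mild_diffuse=m.stir_mild
            )
            for m in spec.muscles
        },
    )
    return PhantomDataset(
        spec=spec, water=water, fat=fat, stir=stir_img, labelmap=labelmap,
        truth_ff=truth_ff, limb=limb, truth_stir_dixon=lesions,
        truth_stir=StirMask(mask=stir_truth, spacing=spec.spacing, provenance="external"),
        truth_transform=spec.dixon_to_stir, stir_origin=(0.0, 0.0, origin_z),
        truth_stir_fraction=fractions, truth_stir_fraction_eroded=fractions_eroded,
        analytic_mean_ff=analytic_mean, ratings=ratings,
    )


def make_followup(dataset: PhantomDataset) -> PhantomDataset:
    """Follow-up timepoint: per-muscle FF increase weighted toward axial
    FF-transition zones.

    For each muscle with a programmed mean increase (``progression_dff`` in
    percentage points), the voxelwise increment is proportional to the
    magnitude of the axial gradient of the truth FF raised to the
    concentration exponent, renormalized so the muscle-mean increment
    equals the programmed value; zero-gradient (homogeneous) muscles fall
    back to a uniform increment. Values are clipped at 100 with the lost
    mass reported. Volumes are regenerated from the updated field with a
    fresh noise draw (seed + 1).
    """
    spec = dataset.spec
    labels = dataset.labelmap.labels
    new_ff = dataset.truth_ff.copy()
    clipped = 0.0
    _, _, z = _coords(spec)
    for m in spec.muscles:
        dff = spec.progression_dff.get(m.code, 0.0)
        mask = labels == m.code
        if dff == 0.0 or not mask.any():
            continue
        counts = mask.sum(axis=(0, 1))
        occ = np.flatnonzero(counts)
        f_slices = m.ff_pattern(_muscle_u(m, z[occ]))
        grad = np.abs(np.gradient(f_slices, z[occ])) if len(occ) > 1 else np.zeros(1)
        w = grad**spec.progression_concentration
        voxel_mean_w = float((w * counts[occ]).sum() / counts[occ].sum())
        if voxel_mean_w <= 0:
            w = np.ones_like(w)
            voxel_mean_w = 1.0
        inc_slices = dff * w / voxel_mean_w
        for i, k in enumerate(occ):
            new_ff[:, :, k][mask[:, :, k]] += inc_slices[i]
        over = np.clip(new_ff[mask] - 100.0, 0, None)
        clipped += float(over.sum())
    if clipped > 0:
        logger.warning("follow-up FF clipped at 100%%; lost mass %.3g point-voxels", clipped)
        new_ff = np.where(np.isnan(new_ff), new_ff, np.minimum(new_ff, 100.0))

    fspec = replace(spec, seed=spec.seed + 1)
    follow = generate(fspec)  # regenerate geometry/STIR deterministically
    # overwrite the Dixon channels with ones built from the progressed field
    rng = np.random.default_rng(fspec.seed + 104729)
    ff = np.nan_to_num(new_ff, nan=0.0)
    water_clean = np.where(dataset.limb, spec.s0 * (1.0 - ff / 100.0), 0.0)
    fat_clean = np.where(dataset.limb, spec.s0 * (ff / 100.0), 0.0)
    follow.water = VolumetricImage(_dixon_noise(spec, water_clean, dataset.limb, rng), spec.spacing)
    follow.fat = VolumetricImage(_dixon_noise(spec, fat_clean, dataset.limb, rng), spec.spacing)
    follow.truth_ff = new_ff
    follow.analytic_mean_ff = {
        c: float(np.mean(new_ff[labels == c])) for c in follow.analytic_mean_ff
    }
    follow.ratings = ClinicalRatings(
        fat_rating={c: fat_rating_from_ff(v) for c, v in follow.analytic_mean_ff.items()},
        stir_grade=dict(dataset.ratings.stir_grade),
    )
    follow.clipped_ff_mass = clipped
    return follow


def truth_ratings(dataset: PhantomDataset) -> ClinicalRatings:
    """Ordinal truth ratings derived from the ground-truth fields."""
    return dataset.ratings


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def minimal_spec(noise_sd: float = 0.0, seed: int = 0, **overrides) -> PhantomSpec:
    """Two-muscle phantom on a small grid; fast enough for unit tests."""
    muscles = [
        MuscleSpec(
            code=1, name="tibialis anterior", side="left",
            center_mm=(25.0, 39.0), radii_mm=(9.0, 7.0), z_extent_mm=(8.0, 84.0),
            ff_pattern=FFPattern(kind="homogeneous", ff_const=20.0),
            taper="sine", taper_min=0.5, stir_fraction=0.3,
        ),
        MuscleSpec(
            code=2, name="tibialis anterior", side="right",
            center_mm=(54.0, 42.0), radii_mm=(7.0, 5.5), z_extent_mm=(12.0, 88.0),
            ff_pattern=FFPattern(kind="high_distal", ff_low=10.0, ff_high=70.0),
            taper="sine", taper_min=0.5,
        ),
        # limbs are azimuthally asymmetric; a third, smaller muscle off the
        # left-right axis keeps phantom registration problems well posed
        MuscleSpec(
            code=3, name="soleus", side="left",
            center_mm=(39.0, 22.0), radii_mm=(6.0, 5.0), z_extent_mm=(20.0, 76.0),
            ff_pattern=FFPattern(kind="high_proximal", ff_low=5.0, ff_high=45.0),
            taper="linear", taper_min=0.6,
        ),
    ]
    base = dict(
        shape=(40, 40, 24), spacing=(2.0, 2.0, 4.0),
        limb_radius_mm=34.0, fat_thickness_mm=5.0,
        muscles=muscles, noise_sd=noise_sd, seed=seed,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def five_pattern_spec(noise_sd: float = 0.0, seed: int = 0, **overrides) -> PhantomSpec:
    """One muscle per archetypal FF distribution, arranged around the limb."""
    names = ["vastus lateralis", "rectus femoris", "semimembranosus",
             "biceps femoris long head", "adductor magnus"]
    patterns = [
        FFPattern(kind="homogeneous", ff_const=35.0),
        FFPattern(kind="high_distal", ff_low=10.0, ff_high=70.0),
        FFPattern(kind="high_proximal", ff_low=10.0, ff_high=70.0),
        FFPattern(kind="high_ends", ff_low=15.0, ff_high=65.0),
        FFPattern(kind="high_center", ff_low=15.0, ff_high=65.0),
    ]
    ring_r = 26.0
    cx0 = cy0 = (64 - 1) * 1.5 / 2.0
    muscles = []
    for i, (name, pat) in enumerate(zip(names, patterns)):
        ang = 2 * np.pi * i / 5
        muscles.append(
            MuscleSpec(
                code=i + 1, name=name, side="left",
                center_mm=(cx0 + ring_r * np.cos(ang), cy0 + ring_r * np.sin(ang)),
                radii_mm=(9.0, 7.5), z_extent_mm=(9.0, 132.0),
                ff_pattern=pat, taper="sine", taper_min=0.45,
            )
        )
    base = dict(shape=(64, 64, 48), spacing=(1.5, 1.5, 3.0), limb_radius_mm=45.0,
                fat_thickness_mm=6.0, muscles=muscles, noise_sd=noise_sd, seed=seed)
    base.update(overrides)
    return PhantomSpec(**base)


def large_muscle_spec(noise_sd: float = 0.0, seed: int = 0, **overrides) -> PhantomSpec:
    """Two >=10,000-voxel muscles for noise-robustness checks."""
    muscles = [
        MuscleSpec(
            code=1, name="quadriceps", side="left",
            center_mm=(28.0, 47.25), radii_mm=(17.0, 14.0), z_extent_mm=(6.0, 138.0),
            ff_pattern=FFPattern(kind="homogeneous", ff_const=30.0),
            taper="sine", taper_min=0.7,
        ),
        MuscleSpec(
            code=2, name="quadriceps", side="right",
            center_mm=(66.5, 47.25), radii_mm=(17.0, 14.0), z_extent_mm=(6.0, 138.0),
            ff_pattern=FFPattern(kind="high_proximal", ff_low=15.0, ff_high=55.0),
            taper="sine", taper_min=0.7,
        ),
    ]
    base = dict(shape=(64, 64, 48), spacing=(1.5, 1.5, 3.0), limb_radius_mm=45.0,
                fat_thickness_mm=6.0, muscles=muscles, noise_sd=noise_sd, seed=seed)
    base.update(overrides)
    return PhantomSpec(**base)


def rescan_spec(spec: PhantomSpec, jitter_mm: float = 0.7, seed_offset: int = 1000) -> PhantomSpec:
    """A short-interval repeat acquisition of the same subject.

    Re-positions the limb by a small random sub-voxel shift (muscle axes and
    extents move together), draws fresh noise, and re-rasterizes. Volumes
    and label maps therefore differ only by voxelization of the shifted
    geometry plus noise — the phantom analogue of a scan-rescan pair with
    ground-truth segmentation at both visits (no biological progression).
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    dx, dy = rng.uniform(-jitter_mm, jitter_mm, 2)
    dz = rng.uniform(-jitter_mm, jitter_mm)
    muscles = [
        replace(
            m,
            center_mm=(m.center_mm[0] + dx, m.center_mm[1] + dy),
            z_extent_mm=(m.z_extent_mm[0] + dz, m.z_extent_mm[1] + dz),
        )
        for m in spec.muscles
    ]
    return replace(spec, muscles=muscles, seed=spec.seed + seed_offset)


def cohort_specs(
    n_subjects: int = 10,
    muscles_per_subject: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Synthetic cohort with severity spread across the rating scales.

    Each subject carries ``muscles_per_subject`` homogeneous muscles whose
    mean FF is drawn over [2, 95]% and whose STIR+ fraction over [0, 80]%,
    so the cohort exercises every fat-rating and STIR-grade bin.
    """
    rng = np.random.default_rng(seed)
    specs = []
    centers = [(22.0, 39.0), (56.0, 39.0), (39.0, 58.0)]
    for s in range(n_subjects):
        muscles = []
        for i in range(muscles_per_subject):
            ff = float(rng.uniform(2.0, 95.0))
            stir_fraction = float(rng.uniform(0.0, 0.8))
            if stir_fraction < 0.05:
                stir_fraction = 0.0
            muscles.append(
                MuscleSpec(
                    code=i + 1, name=f"muscle_{i + 1}", side="left",
                    center_mm=centers[i % len(centers)],
                    radii_mm=(10.0, 8.0), z_extent_mm=(8.0, 88.0),
                    ff_pattern=FFPattern(kind="homogeneous", ff_const=ff),
                    taper="sine", taper_min=0.55,
                    stir_fraction=stir_fraction,
                )
            )
        specs.append(
            PhantomSpec(
                shape=(40, 40, 26), spacing=(2.0, 2.0, 4.0),
                limb_radius_mm=37.0, fat_thickness_mm=5.0,
                muscles=muscles, noise_sd=noise_sd,
                stir_noise_sd=5.0, seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
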