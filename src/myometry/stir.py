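"""STIR hyperintensity quantification.

Pathway: segment STIR-positive voxels on the STIR image with limb-local
Otsu thresholding, rigidly register the Dixon frame to the STIR frame,
resample the muscle labels onto the STIR grid, erode one pixel layer to
absorb residual registration error at muscle borders, and report per-muscle
STIR content — the percentage of a muscle's voxels that are STIR positive.

Local thresholding emulates an operator's threshold-paint strokes with a
deterministic tiling: circular windows whose diameter is a fraction
(default 20%) of the limb's equivalent diameter, tiled with 50% overlap;
each window contributes the pixels above both its Otsu threshold and a
global hyperintensity floor (a multiple of typical muscle intensity), and a
window whose Otsu split does not clear a robust bimodality guard
contributes nothing, so homogeneous windows are never labeled all-bright.
Because windows fully inside a large lesion are homogeneous and hence
rejected, detected boundary annuli are closed by per-slice hole filling
before the limb-edge exclusion margin is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_multiotsu, threshold_otsu

from .core import MuscleLabelMap, VolumetricImage
from .errors import AlignmentError, ParameterError, RegistrationError
from .morphology import ErosionSpec, disc_footprint, erode_labels

logger = logging.getLogger("myometry")


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """6-DOF rigid map y = R (x - c) + c + t in physical (mm) coordinates.

    Stored as a rotation matrix plus translation and rotation centre;
    Euler angles (degrees, extrinsic xyz) are derived views for reporting.
    As used by the STIR pathway this is the map from STIR-frame points to
    Dixon-frame points (the resampling direction).
    """

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(
        cls,
        angles_deg: tuple[float, float, float],
        translation_mm: tuple[float, float, float],
        center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", angles_deg, degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation_mm), np.asarray(center_mm))

    @property
    def rotation_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.matrix).as_euler("xyz", degrees=True)

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation magnitude (geodesic angle), degrees."""
        return float(np.degrees(Rotation.from_matrix(self.matrix).magnitude()))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        out = (pts - self.center) @ self.matrix.T + self.center + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        # flatten both to y = M x + v form, then refactor about self.center
        m1, v1 = other.matrix, other.translation + other.center - other.matrix @ other.center
        m2, v2 = self.matrix, self.translation + self.center - self.matrix @ self.center
        m = m2 @ m1
        v = m2 @ v1 + v2
        return RigidTransform(m, v + m @ self.center - self.center, self.center)

    def inverse(self) -> "RigidTransform":
        minv = self.matrix.T
        v = self.translation + self.center - self.matrix @ self.center
        vinv = -minv @ v
        return RigidTransform(minv, vinv + minv @ self.center - self.center, self.center)

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(self.matrix.flatten())
        t.SetCenter(tuple(self.center))
        t.SetTranslation(tuple(self.translation))
        return t

    @classmethod
    def from_sitk(cls, t) -> "RigidTransform":
        matrix = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
        return cls(matrix, np.asarray(t.GetTranslation()), np.asarray(t.GetCenter()))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": [float(v) for v in self.rotation_deg],
            "translation_mm": [float(v) for v in self.translation],
            "center_mm": [float(v) for v in self.center],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_euler(d["rotation_deg"], d["translation_mm"], d["center_mm"])


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------

def to_sitk_image(vol: VolumetricImage, origin: tuple[float, float, float] = (0, 0, 0)) -> sitk.Image:
    """VolumetricImage -> sitk.Image (array axes (x,y,z) -> sitk (z,y,x))."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0))))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(origin))
    return img


def _labels_to_sitk(lmap: MuscleLabelMap, origin=(0, 0, 0)) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(lmap.labels.astype(np.int32), (2, 1, 0)))
    )
    img.SetSpacing(tuple(lmap.spacing))
    img.SetOrigin(tuple(origin))
    return img


# ---------------------------------------------------------------------------
# Limb mask and STIR+ segmentation
# ---------------------------------------------------------------------------

@dataclass
class StirMask:
    """Binary STIR-positive mask on the STIR image grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = "threshold"  # "threshold" | "manual" | "external"


def limb_mask(stir: VolumetricImage) -> np.ndarray:
    """Foreground limb mask, slice by slice.

    The air/tissue threshold is estimated once from the whole volume — with
    fat-suppressed subcutaneous tissue the histogram is multimodal (air,
    fat, muscle, possible hyperintensity), and the lowest 3-class Otsu
    threshold keeps the whole limb; volume-level statistics are robust to
    single slices whose content (e.g. a large lesion) skews a per-slice
    histogram. Hole filling and largest-component selection then run per
    slice. A slice with no foreground yields an empty mask slice.
    """
    axis = stir.axial_axis
    out = np.zeros(stir.shape, dtype=bool)
    if np.ptp(stir.data) == 0:
        return out
    try:
        thr = threshold_multiotsu(stir.data.ravel(), classes=3)[0]
    except ValueError:
        thr = threshold_otsu(stir.data.ravel())
    for z in range(stir.shape[axis]):
        sl: list = [slice(None)] * 3
        sl[axis] = z
        sl = tuple(sl)
        plane = stir.data[sl]
        fg = plane > thr
        fg = ndimage.binary_fill_holes(fg)
        lab, n = ndimage.label(fg)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        out[sl] = lab == (int(np.argmax(sizes)) + 1)
    return out


def _window_centers(limb_plane: np.ndarray, radius: int) -> list[tuple[int, int]]:
    """Centres of circular windows tiling the limb with 50% overlap."""
    xs, ys = np.nonzero(limb_plane)
    step = max(1, radius)  # step = radius -> adjacent windows overlap by one radius
    centers = []
    for cx in range(xs.min(), xs.max() + step, step):
        for cy in range(ys.min(), ys.max() + step, step):
            if limb_plane[min(cx, limb_plane.shape[0] - 1), min(cy, limb_plane.shape[1] - 1)]:
                centers.append((cx, cy))
    return centers


def _hyperintensity_floor(stir_vals: np.ndarray, factor: float) -> float:
    """Global STIR+ floor over limb voxels.

    Fat-suppressed tissue is split off with the lowest 3-class Otsu
    threshold; typical muscle intensity is the lower quartile of what
    remains (robust to lesions occupying a large share of muscle). When the
    limb holds a credible hyperintense class — the upper 3-class Otsu
    threshold isolates voxels at least ``factor`` x typical muscle — that
    threshold is the floor (it bisects muscle and lesion, which classifies
    partial-volume boundary voxels by majority tissue). Otherwise the floor
    is ``factor`` x typical muscle, a conservative bound refined by the
    per-window local thresholds."""
    try:
        t_fat, t_bright = threshold_multiotsu(stir_vals, classes=3)
    except ValueError:
        t_fat = threshold_otsu(stir_vals) if np.ptp(stir_vals) > 0 else stir_vals.min()
        t_bright = None
    muscle_vals = stir_vals[stir_vals > t_fat]
    if muscle_vals.size == 0:
        muscle_vals = stir_vals
    muscle_ref = float(np.percentile(muscle_vals, 25))
    if t_bright is not None and t_bright > factor * muscle_ref:
        bright_vals = stir_vals[stir_vals > t_bright]
        if bright_vals.size and float(np.median(bright_vals)) >= factor * muscle_ref:
            return float(t_bright)
    return factor * muscle_ref


def segment_stir(
    stir: VolumetricImage,
    limb: np.ndarray,
    region_fraction: float = 0.20,
    edge_margin_px: int = 2,
    separation_mad: float = 3.0,
    hyperintensity_factor: float = 1.5,
    min_window_px: int = 9,
    ff_on_stir: np.ndarray | None = None,
    ff_veto_threshold: float = 50.0,
) -> StirMask:
    """Segment STIR-positive voxels by tiled limb-local Otsu thresholding.

    A pixel is marked STIR+ when some covering window's Otsu threshold
    passes the bimodality guard and the pixel exceeds both that local
    threshold and the global hyperintensity floor. The floor encodes what
    "hyperintense" means — brighter than normal muscle by a clear margin —
    so that muscle-against-fat contrast inside a window is never mistaken
    for hyperintensity; the local thresholds adapt the exact boundary to
    intensity inhomogeneity across the limb.

    Parameters
    ----------
    region_fraction : float
        Window diameter as a fraction of the limb's per-slice equivalent
        diameter (default 0.20).
    edge_margin_px : int
        Pixels adjacent to the limb boundary to exclude (smooth edge
        artifacts from image biasing).
    separation_mad : float
        Bimodality guard: a window's Otsu threshold must exceed the window
        median by this many (scaled) median absolute deviations, else the
        window is considered homogeneous and yields no detections.
    hyperintensity_factor : float
        Global floor as a multiple of the limb's typical (lower-quartile)
        muscle intensity; candidate pixels below it are never STIR+.
    ff_on_stir : ndarray, optional
        Voxelwise Dixon fat fraction resampled onto the STIR grid. When
        given, candidate STIR+ voxels with FF above ``ff_veto_threshold``
        are vetoed — the automated version of cross-checking bright spots
        against the Dixon images to avoid calling fat hyperintense.
    """
    if not 0 < region_fraction <= 1:
        raise ParameterError(f"region_fraction must lie in (0, 1], got {region_fraction}")
    limb = np.asarray(limb, dtype=bool)
    if limb.shape != stir.shape:
        raise AlignmentError("limb mask shape does not match STIR volume")
    axis = stir.axial_axis
    detected = np.zeros(stir.shape, dtype=bool)
    if not limb.any():
        return StirMask(mask=detected, spacing=stir.spacing, provenance="threshold")
    floor = _hyperintensity_floor(stir.data[limb], hyperintensity_factor)
    inplane = tuple(a for a in range(3) if a != axis)
    areas = limb.sum(axis=inplane)
    med_d_eq = 2.0 * np.sqrt(np.median(areas[areas > 0]) / np.pi)
    med_radius = int(round(region_fraction * med_d_eq / 2.0))
    if np.pi * med_radius**2 < min_window_px:
        raise ParameterError(
            f"region_fraction {region_fraction} gives {med_radius} px window radius "
            f"(area below {min_window_px} px^2) on the median limb slice"
        )
    for z in range(stir.shape[axis]):
        sl: list = [slice(None)] * 3
        sl[axis] = z
        sl = tuple(sl)
        plane = stir.data[sl]
        limb_plane = limb[sl]
        area = int(limb_plane.sum())
        if area == 0:
            continue
        d_eq = 2.0 * np.sqrt(area / np.pi)
        # partial-coverage end slices get the smallest viable window
        radius = max(2, int(round(region_fraction * d_eq / 2.0)))
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        disc = (yy * yy + xx * xx) <= radius * radius
        marked = np.zeros_like(limb_plane)
        for cx, cy in _window_centers(limb_plane, radius):
            x0, x1 = max(0, cx - radius), min(plane.shape[0], cx + radius + 1)
            y0, y1 = max(0, cy - radius), min(plane.shape[1], cy + radius + 1)
            sub_disc = disc[
                x0 - (cx - radius) : x1 - (cx - radius),
                y0 - (cy - radius) : y1 - (cy - radius),
            ]
            window_sel = sub_disc & limb_plane[x0:x1, y0:y1]
            vals = plane[x0:x1, y0:y1][window_sel]
            if vals.size < min_window_px:
                continue
            effective = floor
            if np.ptp(vals) > 0:
                thr = threshold_otsu(vals)
                med = np.median(vals)
                mad = 1.4826 * np.median(np.abs(vals - med))
                if thr > med + separation_mad * mad:
                    # credible local bright class: let the local split tighten
                    # (never loosen) the global hyperintensity floor
                    effective = max(thr, floor)
            bright = np.zeros_like(window_sel)
            bright[window_sel] = plane[x0:x1, y0:y1][window_sel] > effective
            marked[x0:x1, y0:y1] |= bright
        # close interiors of large lesions whose inside windows were homogeneous
        marked = ndimage.binary_fill_holes(marked)
        if edge_margin_px > 0:
            interior = ndimage.binary_erosion(
                limb_plane, structure=disc_footprint(edge_margin_px)
            )
            marked &= interior
        else:
            marked &= limb_plane
        detected[sl] = marked
    if ff_on_stir is not None:
        veto = np.asarray(ff_on_stir) > ff_veto_threshold
        n_veto = int(np.count_nonzero(detected & veto))
        if n_veto:
            logger.info("FF veto removed %d candidate STIR+ voxels", n_veto)
        detected &= ~veto
    return StirMask(mask=detected, spacing=stir.spacing, provenance="threshold")


# ---------------------------------------------------------------------------
# Registration and resampling
# ---------------------------------------------------------------------------

def register_rigid(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    metric: str = "mattes",
    seed: int = 12345,
    sampling_fraction: float = 0.5,
    moving_origin: tuple[float, float, float] = (0, 0, 0),
    fixed_origin: tuple[float, float, float] = (0, 0, 0),
) -> RigidTransform:
    """Recover the 6-DOF rigid map from fixed-frame to moving-frame points.

    Multi-resolution (4x, 2x, 1x) registration initialized by centre-of-
    mass alignment; Mattes mutual information by default (the Dixon water
    and STIR images are different contrasts), mean squared error available
    for same-modality checks. Deterministic for a fixed ``seed``.
    """
    if metric not in ("mattes", "mse"):
        raise ParameterError(f"metric must be 'mattes' or 'mse', got {metric!r}")
    f_img = to_sitk_image(fixed, origin=fixed_origin)
    m_img = to_sitk_image(moving, origin=moving_origin)
    f_img = sitk.Cast(f_img, sitk.sitkFloat64)
    m_img = sitk.Cast(m_img, sitk.sitkFloat64)

    # evaluate the metric only inside a conservatively trimmed limb mask: a
    # region whose samples stay inside the moving buffer for any plausible
    # offset, so metric values are comparable across candidate transforms
    # (mutual information over a sliding overlap region is not)
    fmask_img = None
    fmask = limb_mask(fixed)
    if fmask.any():
        axis = fixed.axial_axis
        occupied = np.flatnonzero(fmask.sum(axis=tuple(a for a in range(3) if a != axis)))
        trim = int(np.ceil(15.0 / fixed.spacing[axis]))  # mm of axial margin
        keep = occupied[trim:-trim] if len(occupied) > 2 * trim else occupied
        sel = np.zeros(fmask.shape[axis], dtype=bool)
        sel[keep] = True
        fmask &= np.moveaxis(np.broadcast_to(sel, np.moveaxis(fmask, axis, -1).shape), -1, axis)
        footprint = np.ones((7, 7), dtype=bool)
        for z in np.flatnonzero(sel):
            sl: list = [slice(None)] * 3
            sl[axis] = z
            fmask[tuple(sl)] = ndimage.binary_erosion(fmask[tuple(sl)], structure=footprint)
        if fmask.any():
            fmask_img = sitk.GetImageFromArray(
                np.ascontiguousarray(np.transpose(fmask.astype(np.uint8), (2, 1, 0))))
            fmask_img.CopyInformation(f_img)

    candidates = []
    trace: list[float] = []
    # multi-start: moments- and geometry-centred initializations both run to
    # convergence and the better final metric wins — cheap insurance against
    # a poor centre-of-mass estimate when coverage differs between frames
    for init_mode in (
        sitk.CenteredTransformInitializerFilter.MOMENTS,
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    ):
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler3DTransform(), init_mode
        )
        reg = sitk.ImageRegistrationMethod()
        if metric == "mattes":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
        else:
            reg.SetMetricAsMeanSquares()
        if fmask_img is not None:
            reg.SetMetricFixedMask(fmask_img)
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-9, numberOfIterations=200)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        # a half-voxel smoothing at full resolution keeps the metric surface
        # differentiable against voxelization; without it LBFGSB stalls on
        # plateaus of piecewise-constant intensity
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.5])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(initial, inPlace=False)
        reg.AddCommand(sitk.sitkIterationEvent, lambda r=reg: trace.append(r.GetMetricValue()))
        try:
            final = reg.Execute(f_img, m_img)
        except RuntimeError as exc:
            # e.g. a geometry-centred start with no overlap at the coarse level;
            # fine as long as some start converges
            logger.warning("registration start failed (%s); trying next initializer", exc)
            continue
        final = final.Downcast()
        if isinstance(final, sitk.CompositeTransform):
            final = final.GetNthTransform(final.GetNumberOfTransforms() - 1).Downcast()
        candidates.append((reg.GetMetricValue(), RigidTransform.from_sitk(final),
                           reg.GetOptimizerStopConditionDescription()))
    if not candidates:
        raise RegistrationError("no registration start converged", metric_trace=trace)
    best_metric, best, stop = min(candidates, key=lambda c: c[0])

    # the through-plane axis is the weakly constrained one (thick slices,
    # near-cylindrical anatomy): the metric has sub-slice-scale ripples the
    # optimizer does not cross, so refine at full resolution from axial
    # perturbations of the coarse optimum down to quarter-slice steps and
    # keep the best final metric
    dz = fixed.spacing[fixed.axial_axis]
    refined: list[tuple[float, RigidTransform, str]] = []
    shifts = sorted({s * dz for s in (-1, -0.5, 0.0, 0.5, 1)})
    for shift in shifts:
        start = sitk.Euler3DTransform()
        start.SetCenter(tuple(best.center))
        start.SetMatrix(tuple(best.matrix.flatten()))
        tr = best.translation.copy()
        tr[fixed.axial_axis] += shift
        start.SetTranslation(tuple(tr))
        reg = sitk.ImageRegistrationMethod()
        if metric == "mattes":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
        else:
            reg.SetMetricAsMeanSquares()
        if fmask_img is not None:
            reg.SetMetricFixedMask(fmask_img)
        reg.SetInterpolator(sitk.sitkLinear)
        # gradient descent with physical-shift scaling for the local polish:
        # quasi-Newton steps are mis-scaled across rotation/translation
        # parameters here and stall short of the optimum
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=0.5, minStep=1e-5, numberOfIterations=120,
            relaxationFactor=0.5, gradientMagnitudeTolerance=1e-10,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([1])
        reg.SetSmoothingSigmasPerLevel([0.5])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(start, inPlace=False)
        try:
            final = reg.Execute(f_img, m_img)
        except RuntimeError as exc:
            logger.warning("axial refinement start %+.1f mm failed (%s)", shift, exc)
            continue
        final = final.Downcast()
        if isinstance(final, sitk.CompositeTransform):
            final = final.GetNthTransform(final.GetNumberOfTransforms() - 1).Downcast()
        refined.append((reg.GetMetricValue(), RigidTransform.from_sitk(final),
                        reg.GetOptimizerStopConditionDescription()))
    if refined:
        best_metric, best, stop = min(refined, key=lambda c: c[0])
    logger.info("registration (%s): %d evaluations, best metric %.6g, stop: %s",
                metric, len(trace), best_metric, stop)
    return best


def resample_labels(
    labelmap: MuscleLabelMap,
    transform: RigidTransform,
    reference: VolumetricImage,
    labelmap_origin: tuple[float, float, float] = (0, 0, 0),
    reference_origin: tuple[float, float, float] = (0, 0, 0),
) -> MuscleLabelMap:
    """Nearest-neighbour resample of integer labels onto the reference grid.

    ``transform`` maps reference-frame points to label-frame points (the
    output of ``register_rigid(moving=dixon, fixed=stir)``). Voxels mapping
    outside the label volume become background.
    """
    lab_img = _labels_to_sitk(labelmap, origin=labelmap_origin)
    ref_img = to_sitk_image(reference, origin=reference_origin)
    out = sitk.Resample(lab_img, ref_img, transform.to_sitk(), sitk.sitkNearestNeighbor, 0)
    arr = np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0)).astype(labelmap.labels.dtype)
    return MuscleLabelMap(
        labels=arr,
        dictionary=dict(labelmap.dictionary),
        spacing=reference.spacing,
        axial_axis=reference.axial_axis,
        superior_direction=reference.superior_direction,
    )


# ---------------------------------------------------------------------------
# Content
# ---------------------------------------------------------------------------

@dataclass
class StirContent:
    """Per-muscle STIR positivity."""

    code: int
    name: str
    side: str
    stir_pct: float  # 100 * stir_voxels / total_voxels; NaN if muscle empty
    stir_voxels: int
    total_voxels: int
    flagged_empty: bool = False


def stir_content(
    stir_mask: StirMask,
    labels_on_stir: MuscleLabelMap,
    erode_first: bool = True,
) -> list[StirContent]:
    """STIR content (%) per muscle: STIR+ voxels inside the (optionally
    one-layer-eroded) muscle boundary as a percentage of its voxels."""
    if stir_mask.mask.shape != labels_on_stir.labels.shape:
        raise AlignmentError("STIR mask and labels are on different grids")
    lmap = labels_on_stir
    if erode_first:
        lmap = erode_labels(labels_on_stir, ErosionSpec(mode="one_layer"))
    out: list[StirContent] = []
    for code in sorted(labels_on_stir.dictionary):
        entry = labels_on_stir.dictionary[code]
        total = lmap.voxel_count(code)
        if total == 0:
            logger.warning("code %d (%s) empty after erosion on STIR grid; flagged", code, entry.name)
            out.append(StirContent(code, entry.name, entry.side, float("nan"), 0, 0, True))
            continue
        pos = int(np.count_nonzero(stir_mask.mask & lmap.mask(code)))
        out.append(StirContent(code, entry.name, entry.side, 100.0 * pos / total, pos, total))
    return out
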