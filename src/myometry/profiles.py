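"""Slice-wise CSA decomposition and percent-of-length normalization.

Muscle composition is computed on every axial slice the muscle occupies
(boundary CSA = labeled pixels x pixel area; area FF is the voxel-ratio
mean restricted to the slice; fat/lean CSA split the boundary CSA by the
area FF) and then re-expressed on a 0-100% inferior-to-superior axis with
linear interpolation at 1% increments. Percent positions come from
physical slice positions in mm, not slice counts, so anisotropic or gapped
acquisitions normalize correctly. Interpolation is piecewise-linear between
slice centres: linearity preserves the lean + fat = boundary closure at
every interpolated point, which splines would not.

The muscle ends taper to a few pixels where discretization noise dominates,
so profiles are conventionally displayed trimmed to the central 10-90% of
length; ``trim_profile`` restricts the grid while keeping the untrimmed
profile available for metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .composition import voxel_ff
from .core import MuscleLabelMap, VolumetricImage
from .errors import AlignmentError, EmptyMuscleError, ParameterError

logger = logging.getLogger("myometry")

METRIC_NAMES = ("boundary_csa", "lean_csa", "fat_csa", "area_ff")


@dataclass
class SliceMetrics:
    """Composition of one axial slice of one muscle."""

    index: int  # storage slice index
    position_mm: float  # physical position, increasing toward superior
    boundary_csa: float  # mm^2
    lean_csa: float  # mm^2
    fat_csa: float  # mm^2
    area_ff: float  # percent; NaN when every pixel in the slice is zero-signal


@dataclass
class LengthProfile:
    """Muscle metrics on a percent-of-length grid (0 = inferior end)."""

    percent: np.ndarray
    boundary_csa: np.ndarray
    lean_csa: np.ndarray
    fat_csa: np.ndarray
    area_ff: np.ndarray
    inferior_slice: int
    superior_slice: int
    untrimmed: "LengthProfile | None" = field(default=None, repr=False)

    def metric(self, name: str) -> np.ndarray:
        if name not in METRIC_NAMES:
            raise ParameterError(f"unknown profile metric {name!r}")
        return getattr(self, name)


def slice_metrics(
    water: VolumetricImage,
    fat: VolumetricImage,
    labelmap: MuscleLabelMap,
    code: int,
    min_voxels: int = 1,
) -> list[SliceMetrics]:
    """Per-slice composition for one muscle, ordered inferior to superior.

    A slice counts as occupied when it holds at least ``min_voxels`` labeled
    pixels (default 1: no minimum-area filtering; end effects are handled
    by trimming instead).
    """
    if code not in labelmap.dictionary:
        raise EmptyMuscleError(f"code {code} not in label dictionary")
    mask = labelmap.mask(code)
    if not mask.any():
        raise EmptyMuscleError(f"code {code} has no voxels")
    axis = labelmap.axial_axis
    pixel_area = labelmap.pixel_area
    dz = labelmap.spacing[axis]
    ffmap = voxel_ff(water, fat, mask)

    inplane = tuple(a for a in range(3) if a != axis)
    counts = mask.sum(axis=inplane)
    occupied = np.flatnonzero(counts >= max(1, min_voxels))

    out: list[SliceMetrics] = []
    for idx in occupied:
        sl: list = [slice(None)] * 3
        sl[axis] = idx
        sl = tuple(sl)
        n = int(counts[idx])
        boundary = n * pixel_area
        defined = ffmap.defined[sl]
        if defined.any():
            ff = float(np.mean(ffmap.values[sl][defined]))
        else:
            ff = float("nan")
        out.append(
            SliceMetrics(
                index=int(idx),
                position_mm=float(idx) * dz * labelmap.superior_direction,
                boundary_csa=boundary,
                lean_csa=boundary * (1.0 - ff / 100.0),
                fat_csa=boundary * ff / 100.0,
                area_ff=ff,
            )
        )
    out.sort(key=lambda s: s.position_mm)  # inferior first regardless of storage direction
    return out


def normalize_profile(slices: list[SliceMetrics]) -> LengthProfile:
    """Map per-slice metrics onto the 0-100% length grid at 1% increments.

    0% is the inferior-most occupied slice and 100% the superior-most; each
    metric is linearly interpolated between slice centres. A single-slice
    muscle yields a constant profile.
    """
    if not slices:
        raise EmptyMuscleError("no occupied slices to normalize")
    ordered = sorted(slices, key=lambda s: s.position_mm)
    pos = np.array([s.position_mm for s in ordered])
    grid = np.arange(101, dtype=float)
    if len(ordered) == 1:
        logger.warning("single-slice muscle: profile is constant")
        vals = {m: np.full(101, getattr(ordered[0], m)) for m in METRIC_NAMES}
    else:
        span = pos[-1] - pos[0]
        percent_pos = (pos - pos[0]) / span * 100.0
        vals = {
            m: np.interp(grid, percent_pos, np.array([getattr(s, m) for s in ordered]))
            for m in METRIC_NAMES
        }
    return LengthProfile(
        percent=grid,
        boundary_csa=vals["boundary_csa"],
        lean_csa=vals["lean_csa"],
        fat_csa=vals["fat_csa"],
        area_ff=vals["area_ff"],
        inferior_slice=ordered[0].index,
        superior_slice=ordered[-1].index,
    )


def trim_profile(profile: LengthProfile, low: float = 10.0, high: float = 90.0) -> LengthProfile:
    """Restrict a profile to [low, high] percent of length.

    The returned profile keeps a reference to the untrimmed profile so
    whole-muscle metrics remain computable after trimming for display.
    """
    if not (0 <= low < high <= 100):
        raise ParameterError(f"invalid trim bounds [{low}, {high}]")
    keep = (profile.percent >= low) & (profile.percent <= high)
    base = profile.untrimmed if profile.untrimmed is not None else profile
    return LengthProfile(
        percent=profile.percent[keep],
        boundary_csa=profile.boundary_csa[keep],
        lean_csa=profile.lean_csa[keep],
        fat_csa=profile.fat_csa[keep],
        area_ff=profile.area_ff[keep],
        inferior_slice=profile.inferior_slice,
        superior_slice=profile.superior_slice,
        untrimmed=base,
    )


def profile_delta(baseline: LengthProfile, followup: LengthProfile) -> dict[str, np.ndarray]:
    """Follow-up minus baseline for every metric, per percent point."""
    if baseline.percent.shape != followup.percent.shape or not np.array_equal(
        baseline.percent, followup.percent
    ):
        raise AlignmentError("profiles are on different percent grids")
    return {m: followup.metric(m) - baseline.metric(m) for m in METRIC_NAMES}


def muscle_profile(
    water: VolumetricImage,
    fat: VolumetricImage,
    labelmap: MuscleLabelMap,
    code: int,
    trim: tuple[float, float] | None = None,
) -> LengthProfile:
    """Convenience: slice metrics -> normalized (optionally trimmed) profile."""
    prof = normalize_profile(slice_metrics(water, fat, labelmap, code))
    if trim is not None:
        prof = trim_profile(prof, *trim)
    return prof
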