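"""Per-muscle composition: boundary volume, fat fraction, fat/lean volume.

The per-muscle fat fraction is the mean of voxelwise signal ratios,

    FF_muscle = (1/TP) * sum_p FSI_p / (FSI_p + WSI_p) * 100,

over the TP voxels in the muscle label, where FSI/WSI are the Dixon fat and
water signal intensities. This voxel-mean form is used deliberately instead
of total-fat / total-signal: the two differ under intensity inhomogeneity.
Fat and lean volumes follow as

    FatVolume  = BoundaryVolume * FF/100
    LeanVolume = BoundaryVolume * (1 - FF/100)

so fat + lean = boundary closes exactly by construction. Voxels with zero
total signal have an undefined ratio; they are excluded from the FF average
(counted separately) but still contribute to the boundary volume, which is
purely a voxel count times voxel volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MuscleLabelMap, VolumetricImage
from .errors import AlignmentError, EmptyMuscleError, ParameterError

logger = logging.getLogger("myometry")


@dataclass
class FFMap:
    """Voxelwise fat fraction (percent) over a mask.

    ``values`` is NaN outside the mask and at excluded (zero-signal)
    voxels; ``mask`` is the full muscle mask, ``excluded`` the zero-signal
    subset of it.
    """

    values: np.ndarray
    mask: np.ndarray
    excluded: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def defined(self) -> np.ndarray:
        return self.mask & ~self.excluded

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.defined]


@dataclass
class FFHistogram:
    """Fat-fraction histogram over a muscle's voxels (0-100%)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


@dataclass
class CompositionMetrics:
    """Volumetric composition of one muscle."""

    code: int
    name: str
    side: str
    boundary_volume: float  # mm^3
    fat_fraction: float  # percent; NaN if every voxel had zero signal
    fat_volume: float  # mm^3
    lean_volume: float  # mm^3
    tp: int  # voxels entering the FF average
    excluded_voxels: int  # zero-signal voxels (in boundary, not in FF)
    present: bool = True  # False for dictionary codes absent from the grid

    def to_records(self) -> list[dict]:
        unit_map = [
            ("boundary_volume", self.boundary_volume, "mm^3"),
            ("fat_fraction", self.fat_fraction, "%"),
            ("fat_volume", self.fat_volume, "mm^3"),
            ("lean_volume", self.lean_volume, "mm^3"),
            ("tp", self.tp, "voxels"),
            ("excluded_voxels", self.excluded_voxels, "voxels"),
        ]
        return [
            {"muscle": self.name, "side": self.side, "metric": m, "value": v, "units": u}
            for m, v, u in unit_map
        ]


def _check_grids(water: VolumetricImage, fat: VolumetricImage) -> None:
    if not water.same_grid(fat):
        raise AlignmentError(
            f"water grid {water.shape}@{water.spacing} != fat grid {fat.shape}@{fat.spacing}"
        )


def voxel_ff(water: VolumetricImage, fat: VolumetricImage, mask: np.ndarray) -> FFMap:
    """Voxelwise fat fraction FSI/(FSI+WSI)*100 over ``mask``.

    Zero-total-signal voxels are marked excluded rather than assigned a
    value, so downstream averages never see NaN from a 0/0.
    """
    _check_grids(water, fat)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != water.shape:
        raise AlignmentError(f"mask shape {mask.shape} != volume shape {water.shape}")
    if not mask.any():
        raise EmptyMuscleError("empty mask passed to voxel_ff")
    total = water.data + fat.data
    excluded = mask & (total == 0)
    values = np.full(water.shape, np.nan)
    ok = mask & (total > 0)
    values[ok] = fat.data[ok] / total[ok] * 100.0
    return FFMap(values=values, mask=mask, excluded=excluded, spacing=water.spacing)


def muscle_composition(
    water: VolumetricImage,
    fat: VolumetricImage,
    labelmap: MuscleLabelMap,
    code: int,
    on_all_excluded: str = "nan",
) -> CompositionMetrics:
    """Boundary volume, fat fraction and fat/lean volumes for one muscle.

    ``on_all_excluded`` controls the degenerate case where every labeled
    voxel has zero total signal: ``"nan"`` (default) reports an undefined
    FF, ``"error"`` raises.
    """
    if code not in labelmap.dictionary:
        raise EmptyMuscleError(f"code {code} not in label dictionary")
    mask = labelmap.mask(code)
    n_voxels = int(np.count_nonzero(mask))
    if n_voxels == 0:
        raise EmptyMuscleError(f"code {code} has no voxels in the label grid")
    ffmap = voxel_ff(water, fat, mask)
    tp = int(np.count_nonzero(ffmap.defined))
    excluded = int(np.count_nonzero(ffmap.excluded))
    boundary = n_voxels * labelmap.voxel_volume
    if tp == 0:
        if on_all_excluded == "error":
            raise EmptyMuscleError(f"code {code}: all {n_voxels} voxels have zero signal")
        ff = float("nan")
    else:
        ff = float(np.mean(ffmap.values[ffmap.defined]))
    label = labelmap.dictionary[code]
    return CompositionMetrics(
        code=code,
        name=label.name,
        side=label.side,
        boundary_volume=boundary,
        fat_fraction=ff,
        fat_volume=boundary * ff / 100.0,
        lean_volume=boundary * (1.0 - ff / 100.0),
        tp=tp,
        excluded_voxels=excluded,
    )


def ff_histogram(ffmap: FFMap, bin_width: float = 1.0) -> FFHistogram:
    """Histogram of voxelwise FF with uniform bins over [0, 100].

    ``bin_width`` must divide 100; the default 1% gives the 101-edge grid.
    The final bin is closed so FF = 100 is counted.
    """
    n_bins = 100.0 / bin_width
    if bin_width <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ParameterError(f"bin_width must be positive and divide 100, got {bin_width}")
    edges = np.linspace(0.0, 100.0, int(round(n_bins)) + 1)
    values = ffmap.in_mask_values()
    if values.size == 0:
        logger.warning("ff_histogram called on a map with no defined voxels")
        return FFHistogram(bin_edges=edges, counts=np.zeros(len(edges) - 1, dtype=np.int64))
    counts, _ = np.histogram(values, bins=edges)
    return FFHistogram(bin_edges=edges, counts=counts)


def composition_table(
    water: VolumetricImage,
    fat: VolumetricImage,
    labelmap: MuscleLabelMap,
) -> list[CompositionMetrics]:
    """Composition metrics for every dictionary code, ascending.

    Codes in the dictionary but absent from the grid (differing coverage
    between sites) produce flagged zero-volume rows rather than errors, so
    multi-site tables stay rectangular.
    """
    present = set(labelmap.codes_present())
    out: list[CompositionMetrics] = []
    for code in sorted(labelmap.dictionary):
        if code in present:
            out.append(muscle_composition(water, fat, labelmap, code))
        else:
            label = labelmap.dictionary[code]
            logger.warning("code %d (%s %s) absent from grid; zero row emitted",
                           code, label.name, label.side)
            out.append(
                CompositionMetrics(
                    code=code, name=label.name, side=label.side,
                    boundary_volume=0.0, fat_fraction=float("nan"),
                    fat_volume=0.0, lean_volume=0.0, tp=0, excluded_voxels=0,
                    present=False,
                )
            )
    return out
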