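"""Data model and I/O for volumes, label maps, dictionaries and metric tables.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with ``z`` the axial (inferior-superior)
axis by default and increasing slice index = superior; both are overridable
per image because acquisition orientation varies by site. All lengths are
millimetres internally (areas mm^2, volumes mm^3) — a single unit system
avoids silent x1000 errors; rendering in cm^3 is left to presentation code.

The label dictionary is a JSON sidecar of ``{code, name, side}`` records
rather than embedded metadata: it survives format conversion and is
diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DictionaryError,
    DimensionalityError,
    HeaderError,
    IntensityError,
    ParameterError,
)

logger = logging.getLogger("myometry")

#: Tolerance (mm) when comparing voxel spacings of grids that must match.
#: Absorbs header float noise without hiding real grid mismatches.
SPACING_TOL_MM = 1e-4

VALID_SIDES = frozenset({"left", "right", "midline"})
SIGNAL_KINDS = frozenset({"dixon_water", "dixon_fat", "stir"})


@dataclass
class VolumetricImage:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray
        3D array of signal intensities (arbitrary units).
    spacing : tuple of float
        Per-axis voxel size in mm, ordered like the array axes.
    axial_axis : int
        Index of the inferior-superior axis (default 2).
    superior_direction : int
        +1 if increasing index along ``axial_axis`` moves superior, else -1.
    affine : ndarray, optional
        4x4 voxel-to-world matrix carried through save/load round trips.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axial_axis: int = 2
    superior_direction: int = 1
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise HeaderError(f"voxel spacing must be 3 strictly positive values, got {self.spacing}")
        if self.axial_axis not in (0, 1, 2):
            raise ParameterError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")
        if self.superior_direction not in (1, -1):
            raise ParameterError("superior_direction must be +1 or -1")

    # -- derived geometry ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (product of the three spacings)."""
        return float(np.prod(self.spacing))

    @property
    def inplane_axes(self) -> tuple[int, int]:
        return tuple(a for a in range(3) if a != self.axial_axis)  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm^2 (product of the two in-plane spacings)."""
        a, b = self.inplane_axes
        return float(self.spacing[a] * self.spacing[b])

    @property
    def axial_spacing(self) -> float:
        return float(self.spacing[self.axial_axis])

    def axial_positions(self) -> np.ndarray:
        """Physical position (mm) of every slice centre along the axial axis."""
        n = self.shape[self.axial_axis]
        return np.arange(n) * self.axial_spacing

    def same_grid(self, other: "VolumetricImage", tol: float = SPACING_TOL_MM) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )


@dataclass(frozen=True)
class MuscleLabel:
    """One dictionary entry: a muscle name and its side."""

    name: str
    side: str

    def __post_init__(self) -> None:
        if self.side not in VALID_SIDES:
            raise DictionaryError(f"side must be one of {sorted(VALID_SIDES)}, got {self.side!r}")


@dataclass
class MuscleLabelMap:
    """Integer-coded 3D segmentation plus its label dictionary.

    Code 0 is background and never appears in the dictionary; every nonzero
    code present in the grid must be in the dictionary.
    """

    labels: np.ndarray
    dictionary: dict[int, MuscleLabel]
    spacing: tuple[float, float, float]
    axial_axis: int = 2
    superior_direction: int = 1
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(f"label map must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise DictionaryError("label map contains non-integer values")
            self.labels = np.round(self.labels).astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if 0 in self.dictionary:
            raise DictionaryError("code 0 is background and may not appear in the dictionary")
        if any(code <= 0 for code in self.dictionary):
            raise DictionaryError("label codes must be positive integers")
        orphans = sorted(set(self.codes_present()) - set(self.dictionary))
        if orphans:
            raise DictionaryError(f"codes present in grid but missing from dictionary: {orphans}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def codes_present(self) -> list[int]:
        present = np.unique(self.labels)
        return [int(c) for c in present if c != 0]

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def voxel_count(self, code: int) -> int:
        return int(np.count_nonzero(self.labels == code))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def inplane_axes(self) -> tuple[int, int]:
        return tuple(a for a in range(3) if a != self.axial_axis)  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        a, b = self.inplane_axes
        return float(self.spacing[a] * self.spacing[b])

    def with_labels(self, labels: np.ndarray) -> "MuscleLabelMap":
        """A copy of this map carrying a new label grid on the same geometry."""
        return MuscleLabelMap(
            labels=labels,
            dictionary=dict(self.dictionary),
            spacing=self.spacing,
            axial_axis=self.axial_axis,
            superior_direction=self.superior_direction,
            affine=None if self.affine is None else self.affine.copy(),
        )


@dataclass
class ClinicalRatings:
    """Ordinal clinical ratings per muscle code.

    ``fat_rating``: 1 (normal appearance) ... 6 (complete fascial loss).
    ``stir_grade``: 0 (normal) ... 4 (elevations in >60% of the volume).
    """

    fat_rating: dict[int, int] = field(default_factory=dict)
    stir_grade: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, r in self.fat_rating.items():
            if not 1 <= int(r) <= 6:
                raise ParameterError(f"fat rating for code {code} out of range 1-6: {r}")
        for code, g in self.stir_grade.items():
            if not 0 <= int(g) <= 4:
                raise ParameterError(f"STIR grade for code {code} out of range 0-4: {g}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _infer_axial_axis(affine: np.ndarray) -> tuple[int, int]:
    """Infer which array axis points inferior-superior from the affine.

    Returns (axis index, +1/-1 for superior direction). NIfTI world z is
    superior, so the axis whose affine column has the largest |z| component
    is axial.
    """
    rot = affine[:3, :3]
    axis = int(np.argmax(np.abs(rot[2, :])))
    direction = 1 if rot[2, axis] >= 0 else -1
    return axis, direction


def load_volume(
    path: str | Path,
    kind: str,
    axial_axis: int | None = None,
    superior_direction: int | None = None,
) -> VolumetricImage:
    """Load a 3D NIfTI signal volume.

    ``kind`` names the acquisition (``dixon_water``, ``dixon_fat`` or
    ``stir``) and is used to reject physically impossible negative
    intensities with an informative message. Orientation is inferred from
    the header affine; pass ``axial_axis``/``superior_direction`` to
    override per-file.
    """
    if kind not in SIGNAL_KINDS:
        raise ParameterError(f"kind must be one of {sorted(SIGNAL_KINDS)}, got {kind!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D volume, got {data.ndim}D {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise HeaderError(f"{path}: non-positive voxel spacing in header: {spacing}")
    if not np.all(np.isfinite(data)):
        raise IntensityError(f"{path}: non-finite intensities in {kind} volume")
    if np.any(data < 0):
        raise IntensityError(f"{path}: negative intensities are invalid for a {kind} volume")
    affine = np.asarray(img.affine, dtype=float)
    inf_axis, inf_dir = _infer_axial_axis(affine)
    return VolumetricImage(
        data=data,
        spacing=spacing,
        axial_axis=inf_axis if axial_axis is None else axial_axis,
        superior_direction=inf_dir if superior_direction is None else superior_direction,
        affine=affine,
    )


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(image: VolumetricImage, path: str | Path) -> None:
    """Write a volume to NIfTI, preserving spacing (and affine if present)."""
    affine = image.affine if image.affine is not None else _default_affine(image.spacing)
    out = nib.Nifti1Image(np.asarray(image.data), affine)
    out.header.set_zooms(image.spacing)
    nib.save(out, str(path))


def load_label_dictionary(path: str | Path) -> dict[int, MuscleLabel]:
    """Read the JSON sidecar: a list of ``{code, name, side}`` records."""
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        records = [{"code": int(k), **v} for k, v in raw.items()]
    else:
        records = raw
    dictionary: dict[int, MuscleLabel] = {}
    for rec in records:
        code = int(rec["code"])
        if code in dictionary:
            raise DictionaryError(f"duplicate label code {code} in dictionary")
        dictionary[code] = MuscleLabel(name=rec["name"], side=rec["side"])
    return dictionary


def save_label_dictionary(dictionary: dict[int, MuscleLabel], path: str | Path) -> None:
    records = [
        {"code": code, "name": lab.name, "side": lab.side}
        for code, lab in sorted(dictionary.items())
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def load_labelmap(
    path: str | Path,
    dictionary_path: str | Path,
    reference: VolumetricImage | None = None,
) -> MuscleLabelMap:
    """Load and validate an integer label map against its reference grid.

    The label grid must match the reference image's shape exactly and its
    spacing within ``SPACING_TOL_MM``. Per-code voxel counts are logged.
    When no reference is given (label-only workflows such as erosion), the
    map's own header geometry is used.
    """
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim == 4 and labels.shape[3] == 1:
        labels = labels[..., 0]
    if labels.ndim != 3:
        raise DimensionalityError(f"{path}: label map must be 3D, got {labels.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if reference is not None:
        if labels.shape != reference.shape:
            raise AlignmentError(
                f"{path}: label grid {labels.shape} does not match reference {reference.shape}"
            )
        if any(abs(a - b) > SPACING_TOL_MM for a, b in zip(spacing, reference.spacing)):
            raise AlignmentError(
                f"{path}: label spacing {spacing} does not match reference {reference.spacing} "
                f"within {SPACING_TOL_MM} mm"
            )
        spacing = reference.spacing
        axial_axis = reference.axial_axis
        superior_direction = reference.superior_direction
    else:
        axial_axis, superior_direction = _infer_axial_axis(np.asarray(img.affine, dtype=float))
    dictionary = load_label_dictionary(dictionary_path)
    lmap = MuscleLabelMap(
        labels=labels,
        dictionary=dictionary,
        spacing=spacing,
        axial_axis=axial_axis,
        superior_direction=superior_direction,
        affine=np.asarray(img.affine, dtype=float),
    )
    for code in lmap.codes_present():
        logger.info("label %d (%s %s): %d voxels", code, dictionary[code].name,
                    dictionary[code].side, lmap.voxel_count(code))
    return lmap


def save_labelmap(lmap: MuscleLabelMap, path: str | Path) -> None:
    affine = lmap.affine if lmap.affine is not None else _default_affine(lmap.spacing)
    out = nib.Nifti1Image(np.asarray(lmap.labels, dtype=np.int16), affine)
    out.header.set_zooms(lmap.spacing)
    nib.save(out, str(path))


# ---------------------------------------------------------------------------
# Metric tables
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["muscle", "side", "metric", "value", "units"]


def write_metrics_table(rows: list[dict], path: str | Path, format: str = "csv") -> None:
    """Write per-muscle metric records with a stable schema.

    Each record carries (muscle, side, metric, value, units). Numbers are
    formatted to 6 significant digits so tables are byte-stable across
    platforms; an empty record list still yields a header-only file.
    """
    if format not in ("csv", "json"):
        raise ParameterError(f"format must be 'csv' or 'json', got {format!r}")
    if not rows:
        logger.warning("writing empty metrics table to %s", path)
    frame = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    frame["value"] = [
        float(f"{float(v):.6g}") if np.isfinite(v) else float(v) for v in frame["value"]
    ]
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.6g")
    else:
        frame.to_json(path, orient="records", indent=1)


def read_metrics_table(path: str | Path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        return pd.read_csv(path)
    return pd.read_json(path, orient="records")
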