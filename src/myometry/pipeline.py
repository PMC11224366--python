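"""Run orchestration: config, stages, manifests.

A run executes composition -> length profiles -> (optionally) the STIR
pathway for one subject, writing every artifact under a fresh run
directory. The resolved configuration is serialized before any computation
and every produced file is recorded in a manifest with its SHA-256 hash,
so a run is fully reconstructable and rerun determinism is checkable by
hash comparison. No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import profiles as prof
from .composition import CompositionMetrics
from .core import (
    load_labelmap,
    load_volume,
    save_labelmap,
    write_metrics_table,
)
from .errors import AlignmentError, ComputationError, ConfigurationError
from .stir import limb_mask, register_rigid, resample_labels, segment_stir, stir_content

logger = logging.getLogger("myometry")


@dataclass
class RunConfig:
    """Resolved inputs and parameters for one subject run."""

    water: str
    fat: str
    labels: str
    dictionary: str
    out_dir: str
    stir: str | None = None
    seed: int = 0
    axial_axis: int | None = None  # orientation overrides; None = from header
    superior_direction: int | None = None
    bin_width: float = 1.0
    trim: tuple[float, float] = (10.0, 90.0)
    stir_region_fraction: float = 0.20
    stir_edge_margin_px: int = 2
    stir_erode_first: bool = True
    registration_metric: str = "mattes"
    write_ff_maps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.trim, list):
            cfg.trim = tuple(cfg.trim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    out_dir: str
    artifacts: dict[str, str] = field(default_factory=dict)  # rel path -> sha256
    stages_completed: list[str] = field(default_factory=list)

    def record(self, path: Path, root: Path) -> None:
        self.artifacts[str(path.relative_to(root))] = sha256_file(path)

    def write(self, root: Path) -> None:
        with open(root / "manifest.json", "w") as fh:
            json.dump(
                {"artifacts": self.artifacts, "stages_completed": self.stages_completed},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")


def composition_frame(metrics: list[CompositionMetrics]) -> pd.DataFrame:
    """Wide per-muscle table (one row per code) from composition metrics."""
    return pd.DataFrame(
        [
            {
                "code": m.code, "muscle": m.name, "side": m.side,
                "boundary_volume_mm3": m.boundary_volume,
                "fat_fraction_pct": m.fat_fraction,
                "fat_volume_mm3": m.fat_volume,
                "lean_volume_mm3": m.lean_volume,
                "tp": m.tp, "excluded_voxels": m.excluded_voxels,
                "present": m.present,
            }
            for m in metrics
        ]
    )


def read_composition_frame(path: str | Path) -> dict[int, CompositionMetrics]:
    """Read a wide composition CSV back into per-code metrics."""
    frame = pd.read_csv(path)
    out: dict[int, CompositionMetrics] = {}
    for _, row in frame.iterrows():
        out[int(row["code"])] = CompositionMetrics(
            code=int(row["code"]), name=row["muscle"], side=row["side"],
            boundary_volume=float(row["boundary_volume_mm3"]),
            fat_fraction=float(row["fat_fraction_pct"]),
            fat_volume=float(row["fat_volume_mm3"]),
            lean_volume=float(row["lean_volume_mm3"]),
            tp=int(row["tp"]), excluded_voxels=int(row["excluded_voxels"]),
            present=bool(row["present"]),
        )
    return out


def profile_frame(profile: prof.LengthProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "percent": profile.percent,
            "boundary_csa_mm2": profile.boundary_csa,
            "lean_csa_mm2": profile.lean_csa,
            "fat_csa_mm2": profile.fat_csa,
            "area_ff_pct": profile.area_ff,
        }
    )


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest.stages_completed.append(name)
                logger.info("stage %s: done", name)
                return False
            raise ComputationError(
                f"stage {name!r} failed: {exc}; completed stages: {manifest.stages_completed}"
            ) from exc

    return _Ctx()


def run_subject(config: RunConfig) -> RunManifest:
    """Execute the full single-subject quantification pathway."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(root / "config.yaml")  # snapshot before any computation
    manifest = RunManifest(out_dir=str(root))
    manifest.record(root / "config.yaml", root)

    if config.stir is not None and not Path(config.stir).exists():
        raise ConfigurationError(f"STIR stage requested but input missing: {config.stir}")

    with _stage(manifest, "load"):
        water = load_volume(config.water, "dixon_water", config.axial_axis,
                            config.superior_direction)
        fat = load_volume(config.fat, "dixon_fat", config.axial_axis,
                          config.superior_direction)
        labelmap = load_labelmap(config.labels, config.dictionary, reference=water)

    with _stage(manifest, "composition"):
        table = comp.composition_table(water, fat, labelmap)
        composition_frame(table).to_csv(root / "composition.csv", index=False,
                                        float_format="%.6g")
        manifest.record(root / "composition.csv", root)
        records = [r for m in table if m.present for r in m.to_records()]
        write_metrics_table(records, root / "composition_long.csv")
        manifest.record(root / "composition_long.csv", root)
        hist_dir = root / "histograms"
        hist_dir.mkdir(exist_ok=True)
        for m in table:
            if not m.present:
                continue
            ffmap = comp.voxel_ff(water, fat, labelmap.mask(m.code))
            hist = comp.ff_histogram(ffmap, config.bin_width)
            pd.DataFrame(
                {"bin_low": hist.bin_edges[:-1], "bin_high": hist.bin_edges[1:],
                 "count": hist.counts, "frequency": hist.normalized}
            ).to_csv(hist_dir / f"ff_hist_{m.code:03d}.csv", index=False, float_format="%.6g")
            manifest.record(hist_dir / f"ff_hist_{m.code:03d}.csv", root)

    with _stage(manifest, "profiles"):
        prof_dir = root / "profiles"
        prof_dir.mkdir(exist_ok=True)
        for code in labelmap.codes_present():
            slices = prof.slice_metrics(water, fat, labelmap, code)
            pd.DataFrame([vars(s) for s in slices]).to_csv(
                prof_dir / f"slices_{code:03d}.csv", index=False, float_format="%.6g")
            manifest.record(prof_dir / f"slices_{code:03d}.csv", root)
            profile = prof.normalize_profile(slices)
            profile_frame(profile).to_csv(
                prof_dir / f"profile_{code:03d}.csv", index=False, float_format="%.6g")
            manifest.record(prof_dir / f"profile_{code:03d}.csv", root)

    if config.stir is not None:
        with _stage(manifest, "stir"):
            stir = load_volume(config.stir, "stir", config.axial_axis,
                               config.superior_direction)
            limb = limb_mask(stir)
            mask = segment_stir(
                stir, limb,
                region_fraction=config.stir_region_fraction,
                edge_margin_px=config.stir_edge_margin_px,
            )
            transform = register_rigid(water, stir, metric=config.registration_metric,
                                       seed=config.seed)
            labels_on_stir = resample_labels(labelmap, transform, stir)
            content = stir_content(mask, labels_on_stir, erode_first=config.stir_erode_first)
            pd.DataFrame([vars(c) for c in content]).to_csv(
                root / "stir_content.csv", index=False, float_format="%.6g")
            manifest.record(root / "stir_content.csv", root)
            with open(root / "transform.json", "w") as fh:
                json.dump(transform.to_dict(), fh, indent=1)
                fh.write("\n")
            manifest.record(root / "transform.json", root)
            save_labelmap(labels_on_stir.with_labels(mask.mask.astype(np.int16)),
                          root / "stir_mask.nii.gz")
            manifest.record(root / "stir_mask.nii.gz", root)

    manifest.write(root)
    return manifest


def run_longitudinal(baseline: RunConfig, followup: RunConfig) -> pd.DataFrame:
    """Per-muscle change report, sign convention follow-up minus baseline."""
    out_rows = []
    loaded = []
    for cfg in (baseline, followup):
        water = load_volume(cfg.water, "dixon_water", cfg.axial_axis, cfg.superior_direction)
        fat = load_volume(cfg.fat, "dixon_fat", cfg.axial_axis, cfg.superior_direction)
        lmap = load_labelmap(cfg.labels, cfg.dictionary, reference=water)
        loaded.append((water, fat, lmap))
    (wa, fa, la), (wb, fb, lb) = loaded
    if set(la.dictionary) != set(lb.dictionary):
        raise AlignmentError("baseline and follow-up label dictionaries differ")
    tab_a = {m.code: m for m in comp.composition_table(wa, fa, la)}
    tab_b = {m.code: m for m in comp.composition_table(wb, fb, lb)}
    shared = sorted(c for c in tab_a if tab_a[c].present and tab_b[c].present)
    for code in shared:
        a, b = tab_a[code], tab_b[code]
        profile_a = prof.muscle_profile(wa, fa, la, code)
        profile_b = prof.muscle_profile(wb, fb, lb, code)
        delta = prof.profile_delta(profile_a, profile_b)
        out_rows.append(
            {
                "code": code, "muscle": a.name, "side": a.side,
                "delta_ff_pct": b.fat_fraction - a.fat_fraction,
                "delta_boundary_volume_mm3": b.boundary_volume - a.boundary_volume,
                "delta_fat_volume_mm3": b.fat_volume - a.fat_volume,
                "delta_lean_volume_mm3": b.lean_volume - a.lean_volume,
                "max_abs_profile_dff_pct": float(np.max(np.abs(delta["area_ff"]))),
            }
        )
    report = pd.DataFrame(out_rows)
    out = Path(followup.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "longitudinal_delta.csv", index=False, float_format="%.6g")
    return report
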