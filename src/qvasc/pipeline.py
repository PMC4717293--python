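"""End-to-end orchestration: simulate -> qmap -> dsc -> region report.

One YAML config (cohort design, acquisition constants, processing flags,
seed) drives the whole chain; outputs are a per-animal/region tidy summary
table, a contrast report CSV and a JSON manifest with parameters and
per-file checksums so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import AcquisitionMeta, Sequence, write_map, write_regions
from .dsc import process_dsc
from .qmap import DEFAULT_EPSILON, compute_relaxation_maps
from .regions import build_report, summarize_regions
from .synthetic import CohortSpec, iter_animals, make_phantom, study_defaults_24mo

__all__ = [
    "PipelineConfig",
    "load_config",
    "validate_config",
    "analyze_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``validate_config``)."""

    out_dir: str = "qvasc_out"
    seed: int = 0
    cohort: dict[str, Any] = field(default_factory=dict)
    preset: str | None = "study_defaults_24mo"
    acquisition: dict[str, dict[str, float]] = field(default_factory=dict)
    r_trunc: float = 0.2
    baseline_frames: int = 75
    aif_voxels: int = 10
    aif_roi_label: int | None = 7  # restrict AIF search to the arterial ROI
    epsilon: float = DEFAULT_EPSILON
    n_perm: int = 5000
    statistic: str = "median"
    write_maps: bool = False
    log_level: str = "INFO"

    def build_cohort_spec(self) -> CohortSpec:
        overrides = dict(self.cohort)
        for key, seq in (("ge", "gradient_echo"), ("se", "spin_echo"), ("dsc", "dynamic_epi")):
            acq = self.acquisition.get(key)
            if acq:
                overrides[f"meta_{key}"] = AcquisitionMeta(
                    te_s=float(acq["te_s"]),
                    tr_s=float(acq["tr_s"]),
                    sequence=Sequence(seq),
                    baseline_frames=acq.get("baseline_frames"),
                )
        for tup_key in ("shape_ss", "shape_dsc"):
            if tup_key in overrides:
                overrides[tup_key] = tuple(overrides[tup_key])
        if self.preset:
            if self.preset != "study_defaults_24mo":
                raise ValueError(f"unknown cohort preset {self.preset!r}")
            return study_defaults_24mo(seed=self.seed, **overrides)
        return CohortSpec(seed=self.seed, **overrides)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff executable."""
    issues: list[str] = []
    if not (0.0 < config.r_trunc < 1.0):
        issues.append(f"r_trunc must be in (0,1), got {config.r_trunc}")
    if config.baseline_frames < 1:
        issues.append(f"baseline_frames must be >= 1, got {config.baseline_frames}")
    if config.aif_voxels < 1:
        issues.append(f"aif_voxels must be >= 1, got {config.aif_voxels}")
    if config.epsilon < 0:
        issues.append(f"epsilon must be >= 0, got {config.epsilon}")
    if config.n_perm < 1000:
        issues.append(f"n_perm must be >= 1000, got {config.n_perm}")
    if config.statistic not in ("mean", "median"):
        issues.append(f"statistic must be 'mean' or 'median', got {config.statistic!r}")
    for key, acq in (config.acquisition or {}).items():
        if "te_s" not in acq:
            issues.append(f"acquisition.{key}: missing te_s")
        elif not acq["te_s"] > 0:
            issues.append(f"acquisition.{key}: te_s must be > 0")
        if "tr_s" not in acq:
            issues.append(f"acquisition.{key}: missing tr_s")
    try:
        spec = config.build_cohort_spec()
    except (ValueError, TypeError, KeyError) as exc:
        issues.append(f"cohort: {exc}")
        return issues
    try:
        make_phantom(spec.shape_ss)
        make_phantom(spec.shape_dsc)
    except ValueError as exc:
        issues.append(f"cohort: {exc}")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending animal."""

    def __init__(self, stage: str, animal_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for animal {animal_id!r}: {cause}")
        self.stage = stage
        self.animal_id = animal_id


def analyze_cohort(
    spec,
    r_trunc: float = 0.2,
    baseline_frames: int | None = None,
    aif_voxels: int = 10,
    aif_roi_label: int | None = 7,
    epsilon: float = DEFAULT_EPSILON,
    statistic: str = "median",
    include_steady: bool = True,
    include_dsc: bool = True,
    maps_dir: Path | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Simulate and process a cohort; return the tidy per-animal/region
    summary table (columns as :func:`qvasc.regions.summarize_regions`) and
    stage counters.

    Steady-state maps contribute ``q``, ``n`` and ``rcbv_ss`` rows; the
    dynamic series contributes ``rcbv_dsc`` and ``rcbf``.  With
    ``maps_dir`` set, per-animal maps are written there as NIfTI.
    """
    phantom_ss = make_phantom(spec.shape_ss)
    phantom_dsc = make_phantom(spec.shape_dsc)
    bl = spec.meta_dsc.baseline_frames if baseline_frames is None else baseline_frames
    summaries: list[pd.DataFrame] = []
    counts = {"clipped_voxels": 0, "failed_fits": 0}
    for animal in iter_animals(spec, include_steady, include_dsc):
        aid = animal.truth.animal_id
        gt = animal.truth.genotype
        written: list[tuple[str, Any]] = []
        if include_steady:
            try:
                maps = compute_relaxation_maps(
                    animal.steady.se_pre, animal.steady.se_post,
                    animal.steady.ge_pre, animal.steady.ge_post,
                    epsilon=epsilon,
                )
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError("qmap", aid, exc) from exc
            for name, vol in (
                ("q", maps.q), ("n", maps.n_density), ("rcbv_ss", maps.rcbv_ss),
            ):
                summaries.append(
                    summarize_regions(
                        vol, phantom_ss, aid, gt, spec.age_group, name, statistic
                    )
                )
            written += [("dr2", maps.dr2), ("dr2star", maps.dr2star), ("q", maps.q),
                        ("n", maps.n_density), ("rcbv_ss", maps.rcbv_ss)]
        if include_dsc:
            try:
                restrict = (
                    phantom_dsc.labels == aif_roi_label
                    if aif_roi_label is not None
                    else None
                )
                perf = process_dsc(
                    animal.dsc,
                    baseline_frames=bl,
                    r_trunc=r_trunc,
                    aif_voxels=aif_voxels,
                    aif_restrict=restrict,
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError("dsc", aid, exc) from exc
            counts["failed_fits"] += perf.n_failed_fits
            for name, vol in (("rcbv_dsc", perf.rcbv), ("rcbf", perf.rcbf)):
                summaries.append(
                    summarize_regions(
                        vol, phantom_dsc, aid, gt, spec.age_group, name, statistic
                    )
                )
            written += [("rcbv_dsc", perf.rcbv), ("rcbf", perf.rcbf), ("bat", perf.bat)]
        if maps_dir is not None:
            adir = Path(maps_dir) / aid
            adir.mkdir(parents=True, exist_ok=True)
            for name, vol in written:
                write_map(vol, adir / f"{name}.nii.gz", allow_nan=True)
    return pd.concat(summaries, ignore_index=True), counts


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run simulate -> qmap -> dsc -> regions and write report + manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.build_cohort_spec()
    write_regions(make_phantom(spec.shape_ss), out / "labels_ss.nii.gz")
    write_regions(make_phantom(spec.shape_dsc), out / "labels_dsc.nii.gz")

    table, counts = analyze_cohort(
        spec,
        r_trunc=config.r_trunc,
        baseline_frames=config.baseline_frames,
        aif_voxels=config.aif_voxels,
        aif_roi_label=config.aif_roi_label,
        epsilon=config.epsilon,
        statistic=config.statistic,
        maps_dir=(out / "maps") if config.write_maps else None,
    )
    table.to_csv(out / "summaries.csv", index=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = build_report(table, n_perm=config.n_perm, seed=config.seed)
    report.to_csv(out / "report.csv", index=False)

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "software": {"name": "qvasc", "version": __version__},
        "seed": config.seed,
        "config": asdict(config),
        "counts": counts,
        "n_animals": int(spec.n_control + spec.n_transgenic),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
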