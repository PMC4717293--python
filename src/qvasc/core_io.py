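"""Domain containers and NIfTI-1 I/O.

Volumes and dynamic series are stored with 0-based voxel indices and a
per-axis voxel size in millimetres.  No world-space registration is
implemented: grids are aligned at their common corner, so a voxel centre
sits at ``(i + 0.5) * spacing`` along each axis.  Acquisition metadata
(echo time, repetition time, number of pre-bolus baseline frames) travels
with the image rather than living in file-name conventions.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Sequence",
    "AcquisitionMeta",
    "VolumeImage",
    "DynamicSeries",
    "RegionSet",
    "CANONICAL_REGIONS",
    "read_meta",
    "read_volume",
    "write_map",
    "read_series",
    "write_series",
    "read_regions",
    "write_regions",
]


class Sequence(str, enum.Enum):
    """MRI sequence family of an acquisition."""

    gradient_echo = "gradient_echo"
    spin_echo = "spin_echo"
    dynamic_epi = "dynamic_epi"


#: Canonical label -> region-name mapping used throughout the package.
#: Labels 1-6 are the reported gray-matter regions, 7 is a small arterial
#: region used for arterial-input-function selection; 0 is background.
CANONICAL_REGIONS: dict[int, str] = {
    1: "olfactory_bulb",
    2: "cortex",
    3: "striatum",
    4: "hippocampus",
    5: "thalamus",
    6: "cerebellum",
    7: "artery",
}

#: The six tissue regions summarised in group reports (no artery).
TISSUE_REGIONS: tuple[str, ...] = tuple(
    name for label, name in CANONICAL_REGIONS.items() if name != "artery"
)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Echo/repetition times and baseline length of one acquisition.

    Parameters
    ----------
    te_s : float
        Echo time in seconds (e.g. 0.0055 for a 5.5 ms gradient echo).
    tr_s : float
        Repetition time in seconds; for a dynamic series this is the
        frame spacing.
    sequence : Sequence
        Sequence family.
    baseline_frames : int, optional
        Number of pre-bolus frames (dynamic series only); must be >= 1
        when the sequence is dynamic.
    """

    te_s: float
    tr_s: float
    sequence: Sequence = Sequence.gradient_echo
    baseline_frames: int | None = None

    def __post_init__(self) -> None:
        if not self.te_s > 0:
            raise ValueError(f"te_s must be > 0, got {self.te_s}")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be > 0, got {self.tr_s}")
        seq = Sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if seq is Sequence.dynamic_epi:
            if self.baseline_frames is None or self.baseline_frames < 1:
                raise ValueError(
                    "dynamic series require baseline_frames >= 1, got "
                    f"{self.baseline_frames}"
                )


@dataclass
class VolumeImage:
    """A 3D scalar map with voxel spacing and acquisition metadata."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"VolumeImage requires a 3D array, got ndim={self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise ValueError(f"empty volume shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, meta: AcquisitionMeta | None = None) -> "VolumeImage":
        """Same grid, new voxel values (and optionally new metadata)."""
        return VolumeImage(values, self.spacing_mm, meta if meta is not None else self.meta)


@dataclass
class DynamicSeries:
    """A 4D (x, y, z, t) time-resolved acquisition with a uniform time axis.

    ``time_s[k] = k * tr_s`` counts from the start of the recording; the
    first ``meta.baseline_frames`` frames are pre-bolus baseline.
    """

    values: np.ndarray
    time_s: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"DynamicSeries requires a 4D array, got ndim={self.values.ndim}"
            )
        self.time_s = np.asarray(self.time_s, dtype=float)
        nt = self.values.shape[3]
        if self.time_s.shape != (nt,):
            raise ValueError("time axis length does not match frame count")
        steps = np.diff(self.time_s)
        if nt > 1 and not np.allclose(steps, self.meta.tr_s, rtol=1e-6, atol=1e-9):
            raise ValueError("time axis must increase uniformly by tr_s")
        bl = self.meta.baseline_frames
        if bl is None:
            raise ValueError("dynamic series require baseline_frames in metadata")
        if nt < bl + 2:
            raise ValueError(f"need at least baseline_frames + 2 frames, got {nt}")

    # spacing of the spatial grid; series carry no spacing of their own in
    # this package beyond what the file header stores, so default isotropic
    spacing_mm: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]


@dataclass
class RegionSet:
    """Integer label volume plus label -> region-name mapping.

    Label 0 is background; every named label must occur in the volume.
    """

    labels: np.ndarray
    names: Mapping[int, str]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("RegionSet labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integer-valued")
            self.labels = np.round(lab).astype(np.int32)
        self.names = dict(self.names)
        present = set(np.unique(self.labels).tolist())
        missing = [l for l in self.names if l not in present]
        if missing:
            raise ValueError(f"named labels absent from volume: {missing}")

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask of the named region."""
        for label, name in self.names.items():
            if name == region:
                return self.labels == label
        raise KeyError(f"unknown region {region!r}")

    @property
    def region_names(self) -> list[str]:
        return list(self.names.values())

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


# ---------------------------------------------------------------------------
# file I/O


def read_meta(path: str | Path) -> AcquisitionMeta:
    """Read acquisition metadata from a YAML or JSON config.

    Recognised keys: ``te_s``, ``tr_s``, ``sequence``, ``baseline_frames``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return AcquisitionMeta(
        te_s=float(data["te_s"]),
        tr_s=float(data["tr_s"]),
        sequence=Sequence(data.get("sequence", "gradient_echo")),
        baseline_frames=(
            int(data["baseline_frames"]) if data.get("baseline_frames") is not None else None
        ),
    )


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms())
    return data, zooms


def read_volume(path: str | Path, meta: AcquisitionMeta) -> VolumeImage:
    """Read a 3D NIfTI volume; a non-3D payload raises ``ValueError``."""
    data, zooms = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return VolumeImage(data, zooms[:3], meta)


def write_map(vol: VolumeImage, path: str | Path, allow_nan: bool = False) -> None:
    """Write a 3D map as NIfTI-1.

    By default non-finite values are rejected (callers must mask first);
    pipelines that deliberately export NaN-masked maps pass
    ``allow_nan=True``.
    """
    if not allow_nan and not np.all(np.isfinite(vol.values)):
        raise ValueError("map contains non-finite values; mask before writing")
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), affine), str(path))


def read_series(path: str | Path, meta: AcquisitionMeta) -> DynamicSeries:
    """Read a 4D NIfTI series; the time axis is rebuilt as ``k * tr_s``."""
    data, zooms = _load(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got ndim={data.ndim}")
    time_s = np.arange(data.shape[3]) * meta.tr_s
    series = DynamicSeries(data, time_s, meta)
    series.spacing_mm = zooms[:3]
    return series


def write_series(series: DynamicSeries, path: str | Path) -> None:
    affine = np.diag(list(series.spacing_mm) + [1.0])
    img = nib.Nifti1Image(series.values.astype(np.float64), affine)
    img.header.set_zooms(tuple(series.spacing_mm) + (series.meta.tr_s,))
    nib.save(img, str(path))


def read_regions(path: str | Path, names: Mapping[int, str] | None = None) -> RegionSet:
    """Read an integer label volume; ``names`` defaults to the canonical map
    restricted to labels present in the file."""
    data, zooms = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got ndim={data.ndim}")
    labels = np.round(data).astype(np.int32)
    if names is None:
        present = set(np.unique(labels).tolist())
        names = {l: n for l, n in CANONICAL_REGIONS.items() if l in present}
    return RegionSet(labels, names, zooms[:3])


def write_regions(regions: RegionSet, path: str | Path) -> None:
    affine = np.diag(list(regions.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(regions.labels.astype(np.int16), affine), str(path))
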