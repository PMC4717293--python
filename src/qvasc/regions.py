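"""ROI summarisation and genotype-group contrasts.

Each animal contributes one summary value (voxel mean by default, median
by flag) per region and map.  Group contrasts are reported as percent
change, 100 * (mean_tg - mean_ctrl) / mean_ctrl, with a two-sided
permutation p-value over genotype-label permutations standing in for a
mixed-effects fit (with one value per animal and region the genotype
contrast reduces to a two-sample comparison; the tidy table is exported
so a mixed model can be fitted externally if desired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import RegionSet, VolumeImage

__all__ = [
    "GroupContrast",
    "summarize_regions",
    "percent_change",
    "permutation_contrast",
    "build_report",
]

MIN_PERMUTATIONS = 1000


@dataclass(frozen=True)
class GroupContrast:
    """Two-group contrast of one region/map summary."""

    region: str
    map_name: str
    percent_change: float
    p_perm: float
    n_ctrl: int
    n_tg: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_perm <= 1.0):
            raise ValueError(f"p_perm must lie in (0, 1], got {self.p_perm}")


def summarize_regions(
    vol: VolumeImage,
    regions: RegionSet,
    animal_id: str,
    genotype: str,
    age_group: str,
    map_name: str,
    statistic: str = "mean",
    min_voxels: int = 10,
    exclude: tuple[str, ...] = ("artery",),
) -> pd.DataFrame:
    """Per-region summary of one map for one animal.

    Returns one row per region with columns animal_id, genotype,
    age_group, region, map, value, n_voxels, flagged.  NaN voxels are
    ignored; regions with fewer than ``min_voxels`` valid voxels are
    flagged; empty regions produce no row (with a warning).
    """
    if vol.shape != regions.labels.shape:
        raise ValueError(f"map grid {vol.shape} != label grid {regions.labels.shape}")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    reduce = np.nanmean if statistic == "mean" else np.nanmedian
    rows = []
    for label, name in regions.names.items():
        if name in exclude:
            continue
        values = vol.values[regions.labels == label]
        n_valid = int(np.isfinite(values).sum())
        if n_valid == 0:
            warnings.warn(f"region {name!r}: no valid voxels, row omitted")
            continue
        rows.append(
            {
                "animal_id": animal_id,
                "genotype": genotype,
                "age_group": age_group,
                "region": name,
                "map": map_name,
                "value": float(reduce(values)),
                "n_voxels": n_valid,
                "flagged": n_valid < min_voxels,
            }
        )
    return pd.DataFrame(rows)


def percent_change(ctrl: np.ndarray, tg: np.ndarray) -> float:
    """100 * (mean_tg - mean_ctrl) / mean_ctrl."""
    ctrl = np.asarray(ctrl, float)
    tg = np.asarray(tg, float)
    if ctrl.size == 0 or tg.size == 0:
        raise ValueError("both groups must be nonempty")
    m_ctrl = ctrl.mean()
    if m_ctrl == 0:
        raise ValueError("control mean is zero; percent change undefined")
    return float(100.0 * (tg.mean() - m_ctrl) / m_ctrl)


def permutation_contrast(
    ctrl: np.ndarray,
    tg: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    region: str = "",
    map_name: str = "",
) -> GroupContrast:
    """Two-sided permutation test of the group-mean difference.

    p = (1 + #{|delta_perm| >= |delta_obs|}) / (1 + n_perm) over random
    genotype-label permutations; identical samples give p = 1.
    """
    ctrl = np.asarray(ctrl, float)
    tg = np.asarray(tg, float)
    if ctrl.size + tg.size < 4:
        raise ValueError("need at least 4 values across both groups")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([ctrl, tg])
    n_c = ctrl.size
    delta_obs = tg.mean() - ctrl.mean()
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, pooled.size)), axis=1)
    delta_perm = perms[:, n_c:].mean(axis=1) - perms[:, :n_c].mean(axis=1)
    p = (1.0 + np.sum(np.abs(delta_perm) >= np.abs(delta_obs) - 1e-12)) / (1.0 + n_perm)
    return GroupContrast(
        region=region,
        map_name=map_name,
        percent_change=percent_change(ctrl, tg),
        p_perm=float(p),
        n_ctrl=int(n_c),
        n_tg=int(tg.size),
    )


def build_report(
    summaries: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy contrast table: one row per age_group x region x map.

    Columns: age_group, region, map, n_ctrl, n_tg, mean_ctrl, mean_tg,
    percent_change, p_perm.  Cells missing one genotype group are omitted
    with a warning.
    """
    cols = [
        "age_group", "region", "map", "n_ctrl", "n_tg",
        "mean_ctrl", "mean_tg", "percent_change", "p_perm",
    ]
    if summaries.empty:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    rows = []
    for (age, region, map_name), grp in summaries.groupby(
        ["age_group", "region", "map"], sort=True
    ):
        ctrl = grp.loc[grp.genotype == "control", "value"].to_numpy()
        tg = grp.loc[grp.genotype == "transgenic", "value"].to_numpy()
        if ctrl.size < 2 or tg.size < 2:
            warnings.warn(f"{age}/{region}/{map_name}: missing or too-small group, row omitted")
            continue
        contrast = permutation_contrast(
            ctrl, tg, n_perm=n_perm, seed=rng, region=region, map_name=map_name
        )
        rows.append(
            {
                "age_group": age,
                "region": region,
                "map": map_name,
                "n_ctrl": contrast.n_ctrl,
                "n_tg": contrast.n_tg,
                "mean_ctrl": float(ctrl.mean()),
                "mean_tg": float(tg.mean()),
                "percent_change": contrast.percent_change,
                "p_perm": contrast.p_perm,
            }
        )
    return pd.DataFrame(rows, columns=cols)
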