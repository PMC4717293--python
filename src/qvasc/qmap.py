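"""Steady-state relaxation-rate mapping and the relaxation shift index Q.

With an intravascular iron-oxide tracer at steady state, pre/post-contrast
spin-echo and gradient-echo images give the transverse relaxation-rate
changes

    dR2  = (1/TE_SE) * ln(S_pre  / S_post)       (microvessel weighted)
    dR2* = (1/TE_GE) * ln(S*_pre / S*_post)      (all vessel sizes)

Negative rates (noise) are clipped to zero.  The relaxation shift index

    Q = dR2 / (dR2*)^(2/3)

is approximately independent of tracer dose and blood volume and scales
with microvessel density; density is estimated as N ~= Q^3 * 329 (reported
in the source literature's printed unit, s/mm^2).  dR2* itself is
proportional to relative blood volume and is therefore also exported as
rCBV(dR2*).

The gradient-echo maps are usually acquired on a finer grid than the
spin-echo maps; ``resample_to_grid`` moves them onto the spin-echo grid by
cubic-spline interpolation before Q is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core_io import VolumeImage

__all__ = [
    "RelaxationMaps",
    "compute_delta_r2",
    "compute_delta_r2star",
    "resample_to_grid",
    "compute_q",
    "compute_vessel_density",
    "compute_rcbv_ss",
    "compute_relaxation_maps",
]

#: Proportionality constant between Q^3 and microvessel density.
DENSITY_CONSTANT = 329.0

#: dR2* below this (s^-1) is treated as zero when forming Q.
DEFAULT_EPSILON = 1e-6


@dataclass
class RelaxationMaps:
    """Steady-state output maps, all on the spin-echo grid."""

    dr2: VolumeImage
    dr2star: VolumeImage
    q: VolumeImage
    n_density: VolumeImage
    rcbv_ss: VolumeImage


def _delta_r(pre: VolumeImage, post: VolumeImage, te_s: float) -> VolumeImage:
    if pre.shape != post.shape:
        raise ValueError(f"pre/post grids differ: {pre.shape} vs {post.shape}")
    if not te_s > 0:
        raise ValueError(f"te_s must be > 0, got {te_s}")
    s_pre = pre.values
    s_post = post.values
    bad = ~((s_pre > 0) & (s_post > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = np.log(s_pre / s_post) / te_s
    dr[bad] = np.nan
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels with nonpositive signal masked (NaN)", stacklevel=3)
    # negative rates are a noise artefact; zero them to keep Q real
    np.clip(dr, 0.0, None, out=dr)
    return pre.with_values(dr)


def compute_delta_r2(pre: VolumeImage, post: VolumeImage, te_s: float | None = None) -> VolumeImage:
    """dR2 map from pre/post spin-echo volumes; negatives clipped to 0."""
    return _delta_r(pre, post, pre.meta.te_s if te_s is None else te_s)


def compute_delta_r2star(
    pre: VolumeImage, post: VolumeImage, te_s: float | None = None
) -> VolumeImage:
    """dR2* map from pre/post gradient-echo volumes; negatives clipped to 0."""
    return _delta_r(pre, post, pre.meta.te_s if te_s is None else te_s)


def resample_to_grid(src: VolumeImage, target: VolumeImage) -> VolumeImage:
    """Cubic-spline resampling of ``src`` onto ``target``'s grid.

    Grids share a corner origin; a voxel centre sits at
    ``(i + 0.5) * spacing``.  Target centres outside the source extent
    become NaN; fully disjoint extents raise ``ValueError``.
    """
    src_extent = [n * s for n, s in zip(src.shape, src.spacing_mm)]
    coords = []
    inside = np.ones(target.shape, dtype=bool)
    for ax in range(3):
        n_t = target.shape[ax]
        centre = (np.arange(n_t) + 0.5) * target.spacing_mm[ax]
        idx = centre / src.spacing_mm[ax] - 0.5
        shape = [1, 1, 1]
        shape[ax] = n_t
        coords.append(np.broadcast_to(idx.reshape(shape), target.shape))
        ax_inside = (centre >= 0.0) & (centre <= src_extent[ax])
        inside &= np.broadcast_to(ax_inside.reshape(shape), target.shape)
    if not inside.any():
        raise ValueError("source and target extents are disjoint")
    stacked = np.stack(coords)
    finite = np.isfinite(src.values)
    if finite.all():
        out = map_coordinates(src.values, stacked, order=3, mode="nearest")
    else:
        # masked interpolation: NaN voxels would poison the global spline
        # prefilter, so interpolate value*weight and weight separately and
        # renormalise; targets dominated by masked sources become NaN
        filled = np.where(finite, src.values, 0.0)
        num = map_coordinates(filled, stacked, order=3, mode="nearest")
        den = map_coordinates(finite.astype(float), stacked, order=3, mode="nearest")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        out[den < 0.5] = np.nan
    out[~inside] = np.nan
    return VolumeImage(out, target.spacing_mm, src.meta)


def compute_q(
    dr2: VolumeImage | np.ndarray,
    dr2star: VolumeImage | np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> VolumeImage | np.ndarray:
    """Relaxation shift index Q = dR2 / (dR2*)^(2/3).

    Inputs must be clipped (nonnegative) rate maps on one grid; voxels
    with dR2* below ``epsilon`` get Q = 0; NaN (masked) propagates.
    """
    a = dr2.values if isinstance(dr2, VolumeImage) else np.asarray(dr2, float)
    b = dr2star.values if isinstance(dr2star, VolumeImage) else np.asarray(dr2star, float)
    if a.shape != b.shape:
        raise ValueError(f"grids differ: {a.shape} vs {b.shape}")
    if np.any(a[np.isfinite(a)] < 0) or np.any(b[np.isfinite(b)] < 0):
        raise ValueError("negative relaxation rates: clip before computing Q")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = a / b ** (2.0 / 3.0)
    q = np.where(b < epsilon, 0.0, q)
    q[~(np.isfinite(a) & np.isfinite(b))] = np.nan
    if isinstance(dr2, VolumeImage):
        return dr2.with_values(q)
    return q


def compute_vessel_density(q: VolumeImage | np.ndarray) -> VolumeImage | np.ndarray:
    """Microvessel density N ~= Q^3 * 329 (printed unit s/mm^2)."""
    v = q.values if isinstance(q, VolumeImage) else np.asarray(q, float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("Q must be nonnegative")
    n = v**3 * DENSITY_CONSTANT
    if isinstance(q, VolumeImage):
        return q.with_values(n)
    return n


def compute_rcbv_ss(dr2star: VolumeImage) -> VolumeImage:
    """rCBV(dR2*): the steady-state dR2* map re-labelled as relative blood
    volume (arbitrary units), kept as a distinct named output."""
    return dr2star.with_values(dr2star.values.copy())


def compute_relaxation_maps(
    se_pre: VolumeImage,
    se_post: VolumeImage,
    ge_pre: VolumeImage,
    ge_post: VolumeImage,
    epsilon: float = DEFAULT_EPSILON,
) -> RelaxationMaps:
    """Full steady-state chain: dR2, dR2* (resampled to the SE grid), Q, N,
    rCBV(dR2*).

    dR2* is computed and clipped on the native gradient-echo grid, cubic-
    spline resampled onto the spin-echo grid, and re-clipped (interpolation
    can undershoot below zero near edges) before Q is formed.
    """
    dr2 = compute_delta_r2(se_pre, se_post)
    dr2star_ge = compute_delta_r2star(ge_pre, ge_post)
    if dr2star_ge.shape != dr2.shape or dr2star_ge.spacing_mm != dr2.spacing_mm:
        dr2star = resample_to_grid(dr2star_ge, dr2)
        np.clip(dr2star.values, 0.0, None, out=dr2star.values)
    else:
        dr2star = dr2star_ge
    q = compute_q(dr2, dr2star, epsilon=epsilon)
    n = compute_vessel_density(q)
    return RelaxationMaps(
        dr2=dr2,
        dr2star=dr2star,
        q=q,
        n_density=n,
        rcbv_ss=compute_rcbv_ss(dr2star),
    )
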