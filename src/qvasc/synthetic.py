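"""Synthetic phantom cohorts for parameter-recovery testing.

The generator emulates a two-genotype mouse imaging study end to end:

* a deterministic digital brain phantom (an ellipsoid partitioned into the
  six reported gray-matter regions plus a small arterial region),
* pre/post-contrast gradient-echo and spin-echo volumes whose voxelwise
  relaxation-rate changes encode a ground-truth vessel-density field
  (the steady-state forward model is the exact inverse of the dR2/dR2*
  estimators, so noiseless data are recovered analytically), and
* a 4D dynamic bolus-passage series built from the indicator-dilution
  model  C_t(t) = CBF * (C_a (x) R)(t)  with an exponential residue
  R(t) = exp(-t / MTT), MTT = CBV / CBF, and a gamma-variate arterial
  input in the artery voxels.

Genotype effects are multiplicative factors on the *truth* parameter whose
recovered percent change is to be checked: a Q-level factor for Q, a
CBF/CBV-level factor for the perfusion read-outs, and a separate dR2*
factor for steady-state rCBV (Q and density-level factors differ because
density scales as Q^3).  Per-animal biological variability is lognormal
multiplicative scatter around the group truth.  Everything is reproducible
from the cohort seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core_io import (
    CANONICAL_REGIONS,
    TISSUE_REGIONS,
    AcquisitionMeta,
    DynamicSeries,
    RegionSet,
    Sequence,
    VolumeImage,
)
from .gamma import GammaVariateFit, gamma_variate

__all__ = [
    "RegionTruth",
    "EffectSizes",
    "CohortSpec",
    "AnimalTruth",
    "SteadyStateImages",
    "AnimalData",
    "Cohort",
    "make_phantom",
    "synth_steady_state",
    "synth_dsc",
    "sample_animal_truths",
    "iter_animals",
    "make_cohort",
    "study_defaults_24mo",
    "DEFAULT_META_GE",
    "DEFAULT_META_SE",
    "DEFAULT_META_DSC",
]

# default acquisition constants: 5.5 ms gradient echo, 30 ms spin echo,
# 10 ms dynamic EPI at 400 ms frame spacing with a 30 s (75-frame) baseline
DEFAULT_META_GE = AcquisitionMeta(te_s=0.0055, tr_s=0.040, sequence=Sequence.gradient_echo)
DEFAULT_META_SE = AcquisitionMeta(te_s=0.030, tr_s=2.0, sequence=Sequence.spin_echo)
DEFAULT_META_DSC = AcquisitionMeta(
    te_s=0.010, tr_s=0.4, sequence=Sequence.dynamic_epi, baseline_frames=75
)

#: Default arterial input: onset at the end of the 30 s baseline, shape 3,
#: scale 1.5 s (first-pass peak ~50 1/s about 4.5 s after onset).
DEFAULT_AIF = GammaVariateFit(amplitude=11.0, t0=30.0, alpha=3.0, beta=1.5)


@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth vascular parameters of one region.

    ``q_true`` in s^(-1/3); ``dr2star_true`` in 1/s (steady state);
    ``cbf_true`` and ``cbv_true`` in arbitrary flow / volume units.  The
    microvessel-weighted rate is derived, dR2 = Q * (dR2*)^(2/3).
    """

    q_true: float
    dr2star_true: float
    cbf_true: float
    cbv_true: float

    def __post_init__(self) -> None:
        for name in ("q_true", "dr2star_true", "cbf_true", "cbv_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def dr2_true(self) -> float:
        return self.q_true * self.dr2star_true ** (2.0 / 3.0)

    @property
    def mtt_true(self) -> float:
        if self.cbf_true == 0:
            if self.cbv_true > 0:
                raise ValueError("cbf_true = 0 with cbv_true > 0: undefined MTT")
            return 0.0
        return self.cbv_true / self.cbf_true


@dataclass(frozen=True)
class EffectSizes:
    """Multiplicative genotype effects on a region's truth parameters.

    ``cbf`` models vascular rarefaction: flow and dynamic-tracer blood
    volume fall proportionally (mean transit time preserved), so it
    multiplies both ``cbf_true`` and ``cbv_true``.  ``cbv_dsc`` is a pure
    volume effect (it lengthens MTT); ``cbv_ss`` acts on steady-state
    dR2* (the rCBV(dR2*) read-out), which the study treats as a separate
    blood-volume interpretation from the dynamic one.
    """

    q: float = 1.0
    cbf: float = 1.0
    cbv_dsc: float = 1.0
    cbv_ss: float = 1.0  # factor on steady-state dR2*, i.e. rCBV(dR2*)

    def __post_init__(self) -> None:
        for name in ("q", "cbf", "cbv_dsc", "cbv_ss"):
            if getattr(self, name) < 0:
                raise ValueError(f"effect factor {name} must be >= 0")


def _default_region_truth() -> dict[str, RegionTruth]:
    # gray-matter baseline: Q 0.63 s^-1/3, steady-state dR2* 20 1/s,
    # relative CBV 0.3 a.u. with a 1.5 s mean transit time
    tissue = RegionTruth(q_true=0.63, dr2star_true=20.0, cbf_true=0.2, cbv_true=0.3)
    truth = {name: tissue for name in TISSUE_REGIONS}
    truth["artery"] = RegionTruth(q_true=0.3, dr2star_true=60.0, cbf_true=0.0, cbv_true=0.0)
    return truth


@dataclass
class CohortSpec:
    """Design of a synthetic two-genotype cohort."""

    n_control: int = 14
    n_transgenic: int = 8
    region_truth: dict[str, RegionTruth] = field(default_factory=_default_region_truth)
    effect: dict[str, EffectSizes] = field(default_factory=dict)
    noise_sigma: float = 0.025  # additive noise s.d. as fraction of baseline signal
    scatter_sigma: float = 0.05  # lognormal per-animal biological scatter
    seed: int = 0
    age_group: str = "24mo"
    aif: GammaVariateFit = DEFAULT_AIF
    baseline_signal: float = 1000.0
    noise_model: str = "gaussian"  # or "rician"
    shape_ss: tuple[int, int, int] = (48, 48, 8)
    ge_upsample: int = 2
    shape_dsc: tuple[int, int, int] = (24, 24, 6)
    n_frames: int = 300
    meta_ge: AcquisitionMeta = DEFAULT_META_GE
    meta_se: AcquisitionMeta = DEFAULT_META_SE
    meta_dsc: AcquisitionMeta = DEFAULT_META_DSC

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_transgenic < 2:
            raise ValueError("group sizes must be >= 2")
        if self.noise_sigma < 0 or self.scatter_sigma < 0:
            raise ValueError("noise/scatter s.d. must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.n_frames < (self.meta_dsc.baseline_frames or 0) + 30:
            raise ValueError("n_frames must be >= baseline_frames + 30")


@dataclass
class AnimalTruth:
    """One animal's realised (scattered) ground truth."""

    animal_id: str
    genotype: str  # "control" | "transgenic"
    region_values: dict[str, RegionTruth]
    bat_s: float
    aif: GammaVariateFit

    def map_on(self, phantom: RegionSet, param: str) -> np.ndarray:
        """Voxel map of ``param`` ('q', 'dr2', 'dr2star', 'cbf', 'cbv')."""
        attr = {"q": "q_true", "dr2": "dr2_true", "dr2star": "dr2star_true",
                "cbf": "cbf_true", "cbv": "cbv_true"}[param]
        out = np.zeros(phantom.labels.shape)
        for label, name in phantom.names.items():
            out[phantom.labels == label] = getattr(self.region_values[name], attr)
        return out


@dataclass
class SteadyStateImages:
    ge_pre: VolumeImage
    ge_post: VolumeImage
    se_pre: VolumeImage
    se_post: VolumeImage


@dataclass
class AnimalData:
    truth: AnimalTruth
    steady: SteadyStateImages | None = None
    dsc: DynamicSeries | None = None


@dataclass
class Cohort:
    spec: CohortSpec
    phantom_ss: RegionSet
    phantom_dsc: RegionSet
    animals: list[AnimalData]


# ---------------------------------------------------------------------------
# phantom geometry


def make_phantom(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    artery_radius: float | None = None,
    min_region_voxels: int = 50,
) -> RegionSet:
    """Deterministic brain phantom: an ellipsoid split into six equal-size
    slabs along x (the six reported regions) plus a small central artery
    cylinder.

    Raises ``ValueError`` if the shape cannot host all seven labels with at
    least ``min_region_voxels`` voxels each.
    """
    nx, ny, nz = shape
    idx = np.indices(shape, dtype=float)
    centre = [(n - 1) / 2.0 for n in shape]
    semi = [max(0.45 * n, 0.5) for n in shape]
    r2 = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
    brain = r2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    if brain.sum() < 7 * min_region_voxels:
        raise ValueError(f"shape {shape} too small to host 7 regions of >= {min_region_voxels} voxels")

    # artery first: vertical cylinder through the brain centre, smallest
    # radius that reaches min_region_voxels so it stays small on any grid
    rho2 = (idx[0] - centre[0]) ** 2 + (idx[1] - centre[1]) ** 2
    if artery_radius is None:
        for r in np.arange(1.0, min(nx, ny) / 4.0, 0.5):
            if int(((rho2 <= r**2) & brain).sum()) >= min_region_voxels:
                artery_radius = float(r)
                break
        else:
            raise ValueError(f"shape {shape} too small to host an artery region")
    artery = (rho2 <= artery_radius**2) & brain

    # six tissue slabs balanced over the non-arterial brain by x-quantiles
    tissue = brain & ~artery
    edges = np.quantile(idx[0][tissue], np.linspace(0, 1, 7)[1:-1])
    slab = np.digitize(idx[0], edges) + 1  # 1..6
    labels[tissue] = slab[tissue]
    labels[artery] = 7

    counts = np.bincount(labels.ravel(), minlength=8)
    bad = [CANONICAL_REGIONS[l] for l in range(1, 8) if counts[l] < min_region_voxels]
    if bad:
        raise ValueError(f"shape {shape} too small: regions below {min_region_voxels} voxels: {bad}")
    return RegionSet(labels, CANONICAL_REGIONS, spacing_mm)


def _upsample_xy(vol: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(np.repeat(vol, factor, axis=0), factor, axis=1)


def _add_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator, model: str) -> np.ndarray:
    if sigma == 0:
        return signal
    if model == "rician":
        # magnitude of a complex signal with i.i.d. Gaussian channel noise
        return np.hypot(signal + rng.normal(0.0, sigma, signal.shape),
                        rng.normal(0.0, sigma, signal.shape))
    return signal + rng.normal(0.0, sigma, signal.shape)


# ---------------------------------------------------------------------------
# forward models


def synth_steady_state(
    phantom: RegionSet,
    truth: AnimalTruth,
    meta_ge: AcquisitionMeta = DEFAULT_META_GE,
    meta_se: AcquisitionMeta = DEFAULT_META_SE,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline_signal: float = 1000.0,
    ge_upsample: int = 2,
    noise_model: str = "gaussian",
) -> SteadyStateImages:
    """Pre/post-contrast GE and SE volumes implementing the exact inverse of
    the relaxation-rate estimators.

    SE volumes live on the phantom grid; GE volumes on a grid ``ge_upsample``
    times finer in-plane (to exercise resampling).  Signal is
    ``baseline_signal`` inside the brain (0 outside) with post-contrast
    attenuation ``exp(-TE * dR2)``; zero-mean noise of s.d.
    ``noise_sigma * baseline_signal`` is added to every image.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = noise_sigma * baseline_signal
    fg_se = (phantom.labels > 0).astype(float)
    dr2 = truth.map_on(phantom, "dr2")
    dr2star = _upsample_xy(truth.map_on(phantom, "dr2star"), ge_upsample)
    fg_ge = _upsample_xy(fg_se, ge_upsample)

    def attenuation(te: float, rate: np.ndarray) -> np.ndarray:
        ratio = np.exp(-te * rate)
        if np.any(ratio < np.finfo(float).eps):
            warnings.warn("TE*dR2 so large that the post-contrast signal underflows; flooring")
            ratio = np.maximum(ratio, np.finfo(float).eps)
        return ratio

    se_spacing = phantom.spacing_mm
    ge_spacing = (
        se_spacing[0] / ge_upsample,
        se_spacing[1] / ge_upsample,
        se_spacing[2],
    )
    se_pre = baseline_signal * fg_se
    se_post = se_pre * attenuation(meta_se.te_s, dr2)
    ge_pre = baseline_signal * fg_ge
    ge_post = ge_pre * attenuation(meta_ge.te_s, dr2star)
    return SteadyStateImages(
        ge_pre=VolumeImage(_add_noise(ge_pre, sigma, rng, noise_model), ge_spacing, meta_ge),
        ge_post=VolumeImage(_add_noise(ge_post, sigma, rng, noise_model), ge_spacing, meta_ge),
        se_pre=VolumeImage(_add_noise(se_pre, sigma, rng, noise_model), se_spacing, meta_se),
        se_post=VolumeImage(_add_noise(se_post, sigma, rng, noise_model), se_spacing, meta_se),
    )


def synth_dsc(
    phantom: RegionSet,
    truth: AnimalTruth,
    meta: AcquisitionMeta = DEFAULT_META_DSC,
    n_frames: int = 300,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline_signal: float = 1000.0,
    k: float = 1.0,
    oversample: int = 20,
    noise_model: str = "gaussian",
) -> DynamicSeries:
    """Dynamic bolus-passage series from the indicator-dilution model.

    Artery voxels carry the gamma-variate input C_a(t); each tissue region
    carries C_t(t) = CBF * (C_a (x) R)(t) with R(t) = exp(-t / MTT).  The
    convolution is evaluated on a time grid ``oversample`` times finer than
    the frame spacing (continuous model, not the discrete deconvolution
    operator) and sampled at the frame times.  Signals are
    S(t) = S0 * exp(-TE * C(t) / k); noise is added on the signal.
    """
    if n_frames < (meta.baseline_frames or 0) + 30:
        raise ValueError("n_frames must be >= baseline_frames + 30")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tr = meta.tr_s
    t_frames = np.arange(n_frames) * tr
    dt = tr / oversample
    t_fine = np.arange(n_frames * oversample) * dt
    ca_fine = truth.aif(t_fine)

    conc = np.zeros(phantom.labels.shape + (n_frames,))
    for label, name in phantom.names.items():
        mask = phantom.labels == label
        if not mask.any():
            continue
        rt = truth.region_values[name]
        if name == "artery":
            curve = truth.aif(t_frames)
        elif rt.cbf_true == 0:
            if rt.cbv_true > 0:
                raise ValueError(f"{name}: cbf_true = 0 with cbv_true > 0, MTT undefined")
            curve = np.zeros(n_frames)
        else:
            residue = np.exp(-t_fine / rt.mtt_true)
            conv = dt * np.convolve(ca_fine, residue)[: t_fine.size]
            curve = rt.cbf_true * conv[::oversample]
        conc[mask] = curve

    signal = baseline_signal * np.exp(-meta.te_s * conc / k)
    signal[phantom.labels == 0] = 0.0
    signal = _add_noise(signal, noise_sigma * baseline_signal, rng, noise_model)
    return DynamicSeries(signal, t_frames, meta)


# ---------------------------------------------------------------------------
# cohort assembly


def sample_animal_truths(
    spec: CohortSpec, genotype: str, rng: np.random.Generator
) -> dict[str, RegionTruth]:
    """Per-animal regional truths: group truth x genotype effect x lognormal
    scatter (independent per parameter)."""
    out: dict[str, RegionTruth] = {}
    for name, base in spec.region_truth.items():
        eff = spec.effect.get(name, EffectSizes()) if genotype == "transgenic" else EffectSizes()
        s = spec.scatter_sigma
        jit = np.exp(rng.normal(0.0, s, size=4)) if s > 0 else np.ones(4)
        out[name] = RegionTruth(
            q_true=base.q_true * eff.q * jit[0],
            dr2star_true=base.dr2star_true * eff.cbv_ss * jit[1],
            cbf_true=base.cbf_true * eff.cbf * jit[2],
            cbv_true=base.cbv_true * eff.cbf * eff.cbv_dsc * jit[3],
        )
    return out


def iter_animals(
    spec: CohortSpec,
    include_steady: bool = True,
    include_dsc: bool = True,
) -> Iterator[AnimalData]:
    """Yield per-animal synthetic datasets, reproducibly from ``spec.seed``.

    Animals are ordered controls first; each animal consumes its own RNG
    stream so the cohort is bit-identical for a given spec regardless of
    which modalities are generated.
    """
    phantom_ss = make_phantom(spec.shape_ss)
    phantom_dsc = make_phantom(spec.shape_dsc)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_control + spec.n_transgenic)
    genotypes = ["control"] * spec.n_control + ["transgenic"] * spec.n_transgenic
    for i, (genotype, child) in enumerate(zip(genotypes, children)):
        rng = np.random.default_rng(child)
        truth = AnimalTruth(
            animal_id=f"{genotype[:4]}{i:02d}",
            genotype=genotype,
            region_values=sample_animal_truths(spec, genotype, rng),
            bat_s=(spec.meta_dsc.baseline_frames or 0) * spec.meta_dsc.tr_s,
            aif=spec.aif,
        )
        steady = None
        if include_steady:
            steady = synth_steady_state(
                phantom_ss,
                truth,
                spec.meta_ge,
                spec.meta_se,
                noise_sigma=spec.noise_sigma,
                seed=rng,
                baseline_signal=spec.baseline_signal,
                ge_upsample=spec.ge_upsample,
                noise_model=spec.noise_model,
            )
        dsc = None
        if include_dsc:
            dsc = synth_dsc(
                phantom_dsc,
                truth,
                spec.meta_dsc,
                n_frames=spec.n_frames,
                noise_sigma=spec.noise_sigma,
                seed=rng,
                baseline_signal=spec.baseline_signal,
                noise_model=spec.noise_model,
            )
        yield AnimalData(truth=truth, steady=steady, dsc=dsc)


def make_cohort(
    spec: CohortSpec, include_steady: bool = True, include_dsc: bool = True
) -> Cohort:
    """Materialise the whole cohort (see :func:`iter_animals`)."""
    return Cohort(
        spec=spec,
        phantom_ss=make_phantom(spec.shape_ss),
        phantom_dsc=make_phantom(spec.shape_dsc),
        animals=list(iter_animals(spec, include_steady, include_dsc)),
    )


def study_defaults_24mo(seed: int = 0, **overrides) -> CohortSpec:
    """The default 24-month contrast: regional genotype effects matching the
    reported percent changes (Q factors OB 0.89, CC 0.85, ST 0.74, HC 0.80,
    TH 1.00, CB 0.81; CBF factor 0.65 in CB; CBV(DSC) factor 1.21 and
    CBV(dR2*) factor 1.25 in CC), n = 14 control vs 8 transgenic."""
    effect = {
        "olfactory_bulb": EffectSizes(q=0.89),
        "cortex": EffectSizes(q=0.85, cbv_dsc=1.21, cbv_ss=1.25),
        "striatum": EffectSizes(q=0.74),
        "hippocampus": EffectSizes(q=0.80),
        "thalamus": EffectSizes(q=1.00),
        "cerebellum": EffectSizes(q=0.81, cbf=0.65),
    }
    return CohortSpec(seed=seed, effect=effect, **overrides)
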