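"""Bolus-tracking (dynamic susceptibility contrast) perfusion analysis.

The processing chain converts the dynamic signal to a concentration-
proportional relaxation-rate change,

    C(t) ~ dR2*(t) = -(k / TE) * ln(S(t) / S0),   S0 = pre-bolus mean,

detects the bolus arrival time per voxel with a piecewise linear-quadratic
continuous regression, fits a gamma-variate to the first pass on the
window [BAT, BAT + 2.5 * (TTP - BAT)], selects an arterial input function
by an artery-likelihood search (tall, narrow, early curves), and derives

* rCBV as the ratio of the fitted tissue curve area to the AIF area, and
* rCBF as the peak of the residue function obtained by truncated-SVD
  deconvolution of the tissue curve with the AIF (truncation at a fixed
  fraction ``r_trunc`` of the largest singular value).

All quantities are relative (the proportionality factor k is fixed at 1;
it cancels in rCBV and scales rCBF linearly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core_io import DynamicSeries, VolumeImage
from .gamma import GammaVariateFit, gamma_area, gamma_variate

__all__ = [
    "ConcentrationSeries",
    "ConcentrationCurve",
    "BolusTiming",
    "ArterialInput",
    "PerfusionMaps",
    "NoBolusError",
    "signal_to_concentration",
    "make_brain_mask",
    "estimate_bolus_arrival",
    "fit_gamma_variate",
    "gamma_area",
    "select_aif",
    "compute_rcbv_dsc",
    "compute_rcbf",
    "process_dsc",
]


class NoBolusError(ValueError):
    """Raised when a curve shows no detectable bolus passage."""


@dataclass
class ConcentrationCurve:
    """One voxel's concentration-proportional dR2*(t) trace."""

    time_s: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.conc = np.asarray(self.conc, float)
        if self.time_s.shape != self.conc.shape:
            raise ValueError("time and concentration must have the same length")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("concentration curve contains non-finite values")


@dataclass
class ConcentrationSeries:
    """Voxelwise concentration curves plus validity bookkeeping.

    ``conc`` is (x, y, z, t); ``valid`` marks voxels with a positive
    baseline; ``clamped`` counts frames clamped away from ln(<=0).
    """

    time_s: np.ndarray
    conc: np.ndarray
    valid: np.ndarray
    s0: np.ndarray
    clamped: int = 0

    def curve(self, i: int, j: int, k: int) -> ConcentrationCurve:
        return ConcentrationCurve(self.time_s, self.conc[i, j, k])


@dataclass(frozen=True)
class BolusTiming:
    """Bolus arrival / time-to-peak of one concentration curve."""

    bat_s: float
    ttp_s: float
    fit_rss: float

    def __post_init__(self) -> None:
        if not self.bat_s < self.ttp_s:
            raise ValueError(f"need bat_s < ttp_s, got {self.bat_s} >= {self.ttp_s}")


@dataclass
class ArterialInput:
    """Selected arterial input: averaged curve, gamma fit, provenance."""

    curve: ConcentrationCurve
    fit: GammaVariateFit
    voxel_ids: list[tuple[int, int, int]]
    likelihood: float
    timing: BolusTiming | None = None


@dataclass
class PerfusionMaps:
    """DSC output maps: rCBV, rCBF, BAT; NaN outside the brain mask."""

    rcbv: VolumeImage
    rcbf: VolumeImage
    bat: VolumeImage
    mask: np.ndarray
    aif: ArterialInput | None = None
    n_failed_fits: int = 0


# ---------------------------------------------------------------------------
# concentration conversion and masking


def signal_to_concentration(
    series: DynamicSeries,
    baseline_frames: int | None = None,
    te_s: float | None = None,
    k: float = 1.0,
) -> ConcentrationSeries:
    """Convert signal to dR2*(t) = -(k/TE) ln(S/S0) voxelwise.

    S0 is the mean over the baseline frames.  Voxels with S0 <= 0 are
    marked invalid (conc = NaN is avoided: their curves are zeroed and
    excluded via ``valid``).  Nonpositive in-bolus samples are clamped to
    machine epsilon and counted in ``clamped``.
    """
    bl = series.meta.baseline_frames if baseline_frames is None else baseline_frames
    te = series.meta.te_s if te_s is None else te_s
    if te <= 0:
        raise ValueError("te_s must be > 0")
    if bl is None or bl < 1 or bl >= series.n_frames:
        raise ValueError(f"invalid baseline_frames {bl}")
    s = series.values
    s0 = s[..., :bl].mean(axis=-1)
    valid = s0 > 0
    tiny = np.finfo(float).eps
    clamped = int(np.sum((s <= 0) & valid[..., None]))
    ratio = np.clip(s, tiny, None) / np.where(valid, s0, 1.0)[..., None]
    conc = -(k / te) * np.log(ratio)
    conc[~valid] = 0.0
    return ConcentrationSeries(series.time_s.copy(), conc, valid, s0, clamped)


def make_brain_mask(series: DynamicSeries, threshold_frac: float = 0.2) -> np.ndarray:
    """Voxels whose baseline-mean signal exceeds ``threshold_frac`` of the
    robust (99th percentile) maximum."""
    bl = series.meta.baseline_frames or 1
    base = series.values[..., :bl].mean(axis=-1)
    robust_max = np.percentile(base, 99.0)
    if robust_max <= 0:
        raise ValueError("series has no positive baseline signal")
    mask = base > threshold_frac * robust_max
    if not mask.any():
        raise ValueError("empty brain mask")
    return mask


# ---------------------------------------------------------------------------
# bolus arrival time


#: The piecewise regression is fitted from the first frame up to the frame
#: where the curve first reaches this fraction of its peak: the early rise
#: localises the arrival, while frames near the peak only bias it.
BAT_WINDOW_PEAK_FRAC = 0.5
_BAT_MIN_WINDOW = 6


def _bat_window_end(y: np.ndarray, ttp_idx: int) -> int:
    w = int(np.argmax(y >= BAT_WINDOW_PEAK_FRAC * y[ttp_idx]))
    return int(np.clip(w, _BAT_MIN_WINDOW, ttp_idx))


def _piecewise_rss(y: np.ndarray, t: np.ndarray, w: int) -> tuple[int, float]:
    """Best breakpoint of the linear + continuous-quadratic model on
    frames [0, w] for one curve; returns (breakpoint index, rss)."""
    best = (2, np.inf)
    tw = t[: w + 1]
    yw = y[: w + 1]
    for b in range(2, w):
        ramp = np.clip(tw - t[b], 0.0, None) ** 2
        X = np.column_stack([np.ones_like(tw), tw, ramp])
        coef, res, *_ = np.linalg.lstsq(X, yw, rcond=None)
        rss = float(res[0]) if res.size else float(((X @ coef - yw) ** 2).sum())
        if rss < best[1] - 1e-12:  # strict improvement: ties go to earliest b
            best = (b, rss)
    return best


def estimate_bolus_arrival(
    curve: ConcentrationCurve, baseline_frames: int
) -> BolusTiming:
    """Bolus arrival by exhaustive piecewise linear-quadratic regression.

    A drifting baseline extended by a continuous quadratic departure,
    y = a0 + a1*t + a2*(t - t_b)^2 for t > t_b, is fitted over the early
    rise (up to the half-peak frame) for every candidate breakpoint; the
    breakpoint minimising the residual sum of squares is the arrival
    time.  Curves whose maximum stays within 2 baseline standard
    deviations of the baseline mean raise :class:`NoBolusError`.
    """
    y = curve.conc
    t = curve.time_s
    base = y[:baseline_frames]
    if y.max() <= base.mean() + 2.0 * base.std() or np.ptp(y) == 0:
        raise NoBolusError("curve has no post-baseline rise")
    ttp_idx = int(np.argmax(y))
    if ttp_idx < 3:
        raise NoBolusError("peak too early for breakpoint search")
    b, rss = _piecewise_rss(y, t, _bat_window_end(y, ttp_idx))
    # time to peak: curve maximum after arrival
    after = np.argmax(y[b:]) + b
    return BolusTiming(bat_s=float(t[b]), ttp_s=float(t[after]), fit_rss=rss)


def _bat_map(
    conc: np.ndarray, time_s: np.ndarray, baseline_frames: int, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised arrival-time search for all masked voxels.

    Returns (bat index, ttp index, ok) maps; voxels failing the no-bolus
    check get ok = False.  Voxels are grouped by their time-to-peak index
    so each group shares one breakpoint design matrix per candidate.
    """
    shape = conc.shape[:3]
    flat = conc[mask]  # (V, T)
    base = flat[:, :baseline_frames]
    ok = flat.max(axis=1) > base.mean(axis=1) + 2.0 * base.std(axis=1)
    ttp = flat.argmax(axis=1)
    ok &= ttp >= 3
    bat_idx = np.full(flat.shape[0], -1, dtype=int)

    # window end = half-peak crossing; group voxels sharing one window so
    # each group shares a design matrix per candidate breakpoint
    half = BAT_WINDOW_PEAK_FRAC * flat[np.arange(flat.shape[0]), ttp]
    wend = (flat >= half[:, None]).argmax(axis=1)
    wend = np.clip(wend, _BAT_MIN_WINDOW, ttp)

    for p in np.unique(wend[ok]):
        rows = np.nonzero(ok & (wend == p))[0]
        yw = flat[rows, : p + 1].T  # (T_w, V_p)
        tw = time_s[: p + 1]
        best_rss = np.full(rows.size, np.inf)
        best_b = np.full(rows.size, 2, dtype=int)
        for b in range(2, p):
            ramp = np.clip(tw - time_s[b], 0.0, None) ** 2
            X = np.column_stack([np.ones_like(tw), tw, ramp])
            coef, *_ = np.linalg.lstsq(X, yw, rcond=None)
            rss = ((X @ coef - yw) ** 2).sum(axis=0)
            better = rss < best_rss - 1e-12
            best_rss[better] = rss[better]
            best_b[better] = b
        bat_idx[rows] = best_b

    out_bat = np.full(shape, -1, dtype=int)
    out_ttp = np.full(shape, -1, dtype=int)
    out_ok = np.zeros(shape, dtype=bool)
    out_bat[mask] = bat_idx
    out_ttp[mask] = ttp
    ok_full = np.zeros(shape, dtype=bool)
    ok_full[mask] = ok
    out_ok |= ok_full
    return out_bat, out_ttp, out_ok


# ---------------------------------------------------------------------------
# gamma-variate fitting


def _loglin_init(
    t: np.ndarray, y: np.ndarray, t0: float
) -> tuple[float, float, float]:
    """Log-linearised initial (A, alpha, beta): ln y is linear in
    [1, ln(t - t0), (t - t0)] for a gamma-variate."""
    tau = t - t0
    use = (tau > 0) & (y > 0)
    if use.sum() < 3:
        return y.max(initial=1.0), 2.0, 1.0
    X = np.column_stack([np.ones(use.sum()), np.log(tau[use]), tau[use]])
    coef, *_ = np.linalg.lstsq(X, np.log(y[use]), rcond=None)
    amp = float(np.exp(np.clip(coef[0], -200, 200)))
    alpha = float(np.clip(coef[1], 0.1, 20.0))
    beta = float(np.clip(-1.0 / coef[2], 0.05, 50.0)) if coef[2] < 0 else 5.0
    return amp, alpha, beta


def _gamma_jac(t: np.ndarray, amplitude: float, t0: float, alpha: float, beta: float) -> np.ndarray:
    tau = t - t0
    J = np.zeros((t.size, 4))
    pos = tau > 0
    tp = tau[pos]
    f = amplitude * tp**alpha * np.exp(-tp / beta)
    J[pos, 0] = f / amplitude if amplitude != 0 else tp**alpha * np.exp(-tp / beta)
    J[pos, 1] = f * (-alpha / tp + 1.0 / beta)
    J[pos, 2] = f * np.log(tp)
    J[pos, 3] = f * tp / beta**2
    return J


def fit_gamma_variate(
    curve: ConcentrationCurve,
    timing: BolusTiming,
    window_factor: float = 2.5,
    max_nfev: int = 300,
) -> GammaVariateFit:
    """Least-squares gamma-variate fit on [BAT, BAT + 2.5*(TTP - BAT)].

    Initialisation is a log-linearisation on the window with the onset at
    BAT, followed by bounded nonlinear refinement with the onset free.  A
    non-converged fit is returned flagged (``converged=False``) rather
    than raising, so map-level callers can exclude the voxel.
    """
    t = curve.time_s
    y = curve.conc
    lo, hi = timing.bat_s, timing.bat_s + window_factor * (timing.ttp_s - timing.bat_s)
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 5:
        raise ValueError(f"fit window [{lo:.3g}, {hi:.3g}] s has fewer than 5 frames")
    tw, yw = t[sel], y[sel]
    dt = float(np.median(np.diff(t)))
    t0_init = timing.bat_s - 0.5 * dt
    amp, alpha, beta = _loglin_init(tw, yw, t0_init)
    p0 = [amp, t0_init, alpha, beta]
    lower = [0.0, timing.bat_s - 10.0 * dt, 0.05, 0.01]
    upper = [np.inf, tw[1] - 1e-9, 50.0, 100.0]
    p0 = [float(np.clip(v, l, u)) for v, l, u in zip(p0, lower, upper)]
    try:
        popt, _ = curve_fit(
            gamma_variate, tw, yw, p0=p0, bounds=(lower, upper),
            jac=_gamma_jac, max_nfev=max_nfev, ftol=1e-7, xtol=1e-7, gtol=1e-7,
        )
    except RuntimeError:
        return GammaVariateFit(
            amplitude=float("nan"), t0=float("nan"), alpha=1.0, beta=1.0,
            window=(lo, hi), rss=float("inf"), converged=False,
        )
    rss = float(((gamma_variate(tw, *popt) - yw) ** 2).sum())
    return GammaVariateFit(
        amplitude=float(popt[0]), t0=float(popt[1]), alpha=float(popt[2]),
        beta=float(popt[3]), window=(float(lo), float(hi)), rss=rss,
    )


# ---------------------------------------------------------------------------
# arterial input selection


def _fwhm(t: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation around the peak."""
    p = int(np.argmax(y))
    half = y[p] / 2.0
    left = t[0]
    for i in range(p, 0, -1):
        if y[i - 1] < half <= y[i]:
            left = np.interp(half, [y[i - 1], y[i]], [t[i - 1], t[i]])
            break
    right = t[-1]
    for i in range(p, y.size - 1):
        if y[i + 1] < half <= y[i]:
            right = np.interp(half, [y[i + 1], y[i]], [t[i + 1], t[i]])
            break
    return float(max(right - left, np.diff(t).min()))


def _fit_peak_fwhm(fit: GammaVariateFit, t_max: float, n: int = 2000) -> tuple[float, float]:
    """Peak height and FWHM of a fitted gamma-variate (noise-free features
    for candidate scoring)."""
    # peak at tau = alpha * beta
    peak = float(fit.amplitude * (fit.alpha * fit.beta) ** fit.alpha * np.exp(-fit.alpha))
    tt = np.linspace(fit.t0, max(t_max, fit.t0 + 10 * fit.alpha * fit.beta), n)
    return peak, _fwhm(tt, fit(tt))


def _zscore(x: np.ndarray) -> np.ndarray:
    """Robust z-score (median / scaled MAD): the candidate population is
    dominated by tissue voxels with heavy-tailed fitted widths, which
    would inflate a moment-based scale and drown the arterial signal."""
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    return (x - med) / mad


def select_aif(
    conc: ConcentrationSeries,
    mask: np.ndarray,
    baseline_frames: int,
    m: int = 10,
    restrict: np.ndarray | None = None,
    bat_idx: np.ndarray | None = None,
    ttp_idx: np.ndarray | None = None,
    ok: np.ndarray | None = None,
    fits: dict[tuple[int, int, int], GammaVariateFit] | None = None,
    min_candidates: int = 50,
) -> ArterialInput:
    """Arterial-input search with an artery-likelihood metric.

    Candidates are masked voxels (optionally restricted, e.g. to an
    arterial ROI) passing sanity filters: a detected bolus, a converged
    gamma-variate fit with positive area.  Each candidate is scored

        likelihood = z(peak) + z(1 / FWHM) + z(-BAT)

    (tall, narrow, early); the ``m`` highest-scoring curves are averaged
    and refitted to yield the arterial input function.
    """
    cand_mask = mask & conc.valid
    if restrict is not None:
        cand_mask = cand_mask & restrict
    if int(cand_mask.sum()) < min_candidates:
        raise ValueError(f"fewer than {min_candidates} candidate voxels for AIF search")
    if bat_idx is None or ttp_idx is None or ok is None:
        bat_idx, ttp_idx, ok = _bat_map(conc.conc, conc.time_s, baseline_frames, cand_mask)
    good = cand_mask & ok
    keep: list[tuple[int, int, int]] = []
    kept_fits: list[GammaVariateFit] = []
    for v in map(tuple, np.argwhere(good)):
        if fits is not None:
            f = fits.get(v)
        else:
            timing = BolusTiming(
                bat_s=conc.time_s[bat_idx[v]], ttp_s=conc.time_s[ttp_idx[v]], fit_rss=0.0
            )
            try:
                f = fit_gamma_variate(conc.curve(*v), timing)
            except ValueError:
                continue
        if f is not None and f.converged and gamma_area(f) > 0:
            keep.append(v)
            kept_fits.append(f)
    ids = np.array(keep, dtype=int).reshape(-1, 3)
    if ids.shape[0] == 0:
        raise ValueError("no AIF candidate passed the sanity filters")
    if m > ids.shape[0]:
        raise ValueError(f"m={m} exceeds the {ids.shape[0]} surviving candidates")

    curves = conc.conc[tuple(ids.T)]  # (V, T)
    # score on fitted-curve features: raw peaks/widths are noise-spiked
    t_max = float(conc.time_s[-1])
    feats = np.array([_fit_peak_fwhm(f, t_max) for f in kept_fits])
    peaks, fwhms = feats[:, 0], feats[:, 1]
    bats = conc.time_s[bat_idx[tuple(ids.T)]]
    score = _zscore(peaks) + _zscore(1.0 / fwhms) + _zscore(-bats)
    order = np.argsort(-score, kind="stable")
    top = order[:m]
    mean_curve = ConcentrationCurve(conc.time_s, curves[top].mean(axis=0))
    timing = estimate_bolus_arrival(mean_curve, baseline_frames)
    fit = fit_gamma_variate(mean_curve, timing)
    if not fit.converged or gamma_area(fit) <= 0:
        raise ValueError("gamma-variate fit of the averaged arterial curve failed")
    return ArterialInput(
        curve=mean_curve,
        fit=fit,
        voxel_ids=[tuple(v) for v in ids[top]],
        likelihood=float(score[top].min()),
        timing=timing,
    )


# ---------------------------------------------------------------------------
# perfusion maps


def compute_rcbv_dsc(
    tissue_areas: np.ndarray | dict[tuple[int, int, int], GammaVariateFit],
    aif: ArterialInput,
) -> np.ndarray:
    """rCBV = (tissue gamma-variate area) / (AIF gamma-variate area)."""
    aif_area = gamma_area(aif.fit)
    if not aif_area > 0:
        raise ValueError(f"AIF area must be positive, got {aif_area}")
    if isinstance(tissue_areas, dict):
        shape = tuple(np.max([v for v in tissue_areas], axis=0) + 1)
        out = np.full(shape, np.nan)
        for v, f in tissue_areas.items():
            out[v] = gamma_area(f) / aif_area
        return out
    return np.asarray(tissue_areas, float) / aif_area


def compute_rcbf(
    tissue_conc: np.ndarray,
    aif: ArterialInput,
    r_trunc: float = 0.2,
    tr_s: float | None = None,
    time_s: np.ndarray | None = None,
    use_fitted_aif: bool = True,
) -> np.ndarray:
    """rCBF by truncated-SVD deconvolution of tissue curves with the AIF.

    The AIF (its gamma-variate fit by default, the raw averaged curve
    otherwise) is cast into a lower-triangular Toeplitz convolution matrix
    scaled by the frame spacing; singular values below
    ``r_trunc * s_max`` are zeroed; the residue function is the
    pseudo-inverse applied to each tissue curve and rCBF its maximum,
    floored at 0.

    ``tissue_conc`` is (..., T) on the same time grid as the AIF.
    """
    t_aif = aif.curve.time_s
    if time_s is not None and (
        time_s.shape != t_aif.shape or not np.allclose(time_s, t_aif)
    ):
        raise ValueError("tissue and AIF time grids differ")
    tissue_conc = np.asarray(tissue_conc, float)
    if tissue_conc.shape[-1] != t_aif.size:
        raise ValueError("tissue and AIF time grids differ")
    if tr_s is None:
        tr_s = float(np.median(np.diff(t_aif)))
    ca = aif.fit(t_aif) if use_fitted_aif else aif.curve.conc
    n = ca.size
    A = tr_s * np.tril(
        np.fromfunction(lambda i, j: ca[(i - j).astype(int)], (n, n), dtype=int)
    )
    u, s, vt = np.linalg.svd(A)
    s_inv = np.where(s >= r_trunc * s.max(), 1.0 / np.where(s > 0, s, 1.0), 0.0)
    pinv = (vt.T * s_inv) @ u.T
    residue = tissue_conc @ pinv.T  # (..., T)
    return np.clip(residue.max(axis=-1), 0.0, None)


def process_dsc(
    series: DynamicSeries,
    baseline_frames: int | None = None,
    r_trunc: float = 0.2,
    aif_voxels: int = 10,
    mask_frac: float = 0.2,
    aif_restrict: np.ndarray | None = None,
    spacing_mm: tuple[float, float, float] | None = None,
) -> PerfusionMaps:
    """Full DSC chain: masking, concentration conversion, voxelwise bolus
    timing and gamma-variate fitting, AIF selection, rCBV and rCBF maps.

    rCBV uses fitted tissue curves (first-pass area, recirculation-free);
    rCBF deconvolves the raw tissue concentration curves with the fitted
    AIF.  Voxels without a detectable bolus or a converged fit are NaN in
    the rCBV map; counts are reported in ``n_failed_fits``.
    """
    bl = series.meta.baseline_frames if baseline_frames is None else baseline_frames
    mask = make_brain_mask(series, mask_frac)
    conc = signal_to_concentration(series, bl)
    bat_idx, ttp_idx, ok = _bat_map(conc.conc, conc.time_s, bl, mask & conc.valid)

    shape = series.values.shape[:3]
    areas = np.full(shape, np.nan)
    fits: dict[tuple[int, int, int], GammaVariateFit] = {}
    n_failed = 0
    for v in map(tuple, np.argwhere(mask & conc.valid & ok)):
        timing = BolusTiming(
            bat_s=float(conc.time_s[bat_idx[v]]),
            ttp_s=float(conc.time_s[ttp_idx[v]]),
            fit_rss=0.0,
        )
        try:
            f = fit_gamma_variate(conc.curve(*v), timing)
        except ValueError:
            n_failed += 1
            continue
        if not f.converged:
            n_failed += 1
            continue
        fits[v] = f
        areas[v] = gamma_area(f)

    aif = select_aif(
        conc, mask, bl, m=aif_voxels, restrict=aif_restrict,
        bat_idx=bat_idx, ttp_idx=ttp_idx, ok=ok, fits=fits,
    )
    rcbv = compute_rcbv_dsc(areas, aif)
    rcbv[~mask] = np.nan

    rcbf = np.full(shape, np.nan)
    tissue_ok = mask & conc.valid
    rcbf[tissue_ok] = compute_rcbf(conc.conc[tissue_ok], aif, r_trunc=r_trunc)

    bat = np.full(shape, np.nan)
    sel = mask & conc.valid & ok
    bat[sel] = conc.time_s[bat_idx[sel]]

    if n_failed:
        warnings.warn(f"{n_failed} voxels excluded: gamma-variate fit failed")
    spacing = spacing_mm or getattr(series, "spacing_mm", (1.0, 1.0, 1.0))
    meta = series.meta
    as_vol = lambda a: VolumeImage(a, spacing, meta)
    return PerfusionMaps(
        rcbv=as_vol(rcbv), rcbf=as_vol(rcbf), bat=as_vol(bat),
        mask=mask, aif=aif, n_failed_fits=n_failed,
    )
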