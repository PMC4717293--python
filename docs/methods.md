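# Methods

`qvasc` quantifies cerebral vascular parameters from contrast-enhanced MRI
of the mouse brain along two complementary routes — bolus tracking and
steady-state relaxometry — and ships a synthetic forward model so the whole
chain can be validated by parameter recovery without any animal data.

## Steady-state relaxometry and the relaxation shift index

An intravascular superparamagnetic iron-oxide tracer at steady state
shortens the transverse relaxation times of tissue water in proportion to
the local vascular volume. From pre/post-contrast spin-echo (SE) and
gradient-echo (GE) magnitude images the rate changes are estimated as
two-point log-ratios,

    dR2  = (1/TE_SE) ln(S_pre / S_post),
    dR2* = (1/TE_GE) ln(S*_pre / S*_post),

with negative values (pure noise) clipped to zero before any further use,
and voxels with nonpositive signal masked to NaN (never zero). dR2 is
sensitive mainly to capillary-scale vessels while dR2* senses all vessel
sizes; dR2* in arbitrary units is therefore also exported as a
steady-state relative blood volume estimate, rCBV(dR2*). The
static-dephasing scaling of the two rates with vessel radius motivates the
relaxation shift index

    Q = dR2 / (dR2*)^(2/3),

which cancels the tracer dose and blood-volume dependence and tracks
microvessel density; density is reported as N ~= Q^3 * 329, in the unit
that convention prints (s/mm^2). The dose-invariance
(c^(2/3) dR2, c dR2*) -> Q is verified as a property test.

The GE slab is acquired on a finer grid than the SE slices; dR2* is
computed and clipped on its native grid, moved to the SE grid by
cubic-spline interpolation, and re-clipped (interpolation can undershoot
near edges). NaN-masked voxels are handled by mask-weighted
interpolation: value*weight and weight are interpolated separately and
renormalised, and a target voxel whose interpolated weight falls below 0.5
is masked — a plain spline prefilter would otherwise propagate a single
NaN through the whole volume. Spline boundary ringing decays by roughly a
factor 14 per voxel from any sharp edge, so maps are exact in the interior
and perturbed only in a 1-2 voxel rim at tissue boundaries. Voxels whose
dR2* falls below epsilon = 1e-6 1/s after clipping get Q = 0; in-vivo
data rarely contain exact zeros, but synthetic data do, hence the guard.

## Bolus tracking (DSC)

During the first pass of the tracer bolus, dynamic EPI signal is converted
to a concentration-proportional rate change

    C(t) ~ dR2*(t) = -(k/TE) ln(S(t)/S0),

with S0 the pre-bolus baseline mean and the proportionality factor k fixed
at 1: only relative quantities are reported, and k cancels in rCBV and
scales rCBF linearly. Brain masking keeps voxels whose baseline mean
exceeds 20% of the robust (99th percentile) maximum.

**Bolus arrival (BAT).** Per voxel, a piecewise linear-quadratic
continuous regression y = a0 + a1 t + a2 (t - t_b)^2_+ is fitted for every
candidate breakpoint t_b, and the breakpoint minimising the residual sum
of squares is the arrival time (ties to the earliest frame). The fit
window runs from the first frame to the frame where the curve first
reaches half its peak: fitted through the peak, the quadratic chases the
peak curvature and places the breakpoint several frames early; restricted
to the early rise it recovers a known onset within one frame (400 ms).
Curves whose maximum stays within two baseline standard deviations of the
baseline mean are rejected as bolus-free.

**First-pass model.** A gamma-variate
C(t) = A (t - t0)^alpha exp(-(t - t0)/beta) is least-squares fitted on the
window [BAT, BAT + 2.5 (TTP - BAT)] — the bracket is read with this sign,
the only reading that gives a positive span — initialised by
log-linearisation and refined with bounded Levenberg-Marquardt using the
analytic Jacobian. Non-converged voxels are flagged and excluded from
maps. The first-pass area has the closed form
A beta^(alpha+1) Gamma(alpha+1), verified against adaptive quadrature to
1e-6 over alpha in [0.5, 6], beta in [0.2, 5].

**Arterial input (AIF).** Candidates are masked voxels with a detected
bolus and a converged, positive-area gamma fit. Each is scored by an
artery-likelihood z(peak) + z(1/FWHM) + z(-BAT) — tall, narrow, early —
where peak and FWHM are taken from the fitted curve (raw noise spikes fake
narrow widths) and the z-scores are robust (median/MAD), because ~95% of
candidates are tissue voxels whose fitted-width distribution is heavy-
tailed and would swamp a moment-based scale. The m = 10 highest-scoring
curves are averaged and refitted. On phantoms this selects >= 80%
genuinely arterial voxels even when the search runs over the whole brain;
pipeline runs restrict the search to the arterial ROI label (the CLI's
`--aif-roi`), which is known by construction in a simulated study.

**rCBV and rCBF.** rCBV is the ratio of the fitted tissue first-pass area
to the AIF area. rCBF comes from deconvolution: the fitted AIF is cast
into a lower-triangular Toeplitz convolution matrix scaled by the frame
spacing, singular values below r_trunc = 0.2 of the maximum are zeroed,
and the residue function r(t) = CBF * R(t) is the pseudo-inverse applied
to the raw tissue curve; rCBF is max_t r(t), floored at zero. Increasing
r_trunc can only shrink the residue (tested as a monotonicity property).

**Known bias of truncated SVD.** At the 0.2 truncation threshold only a
few percent of the singular values survive, and the reconstructed residue
peak is attenuated by a factor ~0.5-0.7 depending on the mean transit
time (shorter MTT, sharper residue, stronger attenuation). This is an
inherent property of the method at this threshold, not an implementation
artefact: it persists when the tissue curve is generated with the exact
discrete convolution operator. Consequently absolute CBF recovery is
~0.5x truth under the default conditions; the attenuation is uniform
across regions sharing an MTT, so *relative* CBF — the quantity the
method reports — and between-group percent changes are preserved. The
delta-AIF identity (residue peak recovered within 5%) holds at low
truncation (r_trunc = 0.01).

## The synthetic cohort

The phantom is an ellipsoidal "brain" on a rectangular grid, partitioned
into six equal-size slabs standing in for the olfactory bulb, cortex,
striatum, hippocampus, thalamus and cerebellum, plus a thin central
artery column (>= 50 voxels per label, artery radius chosen as the
smallest that reaches 50). Steady-state data are generated as the exact
inverse of the rate estimators: S_post = S_pre exp(-TE dR2_true), with
the GE pair on a 2x finer in-plane grid to exercise resampling. Dynamic
data follow the indicator-dilution model C_t = CBF (C_a (x) R) with
exponential residue R(t) = exp(-t/MTT), MTT = CBV/CBF, evaluated on a
20x oversampled time grid and sampled at the frame times, so the
deconvolution is never tested against its own discretisation. Artery
voxels carry the gamma-variate input directly. Noise is additive
Gaussian on the magnitude signal (a high-SNR approximation appropriate
for cryogenic-coil mouse data; a Rician option exists behind
`noise_model="rician"`).

Default acquisition constants: GE TE 5.5 ms, SE TE 30 ms, dynamic EPI TE
10 ms at TR 0.4 s, 300 frames with a 30 s (75-frame) pre-bolus baseline.
Default truths, chosen once as field-realistic values (the study reports
no absolute baselines for these): gray-matter Q 0.63 s^(-1/3) (the
reported control-group mean), steady-state dR2* 20 1/s, relative CBV 0.3
a.u., MTT 1.5 s (hence relative CBF 0.2 a.u./s), arterial input with
shape alpha = 3, scale beta = 1.5 s, onset at the end of the baseline and
first-pass peak ~50 1/s, noise 2.5% of baseline signal (SNR 40),
per-animal lognormal biological scatter 5%.

Genotype effects are multiplicative factors on the truth parameter whose
recovered contrast is of interest, stored per interpretation because the
quantities are nonlinearly related (N ~ Q^3; steady-state and dynamic
blood volume are distinct read-outs): a Q-level factor; a dR2*-level
factor for rCBV(dR2*); a pure-volume factor for rCBV(DSC) (which
lengthens MTT); and a flow factor modelling vascular rarefaction, which
scales CBF and CBV together at preserved MTT — the physiologically
standard picture for capillary loss, and the only convention under which
the MTT-dependent deconvolution attenuation cancels exactly between
groups. The default 24-month effect table: Q factors 0.89 / 0.85 / 0.74 /
0.80 / 1.00 / 0.81 (OB / CC / ST / HC / TH / CB), cerebellar CBF factor
0.65, cortical CBV(DSC) factor 1.21 and cortical dR2* factor 1.25.

Default problem sizes are chosen so a full two-modality cohort runs on a
single CPU in minutes: steady-state grid 48 x 48 x 8 (GE 96 x 96 x 8),
dynamic grid 24 x 24 x 6 x 300. Everything is reproducible bit-for-bit
from the cohort seed; each animal consumes an independent spawned RNG
stream.

What the generator does *not* emulate: anatomy, partial-volume and
susceptibility artefacts, recirculation of the bolus, tracer leakage,
motion, slice gaps, or the microvascular network physics behind the
2/3-exponent (which is assumed, not simulated). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every property of in-vivo data.

## Region statistics

Each animal contributes one summary value per region and map; the ROI
statistic is the voxel **median** by default. The median is preferred
here because
voxelwise Q (a ratio with a noisy 2/3-power denominator) and rCBF (an
extremum statistic) have right-skewed finite-SNR distributions — at SNR
40 region means of Q overshoot truth by 6-8% while medians are within 1%.
The mean is available via `statistic="mean"`.

Group contrasts are percent changes of the group means of these
per-animal summaries, with a two-sided label-permutation p-value
(p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm), n_perm >= 1000,
seeded). With one value per animal and region, the genotype contrast of a
mixed-effects model reduces to this two-sample comparison; the tidy
summary table is exported so a full mixed model can be fitted in external
statistics software if multiple age groups are pooled. No
multiple-testing correction is applied, matching the original analysis.
Under null cohorts the test's false-positive rate at alpha = 0.05 is
calibrated (checked against the binomial interval over 200 replicates).

## Statistical precision of cohort contrasts

With 5% per-animal scatter and groups of 14 and 8, a group percent-change
contrast has a sampling standard deviation of ~3 percentage points; the
pipeline itself tracks any given cohort's realised contrast within ~1
point. Recovered contrasts for a single seeded cohort therefore scatter
by a few points around the configured effect sizes — a property of the
emulated study design, not of the estimators.

## Numerical choices and degenerate inputs

* Machine-epsilon clamping of nonpositive dynamic signal before the log;
  affected voxels are counted.
* Post-contrast steady-state signal is floored at machine epsilon with a
  warning if TE * dR2 would underflow.
* Gamma fits: bounds A >= 0, alpha in [0.05, 50], beta in [0.01, 100] s,
  onset within 10 frames before BAT; at most 300 function evaluations;
  failures are flagged, never silently extrapolated.
* Breakpoint ties in the BAT search go to the earliest frame.
* Identical AIF candidate curves (degenerate tie) yield all-zero robust
  z-scores; any selection is then valid and the averaged curve equals the
  common curve.
* All emitted maps are NaN outside the mask and nonnegative inside.

## Known limitations

* Absolute CBF is attenuated by the 0.2-threshold truncated SVD (see
  above); only relative flow is meaningful, as the rCBF name states.
* No leakage or partial-volume correction of the AIF; no motion
  correction; no block-circulant (delay-insensitive) deconvolution.
* Two-point single-TE relaxometry only; no multi-echo fitting.
* The artery column is thin by design, so its own steady-state Q value is
  partial-volume dominated; it is excluded from region reports.
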