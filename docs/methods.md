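# Methods

## Flow quantification model

The package operates on one 2-D acquisition plane through the ascending (and
optionally descending) aorta: per cardiac phase, a signed through-plane
velocity field v(x, y) in cm/s and a boolean lumen mask. Acquisition is
assumed R-wave-triggered with retrospective gating, so frames are uniformly
spaced over the RR interval and systole onset is taken at frame 0. Stored
velocities keep the acquisition sign; each region of interest declares a
`forward_sign` (+1 ascending, −1 descending by default) because the two
vessels have opposite through-plane directions in a single plane.

**Flow rates.** Within the mask, pixels whose signed velocity agrees with
`forward_sign` form the forward component, the rest the retrograde
component: per frame, forward = Σ max(s·v, 0)·a and retro = Σ max(−s·v, 0)·a
with a the pixel area in cm² (cm/s × cm² = mL/s). Volumes use the rectangle
rule with Δt = RR/n_frames, the frame-based convention of retrospectively
gated PC cine; a trapezoid option exists behind `rule="trapezoid"` but is
not the default, so rates and volumes are reproducible across tools that
treat each frame as representative of its frame interval.

**Landmarks.** Peak systole is the frame of maximal net rate. End systole is
the first linearly interpolated downward zero crossing of the net rate after
the peak; the end-systolic frame index is the last frame at or before that
crossing. Systole = frames [0, end]; late systole = [peak, end]; diastole is
the remainder. A curve with no post-peak crossing raises an error in strict
mode; lenient mode substitutes the post-peak minimum with a warning.

**Flow displacement.** FD is the distance between the unweighted mask
centroid and the forward-velocity-weighted centroid, in physical mm using
the (possibly anisotropic) pixel spacing, normalised per frame to the
equivalent lumen diameter D_eq = 2√(area/π) and reported in percent.
Normalising to D_eq is the dominant convention in the jet-eccentricity
literature; a radius variant is available via `normalization="radius"`.
Frames with no forward pixels have undefined FD and are treated as gated.

**Rotational angle and speed.** The jet angle is the direction of the
centroid offset: 0° at image "up" (−y), increasing clockwise on screen,
range (−180°, 180°]. Only relative angles enter any reported metric, so the
zero reference is pure convention; the synthetic generator shares it through
one pair of helper functions. Early-systolic aortic flow is mostly laminar, so
frames with FD ≤ 12 % carry no meaningful direction: their RA is set to 0
for plotting but they are excluded (not zero-filled) from ΔRA and RS. ΔRA is
RA at end systole minus RA at the stabilisation point — operationalised as
the first frame after peak systole whose frame-to-frame RA change stays
below 10°/frame for two consecutive frame pairs (both thresholds
configurable); angular differences always take the minimal wrap. RS between
consecutive ungated frames is wrap(ΔRA)/(360·Δt) in rev/s, and RSls_avg
averages eligible pairs from peak to end systole.

**sFRR, RAC, PWV.** sFRR = 100·SRF/SFF with both volumes integrated over the
systolic window; it is reported as missing when SFF = 0. RAC uses the
frame-wise pixel-count areas. PWV divides the arch centerline length
(polyline arc length, mm → m) by the transit time between the half-maximum
crossings of the ascending and descending systolic upslopes, each linearly
interpolated between the bracketing frames. The half-maximum is taken on the
forward rate (robust to small retrograde components; `which="net"`
switches), the search keeps the last upward crossing before the peak so an
early noise blip cannot capture the landmark, and peaks below 5 % prominence
are rejected.

## Cohort statistics

Stepwise OLS uses forward selection with backward elimination at
p_enter = 0.05 / p_remove = 0.10 (configurable), preceded by a univariate
screen at p < 0.05; ties break on the smaller p-value then alphabetically,
making selection deterministic. A condition-number guard rejects
(near-)collinear candidate sets. The composite PVO2 model
(20.729 + 0.443·FFi − 0.261·FDs_avg − 0.172·LVEF) is exposed as a fixed
predictor for CMR-derived PVO2. ROC analysis is the empirical curve with
tie-halved concordance AUC, Youden-threshold selection at midpoints between
adjacent scores (ties resolved toward higher specificity), and a normal
approximation CI using the Hanley–McNeil standard error. The nested logistic
likelihood-ratio test compares converged statsmodels fits; a singular
Hessian from collinear terms falls back to BFGS, and genuine separation
raises a distinct error. Agreement indices: ICC is two-way mixed,
consistency, average measures, ICC = (MS_between − MS_error)/MS_between with
F-bound CIs; the paired CV is 100·√(Σd²/2n) / (Σ(m1+m2)/2n) — the
within-subject SD over the grand mean — reported as missing when the grand
mean is near zero; Bland–Altman limits are mean ± 1.96·SD of the paired
differences. No multiple-comparison adjustment is applied anywhere. One MET
is 3.5 mL O2/kg/min; exercise-capacity strata are high (PVO2 ≤ 14), low/
intermediate (14 < PVO2 ≤ 20) and normal (> 20 mL/kg/min), boundaries
inclusive as written.

## Synthetic data: what it emulates and what it does not

The velocity generator builds, per frame, a rasterised-disc lumen whose
radius pulses with the systolic shape (defaults 13.35 → 15.0 mm, areas
5.6 → 7.1 cm², RAC ≈ 26 %), a truncated-Gaussian forward jet (σ = 0.25·r)
placed at a requested offset — a fraction of that frame's D_eq along a
requested angle — and scaled so its pixel sum equals the sin² waveform's
forward rate exactly, a retrograde crescent at the lumen edge opposite the
jet (disjoint from the forward region, scaled to the frame's retrograde
rate exactly), a small negative diastolic baseline (−2 mL/s) so the net
curve crosses zero at end systole, and optional Gaussian velocity noise
inside the lumen. Because forward and retrograde regions are disjoint and
exactly scaled, integrating the noise-free fields reproduces the imposed
curves to float precision, and every imposed quantity is recorded in a
`GroundTruth`. Defaults describe a healthy adult: RR 820 ms, 30 frames,
systole 35 % of RR, systolic forward volume ≈ 72 mL (peak 500 mL/s).

The Gaussian-jet centre is the FD ground truth; mask-edge truncation biases
the measured centroid toward the centre by a few tenths of a percentage
point at 0.20·D_eq offsets, which is inside every stated tolerance. The
cohort generator draws independent normal covariates (FFi 42.7 ± 6.5 mL/m²,
FDs_avg 17 ± 6 %, LVEF 63 ± 7 %), sets PVO2 from the composite model plus
6 mL/kg/min noise (R² ≈ 0.25, ~7 % of subjects in the high-risk stratum) and
adds decoy covariates (age, an age-correlated aortic area, RAC, pure noise)
for selection tests.

Not emulated: real velocity-encoding artefacts (aliasing, eddy-current
background phase), segmentation error (masks are exact discs), intra-frame
motion, non-circular lumen shapes, correlated covariates in the cohort, and
any genuine haemodynamics (no Navier–Stokes). Passing recovery tests
therefore demonstrates that the *measurement pipeline* is correct and
well-conditioned, not that it is robust to acquisition artefacts.

## Numerical choices and problem sizes

- Grids are 96×96 at 0.5 mm pixels; FD recovery is accurate to ≲0.5
  percentage points there and exact against a per-pixel oracle by
  construction.
- The PWV harness uses 60 frames (13.7 ms frames): transit-time methods need
  temporal resolution comparable to the transit being measured (20 ms), and
  at 30 frames the linear interpolation of the half-maximum crossing leaves
  a ~2 % velocity error, at 60 frames ~1 %.
- Rotation-recovery runs impose the rotation over the whole cycle so the
  imposed rate is uniform across every measured frame pair; rotation started
  mid-window would make the first pair average the moving and stationary
  segments.
- Stepwise recovery uses 200 cohorts of n = 169. At the generator's noise
  level the LVEF partial effect has ≈ 0.74 power at p_enter = 0.05 (FDs_avg
  ≈ 0.92), so exact recovery of the three-term model occurs in roughly half
  of cohorts rather than nearly all; conditional on selection, mean
  coefficients recover the generating values. This is a property of the
  stated effect sizes and noise, not of the selection implementation, and is
  reported as measured.
- Angle wrap uses the (−180°, 180°] branch everywhere; ΔRA/RS never see a
  raw 360° jump.
- Degenerate inputs are reported as missing rather than coerced: sFRR with
  zero SFF, CV with near-zero mean, ΔRA with no stabilisation point, RS with
  no eligible pair.

## Known limitations

- The FD "vessel size" normalisation and the RA zero reference are
  conventions chosen here (equivalent diameter; image-up zero, clockwise);
  other software may normalise to a measured diameter or use a different
  angular origin, shifting absolute FD/RA values but not the relative
  quantities the summary metrics use.
- Systole is assumed to start at frame 0; an upslope-foot onset would
  slightly change FDs_avg and SFF and is configurable only through the
  landmark windows.
- The rectangle rule under-integrates rapidly changing curves at coarse
  temporal resolution (bounded by ~1 % at the default 30 frames).
- Logistic LRT p-values are asymptotic; small-sample exactness is not
  attempted.
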