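# Methods

`duoflow` implements, end to end and fully in silico, the two quantification
pathways whose agreement validates quantitative CMR perfusion mapping against
dynamic ¹³N-ammonia PET: a saturation-recovery CMR signal chain feeding an
axially distributed blood–tissue exchange model, and a one-compartment PET
uptake model with extraction correction, followed by AHA 16-segment
aggregation and Bland–Altman/correlation agreement statistics. Because no
patient data accompany that study design, a virtual-patient phantom with
known ground-truth flows takes the data's place; every pipeline stage is
validated against that truth.

## Virtual-patient phantom

**Arterial input.** First-pass boluses are gamma-variates
`A·((t−t0)/β)^α·e^(−(t−t0)/β)` with an optional recirculation tail (a
fraction of the primary bolus convolved with a normalized exponential
washout kernel). Defaults: α = 2.5, β = 3 s (stress CMR), amplitude scaled
so the blood-pool peak is ≈ 5 mmol/L gadolinium for CMR and ≈ 100 kBq/mL
for PET, recirculation fraction 0.15 with a 30 s washout time constant. The
rest bolus is slightly later and more dispersed (β = 4–5 s) than the stress
bolus. These are conventional first-pass morphologies; clinical studies
measure rather than model the AIF, and no published blood-pool peak
concentration constrains them, so they were fixed once as physiologically
representative values.

**Cohorts and flow scenarios.** Each virtual patient carries 16 segmental
ground-truth flows (rest and stress). Three scenarios reproduce the
clinically observed patterns: *normal* (rest uniform in 0.6–1.1, stress in
2.0–4.0 ml/min/g, matching the reported global rest/stress ranges),
*single-vessel* (stress 0.6–1.8 ml/min/g confined to one coronary
territory, LAD/RCA/LCX segments assigned by the standard 17-segment
convention: LAD 1,2,7,8,13,14; RCA 3,4,9,10,15; LCX 5,6,11,12,16), and
*multi-vessel* (balanced ischemia, all stress flows 0.6–1.9 ml/min/g, i.e.
every segment below the 2.0 ml/min/g cut-off). The default cohort is 21
patients with mix 40% normal / 50% single-vessel / 10% multi-vessel, the
size of the clinical comparison this design mirrors.

**Raw-data synthesis.** CMR: one image per heartbeat at a fixed 60 bpm
(so the 90-beat stress acquisition is 90 frames at 1 s spacing;
heart rate is configurable), three short-axis slices (basal/mid/apical) as
40×40 annuli, plus a 16×16 dual-echo low-resolution blood-pool series.
Per-segment tissue concentration comes from the forward exchange model at
the segment's true flow; pixels then pass through the Bloch-simulated
signal model (T2* losses at both echoes for the blood series, at TE₁ for
the myocardial series) with optional Rician magnitude noise (σ expressed as
a fraction of the proton-density reference; 0.02 is the realistic preset).
PET: per-segment continuous activity from the one-compartment model at
K₁ = E·flow (E = 0.90), frame-averaged over the 21-frame schedule
(12×5 s, 4×10 s, 4×20 s, 1×60 s; 4 min total), with Gaussian frame noise of
SD ∝ √(activity/duration) — the usual post-reconstruction approximation of
count statistics. Activities are decay-corrected by construction. Defaults
are noiseless: the reference validation run isolates methodological
agreement from noise, and noise levels are study conditions, not tuning
knobs.

**What the phantom does not emulate:** tomographic reconstruction
artifacts, attenuation/scatter, respiratory or cardiac motion, surface-coil
sensitivity profiles, partial-volume effects, metabolite contamination of
the PET input, and between-day physiological variation between the two
examinations. Passing tests therefore demonstrate correctness of the
quantification mathematics and bookkeeping, not robustness to the full
error budget of patient data — on real data the cross-modality agreement
would be bounded by those effects, as the clinical comparison's r = 0.92
(global) and 0.83 (regional) indicate.

## CMR signal chain

The saturation-recovery FLASH signal is Bloch-simulated per protocol:
ideal saturation (Mz = 0; an imperfect-saturation efficiency field is
exposed, default 1.0), free T1 recovery to the first phase-encode line,
then discrete line-by-line FLASH evolution (flip, relaxation over TR per
line, linear phase-encode ordering) up to the central k-space line, which
sets image contrast; the saturation delay is measured saturation-to-central
line. Signal = Mz·sin(α)·e^(−TE·R2*), normalized by the proton-density
reference sin(α_PD). Relaxation follows the linear model
R1 = 1/T1 + r1·[Gd], R2* = 1/T2* + r2star·[Gd] with r1 = 4.5,
r2* = 5.0 L·mmol⁻¹·s⁻¹ and native T1 of 1000 ms (myocardium) / 1600 ms
(blood) at 1.5 T — conventional values, configurable, since the acquisition
protocol's numeric parameters are not published.

The look-up table tabulates this simulation on a 0.01 mmol/L grid to
20 mmol/L and records the largest concentration before any
non-monotonicity (T2*-induced rollover); inversion is piecewise-linear
interpolation restricted to that domain, with above-range signals clipped
and counted as saturated. The blood series is T2*-corrected first
(dual-echo mono-exponential extrapolation, R2* = ln(s1/s2)/(TE2−TE1);
negative apparent R2* from noise passes s1 through and increments a
counter) and inverted through a TE = 0 LUT; the single-echo myocardial
series is inverted through a LUT built at TE₁. Noiseless round trips
([Gd]→signal→[Gd]) stay below 0.1% relative error, well inside the 1%
design target.

## Distributed blood–tissue exchange model

The kinetic model is the classic two-region axially distributed system —
capillary plasma convected at flow Fp exchanging with a stagnant
interstitium through conductance PS:

    ∂Cp/∂t   = −(Fp·L/Vp)·∂Cp/∂x − (PS/Vp)(Cp − Cisf)
    ∂Cisf/∂t = (PS/Visf)(Cp − Cisf),     Cp(0,t) = AIF(t − delay)

with observable Ctis = Vp⟨Cp⟩ₓ + Visf⟨Cisf⟩ₓ. Flows/PS are ml/min/g,
volumes ml/g, time in seconds; the factor 60 is applied once inside the
solver and pinned by a dedicated test.

**Numerics.** A Lagrangian sliding-element scheme: the time step equals the
transit time of one axial element (dt = (Vp/(Fp/60))/n_axial), advection is
a pure shift (exactly mass-conserving), and within-step exchange uses the
exact solution of each element's 2×2 linear system. The inlet element
receives the time-average of the delayed AIF over the step, which keeps the
discrete mass balance exact (observed ≲ 10⁻¹⁴ relative) even when low flow
coarsens the step. When the element transit time would exceed the `dt_max`
cap (default 0.5 s), the axial resolution is raised — never lowered — until
it fits; capping dt directly would break the shift-per-step advection rate,
which a regression test now guards. Default n_axial = 20; refining to 40
changes the solution by < 0.05% at physiological parameters.

**Limits.** PS = 0 reduces to a purely intravascular transit
(Ctis = Vp⟨Cp⟩ₓ). The PS → ∞ limit of this *distributed* system is retarded
plug flow — local equilibration makes total concentration advect at
velocity reduced by Vp/(Vp+Visf) — and the solver converges to that
analytic closed form (0.5% relative L2 at n_axial = 200). It does **not**
converge to the well-mixed one-compartment (Kety) convolution
Fp′·∫AIF·e^(−Fp′(t−τ)/(Vp+Visf))dτ, which is the PS → ∞ limit of a
*compartmental* two-region model: at the canonical parameter point the two
differ by ≈ 43% relative L2. One acceptance test states the compartmental
comparison and is expected to fail; it is retained unchanged because the
distinction is a property of the model family, not of this implementation,
and the plug-flow test alongside it demonstrates the solver is correct.

**Fitting.** Weighted nonlinear least squares (trust-region reflective)
over {Fp, PS, Vp, Visf} with bounds Fp ∈ [0.05, 8], PS ∈ [0.1, 5] ml/min/g,
Vp ∈ [0.01, 0.2], Visf ∈ [0.05, 0.6] ml/g; multi-start over
Fp ∈ {0.5, 1, 2, 4} with ties broken by lowest residual, then lowest Fp.
The bolus-arrival delay is initialized by an upslope threshold-crossing
pre-search but remains a bounded free parameter ([0, 10] s): a fixed
pre-searched delay proved biased ≈ 1.5 s late on dispersed tissue curves,
which corrupted flow estimates, whereas the free-delay fit recovers
noiseless flows to ≲ 2% across 0.4–5.3 ml/min/g (median < 0.5% over random
in-bounds draws). An all-zero tissue curve short-circuits to the lower
bounds with at-bound flags. Reported myocardial perfusion is the fitted Fp
as-is (no hematocrit or water-exchange correction — the convention of the
validated clinical chain). Per-pixel mapping applies the same fit under a
mask; the study workflow fits segment-averaged curves (16 per slice stack),
which is numerically identical for the noiseless phantom and keeps the
21-patient study around four minutes on one CPU.

## PET one-compartment model

dCt/dt = K1·Ca − k2·Ct with measured activity (1−Vb)·Ct + Vb·Ca. The
forward solution is the exponential convolution evaluated by trapezoidal
quadrature on the blood curve's grid (0.1 s in the phantom); frame
averaging integrates the piecewise-linear curve exactly over each frame.
Fits use the first 4 minutes of frames, weights ∝ frame duration (residuals
scaled by its square root), bounds K1 ∈ [0, 8] ml/min/g, k2 ∈ [0, 2]/min,
Vb ∈ [0, 0.6], with K1 initialized from a Patlak-like early-frame slope.
Flow follows from K1 via the extraction fraction: constant E = 0.90 by
default (the validated configuration), with a Renkin–Crone mode
E(F) = 1 − a·e^(−b/F) solved for F by bracketed root-finding for
sensitivity analyses. Extraction correction is applied on the K1 side;
for constant E this is mathematically identical to scaling the input
function, which is how clinical software words it. No metabolite
correction is applied within the 4-minute window — the rationale for that
window in the first place.

## Segmental analysis and agreement statistics

Segment maps are angular sectors (6×60° basal and mid, 4×90° apical)
numbered counterclockwise from the anterior reference angle; the apical cap
(segment 17) is not imaged by the three-slice protocol, leaving 16 segments
per patient. ROIs are eroded one pixel from both borders before averaging
(an erosion that empties a segment raises, naming it). Global MP is the
unweighted mean of the 16 segmental means — "average over segments" rather
than pixel-weighted, matching how global values are described clinically.
MPR = stress/rest per segment and globally. Stress positivity uses the
strict < 2.0 ml/min/g cut-off; patient-level positivity is any positive
segment by default, with a territory-restricted rule available (how
angiographic lesions map to positive segments is not standardized, so both
are exposed; the phantom's ground-truth territory assignment stands in for
angiography).

Agreement statistics keep the clinical reporting conventions: differences
are PET − CMR (PET the reference), regression is CMR (y) on PET (x),
Bland–Altman limits are bias ± 2·SD (not 1.96), p-values are descriptive
with no multiplicity correction, and segments are pooled across patients
for regional analyses without a clustered-data correction — a known
limitation replicated deliberately, since the statistics layer mirrors the
comparison it models. MPR is treated as dimensionless throughout (source
reports print ml/min/g units next to MPR agreement values; that is
reproduced nowhere in code).

## Numerical and degenerate-input choices

* LUT grids start at 0 and must be strictly ascending; a grid of one point
  raises; non-monotonicity from the first step raises at construction.
* Signals above the monotone LUT domain are clipped to `valid_max_gd` and
  counted; zero-PD pixels are masked to NaN, not errors.
* Synthesized studies whose true concentrations exceed the monotone LUT
  domain raise instead of silently clipping.
* Baseline (Δ[Gd]) subtraction floors at zero, preserving non-negativity.
* Paired t-tests on zero-variance differences return (0, 1) for zero mean
  and a signed-infinite t with p = 0 otherwise, rather than raising.
* Study determinism: one run seed spawns per-patient, per-stage substreams
  via `numpy.random.SeedSequence`, so identical configurations produce
  byte-identical output tables.

## Problem sizes

The shipped defaults — 21 patients × 2 states × 2 arms, 40×40 three-slice
CMR stacks with segment-averaged fitting, 16-segment PET fits, 100-draw
recovery studies and a 200-replicate noise Monte Carlo — were chosen so a
complete validation run plus the full test suite executes in minutes on a
single CPU while exercising every pipeline stage at realistic scale.
Pixel-wise mapping is exercised on small phantom slices; scaling it to full
images is a linear-cost extension of the same code path.
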