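# Methods

`coralmound` implements an integrated paleoenvironmental reconstruction
workflow for cold-water coral (CWC) mound sediment cores of the kind drilled
on the Norwegian shelf: U-series dating of coral fragments with closed-system
screening, cluster-based aggradation chronology, CT-based coral-content
quantification, and a foraminiferal Mg/Ca + δ¹⁸O proxy chain yielding
bottom-water temperature (BWT), seawater δ¹⁸O, potential density σ_Θ and two
independent salinity estimates, all with propagated 2 SD uncertainties.

## Seawater equation of state (`eos80`)

Density follows the International Equation of State of Seawater 1980
(UNESCO 1983 polynomials): a one-atmosphere polynomial in (S, T) plus a
secant-bulk-modulus pressure correction. Potential temperature integrates
the adiabatic lapse-rate polynomial with the classic single 4th-order
Runge–Kutta step; σ_Θ is the density anomaly of (S, θ) at 0 dbar. Salinity
is recovered from (σ_Θ, T, p) by Brent root finding on S ∈ [0, 42] (unique
by haline monotonicity), to |ΔS| < 10⁻⁶ g/kg.

Numerical choices:

* Validity envelope 0 ≤ S ≤ 42, −2 ≤ T ≤ 40 °C, 0 ≤ p ≤ 12000 dbar; inputs
  outside raise an error naming the offending field. The *potential*
  temperature derived internally may fall slightly below −2 °C and is not
  re-validated.
* Pressure from depth uses p ≈ 1.0053 dbar/m; at the ~100 m shelf depths
  relevant here the exact Saunders formula differs negligibly. The adiabatic
  correction itself is < 0.02 °C at 100 m, so in-situ and potential
  temperature are interchangeable at proxy precision.
* ITS-90/IPTS-68 temperature-scale differences (< 0.002 °C here) are ignored.
* EOS-80 rather than TEOS-10 is used deliberately (σ_Θ offsets < 0.01 kg/m³
  at shelf conditions); `eos80.register_crosscheck` accepts any alternative
  formulation for quantified comparison without adding a dependency.

A documented discrepancy: shipboard CTD processing at the study site reports
σ_Θ ≈ 27.4 kg/m³ at S = 35, T = 8.3 °C, ~101 m, whereas EOS-80 gives ≈ 27.23.
This is a sensor/processing difference in the source data; the package does
not force agreement.

## U-series dating (`useries`)

Closed-system ²³⁰Th/U ages solve

d²³⁴U_m = d²³⁴U_i·e^(−λ₂₃₄t),
(²³⁰Th/²³⁸U) = 1 − e^(−λ₂₃₀t) + (d²³⁴U_m/1000)·λ₂₃₀/(λ₂₃₀−λ₂₃₄)·(1 − e^(−(λ₂₃₀−λ₂₃₄)t))

for t by bracketed Brent iteration on [0, 10⁶ yr] (the right-hand side is
strictly increasing in t), with half-lives 75,584 yr (²³⁰Th), 245,620 yr
(²³⁴U) and 4.4683×10⁹ yr (²³⁸U), stored in one overridable place. Ages are
kyr before measurement; no 1950-datum correction is applied (far below the
reported 2 SDs for these young corals). 2 SD age uncertainties come from
seeded Gaussian Monte-Carlo perturbation of the measured ratios (default
n = 2000).

Reliability is screened, not corrected: fragments with ²³²Th ≥ 6 ppb
(boundary inclusive) or back-calculated initial δ²³⁴U outside the modern
seawater band 145 ± 10 ‰ are flagged; no detrital-Th age correction is
attempted. Input tables may carry either δ²³⁴U or the ²³⁴U/²³⁸U activity
ratio (δ = (ratio − 1)·1000).

## Chronology (`chronology`)

Reliable dates, sorted by depth, are partitioned by a two-axis gap rule: a
new cluster starts when the step to the previous date exceeds the age gap OR
the depth gap. Cluster aggradation rate is (depth span)/(age span) in
cm/kyr; singletons report a missing AR. Sedimentation rates linearly
interpolate ages between dated horizons and refuse extrapolation. Age
reversals are flagged where age decreases downcore by more than k·(combined
2 SD), k = 2 by default. The isostatic paleo-depth correction is linear:
age (ka) × uplift rate (mm/yr) = metres of additional water depth.

Defaults are 0.6 kyr and 110 cm. These recover a three-cluster structure
from the six main-text dates of the study core, with the shallow cluster
(12–24 cm, 1.44–1.64 ka) exactly as published. The published boundary
between the two deeper clusters (193 vs 207 cm, 2.89 vs 3.18 ka) is *not*
recoverable by any consecutive-gap rule from the printed dates alone — that
gap (14 cm, 0.29 kyr) is smaller on both axes than gaps inside the published
clusters — and evidently reflects additional unpublished dates and visual
CT-facies judgement. Published per-cluster ARs (67/223/24 cm/kyr) likewise
cannot be reproduced from the printed cluster bounds (which give 60/200/5.3)
and are not targeted. Matrix sediment is assumed coeval with the coral
framework, following evidence from Norwegian mounds; no offset model is
provided.

## CT quantification (`ct`)

Pipeline: non-local-means denoising (strength h defaults to 0.8× the
estimated noise σ; h = 0 is the identity) → single global threshold (Otsu
over VOI intensities unless given absolutely) → removal of 26-connected
components smaller than 5 voxels → watershed on the negated Euclidean
distance transform (computed in physical mm to honour the 0.9 × 0.6 × 0.6 mm
anisotropy) seeded at distance maxima ≥ 2 voxels apart, splitting touching
clasts → per-slice coral volume % of the VOI along array axis 0 (the core
axis), plus mean/max/min summaries. Small-object removal acts on connected
components *before* watershed so that thin clasts are not lost to
over-segmentation into sub-minimum fragments. Slices with empty VOI report
a missing value.

## Proxy chain (`proxies`)

* BWT: inversion of the exponential *L. lobatula* calibration,
  T = ln(Mg/Ca / a)/b with a = 1.24 ± 0.04 mmol/mol, b = 0.069 ± 0.005 /°C.
  The exponential (not linear) form is used throughout; Mg/Ca below the
  pre-exponential or temperatures above the 0–10 °C calibration interval are
  flagged, never rejected.
* Seawater δ¹⁸O: δ¹⁸O_SW = δ¹⁸O_C − (k₀ + k₁T + k₂T²) + 0.27 ‰, with the
  cosmopolitan epibenthic coefficients k₀ = 3.58, k₁ = −0.245,
  k₂ = 0.0011 (overridable constants taken from the cited calibration
  literature); 0.27 ‰ is the VSMOW→VPDB water adjustment. No ice-volume
  correction is applied (negligible over the last 4 kyr).
* σ_Θ from δ¹⁸O_C: regional quadratic 25.64(±0.26) + 1.43(±0.03)·δ +
  0.21(±0.02)·δ² and the global relation 25.7 + 1.0·δ + 0.12·δ²; both are
  monotone over the observed −0.3…1.6 ‰ range (the regional vertex at
  δ = −3.4 ‰ lies far outside it).
* Salinity route A: S = (δ¹⁸O_SW + 8.6493)/0.2547 (full-precision regional
  mixing line; the 0.26/−8.65 version is the same relation rounded).
  Route B: EOS-80 inversion from (BWT, σ_Θ, p). Unattainable densities are
  flagged missing, and the batch never aborts.
* Contamination screen: dataset-level OLS R² of Fe/Ca and Al/Ca against
  Mg/Ca, pass iff both < 0.4. High absolute Fe/Ca alone is tolerated
  (pyrite carries no Mg); optional absolute cutoffs can flag samples.

All "±" values are treated as 2 SD (required for internal consistency with
the stated ±1.1 °C BWT uncertainty, which the delta method reproduces as
2×√(0.268² + 0.234² + 0.409²) ≈ 1.08 °C at Mg/Ca = 2.7). Uncertainty
propagation is available as an analytic delta method and as seeded Gaussian
Monte Carlo (default n = 5000) over (Mg/Ca, δ¹⁸O_C, a, b, c₀, c₁, c₂); the
two agree within 10 % at the default noise levels. Whether the published
±0.25 kg/m³ density uncertainty denotes regression error or propagated
measurement error is unstated in the source; the package reports the
propagated value (≈ 0.28 at the observed mean) and exposes the regression
2 SDs separately in `FitResult`.

## Calibration fitting (`calibration`)

The mixing line is an unweighted OLS of δ¹⁸O_SW on S; the density quadratic
is an unweighted OLS of σ_Θ (computed by EOS-80 where not measured) on
*predicted* equilibrium calcite δ¹⁸O — the forward model of the proxy
chain — since pairing density with measured calcite is not possible in a
water-column dataset. Coefficient 2 SDs are twice the OLS standard errors.
Noise-free closed-loop recovery of both fits is exact to machine precision.

## Synthetic data (`synthetic`)

The generators define the study conditions and record full ground truth:

* Hydrographic profile: monotone-cubic interpolation through three-water-mass
  anchors (surface ≈ 15.3 °C / 27.2 g/kg; a ~1 °C warm inversion near 25–40 m
  peaking at ≈ 16.3 °C; 8.3 °C / 35 g/kg at ~100 m), small seeded noise
  (0.05 °C, 0.02 g/kg 1 SD), σ_Θ by EOS-80 with stable stratification
  enforced by minimally increasing salinity where noise would invert it.
* Downcore series: true salinity is moving-average-smoothed white noise
  spanning 33.6–35.1 g/kg (the modern variability at a nearby living reef);
  true BWT follows the water-mass mixing relation (fresher = warmer) across
  6.4–12.4 °C with ±0.25 °C smooth jitter, clipped to the envelope. Observables
  are generated by the exact forward models with Gaussian noise at the stated
  reproducibilities (0.1 mmol/mol and 0.06 ‰, 2 SD); Fe/Ca and Al/Ca are
  independent noise columns emulating pyrite-bearing but unbiased samples.
  The moving-average covariance (window 9) is an arbitrary smoothness choice;
  nothing downstream depends on it.
* Coral dates: uniform depths inside each cluster box with a linear
  age–depth trend plus dating noise (2 SD 0.04 ka default), so the recorded
  true AR = (depth span)/(age span) is statistically recoverable. (Ages
  drawn uniformly in the box, uncorrelated with depth, would make the
  cluster-extreme AR estimator inconsistent.)
* CT phantom: randomly oriented high-intensity capsules ("branches") added
  inside a cylindrical VOI until a target volume fraction is reached, matrix
  100 / coral 200 intensity, Gaussian noise σ = 10; truth per slice is
  recorded before noise.
* U-series: exact forward ratios with multiplicative noise; ²³²Th drawn
  below the 6 ppb screen.

What the generators do *not* emulate: bioturbation and hiatuses, diagenetic
open-system U exchange, CT beam hardening and liner artefacts, ontogenetic
and vital effects beyond the calibration scatter, and real covariance
between water-mass end members and δ¹⁸O_SW seasonality. Passing recovery
tests therefore demonstrates correctness of the inference chain under its
own stated assumptions, not robustness to these real-world effects.

## Problem sizes

Default test and verification sizes — 200-sample downcore recovery, 120-level
hydrography, 36×48×48 CT phantoms, Monte-Carlo n = 2000–5000 — were chosen as
the smallest sizes at which the targeted statistical statements (≥95 % BWT
recovery, ±2 percentage-point CT recovery, 10 % delta-vs-MC agreement) are
stable across seeds.

## Known limitations

* Published per-cluster ARs, the mean 107 cm/kyr sedimentation rate, the
  downcore reconstruction series and per-slice CT percentages depend on
  unpublished supplementary data (additional dates, per-core thresholds,
  Table S2/S3) and are deliberately not reproduction targets; property-based
  substitutes cover the corresponding code paths.
* The published Mg/Ca extremes (2.35–3.26 mmol/mol) are mutually
  inconsistent with the published BWT extremes (7.1–12.5 °C) under the
  published calibration (they imply 9.3–14.0 °C); likewise δ¹⁸O_C = −0.3 ‰
  implies σ_Θ = 25.23, not the published 25.1. The package computes, it does
  not tune; these inconsistencies are inherited from the source values.
* Conductivity–salinity conversion and a full TEOS-10 Gibbs implementation
  are out of scope.
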