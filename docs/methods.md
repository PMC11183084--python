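# Methods

This note records the models implemented in `strutkit`, their
assumptions, the tunable parameters that matter, and the numerical
choices made where the design was genuinely open.

## Strut geometry

A freshly deposited strut on a flat substrate is modelled as a
parabolic cap, h(x) = H·(1 − (2x/a)²), parameterized by vertex height
H (mm) and width a (mm). Everything downstream uses two derived
scalars: the vertex curvature ρ = 8H/a² (reported as a magnitude; the
profile is concave down) and the cross-section area κ = ⅔·H·a. The
pair (ρ, κ) inverts uniquely: a = (12κ/ρ)^{1/3}, H = ρa²/8. Throughput
is Q = κ·v_p. Geometry is carried in mm/mm²/mm³ end to end — image
measurements are naturally in mm — and converted to SI only where
viscosity is computed. Non-symmetric or non-parabolic cap shapes are
out of scope.

## Pattern-refraction optics

The strut acts as a plano-convex cylindrical lens over a striped
background. We model it paraxially with an orthographic camera: the
across-strut magnification is M = 1/(1 − z_bg·ρ·Δn) with
Δn = n_strut − n_medium, so stripes at true angle θ to the strut axis
appear at tan θ′ = tan θ / M. The inversion
ρ = (1 − tan θ′/tan θ)/(z_bg·Δn) is exact within the model. The flat
bottom interface, the substrate and any other unmodelled surfaces are
folded into the *lumped constant* z_bg·Δn (mm), which is not
identifiable from a single image and must be calibrated once against a
strut of known geometry (`OpticalConfig.lumped_zdn`). Absolute
curvatures are only as good as that calibration; ratios and
per-station comparisons are calibration-free. Defaults: n_strut = 1.34
(dilute hydrogel), n_medium = 1.0, z_bg = 0.5 mm — chosen so that
typical fresh struts (ρ up to ~5 mm⁻¹) stay below the focal condition
z_bg·ρ·Δn = 1, beyond which the background is inverted and the
measurement invalid (rejected explicitly). Curvature is read only at
the vertex, consistent with the parabolic profile; no thick-lens or
perspective effects are modelled.

## Spreading kinetics

Two wetting regimes are implemented. Complete wetting:
a(t) = K·((t+t₀)/1 s)^{1/7}; the time is nondimensionalized by the
unit second so K carries mm. Partial wetting:
a(t) = a_s·(1 − e^{−B(t+t₀)})^{1/7}, saturating at the final width
a_s. The full-form prefactor K = (γ_L·18·7·κ³/(λη))^{1/7} and the rate
B = 4·γ_L·18·κ³/(λ·η·a_s⁷) share the material constants (surface
tension γ_L, viscosity η, the dissipation constant λ); their
consistency relation K⁷/(B·a_s⁷) = 7/4 is tested. λ has no published
value and is treated as an opaque input: absolute predictions of K
require it, scalings (K ∝ η^{−1/7}, K ∝ κ^{3/7}) do not. The dilute
concentration–viscosity law η(c) = η_S·(1 + [η]c/3)³ connects K ratios
to concentration ratios.

The first-order expansion of the partial-wetting law is
a ≈ a_s·B^{1/7}·t^{1/7}, so a_s·B^{1/7} is the partial-wetting
analogue of K (relative error of the expansion ≈ Bt/14).

**Fitting.** Trust-region least squares (`scipy.optimize.least_squares`)
with positivity bounds and cost tolerances of 1e-14; standard errors
from the Gauss–Newton covariance (J^T J)^{-1} scaled by the residual
variance. The delay time t₀ is fixed to 0 by default: in free-t₀
diagnostics on zero-delay data its standard error exceeds the fitted
value itself (the t^{1/7} shape is nearly flat in t₀), so the free
mode exists only as a diagnostic and allows either sign. On data
following the pure power law the partial-wetting fit sits on a flat
ridge (a_s → ∞, B → 0 with a_s·B^{1/7} fixed); the optimizer's ridge
point is accepted and model selection resolves the ambiguity. Model
choice is by small-sample AICc with both t₀ fixed to 0; an AICc gap
below 2 is reported as a tie with both fits returned. A series whose
widths are explained at least as well by a constant as by the power
law is flagged `degenerate`. Replicated experiments should be fitted
per replicate and aggregated as mean ± SD of the per-replicate
parameters.

The cell-loading helper converts a loading density (cells/ml) and a
mean single-cell volume (µm³) to a volume fraction in % vol
(1 ml = 10¹² µm³).

## Hanging-strut force balance

Dividing the freely hanging filament into cylindrical elements and
balancing elongational stress against gravity (plus, optionally, the
surface-tension contribution 2γ/d) gives

    η_E = ( ρ_m·g/(dα/dx) − 2γ/d(s) ) · 1/(dv/ds)

with v(s) = 4Q/(πd²) from volume continuity, ε̇ = dv/ds, α the pitch
angle against the horizontal and ρ_m the mass density. The arc-length
form carries a cos α factor and dα/ds = (dα/dx)·cos α; both axes give
identical curves for a pitch angle linear in x (tested). This is the
simplest quasi-static, purely viscous model: no viscoelastic
constitutive behaviour is fitted, and η_E is parameterized by ε̇ only.

**Derivatives from parametric fits.** Raw differentiation of measured
profiles amplifies pixel noise cubically (through d³ in ε̇), so
derivatives are taken on fitted models: the diameter profile is fitted
with an offset exponential d(s) = d_inf + (d0 − d_inf)·e^{−s/s_c} (the
offset form because diameters do not decay to zero), and the pitch
angle with a straight line in x. A raw finite-difference mode
(`raw_viscosity_curve`) is kept for diagnostics — it is the right tool
when the pitch angle is *not* linear, e.g. on synthetic force balances
encoding a strain-rate-dependent power-law viscosity.

**Viscous regime.** Real diameter profiles are parabolic-like: viscous
stretching (d decreasing) followed by elastic recovery (d increasing).
The analysis window ends at the minimum of the median-filtered
(window 5) diameter profile, but only if the profile genuinely rises
afterwards by more than 5% of its total range — otherwise the
"minimum" is noise in a flat tail and the window runs to the last
point. The first 2 grid points after the nozzle exit are excluded
(die-swell/attachment region); both choices are configurable. m ≤ 0 or
dv/ds ≤ 0 inside the window violate the stretching assumptions and
raise; negative η_E values are returned with a flag, never silently
dropped.

All inputs are converted to SI at this module's boundary (mm → m,
rad/mm → rad/m), so η_E emerges in Pa·s; the symbol collision between
vertex curvature and mass density is avoided by naming (`rho` only ever
means curvature; mass density is `density`).

**Conditioning caveat.** The decay length s_c of a 3-parameter
exponential carries an irreducible ~6% standard error at 1 px diameter
noise and ~300 samples (Cramér–Rao); errors in s_c move points *along*
the η_E(ε̇) curve rather than off it, so curve accuracy is governed by
the pitch-slope fit (~1–3% at the same noise).

## Image extraction

Conventions: pixel origin top-left, x rightward, y downward; in side
views gravity is +y, so a sagging strut has positive pitch angle with
no axis flip. All pixel→mm conversions flow through one scale value,
calibrated from the nozzle visible at the top of the frame (darkest
contiguous vertical structure; outer diameter 0.82 mm for 21G), good
to ~2 px. Extraction involves no randomness.

* **Contours**: Canny edges with hysteresis thresholds set as
  fractions of the Otsu level of the smoothed gradient magnitude
  (low = 0.5·Otsu, high = 1.0·Otsu, σ = 2 px), reduced per column to
  extreme rows over the longest contiguous run — two x-monotone
  chains. Valid while the strut is single-valued in x (pitch < 90°).
* **Centerline/diameter**: contours resampled at 1 px abscissa
  spacing and averaged; the centerline is smoothed with a local
  quadratic (Savitzky–Golay, 11 points) before differentiating, and
  the same smoothed curve feeds the tangent angle, the arc length and
  the diameter query points, so cos α = dx/ds holds on the output.
  Local diameter = nearest-neighbor distance to the upper contour plus
  nearest-neighbor distance to the lower one.
* **Width at a station**: measured perpendicular to the local path
  direction as the distance between the two near-black contact-line
  minima, each refined to sub-pixel by a 3-point parabola, averaged
  over ±3 px along-path. An absolute intensity ceiling separates
  contact lines from dark background stripes; stations without a
  detectable dip pair (e.g. beyond the strand) are skipped with a log
  entry. Station ages follow from the remaining path length to the
  nozzle divided by the print speed; stations within 1 mm of a path
  corner are excluded.
* **Stripe angle**: initialized from the zero-padded FFT peak of the
  patch (equivalent to the dominant structure-tensor orientation plus
  projected frequency) and refined by nonlinear least squares of a
  plane-wave model c + A·sin(k_x x + k_y y + φ). The refinement
  matters: discrete-gradient orientation estimators carry an O(k²)
  angle bias that would dominate the curvature inversion at small ρ.
* **In-gel masks**: with no intensity step at the boundary, the strut
  is segmented by reference-wave demodulation — fit the undisturbed
  stripes as a plane wave on the image border, subtract everywhere,
  threshold the squared residual (which jumps within a pixel of the
  contact line), close morphologically and keep the largest component
  with holes filled. The displacement vanishes along the strut
  centerline; a vertical closing element bridges that lane. Weakly
  refracting struts (z·ρ·Δn ≲ 0.2) leave too little residual and are
  underestimated — a known limitation.

## Synthetic scenes

The generators emulate the experimental regime: strut widths
0.4–1.1 mm, spreading times ≤ 12 s, print speed 5 mm/s at ~0.25 mm³/s
(0.25 mg/s of a ~1 g/ml ink), 21G nozzle (0.82 mm) in frame for
self-calibration, pixel scale 0.025 mm/px. Noise is additive Gaussian
with stated SDs and a single seeded generator — fixed seed means
byte-identical arrays and images. Every render writes a JSON
ground-truth sidecar; round-trip tests consume only the render and
compare only against the sidecar.

Bottom views are straight horizontal strands (the optics model lives
in the strut-local frame; meander support is in station placement,
which takes arbitrary polylines and skips corners): sinusoidal
stripes, the across-strut coordinate remapped by the local M inside
the band, near-black contact lines at ±a/2 (omitted in the in-gel
variant). The spreading snapshot maps position to age via
t(x) = t_max − x/v_p at constant κ. Side views draw the silhouette as
the centerline offset by ±d/2 with a ~1.5 px anti-aliased edge, the
nozzle as a dark bar, and extend the strut tangentially out of frame
so no artificial end cap is visible. Hanging-strut trajectories use
the closed form α(s) = gd(m·s + gd⁻¹(α₀)) (the exact solution of
dα/ds = m·cos α for pitch linear in x), exponential d(s), and the
analytic force-balance curve as ground truth; measurement noise is
injected as coordinate jitter followed by the same local-quadratic
smoothing an extraction pipeline applies (span ~10% of the strut
length), plus independent diameter jitter. A separate generator
integrates the force-balance ODE for a prescribed power-law η_E(ε̇) to
test thinning detection.

**What the synthetic scenes do not emulate**: perspective and lens
distortion, uneven illumination, motion blur, ink transparency
gradients, stripe-pattern imperfections, and real contact-line optics
(the rendered edge lines are idealized). Passing round trips therefore
demonstrate correctness of the inversion chain and its noise
robustness, not performance on arbitrary laboratory footage; the
lumped optical calibration in particular must come from a reference
measurement on the actual setup.

## Problem sizes

Defaults used in tests and examples: spreading series n = 24 over
0.5–12 s with σ = 10 µm; trajectories n = 60 (noise-free checks) or
n = 320 (≈ 1 px-per-sample extraction density) over 8 mm; renders at
0.025 mm/px, up to ~2400×120 px for a 60 mm strand. Parameter-recovery
statistics use 100 seeded replicates.
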