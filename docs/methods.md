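# Methods

This note records the models, estimators and numerical choices behind
`spexi`, and what the synthetic-data tests do and do not establish.

## System model

A bent-Laue monochromator produces a focused line beam in which Bragg angle,
and hence energy, varies along the vertical.  At the detector, a distance
`F` behind the focus, each row corresponds to one energy.  All angle-energy
conversions use `E[keV]·λ[Å] = 12.398420` and the cubic d-spacing
`d = a₀/√(h²+k²+l²)` (silicon default, `a₀ = 5.431 Å`); non-cubic crystals
are out of scope.  The crystal asymmetry angle is carried as metadata — it
determines the optics design, but once anchors are measured it does not
enter the pixel-energy mapping.  The `energy_direction` flag (+1: energy
increases with decreasing row index) makes the otherwise ambiguous detector
orientation explicit.

## Calibration estimators

**Beam region.** Per column, the largest contiguous run of rows with
`flat − dark` above a fraction (default 0.10) of the column maximum, with
runs shorter than 8 rows discarded.  All row intervals are half-open and
0-based.

**Edge localization.** Columns of the edge-film attenuation are boxcar
smoothed (default window 3 px) and differentiated by first difference; the
derivative-magnitude peak, refined by a 3-point parabola, is the edge row.
Isolated masked pixels (e.g. zero counts above a thick film's edge) are
filled by linear interpolation before differentiation so the derivative is
defined; the peak itself sits in well-measured pixels.

**Edge width and energy resolution.** The derivative peak's FWHM is
measured by a local Gaussian fit.  The smoothing-plus-difference kernel has
a known width of its own (a trapezoid; its Gaussian-fit FWHM is computed
numerically once per window size) and is removed in quadrature, so the
reported width reflects the beam and detector, not the estimator.  No
attempt is made to deconvolve physical contributions (core-hole lifetime,
pixel integration): references are blurred by the measured width as-is,
which keeps the reference treatment consistent with the data.  The
resolution estimate is the median across columns (robust against
bow-induced outliers), converted to keV via the local energy-per-pixel
gradient; σ = FWHM/(2√(2 ln 2)).  At the default geometry the energy pitch
is ≈1.4 eV/px, so a 1.27 eV FWHM (relative width 1e-4) is below the
sampling floor; the resolution-recovery test therefore uses a 5 m
focus-to-detector distance (0.14 eV/px), where the estimator is validated
to better than 15%.

**One-point energy map.** `θ(p) = θ_K + direction·arctan[(p−p_K)s/F]`,
`E = hc/(2d sin θ)`, per column so the beam bow is honoured.  The angular
offset from the focus is applied 1:1 to the Bragg angle, consistent with
rays diverging from a line focus.

**Two-point energy map.** The same arctan family re-anchored on two
features of known energy: `F_eff = s(p₁−p₂)/tan(θ₁−θ₂)`,
`θ(p) = θ₁ + arctan[(p−p₁)s/F_eff]`.  Exact at both anchors, smooth in
between, independent of the assumed `F`.

**Anchor detection.** The two absorption peaks are first picked as the two
most prominent local maxima of the smoothed column.  Because the anchors
are only ~10 px apart while the map is extrapolated over ±100 px, sub-pixel
peak errors are amplified an order of magnitude; naive 3-point refinement
of a ~2 px-wide peak on the edge slope is biased by up to 0.3 px.  The
default refinement therefore matches the *entire* column spectrum against
the known calibration-species attenuation curve, with the exact Bragg-map
form (p₁, F_eff) as the two free parameters and amplitude/linear-background
projected linearly.  This constrains the anchor spacing with every pixel of
the edge structure and reduces map errors in the beam to well under 1 eV.
A Gaussian-plus-linear-baseline local peak fit is the fallback when no
reference spectrum is supplied.

## References

Elemental total mass-attenuation tables (12 light-to-mid-Z elements,
5–40 keV, edge-straddling knots, K-edge discontinuities kept by branch-wise
storage) are packaged as plain text; they were generated from
Cromer–Liberman photoabsorption plus a Klein–Nishina/empirical
coherent-scattering model and are accurate to a few percent against
standard compilations — adequate for imaging analysis and simulation, not
for dosimetry.  Interpolation is log-log linear within a branch and never
crosses an edge.  Compounds use the mass-fraction mixture rule.  Measured
spectra load from two-column text.  Gaussian resolution blurring operates
on a uniform grid with step ≤ σ/4 and conserves the integral to 0.1%.

Species near-edge spectra (selenate, selenite, selenomethionine) are
*stylized*, not ab-initio: the tabulated elemental selenium edge jump is
chemically shifted (0, +3, +6 eV) and dressed with Gaussian white lines
(σ = 3 eV; selenate's peaks at 12.667 and 12.681 keV) on top of the
tabulated attenuation of the compound's other elements.  The few-eV feature
widths reflect solution-phase near-edge structure, which is intrinsically
broad rather than resolution-limited.  These spectra are used identically
in the forward simulator and the fits: simulations validate the pipeline's
calibration, unmixing and reconstruction — not atomic physics, and not the
transferability of any real XANES library.

## Unmixing

Per column, ordinary least squares on the unmasked pixels (masked pixels
are dropped, never imputed); unconstrained by default so that the
near-zero coefficients of absent materials remain a meaningful diagnostic,
with an optional non-negative mode for noisy low-concentration work.
Columns are fitted independently — no spatial regularization.  Projections
are solved in one vectorized pass over per-column normal equations (Gram
matrices via einsum, batched solve), which fits 1024 columns × 200 pixels ×
4 materials in well under 2 s on one CPU; exactly proportional references
raise an error naming the offending pair, and a design-matrix condition
number above 1e8 warns that the references are not distinct enough over the
band.  Pixels are unweighted; photon-statistics weighting is a documented
possible extension.  Projected density converts to molarity as
`c[mM] = ρt/(L·M)·10⁶` with path length `L` in cm and molar mass `M`.

## CT utilities

**Decay correction.** Storage-ring decay multiplies counts, hence adds a
constant to attenuation.  Each projection's offset is the mean attenuation
over the sample-free margin columns (restricted to the beam region, where
counts are high enough that −ln is effectively unbiased) and is subtracted
as a scalar; per-row offsets were rejected as over-fitting.  Correction is
applied in attenuation space *before* projection fitting, where the offset
is defined, so it cannot leak into the per-material coefficients.

**Rotation center.** The projection nearest 180° from the first is flipped
and cross-correlated with it; the correlation peak, refined parabolically,
gives the center to sub-pixel precision.  Scans covering slightly less
than 180° (endpoint-exclusive angle grids) are accepted down to a 170°
span.  When no pair lies within 10° of opposition, the center falls back
to the intercept of the projection center-of-mass sinusoid
`com(θ) ≈ c + A cos(θ+φ)`.

**FBP.** Standard filtered back projection (ramp, shepp-logan, cosine,
hamming, hann; linear-interpolation back projection, values outside the
inscribed circle zeroed) via scikit-image's `iradon`, with the sinogram
first shifted so the found center sits at the array center.  Sinograms
carry g/cm²; the output is divided by the column spacing (cm) so voxels are
g/cm³.  Validated against the analytic sinogram of a uniform disk
(interior mean within 2%) and by linearity and mass-consistency checks.

## Synthetic data generator

The simulator emulates: a near-Gaussian vertical beam profile (default
FWHM 120 rows on a 400-row detector); a quadratic bow of the beam and edge
row across columns (default 5·10⁻⁴ px/col², the non-uniform-bending
signature); a one-point Bragg energy map per column; an elemental selenium
edge film (0.2 mm) and a selenate solution film for calibration images;
attenuation by line-integral projected densities through a phantom
(forward projection via scikit-image's `radon`); reference spectra blurred
by the system resolution (default: relative edge width 1e-4) *and*
integrated over each pixel's energy span, as a real detector does; linear
flux decay across the scan; Poisson counting noise on beam counts plus
Gaussian read noise (σ=2) on a 100-count dark level, all deterministic per
seed.  Dark/flat/edge stacks default to 10/10/5 frames.

Demo phantoms: `three_species_disks` (a ~0.9 cm water cylinder holding
three disks of 100 mM selenate/selenite/selenomethionine solutions) and
`seedpod` (a central selenomethionine insert at 7 mg/cm³ in water, a
plant-tissue analogue).  Grid width 144 px at 62.5 µm spacing by default —
small enough that a full 180-angle noisy scan simulates and analyses in
seconds on one CPU, large enough that FBP discretization error is well
below the 5% recovery tolerances.

What the simulator does *not* model: source spectrum structure, detector
PSF beyond pixel integration, scatter, harmonics, refraction/phase
effects, or beam bow at the sample plane (small there compared with the
detector).  Passing recovery tests therefore demonstrate the correctness
and internal consistency of the analysis chain under realistic counting
statistics and calibration conditions, not robustness to every real-world
systematic.

## Storage

All mid-way products (energy map, beam region, edge trace, corrected
attenuation, references in use, decay offsets) and final maps are stored in
a single HDF5 keyed-dataset archive — a language-neutral, self-describing
replacement for language-specific serialization — alongside one 32-bit
float TIFF per material map and a plain-text settings record listing the
geometry and every tunable used.  Save→load round-trips are bit-exact, and
a rerun from the same inputs and settings reproduces the outputs exactly.

## Problem sizes used in validation

Acceptance-style checks run the full pipeline at 180 angles, 10⁴ flat
counts, flux decay to 0.90, phantom width 144 px (detector 208×400); the
calibration cross-check uses the full 1024-column detector; property tests
use smaller grids chosen so each effect under test dominates its error
floor (e.g. 144 angles for the decay-correction study, where coarser
angular sampling would hide the decay rings under streak artifacts).
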