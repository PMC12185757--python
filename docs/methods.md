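# Methods

This note records the models, conventions and numerical choices behind
`scatterprint`, and what the synthetic study does and does not show about
real measurements.

## Scattering geometry and units

Momentum transfer is Q = (4π/λ) sin(θ/2) with θ the full scattering angle;
Q is in Å⁻¹ throughout, probing real-space lengths 2π/Q.  Intensities are
in absolute units (cm⁻¹) where available; every curve carries an explicit
absolute/arbitrary flag because the cross-sample correlations only need
consistent relative scaling, not absolute calibration.  Non-positive
intensities (e.g. after background subtraction) are never deleted — they
are retained and masked, since most downstream stages work on logarithms
and must treat them as gaps.

Multi-configuration curves are merged by scaling the low-Q (USAXS) curve
onto the SAXS curve: the scale factor minimises the least-squares
log-intensity mismatch over the overlap window (default
0.0052–0.0055 Å⁻¹), which weights every intensity decade equally.  The
merged curve keeps the high-Q curve's points inside the overlap.

## Slit smearing and Lake desmearing

A Bonse–Hart camera integrates one detector direction, so the recorded
intensity is

    I_s(Q) = (1/L) ∫₀ᴸ I(√(Q² + u²)) du

with a uniform slit weighting of half-length L = 0.015 Å⁻¹ by default.
The literature value is quoted only as a length; the half-length
convention is adopted here and must be kept in mind when comparing
absolute levels.  For L much larger than Q this lowers a Q⁻⁴ Porod tail
to Q⁻³.  The integral is evaluated by 128-node Gauss–Legendre quadrature;
the integrand needs the curve out to √(Q_max² + L²), which is supplied by
a power-law tail fitted to the curve's last decade (Porod-like tails
dominate the USAXS range this is used for).

Desmearing uses the Lake fixed-point iteration started from the measured
curve.  The multiplicative form Iₙ₊₁ = Iₙ · I_meas/S(Iₙ) is the default:
with L larger than the whole measured q-range, the smeared and ideal
curves differ by factors of order L/Q (≈ 50 at the USAXS floor), and the
additive form Iₙ₊₁ = Iₙ + (I_meas − S(Iₙ)) — still available via
`method="additive"` — converges geometrically with rate ≈ 1 − O(Q/L) and
would need hundreds of iterations to do what the multiplicative form does
in under thirty.

Desmearing is ill-posed, and the bare iteration is *semi-convergent*: the
data residual keeps falling while fine-scale ringing grows, seeded by
interpolation/quadrature error.  Three safeguards are built in:

* the iterate with the smallest relative data residual is returned, and
  iteration stops once the residual has risen for 3 consecutive steps;
* multiplicative updates are clipped to ratios in [10⁻³, 10³];
* `smooth_iterates=True` applies a light 1-2-1 geometric smoothing to
  every iterate (regularised Lake iteration).  On smooth single-population
  curves this is unnecessary — the plain round trip recovers the input to
  ≈ 0.2 % RMS in log intensity — but on structurally complex curves
  (droplets + a biopolymer plateau with a sharp knee) the unregularised
  error floor is ~6 % and non-monotone, while the smoothed variant
  descends monotonically to 1–2 %.  It slightly biases sharp features, so
  it is off by default and the analysis drivers opt in explicitly.

Convergence criterion: relative RMS change of ln I below 10⁻⁴ (default)
or 50 iterations.  The iteration grid matters: desmearing is performed on
slit-camera-like densities (the analysis drivers resample the USAXS
segment to 150 log-spaced points); very dense grids only enlarge the
effective null space of the inversion.

## Porod surface areas

For a sharp interface, I → K·Q⁻⁴ with K = 2π(Δρ)²·S_v, where S_v is
interfacial area per unit *sample* volume.  With I in cm⁻¹ and both Q and
Δρ in Å units, Q⁴/(Δρ)² is dimensionless and K/(2π(Δρ)²) is directly in
cm⁻¹ — there are no hidden conversion factors, and a unit test asserts
this.  The printed worked radii satisfy r = 3/S, which implies S is
normalised per unit of *dispersed* material; the package therefore divides
S_v by the oil volume fraction φ, derived from the fat mass fraction with
oil density 0.92 g/mL and product density 1.0 g/mL.  This φ-normalisation
is a reconstruction of an under-specified step and is flagged as such: it
reproduces r = 3/S exactly, but other decompositions of "dispersed
material" are conceivable.

The plateau is the inverse-variance weighted mean of I·Q⁴ over the fit
range (uniform weights without uncertainties), with a standard-error
estimate.  The fit range must look like Porod scattering: the log-log
slope over the window must lie within −4 ± 0.3 (warning) and within
−4 ± 1 (hard error).  The automatic window search scans half-decade
windows from the low-q end and additionally requires the quadratic
log-log coefficient to be below 0.2: the knee between the low-Q rolloff
and the asymptote sweeps *through* slope −4 without being a power law,
and accepting it biases radii by tens of percent.  Default contrast:
oil SLD 8.7 × 10⁻⁶ Å⁻², water 9.47 × 10⁻⁶ Å⁻², both overridable.

Sphere geometry gives r = 3/S; since S is surface-weighted this is the
⟨r³⟩/⟨r²⟩ radius of a polydisperse population, which is what the recovery
tests assert against.

## Peaks and polymorphs

Peaks are local maxima above a baseline built as a rolling minimum of
ln I, smoothed over the same window.  The window defaults to 0.5 Å⁻¹ so
the broad amorphous water halo near 2 Å⁻¹ (FWHM ≈ 1 Å⁻¹) is absorbed into
the baseline.  A candidate must exceed the baseline by the relative
prominence (default 0.2) and its FWHM must be below half the baseline
window — a feature that broad is indistinguishable from the baseline
estimate itself and is discarded rather than reported.  Positions are
refined by a 3-point parabola in (q, ln I).

d-spacings are d = 2π/Q.  The polymorph catalogue stores the Q positions
as authoritative (α 1.53; β′ 1.50 & 1.65 or 1.47, 1.58 & 1.69; β 1.37,
1.65 & 1.70; lamellar 2L at 0.15) and recomputes d; note the α literature
pairing of 1.53 Å⁻¹ with 4.15 Å is internally inconsistent with 2π/Q
(= 4.11 Å), so recomputed d-values are preferred.  Because 1.65 Å⁻¹ is
shared between β and β′ variant sets, assignment reports *all* supported
polymorphs (a polymorph is supported when every position of one variant
set is matched within tolerance, default 0.03 Å⁻¹) instead of forcing a
unique label.

## Structural fingerprints

Each merged curve is interpolated onto n log-spaced Q points (default
100) — linearly in (ln Q, ln I), a deliberate reading since the
downstream quantity is d ln I/d ln Q and the displays are log-log — and
two layers are built: ln-domain min-max normalised intensity (scalar
multiplication of a curve leaves it unchanged), and the signed gradient
between neighbouring nodes assigned to geometric midpoints.  Gradient
moduli are rendered on a linear temperature scale, 0 (black) to 4
(white); values above 4 are clipped *for display only* — the stored
matrices are never clipped.  Regime labels: |g| ≥ 3.5 Porod surface,
3–3.5 steep/smeared surface, 1–3 mass fractal, below 1 plateau, rising
g ≥ 1 a correlation-peak flank.  The point count is a resolution/noise
compromise and is exposed as a parameter.

## Correlations

Intensity read-outs are log-log interpolated at the probe Q.  For the
lamellar probe at 0.15 Å⁻¹ both the raw intensity and the intensity above
a local power-law baseline (fitted over [q/4, 4q] excluding ±0.03 Å⁻¹
around the probe, floored at 0) are computed, since the crystalline
excess, not the total, tracks solid fat.  Spearman's ρ uses midranks;
the two-sided p-value is exact by full permutation enumeration for n ≤ 9
(vectorised over all n! rank orderings) and a t-approximation otherwise,
with the method recorded in the report.  Straight lines are ordinary
least squares.  No multiple-testing correction is applied across probes.

## DLS cumulants and electrokinetics

The field correlation is recovered from g₂ via the Siegert relation
g₂ = B + β|g₁|², with B defaulting to the long-lag mean and β to the
extrapolated zero-lag amplitude.  a₁ and a₂ are the coefficients of a
quadratic fit ln|g₁| = −a₁t + a₂t², and PDI = 2a₂/a₁²; for a Gaussian
decay-rate distribution this equals the relative variance σ²/μ² exactly.
The cumulant expansion is a short-time expansion, so the fit window keeps
|g₁| > 0.4 (mean-rate·lag of order one) and weights points by |g₁|² (the
inverse standard deviation of ln|g₁| under additive noise in g₂);
admitting long lags lets higher cumulants bias a₂ low by ~20 % at
σ/μ = 0.3, well outside the intended 10 % recovery band.  Negative a₂
estimates are floored at PDI = 0 with a flag.

Stokes–Einstein gives r = k_BT/(6πηD), reported in Å.  Henry's equation
ζ = 3U_Eη/(2εf(κr_p)) takes ε as the *absolute* permittivity (ε₀εᵣ,
≈ 6.95 × 10⁻¹⁰ F/m for water at 25 °C); "dielectric constant" is
ambiguous in colloquial use and this convention is asserted in tests.
f is restricted to [1.0, 1.5], with the Smoluchowski value 1.5 as
default.  Mass fraction to molarity: M = (w/100)·ρ·1000/M_w.

## The synthetic-data generator

Curves are additive sums of: lognormal-polydisperse sphere populations
(orientationally averaged form factor, averaged over ±5σ in ln r by
trapezoidal quadrature, absolute scale from φ/⟨V⟩·(Δρ)²·⟨V²F²⟩); power
laws with an optional low-Q cutoff below which they plateau (finite
fractal cluster size — without it, a mass-fractal term would diverge
unphysically into the USAXS range); Gaussian correlation peaks; the broad
water halo (position 2 Å⁻¹, σ = 0.45 Å⁻¹); and a flat background.
Noise is multiplicative lognormal, seeded; all generators are
deterministic given their seed and every artefact carries its planted
truth.

The 29-sample study set emulates the composition structure of commercial
products: fat on a jittered grid over 1–36 % w/w (distinct, well-spaced
values, milk at the low-fat end, cream at the high), carbohydrate bimodal
(about one in five samples is a nut/legume-style product with
0–0.5 % w/w, the rest 0.5–13), protein uniform on 0.1–5.  The default
composition→model link sets: droplet volume fraction from fat (strictly
monotone, so the planted fat → low-Q-intensity link is exact and the
zero-noise rank correlation is 1 by construction); a carbohydrate-scaled
Q⁻² power law (10 cm⁻¹ per % w/w at 0.1 Å⁻¹, cutoff 0.005 Å⁻¹); a
lamellar peak at 0.15 Å⁻¹ for solid-fat samples (cream/yoghurt above
3 % fat); and β-triclinic WAXS peaks for creams.  Droplets in the study
set have mean radius 1.0 µm (20 % lognormal): micron-scale droplets put
the Porod regime below the carbohydrate-network scattering, so — as in
real product sets — only the low-carbohydrate subset of samples exhibits
a usable Porod window (4 of 29 at the analysis seed), while
carbohydrate-rich samples hide the droplet interface.  Amplitude
constants are documented scale choices, not physical claims.

DLS correlation functions use q = 4πn sin(θ/2)/λ with He-Ne optics
defaults (633 nm, 173° backscatter, n = 1.33, 25 °C, η = 0.89 mPa·s),
Rayleigh-like r⁶ intensity weights over a lognormal size distribution,
Γ = D(r)q² decay rates and the Siegert relation with additive seeded
noise.

What the synthetic study does *not* emulate: instrument resolution
smearing of the pinhole SAXS data, multiple scattering, inter-droplet
structure factors (dilute limit assumed), realistic protein/carbohydrate
contrast decomposition, detector artefacts, and the proprietary
regularised inversion used by commercial DLS software (cumulant analysis
is used instead, so full multimodal size distributions are out of scope).
Passing tests therefore demonstrate the correctness of the analysis
chain under these idealised conditions, not the fidelity of any
particular instrument model.

## Problem sizes

Defaults were chosen so everything runs in seconds on one CPU: 200-point
USAXS grids for smearing/desmearing studies, 2000-point full-range
sample curves (needed to resolve σ = 0.02 Å⁻¹ crystal peaks), 150-point
resampled segments for the analysis drivers' desmearing, 128 quadrature
nodes, 301 size-distribution nodes, 29-sample study sets and 200-lag
correlation functions.

## Known limitations

* The slit length is treated as the half-length of a uniform weighting;
  trapezoidal weightings are not offered.
* Desmearing quality is inherently limited on curves whose structure
  changes within one slit length of the range end, because the smearing
  integral then depends mostly on the extrapolated tail.
* The φ-normalisation of the Porod specific surface area is a documented
  reconstruction (see above).
* `equivalent_radius` assumes spheres; for rough or adsorbed-layer
  interfaces the Porod radius overestimates the droplet size.
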