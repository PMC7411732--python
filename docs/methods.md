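# Methods

This note documents the models implemented in `palsim`, the defaults and
why they were chosen, the numerical conventions, and the limits of what the
synthetic studies can show.

## Tissue optics

Soft tissue is parameterized by the power-law reduced scattering spectrum
μ′ₛ(λ) = a·(λ/500 nm)⁻ᵇ with the generic soft-tissue means a = 1.89 mm⁻¹,
b = 1.286, and by the linear chromophore mixture
μₐ = B·O·μₐ^HbO₂ + B(1−O)·μₐ^Hb + W·μₐ^water + Fa·μₐ^lipid with defaults
B = 0.15, O = 0.75, W = 0.20, Fa = 0.10.  The packaged chromophore table
(`data/chromophores.csv`) covers 700–850 nm: whole-blood hemoglobin at
150 g/L converted from the standard molar-extinction tabulation, water from
the Hale–Querry data, lipid from soybean-oil measurements; intermediate
wavelengths are linearly interpolated and out-of-range requests raise.
Published absorption figures for "generic tissue" depend on which spectra
compilation is used; our table yields μₐ = 0.0650 mm⁻¹ at 800 nm, within
the ±15% band that different compilations span.  The table can be replaced
by any CSV with the same columns.

The transport kernel needs μₛ and g separately; tissue uses the similarity
relation μₛ = μ′ₛ/(1−g) with g = 0.95 and η = 1.37.  The water coupling
background is specified directly (μₐ = 3.5640×10⁻⁵ mm⁻¹, μₛ = 1.0 mm⁻¹,
g = 1, η = 1.37): g = 1 means purely forward scattering, so background
"scattering events" change nothing and the medium is effectively clear.

## Monte Carlo transport

Voxel-based, isotropic grids (default scene 89 × 60 × 30 mm at 0.25 mm).
Photons carry a weight, traverse voxels with an exact DDA walk, and between
scattering events (free paths sampled from the local μₛ) are attenuated
continuously: a segment of length l deposits w·(1−e^(−μₐl)).  Fluence uses
the track-length estimator, φ = ∫w dl / (V·N), which equals
absorbed/(μₐ·V·N) wherever μₐ > 0 and remains defined in non-absorbing
voxels.  Henyey–Greenstein deflections are sampled by the standard
inversion; g = 1 short-circuits to cosθ = 1 exactly.  Photons leaving the
grid are terminated into `escaped_weight` (the outer boundary is absorbing;
no boundary reflections are modelled).

Russian roulette (threshold 10⁻⁴, survival 0.1) bounds path lengths.
Unbiased roulette conserves weight only in expectation; to keep the per-run
energy budget exact, the zero-mean roulette correction (kill: +w; survive:
−(1/p−1)·w) is folded into `escaped_weight`, so
`absorbed.sum() + escaped_weight = 1` holds to float accumulation error on
every run.  `escaped_weight` therefore estimates the escape fraction with a
small zero-mean jitter rather than being a pure tally.

Refraction and Fresnel reflection are intentionally absent: every medium in
the intended scenes shares η = 1.37 (index-matched).  Mixing refractive
indices raises `NotImplementedError` instead of silently ignoring the
mismatch.  Runs are strictly single-stream and seeded; identical arguments
give bit-identical results.

## Illumination geometries

Coordinates: x lateral (zero at the array centre), y axial depth (zero at
the transducer face), z elevation; the target surface sits at the 19.5 mm
water standoff.  Three schemes:

* **dark-field** — two 38 × 1.25 mm rectangles on the elevation sides,
  tilted 20° so the centre rays cross at (0, 19.5, 0);
* **bright-field** — one 38 × 5 mm rectangle coaxial with the imaging axis;
* **lateral** — two 5 mm circular beams with exit centres at the two ends
  of the aperture (lateral offset and exit height configurable), steered
  per angle.

The schedule angle θ needed a concrete aiming convention, which the source
material leaves ambiguous.  We adopt the construction that reproduces the
system's documented behaviour: at θ = 0 each beam is aimed at the surface
point on the lateral midline, so the two beams cross exactly at the target
surface; increasing θ rotates each beam toward the vertical by θ, driving
the crossing deeper along the midline (19 mm below the surface at θ = 18°)
while the surface spots slide outward.  This yields the observed phantom
behaviour — A_RMS peaking at a small interior angle (at θ = 0 half of each
beam's crossing lies above the surface; at large θ the in-tissue path, and
with it attenuation, grows) and a monotonically increasing mean signal
depth.  The alternative reading (vertical beams at θ = 0 sweeping inward)
was evaluated and rejected: its beams never reach the central ROI within an
18° schedule and most of them miss a 20 mm cylindrical target outright.

Beams are collimated top-hats.  The real fiber bundles have NA 0.56; the
divergent cone is deliberately not modelled.  Two consequences, verified by
construction and by simulation: (i) the union of surface footprints over
the 0–18° schedule tiles a contiguous mirror-symmetric band of about
±12 mm, not the full ±19 mm field of view — full coverage in the physical
device comes from beam divergence; (ii) for a convex target whose top
touches the focal plane, every collimated ray from exits above it enters
through the upper flank arc, so the deep-ROI fluence advantage of the
lateral scheme saturates around 2× the top-entry schemes (entry points are
only ~2 mm closer to the deep ROI, and the diffusion attenuation rate is
μ_eff = √(3μₐ(μₐ+μ′ₛ)) ≈ 0.45 mm⁻¹).  Published experiments with divergent
fibers report larger factors (4–10×); reproducing those requires modelling
the cone, which is out of scope here.

Timing arithmetic: LPRF_max = ωₛ/Δθ with ωₛ = (60° in radians)/0.2 s =
5.236 rad/s (displayed as 5.2); the chain is evaluated at full precision
and only rounded for reporting, which is why LPRF_max(Δθ=4°) is exactly
75 Hz.  Frame rate = LPRF/(n_angles·K); total subframes =
(n+1)·K·n_elevation, which gives 90 for the 5-angle, K = 2, 9-elevation
protocol and 380 for the 10-angle, K = 2, 19-elevation phantom protocol.

## Acoustic forward model

p₀ = Γ·μₐ·Φ with constant Γ (default 1; only relative amplitudes matter
downstream).  Array elements are ideal points at their centres (128
elements over 38 mm, 7.2 MHz, 40 MHz sampling, c = 1540 m/s — c is
configuration, not physics).  Each element trace sums, over source voxels,
p₀·(r_ref/r)·w(t−r/c) with r_ref = 1 mm and w a Gaussian-windowed cosine
whose −6 dB fractional bandwidth is 0.7.  No directivity, elevation
focusing or acoustic attenuation; out-of-plane clutter emerges naturally
from 3-D geometry.  A `p0_threshold` drops voxels below a fraction of the
maximum to bound the summation cost (default 10⁻⁴ in the pipeline; 0 keeps
everything and makes superposition exact to float precision).

## Reconstruction

Unapodized delay-and-sum with one-way delays
δ = √(y_w² + (x−xᵢ)²)/c, where y_w = standoff + depth (image depth is
referenced to the target surface; the grid carries the standoff so delays
stay correct).  The receive aperture is a symmetric half-width α in
elements, default α = 32 (f-number ≈ 1 at mid-depth; the published sum
bound "x±α" is read as symmetric).  Sample lookup is linear interpolation
(a nearest-sample mode exists for oracle cross-checks); optional Hann
apodization is off by default.  Default pixel spacing is 0.1 mm laterally
and c/fₛ axially (0.0385 mm) — the one-way photoacoustic sample spacing;
the two-way c/(2fₛ) convention belongs to pulse-echo imaging.  Coherent
summation is plain pixel-wise addition of RF-domain subframes; because
both the forward model and DAS are linear, the sum over per-angle partial
illuminations equals the single wide-illumination reconstruction to float
precision, which the tests assert at 10⁻⁹ relative.  Envelope detection is
the per-column analytic-signal magnitude.

## Metrics

A_RMS is the RMS of RF-domain pixel values over an ROI; ȳ is the
|S|-weighted depth centroid.  SNR is computed on the envelope image as the
ROI *mean* of (S_H − mean(noise))/std(noise), in dB as 20·log₁₀ — the mean
(rather than the raw pixel sum) is the only reading consistent with
published SNR magnitudes of 14–25 dB, and the amplitude-domain 20·log₁₀
convention is declared since the source does not state one; a raw-sum
variant would differ only by 20·log₁₀(N_pixels).  Non-positive linear SNR
reports −∞.  The attenuation fit regresses log-amplitude on depth
(least squares) and negates the slope, with a t-based 95% CI from the
slope standard error.  Element-indexed ROIs use 1-based numbering
(elements 62–66 span 1.48 mm around the array centre).  The Monte Carlo
comparison boxes are 2 mm cubes on the midline: A at 2 mm below the target
surface, B at half the target's depth extent, C at 85% of it ("deepest
central interior") — C's placement is a declared default since the
reference placement exists only graphically.

## Synthetic studies: scales and scope

The test suite runs every study at desk scale, chosen as the package's own
defaults: the scheme comparison uses 5×10⁵ photons per scheme on the full
0.25 mm grid (the reference simulations used 5×10⁶; MC standard errors in
the deep ROI are then a few percent, far smaller than the effects probed),
and the phantom sweep uses 3×10⁴ photons per angle on a 0.5 mm grid with
0.15 × 0.1 mm image pixels, where the angle-to-angle differences in A_RMS
and ȳ exceed the Monte Carlo jitter by an order of magnitude.

What passing these studies shows: the transport kernel reproduces
closed-form physics (Beer–Lambert, exponential fluence decay, HG moments,
exact energy budgets), the forward/inverse acoustic chain is consistent
(sub-pixel localization, exact linearity), and the multiangle geometry
produces the qualitative illumination behaviour (interior A_RMS peak,
monotone depth, deep-fluence advantage for narrow targets).  What it does
not show: absolute pressures or SNRs of real acquisitions (no element
impulse-response calibration, no acoustic attenuation, no divergent-beam
fluence), and any effect that depends on the fiber cone (full-FOV surface
coverage, the 4–10× deep-fluence factors).

## Degenerate inputs and tie-breaks

g = 1 scatters forward exactly; μₛ = 0 media propagate ballistically;
μₐ = 0 voxels tally track-length fluence and absorb nothing.  A source
whose centre ray misses the grid raises a geometry error.  Envelope images
must be non-negative; coherent summation refuses envelope-domain inputs
and mixed grids.  All-zero ROIs make ȳ undefined (error), zero noise
variance makes SNR undefined (error), and attenuation fits demand at least
5 strictly positive amplitudes.  Argmax ties in peak finding resolve to
the first (shallowest, leftmost) pixel, numpy convention.
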