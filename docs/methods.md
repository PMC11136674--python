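# Methods

This note documents the models implemented in `phytoray`, their
assumptions, the defaults that matter, and the numerical choices behind
them.  Nothing here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Scene model

Scenes are collections of planar primitives — triangles and rectangular
patches — in a right-handed world frame with +z up and lengths in metres.
Patches may carry a boolean texture mask (e.g. a leaf silhouette from a
PNG alpha channel, threshold alpha > 0.5, binary only): masked-out texels
are fully transparent to rays and excluded from the primitive's area, so a
masked patch's area is width·height·fill-fraction and the masked plus
masked-out areas always sum to the unmasked area.  Every primitive carries
two-sided material references, an emissivity (default 0.95), and an
open-ended `data` map used for annotation (plant/leaf/fruit id, organ,
temperature, chemistry, ...).

Ray–scene intersection is exact nearest-hit with a self-intersection
epsilon of 1e-6 m.  The production kernel is a chunked, fully vectorised
numpy implementation (six matmuls per chunk plus elementwise tests, with a
flattened global texel array for mask lookups).  At the desk scale this
package targets (up to a few thousand primitives) this outperforms a
Python-level bounding-volume hierarchy traversal, so no acceleration
structure is built; the kernel's semantics are pinned test-by-test to a
scalar brute-force oracle, which is the correctness contract an
accelerated structure would also have to satisfy.

Procedural plants (bean-like, sorghum-like, strawberry-like presets) are
deliberately simplified parametric models — stems as crossed thin quads,
leaves as elliptically masked patches on petiole whorls, fruit as
icosahedra.  Their contract is statistical: element counts and sizes fall
inside the configured ranges, generation is bit-reproducible under a fixed
seed, and every primitive is annotated.  The strawberry preset uses plant
height 0.2–0.4 m, berry radius 0.04–0.08 m, leaf length 0.05–0.1 m, 15
stems per plant, 1–3 berries per stem, globally scaled by 0.8; the
bean-like preset (height 0.15–0.25 m, leaf length 0.05–0.09 m, trifoliate
petioles, 1–3 stems) and sorghum-like preset (height 0.8–1.4 m, long
single leaves) are realistic desk-scale choices fixed once here.

## Radiation transport

A reverse Monte-Carlo method: rays are launched from uniformly sampled
points on primitive surfaces toward the sources, so every element is
sampled regardless of its size or orientation.

Sources:

* **Collimated sun** — one direction per ray, occlusion tested; incident
  flux S·cosθ·(visible fraction).  With nothing in the way the estimator
  is exact (zero variance), which is why the flat-plate checks agree with
  the closed form to machine precision.
* **Sun sphere** — directions sampled uniformly in a cone of angular
  radius 0.266°, the solar disk seen from Earth; gives penumbras and has
  the collimated sun as its zero-width limit.
* **Terrestrial sphere / disk / rectangle** — point-pair sampling between
  the primitive and the source surface with visibility tests; spheres are
  treated as isotropic emitters (surface points emitting P/4π per
  steradian), planar sources as cosine emitters (radiance P/πA).  The
  sphere treatment ignores the self-occlusion of a solid sphere's far
  hemisphere, adequate at the source sizes and distances intended here.
* **Diffuse sky** — cosine-weighted hemispherical rays per primitive side;
  rays that escape the scene collect the sky flux.  Any miss is "sky":
  there is no lower hemisphere distinction, so an undersurface with an
  unobstructed downward view also sees sky flux.  The configured value is
  the flux on an unobstructed horizontal surface.
* **Longwave sky** — as diffuse sky with flux σT_sky⁴ in longwave bands.
* **Thermal emission** — each primitive side emits ε·σ·T⁴ into the
  longwave band's to-be-scattered buffer, entering the ordinary scattering
  machinery, which yields self-consistent longwave exchange between
  surfaces.  Longwave surface properties follow Kirchhoff's law
  (ρ = 1 − ε, τ = 0).

Incident energy splits into absorbed (1−ρ−τ), reflected (ρ, re-emitted
from the incident side) and transmitted (τ, re-emitted from the opposite
side); both re-emissions are Lambertian and specular reflection is not
modelled.  Two buffer families are kept: (ρ, τ)-weighted buffers drive
object-to-object scattering, (ρ_o, τ_o)-weighted buffers are what a camera
queries.  All bands ride each geometric ray simultaneously.

Scattering iterates until the residual buffered energy falls below
`residual_fraction_tol` (default 0.005) of the injected energy, or
`max_scattering_iterations` (default 20) is reached, at which point a
warning reports the residual.  The per-iteration energy ledger
(injected = absorbed + escaped + residual) closes to machine precision by
construction — each scattered ray's energy either lands on a primitive or
escapes — so the ledger check in the tests is a check on bookkeeping, not
on sampling noise.  The residual contracts at least geometrically with
ratio bounded by max(ρ+τ) times the fraction of scattered energy that
lands on other primitives.

One inherited approximation: band properties are always weighted by the
*source* spectrum S_λ, which can differ from the true spectral composition
of multiply-scattered radiation.  This is the price of precomputing band
properties once; it is documented behaviour, not a defect.

Default ray counts are 32 direct and 16 diffuse rays per primitive —
enough for percent-level flux estimates on the fixture scenes while
keeping the default test run fast; both are config knobs, and the
Monte-Carlo error shrinks as 1/√n (verified in the suite).

Randomness uses one counter-based Philox stream per (pass, iteration,
primitive uid), making results bit-reproducible and independent of
primitive traversal order.

## Camera

Thin-lens geometry with three parallel planes.  The image plane sits
d = (sensor_width/2)/tan(hfov/2) behind the lens; the focal plane at the
focusing distance in front, scaled by f_d/d.  A pixel ray starts at a
jitter-sampled point on the lens disk and passes through the focal-plane
conjugate of a jitter-sampled point inside the pixel (the conjugate is the
projection of the pixel point through the lens centre, so the three points
are collinear by construction).  lens_diameter = 0 gives a pinhole, with
everything in focus; otherwise off-focal-plane objects blur with a circle
of confusion of world-space diameter lens_diameter·|z−f_d|/f_d.

**Radiometric contract.**  A pixel value is the sample-averaged
camera-weighted scattered exitance (W m⁻²) of the hit side of the surface
each ray strikes, accumulated over all scattering iterations, plus εσT⁴
for longwave bands.  This makes the unobstructed Lambertian flat-plate
pixel exactly ρ_o·S·cosθ and a Lambertian ground's bidirectional
reflectance factor (pixel/(S·cosθ_sun)) equal to ρ at every view angle.
No cosine or solid-angle factor of the camera geometry enters the pixel
value; sky (miss) pixels read a configurable per-band radiance, default 0.
Pixel-sample intersections are computed once per render and reused across
scattering iterations, so images are consistent across iterations and
cheap to accumulate.

**Annotation.**  One deterministic ray per pixel from the lens centre
through the pixel centre; the nearest primitive's datum is returned with
no blending (a mixed pixel gets exactly one label).  Depth maps record the
lens-centre-to-hit distance (+inf for sky); thermal maps record
temperature (K) by default or emitted flux εσT⁴ on request.  Hits on
primitives lacking the requested key fall back to the background value
with a warning (configurable to an error).

**Distortion.**  Forward remap in centred pixel coordinates:
δu = u(p₁r² + p₂r⁴) + 2p₃uv + p₄(r² + 2u²), δv symmetric with p₃↔p₄,
r² = u² + v².  Destinations are rounded to the nearest pixel; unfilled
destinations take the background value, which produces the characteristic
dark border gaps under barrel parameters; collisions resolve last-write in
row-major source order (made deterministic explicitly, not left to array
assignment order).  Zero coefficients return a bitwise copy.  Forward
mapping is the default because it reproduces the "rearranged pixels"
behaviour including gaps; an inverse resampling variant was considered and
deliberately not implemented to keep label maps exactly
nearest-neighbour.

## Leaf optics

The generalised plate model.  Per elementary layer,
k(λ) = Σᵢ Cᵢ·Kᵢ(λ)/N.  A single plate combines the cone-averaged Fresnel
interface transmissivity tav(α, n) — computed by 96-node Gauss–Legendre
quadrature of the unpolarised Fresnel transmittance with sinθcosθ flux
weighting, rather than the closed-form rational expression, trading a
microsecond of precompute for transcription safety — with the isotropic
absorption factor θ(k) = (1−k)e⁻ᵏ + k²E₁(k).  The top interface uses
α = 40° (exposed as a parameter), internal interfaces the full hemisphere
with the inside-out reciprocity tav(90,n)/n².  The remaining N−1 plates
are stacked with the Stokes eigenvalue system, which handles non-integer N
through fractional powers of the eigenvalue b; conservative (R+T=1),
opaque (T=0) and non-reflecting (R=0) plates take their analytic limits to
avoid 0/0.  Outputs outside [0,1] raise rather than being clamped.

Energy conservation: with zero absorbers ρ_λ + τ_λ = 1 holds to machine
precision at every wavelength (verified to 1e-9 in the suite); with
absorption, ρ + τ ≤ 1 and the deficit is the absorptance.

**Coefficient tables.**  n(λ) and Kᵢ(λ) are data.  The bundled table
(`AbsorptionTables.synthetic_default`) is synthetic: smooth Gaussian
absorption bands placed at the documented feature wavelengths (chlorophyll
430/678 nm, carotenoids 450/480, anthocyanins ~548, water overtones
970/1200/1450/1940 nm, SWIR dry-matter/protein/cellulose bands) with
magnitudes chosen so typical concentrations give realistic leaf
absorptances.  It is not a published calibration, and the package says so
wherever it appears; real tables load from delimited text with named
columns.  Consequences for testing: conservation, monotonicity, limits and
continuity hold for any physically plausible table; the reference-oracle
tests compare two independent implementations of the *algorithm* on the
shared table, which is exactly what they are meant to pin down.  Both leaf
sides receive the same (ρ_λ, τ_λ); per-side overrides are available at the
scene layer.

## Calibration

The measured image value of a reference patch photographed head-on under a
known illuminant equals its ρ_o.  The effective response C_λ of each
channel is expanded in 12 Gaussian bumps spanning the channel band (σ =
centre spacing), and amplitudes a ∈ [0,1] are fitted by L-BFGS-B to
minimise ‖G a − m‖² + 10⁻³‖Δ²a‖² + 10⁴‖max(0, C−1)‖², where G maps bump
amplitudes to predicted patch values through the band quadrature.  The
objective history is recorded (monotone over accepted iterates), a
rank-deficient design (spectrally indistinct patches) warns that the fit
is regularisation-dominated, and the reconstructed response is clipped to
[0,1] as a final guard (inactive whenever the true response is in-span).
The same entry point serves a "no-target" mode: user-entered patch values
in place of measurements yield a fully simulated camera response.

## Fixtures and synthetic data

Four canonical scenes make the package testable with no external data:
`single_plate` (closed-form radiometry), `occlusion_pair` (annotation
oracles), `mini_canopy` (textured ground + 2×2 procedural bean canopy
under direct sun and diffuse sky, two shortwave bands, a few hundred
primitives — energy-ledger checks), and `color_board` (18 seeded smooth
random reflectance patches for calibration studies).  These fixtures
emulate the geometric and radiometric structure of real phenotyping
scenes, not their full complexity: real canopies have orders of magnitude
more primitives, non-Lambertian leaves, measured spectra and cluttered
backgrounds, so passing tests demonstrate correctness of the transport,
imaging and annotation machinery — not photorealism of any particular
crop.

## Numerical choices

* Common spectral grid 400–2500 nm at 1 nm; band integrals refine each
  interval 4× before the trapezoid rule because products of
  piecewise-linear spectra are cubic within a cell (keeps quadrature
  within ~1e-7 relative of exact).
* Band weighting with zero source energy in a band raises (undefined
  mean); band/spectrum non-overlap in plain source integration warns and
  returns zero flux.
* Intersection epsilon 1e-6 m; local-coordinate inside tests use 1e-9
  tolerance.
* Image coordinates are row-major, origin top-left, pixel centres at
  half-integers; distortion uses centred coordinates with the principal
  point at the image centre.
* Per-image seeds in a batch derive from SeedSequence(base, index),
  folded below 2³¹.

## Problem sizes

The default verification suite runs scenes of 1–500 primitives, images of
9²–48² pixels at 2–96 samples per pixel, and 4–2000 rays per primitive —
sizes chosen so the whole suite and the acceptance script complete in
seconds on one CPU core while leaving every check's statistical power
intact (the closed-form checks are exact regardless of size; the
Monte-Carlo checks state their expected error explicitly).

## Known limitations

* Lambertian scattering only: no specular highlights, no leaf BRDF
  anisotropy, no polarisation or fluorescence.
* No within-leaf lateral transport: each primitive scatters independently.
* No atmosphere: no absorption or scattering between surfaces and camera.
* Scattered radiation keeps the source's spectral shape (see above).
* The sphere-source model ignores solid-sphere self-occlusion.
* The bundled absorption table is synthetic (see Leaf optics).
* Non-leaf optical properties (soil, stems, fruit) are set empirically and
  do not respond to physiological state.
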