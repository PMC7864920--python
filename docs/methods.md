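# Methods

## Optical model

All propagation is incoherent geometric optics.  Interfaces split a beam's
power with the unpolarised Fresnel average `R_eff = (R_s + R_p)/2`,
`T = 1 − R_eff`; polarisation is reported per interface but never
propagated, and there is no interference or diffraction (the containers are
macroscopic, and narrow-band LED stimuli make coherence effects
irrelevant).  Directions follow the vector form of Snell's law; total
internal reflection occurs when `(n_i/n_t) sin θ_i > 1`, with the grazing
and critical angles treated as exactly fully reflecting.

**Thin-wall treatment.**  Container walls change a ray's direction as if the
two wall faces were locally parallel, so the wall index cancels from the
exit direction (the lateral offset of order the wall thickness is ignored —
sub-millimetre against container radii of 19–50 mm).  Wall *power* uses the
full two-face accounting: the incoherent geometric series over internal
bounces gives

    R = r1 + (1 − r1)² r2 / (1 − r1 r2),   T = (1 − r1)(1 − r2) / (1 − r1 r2)

which collapses to a perfect mirror (R = 1) when the far face is beyond its
critical angle.  `wall_stack_beam_ledger` exposes the same expansion
beam-by-beam with labels and conservation bookkeeping;
`bulb_crossing_beams` names the strong beams of a full container traversal
(entry reflection ~3.7% for glass, returned power R5 + T5 ≈ 3.74% → "4%").

**Absorption.**  Beer–Lambert attenuation along water path segments, default
0.05 m⁻¹ (pure water near 520 nm, configurable on the `Medium`).  Across a
4 cm container this is ≤ 0.2% and negligible, but it is carried so the
power ledger closes.

**Dispersion** is available only as per-wavelength refractive-index
overrides (rerun the tracer per wavelength); no Sellmeier/Cauchy modelling.

## Container scenes

The observer (eye) sits at the origin; azimuth 0° is rostral, positive
clockwise from above; elevation 0° is the equator, +90° up; lengths in mm.
Presets:

| preset | geometry | wall (n) | water level above eye |
|---|---|---|---|
| `petri_lid` | disc Ø 38.7, depth 4 | polystyrene (1.57) | 1.8 (fill 2.3, eye 0.5 above bottom) |
| `cylinder` | Ø 40, height 50, eye on mid-stage +1.75 | acrylic (1.49) | 23.25 (filled) |
| `bulb_8cm[_full]` | sphere Ø 80, opening Ø 48, eye centred | borosilicate (1.473) | 32 (to the rim, elevation 53.1°) |
| `bulb_10cm_low` | sphere Ø 100, eye centred | borosilicate (1.473) | 10 (rim at 11.5°) |
| `ideal` | no container | — | — |

Wall thicknesses are not critical under the thin-wall rule and default to
1.0/2.0/1.5 mm (dish/cylinder/bulb).  Occluders (microscope objective,
holder, stage) are modelled as absorbing *direction sectors* seen from the
eye — an objective cone blocking elevations above a configurable access
angle (default 39.2°), a rear sector for the holder — not as CAD meshes;
the experiments of interest only ever use them as blocked regions.  All
occluders default to off so the optical benchmarks probe the bare
containers.

**Meniscus.**  Optional circular-arc annulus joining the flat surface to the
wall at a configurable contact angle (default 20°, height 1 mm, off unless
requested).  The arc is tangent to the flat surface, so a 90° contact angle
degenerates exactly to flat.  Implementation note: the tracer intersects
the flat surface plane and applies the meniscus *normal* at the hit radius
(a thin-perturbation approximation that is exact in the flat limit); the
perturbed band for the filled bulb spans roughly 53–55° elevation.

## Ray tracing and panoramas

Tracing runs backward from the eye, one ray per cell centre of an
equirectangular grid (column 0 at −180° azimuth, row 0 at +90° elevation).
At each interface the beam branches into reflected and transmitted
components; branches are pruned below `min_power = 1e-3` and after
`max_events = 12` interface events (low-order beams carry essentially all
visible power; the power ledger closes to 1e-6 when absorption is off).
Because containers are tiny relative to the stimulus arena, a branch's exit
*direction* identifies its stimulus source (far-field approximation; exit
position offsets of a few mm are ignored).  Each terminal contribution
keeps its power, TIR count (TIR at horizontal surfaces only), reflection
order, and *mirror parity* — the number of reflections at horizontal
surfaces, whose parity flips perceived vertical motion:
`perceived = (−1)^parity × vertical component`.

Distortion metrics weight cells by `cos(elevation)` (solid angle).  No
anti-aliasing: metrics operate on directions, not pixel colours.  The
default render is 720×360 (0.5°/cell); the shipped tests and simulations
use 144×60 to 360×180 grids, which the convergence test shows agree with
doubled resolution to better than 1% on the headline metrics.

## Stimuli and arena

The reference checkerboard is 36 columns × 18 rows of 10° patches with
quadrant hues (upper right green, upper left purple, lower right blue,
lower left orange), plus sinusoidal gratings (default 0.033 cycles/°,
30 °/s) and uniform fields.  The LED arena model covers 0–168° azimuth ×
±40° elevation (14 × 8 tiles) for whole-field motion; receptive-field
mapping tiles a 180° × 78° field with 36 smallest patches of exactly
30° × 13° (390 deg²), presented as a bisection hierarchy
(1×1, 2×1, 2×2, 3×3, 6×6 tiers), each patch with temporal→nasal and
nasal→temporal motion — 104 phases.  The mapped field is defined so the
smallest patch is exactly 1/36 of it and three patches are 1170 deg², the
small-receptive-field area threshold; it therefore slightly overfills the
physical 168° arena span.

## Neural forward model

Model neurons are retinotopic Gaussian receptive fields in *viewing*
coordinates (default σ = 8° × 5°, i.e. compact fields well under the
three-patch small-RF bound) with Von Mises direction tuning
(`exp(κ(cos Δ − 1))`, default κ = 4 for tuning experiments, κ = 2 for
mapping populations).  The response to a phase is

    gain · S( Σ_cells RF(cell) · [P_even·VM(θ) + P_odd·VM(−θ)] ) + baseline + noise

where `P_even/P_odd` collect the perceived stimulus power reaching the cell
with even/odd mirror parity, and `S(d) = (1+K)d/(d+K)` is a
Michaelis–Menten saturation (default K = 0.5) standing in for calcium
indicator saturation; it compresses the response ratio between whole-field
and single-patch stimuli the way trial-averaged calcium signals do.
Gaussian noise (default σ = 0.01 of the unit full-field response) is added
before per-neuron z-scoring across phases — the analysis sees "z-scores of
the calcium signal" exactly as a recording pipeline would.  There are no
indicator kinetics: the artifact mechanisms are spatial and directional,
not temporal.

**RF detection** uses only smallest-tier patches: per patch, the max z over
the two motion directions; supra-threshold at z ≥ 1.96 (configurable);
4-connected components; power-weighted centroids.  Neurons whose raw
response range stays below `min_response = 0.1` are excluded as
motion-insensitive, mirroring the inclusion criteria of real recordings
(with a purely horizontal mapping stimulus, vertically tuned units are
unmappable and would otherwise contribute noise-only maps).  A cell is
*bipartite* when exactly two components exist; the pair orientation is the
angle of the joining line measured from vertical (0°/180° = vertically
aligned).  Small-RF flag: area ≤ 1170 deg².

**Direction selectivity**: DSI = (R_pref − R_null)/(R_pref + R_null) with
R_null the response opposite the peak (a vector-magnitude variant is a
config switch); OSI is the doubled-angle vector sum; preferred direction is
the vector-sum angle; DS classification at DSI > 0.7.  Preferred-direction
histograms (12 × 30° bins by default) are fitted with sums of 1/2/4 Von
Mises bumps by bounded nonlinear least squares, multi-start from histogram
peaks; component weights are the fitted masses rescaled to the histogram
mass.  The two-proportion z-test uses z = (n1 − n2)/√(n1 + n2) with normal
tails.

## Synthetic populations — what they do and do not capture

`generate_fixture_population` lays receptive-field centres on a jittered
grid (or an upper-nasal-biased "hotspot" layout) with preferred directions
in equal quarters (up/down/TN/NT) and identical gains.  This captures
retinotopic coverage and balanced tuning, which is all the artifact
mechanisms require.  It does not model real response statistics (firing
variability, adaptation, correlations), eye movements, or the true
diversity of RF shapes — so passing mechanism tests demonstrates that the
*optics* produce the reported artifacts under idealised readout, not that
the simulator predicts in-vivo cell counts.  The in-vivo proportions
(e.g. how many of the recorded cells show double fields) depend on biology
and sampling and are deliberately out of scope; the simulator reproduces
the direction and selectivity of each effect.

## Numerical choices and limitations

* Angles in degrees at public interfaces; exact analytic intersections for
  discs, cylinders and spheres (verified against a 0.02 mm marching oracle
  on 1000 random rays per preset to 0.05 mm).
* Determinism: every stochastic stage takes an explicit seed; a single
  global seed is expanded into per-stage seeds (< 2³¹) via
  `numpy.random.SeedSequence` with CRC-keyed stage labels.
* The observer is a point at the scene origin; binocular geometry and eye
  size are ignored.
* Transmitted branches leaving through a wall are not re-intersected with
  the container (convex geometries make re-entry negligible; the petri rim
  region is the only, visually marginal, exception).
* Photometric calibration (cd/m²), scattering, blur and partial opacity of
  glued or moulded container features are out of scope; occluders are
  binary.
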