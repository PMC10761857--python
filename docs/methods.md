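# Methods

This note documents the models, algorithms and numerical choices behind
`porecolony`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Pore-space discretization

A porous medium is a binary raster (pore = 1, solid = 0) with physical
pixel size in µm. Conventions: 0-based row-major coordinates, solid phase
8-connected, pore phase 4-connected (the standard complementary pair that
avoids topological paradoxes on a grid).

**Disk map.** The maximum inscribed disk radius at a pore pixel is the
exact Euclidean distance to the nearest solid pixel centre
(`scipy.ndimage.distance_transform_edt`); it is checked against an O(N²)
brute-force nearest-solid search in the tests.

**Skeleton.** The medial axis (ridge of the distance transform,
`skimage.morphology.medial_axis`) rather than iterative thinning: medial
points are genuine centres of maximal disks, which the segregation index
relies on; thinning can leave branch pixels hugging one wall in wide
junctions. The pseudo-random tie-break order of the thinning is pinned
(`rng=0`) so skeletons — and everything derived from them, e.g. per-DEP
depths — are bit-reproducible.

**Segregation index and DEP rule.** At each skeleton point with inscribed
radius r, solid pixels within 2.5 px of the disk boundary (|d − r| ≤ 2.5,
a band wide enough to absorb raster staircase error) form the tangency
set; ζ_seg is the number of distinct grain labels in it. Counting grains
alone is not sufficient on a raster: a disk in an open junction just
outside a cavity mouth touches only the cavity's two mouth corners — one
grain, but only two tangency points. The defining property of a dead-end
cavity is tangency in *three or more* points of one grain, which is
operationalized by the angular spread of the tangency set around the disk
centre: inside a slot the contacts sit on opposing walls (spread ≥ 180°),
outside the mouth they cluster in front of the disk. A skeleton point
seeds a DEP iff ζ_seg = 1 and the spread is ≥ 160° (the 20° margin absorbs
pixelation); every other point seeds TP. An open domain edge (the crop
boundary at inlet/outlet) inside the band counts as one extra pseudo-grain,
since the pore continues past the crop; such points are flagged.

**Pixel assignment.** Labels propagate from skeleton seeds to pixels by the
maximal-disk covering rule: a pore pixel covered by the inscribed disk of
any TP point is TP; otherwise, if covered by a DEP-point disk, DEP. TP wins
overlaps, which keeps DEP entrances conservative; the few raster pixels
covered by no maximal disk fall back to nearest-seed with ties to TP.
(Plain nearest-seed assignment leaks DEP labels into wide junctions,
because junction pixels near a mouth can be Euclidean-closer to the
cavity's internal skeleton than to the junction centreline.) Pore
components with no TP seed are isolated cavities: labelled DEP, flagged
unreachable.

**Per-DEP records.** DEP regions are 4-connected components of the DEP
label; entrances are DEP pixels 4-adjacent to TP; the depth L is the
skeleton arc length (8-connected graph, diagonal weight √2) from the
entrance point — the DEP skeleton point adjacent to a TP-labelled point —
to the farthest DEP skeleton point. The local pore size is λ = 2r at every
skeleton point (sampling at every point rather than a stride is a free
choice; only the mean and spread are used).

Mirror images can differ from the mirrored classification by single pixels
at even-width cavity mouths (raster medial-axis ties); 90° rotations are
exact. The closed-loop tests require exact label agreement with the
generator's construction truth on all pixels farther than one cavity width
from an entrance, over 20 seeded geometries.

## Stokes flow

Creeping flow is driven by ghost pressure reservoirs attached to the left
(inlet) and right (outlet) edges; top and bottom are sealed. The
discretization is a staggered (MAC) grid — u on vertical faces, v on
horizontal faces, p at pore-cell centres — with no-slip represented by
mirror ghost values (the wall lies half a cell inside the solid), which
recovers Poiseuille profiles in straight channels to second order
(centerline/mean = 1.5 within 2% at 24-cell width). Momentum and
continuity form one sparse saddle-point system solved directly
(`scipy.sparse.linalg.spsolve`), so the discrete divergence of every
accepted solution is at solver precision (measured ~1e-14 relative;
the accepted tolerance is 1e-8 of the mean velocity per pixel). Pore
components not connected to both open edges carry exactly zero velocity.
Because Stokes flow is linear, the unit-pressure solution is rescaled to
match either the imposed flow rate Q through the chip thickness h (2D flux
Q/h) or a target mean pore velocity u_m; the shear rate is u_m/h. The
thickness h enters only through flux conversion and shear — the flow is
plane 2D, with no Brinkman drag for the shallow third dimension
(documented simplification).

## Tracer transport

Finite-volume advection–diffusion on the pore cells, using the Stokes face
velocities directly. Two stepping schemes:

* explicit first-order upwind advection (monotone, CFL-limited, default)
  combined with backward-Euler diffusion factorized once;
* fully implicit upwind: advection folded into the backward-Euler matrix.
  The velocity field is steady, so one factorization serves every step and
  the step size is limited only by accuracy. Used for long displacement
  runs; on a toy cavity scene it reproduces the explicit persistence times
  exactly, with first-order smearing that grows with dt (at dt = 1 s and
  u ≈ 25 µm/s the numerical diffusion is below the physical
  D = 6×10⁻⁴ mm²/s).

Boundary conditions: fixed concentration at the inlet (Dirichlet ghost at
half-cell distance for diffusion, upwind donor for advection), advective
outflow with zero diffusive gradient at the outlet, no flux at solids and
sealed edges; `inlet_value=None` seals the inlet entirely (used for the
pure-diffusion oracle, which matches the closed-form error-function
profile within 1%). A per-step mass budget (boundary fluxes vs mass
change) is tracked; the residual is at machine precision (~1e-16, well
inside the 0.1% requirement). Concentrations stay in [0, 1] by
monotonicity of the upwind/backward-Euler pair.

**Gradient persistence.** For each DEP, the concentration difference Δ(t)
between 5-px strips on either side of the entrance is tracked; the
persistence time is the last saved time with |Δ| above 10% (configurable)
of the *largest* difference the displacement develops at that DEP. The
reference cannot be the t = 0 difference — the initial field is uniform
and the difference is exactly zero; the fully developed gradient is the
natural contrast scale. A DEP whose gradient never develops reports 0.

## Synthetic scenes and what they do (not) emulate

**Geometry.** Grains are rectangles on a jittered lattice separated by
channels of width equal to the target mean pore size; the top and bottom
edges carry solid wall strips, so the medium percolates left to right.
Dead-end cavities — rounded-end slots with depth/width = `cavity_aspect`
(> 1, so they classify as DEP) — are carved into randomly chosen grain
sides until the requested DEP volume fraction (default 8% ± 2%) is met;
the last cavity is shortened to land the fraction, never below 1.2 widths.
Leftover lattice space is absorbed into the walls and the inlet/outlet
manifolds, never into the channels: parallel channels of unequal width
would carry unequal speeds and disperse a displacement front over
centimetres, destroying the entrance gradients the transport analysis
measures. Defaults follow the study conditions: 0.65 µm/px, mean pore size
0.04 mm, DEP depth 0.2 mm, DEP fraction 8%. What is *not* emulated: the
hyperuniform, spinodal-like disorder of the real medium (only porosity,
pore size, DEP fraction and depth are matched), pore-size polydispersity
beyond lattice jitter, and 3D effects. Passing closed-loop tests therefore
shows the chain is correct on media with the right statistics, not that it
is robust to arbitrary natural pore shapes.

**Imaging.** Biomass renders as additive attenuation of a constant bright
background (bright field), with Gaussian read noise seeded independently
of the geometry; frame 0 is background only. Per frame, the deposited
signal has area-normalized class means in the imposed DEP:TP ratio, either
uniform or concentrated in equal-intensity discs ("colonies") whose
centres and masses are recorded. The reporter channel is biomass ×
sigmoidal depth activation (front depth and steepness prescribed; a scalar
front is capped at each cavity's depth). No photobleaching, no optical
PSF, no drift: corrected synthetic stacks are registered by construction.
The imaging noise level is not reported in the source study; the default
is 1% of the background and is configurable. 16-bit quantization makes
"exact" closed-loop recovery exact only to rounding (±1 intensity unit per
pixel).

## Biomass quantification

Bright-field correction is background − frame (cells darken the image),
fluorescence is frame − background; negatives clip to zero and solid
pixels are zeroed. Cluster detection per region (each DEP independently,
the TP network as one region): threshold = multiplier (default 1) × mean
intensity of the regional maxima, where maxima are 8-connected local
maxima of the 3-px median-smoothed frame restricted to the region;
clusters are 8-connected components of raw pixels at or above the
threshold. Colony mass-per-area densities use 64 logarithmic bins spanning
the observed range, normalized to unit integral. The retention curve is
the ratio of area-normalized class means, undefined (NaN) when the TP mean
sits below a floor; biomass series are class sums with
B_tot = B_tp + B_dep exact by construction. All ratios and partitions are
invariant to the intensity scale.

## Reporter profiles

Activity = reporter / biomass where biomass ≥ floor. Depth profiles sample
the DEP skeleton at the points nearest to arc lengths 0, 10, 20, … px from
the entrance (s = 0 at the DEP–TP juncture) and average activity within
the maximal inscribed disk clipped to DEP pixels — clipping avoids
contaminating entrance samples with TP signal. The front is the smallest s
with activity ≥ 80% of the profile's own maximum (per-profile maximum, not
a global one), linearly interpolated between samples. Cross-DEP averaging
resamples on normalized depth s/L before rescaling to the mean L.

## Glucose/AI-2 model

Uniform node-centred grid on [0, L], node 0 on the DEP–TP juncture;
defaults L = 0.2 mm, dx = L/200, dt = 0.1 s. Backward-Euler diffusion with
a conservative flux discretization: with both ends sealed and no
consumption the trapezoid-weighted glucose integral is conserved to
~1e-15 per step. Glucose: Dirichlet c_G = c_0 (5 mM, the feed
concentration) at x = 0, no-flux at L; the uptake term U_1c·c_B
(U_1c = 10 mMol s⁻¹ g⁻¹ dry mass) acts only where c_G > 0 and the field
is clamped to [0, c_0] (the unclamped equation would drive negative
concentrations). AI-2: Dirichlet 0 at x = 0 (perfect advective washout in
the TP — the source states advection removes AI-2 but gives no boundary
condition), no-flux at L, production k_A+·c_B everywhere and uptake
k_A−·f·c_B where the glucose switch f = 1 (c_G below θ_G = 0.01·c_0).

The AI-2 production/uptake rates are not reported; defaults are
k_A+ = 1×10⁻⁶ and k_A− = 2×10⁻⁶ mM s⁻¹ per (g/L). Uptake exceeding
production once derepressed is the biologically expected regime — Lsr
import collapses extracellular AI-2 when the system activates — and the
normalized lsrR signal is insensitive to the absolute scale of the rates.
D_A comes from Stokes–Einstein with hydrodynamic radius ∝ mass^(1/3)
(glucose 180.16 g/mol; AI-2 taken as DPD, 132.12 g/mol, configurable —
which AI-2 species applies is genuinely open).

For lsrR = (1 − c_A)(1 − c_G), glucose is normalized by c_0 and AI-2 by
the steady production scale k_A+·c̄_B·L²/D_A (switchable to the
instantaneous domain maximum). The production scale is the default
because instantaneous-max normalization forces the deep AI-2 factor to
zero — the deep lsrR plateau vanishes and the extracted front loses its
√(D·τ_U) scaling; with the production scale the front ζ_sim tracks
ζ = √(D·τ_U) (log–log slope vs τ_U 0.53 across a 100× biomass range,
ratio 0.88 at defaults). The default DEP biomass for model runs is
c_B = 0.03 g/L dry mass (~10⁸ cells/mL at 3×10⁻¹³ g/cell, a dense but
realistic colonized cavity), which puts ζ at L/2. Biomass can be a
scalar, a profile, or piecewise-constant frames in time; with growing
biomass the front moves monotonically toward the entrance, the regime the
time-resolved measurements probe (with static biomass the front simply
relaxes to its steady position).

## Problem sizes

Tests and examples run coarsened scenes (4 µm/px, 256×320, 0.1 mm DEPs)
whose every geometric ratio matches the defaults; the generator's
full-scale defaults (0.65 µm/px, 1024²) are exercised where only the
geometry is needed. The displacement scenario
(`porecolony.scenarios.tracer_persistence_study`) coarsens the pixel pitch
to 8 µm and the lateral extent to one grain row but keeps the 28.8 mm
streamwise extent at full scale, because the device length — one pore
volume at u_m = 20 µm/s, i.e. 24 min — is what sets how long entrance
gradients survive anywhere in the medium: gradients at a given DEP form
when the displacement front arrives and decay a few diffusive times
(T_d = L²/D ≈ 67 s) later, so the farthest DEPs keep detectable gradients
past one eluted pore volume (measured maximum ≈ 32 min).

## Known limitations

* Strictly 2D: no Taylor dispersion across the chip thickness, no 3D
  vortex structure inside cavities, no oxygen field.
* Biomass dynamics are imposed, not emergent: no motility, chemotaxis,
  growth or detachment model — the generator's phenomenological curves
  stand in for them.
* First-order upwind advection smears sharp fronts by one cell per
  transit; acceptable for threshold-based persistence measures, not for
  dispersion coefficients.
* The classification is only as good as the mask: noisy experimental masks
  would need cleaning (not included) before discretization.
* lsrR is an algebraic readout of the two fields, not a gene-expression
  dynamic model; absolute reporter units are arbitrary.
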