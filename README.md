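# porecolony

Pore-scale analysis of bacterial colonization in heterogeneous porous media.

Microbial habitats such as the gut mucosa, soils and sediments are not
well-mixed: they are porous structures in which advection-dominated
channels coexist with stagnant, cavity-like pockets. `porecolony`
re-implements, as a tested Python library, the computational chain used to
study how *E. coli* colonizes such a medium in a quasi-2D microfluidic
model: transmitting pores (TPs) carry the flow, dead-end pores (DEPs)
exchange solutes only by diffusion, and the interplay of nutrient
depletion, autoinducer-2 (AI-2) accumulation and chemotaxis concentrates
biomass and quorum-sensing (QS) induction inside the DEPs.

It is written for microbial-ecology and biophysics groups who need to go
from raw time-lapse images of a porous micromodel (or fully synthetic
scenes with ground truth) to quantitative statements about where bacteria
accumulate and where QS switches on.

## What it computes

* **Pore-space discretization** (`porecolony.geometry`). From a binary
  mask (pore = 1, solid = 0) the maximum inscribed disk map, the medial
  skeleton, and a segregation index ζ_seg — the number of distinct solid
  grains touched by the maximal inscribed disk at each skeleton point. A
  disk lodged in a cavity touches a single grain in three or more points
  (ζ_seg = 1, DEP); a channel disk touches at least two grains
  (ζ_seg > 1, TP). The result is the "mapped mask" {0 solid, 1 DEP, 2 TP}
  plus per-DEP entrances and depths L, the local pore size
  λ = 2·r along the skeleton, and the DEP volume fraction.
* **Flow and solute transport** (`porecolony.flow`, `porecolony.transport`).
  2D steady incompressible Stokes flow on the mask (staggered-grid sparse
  saddle-point solve; divergence-free to solver precision), the average
  shear rate u_m/h, and advection–diffusion of a passive tracer for
  displacement experiments, with the persistence time of DEP-entrance
  concentration gradients and the diffusive scale T_d = L²/D.
* **Biomass quantification** (`porecolony.biomass`). Background
  subtraction (bright field as attenuation), per-DEP colony detection by
  regional-maxima thresholding, colony mass-per-area distributions, the
  retention curve C_dep/C_tp(t), and class-resolved biomass series with the
  DEP partition B_dep/B_tot.
* **Reporter profiles** (`porecolony.reporter`). Biomass-normalized
  reporter activity, disk-averaged depth profiles along each DEP skeleton
  (every 10 px), and the activation front: the shallowest depth where
  activity reaches 80% of its maximum.
* **Glucose/AI-2 model** (`porecolony.qsmodel`). The coupled 1D system
  along a DEP of depth L (x = 0 at the DEP–TP juncture):

      ∂c_G/∂t = D_G ∂²c_G/∂x² − U_1c·c_B
      ∂c_A/∂t = D_A ∂²c_A/∂x² + k_A+·c_B − k_A−·f·c_B
      lsrR    = (1 − c_A)(1 − c_G)        (normalized fields)

  with f = 1 where glucose falls below a threshold (catabolite repression
  lifted), solved by backward Euler, and the glucose-limitation length
  compared two ways: the scaling ζ = √(D·τ_U) with τ_U = c_0/(U_1c·c̄_B),
  and the simulated lsrR front ζ_sim.
* **Synthetic scenes** (`porecolony.synthetic`). Percolating grain-lattice
  geometries with carved cavities (8% DEP fraction, 0.2 mm depth,
  0.04 mm mean pore size at 0.65 µm/px by default) and bright-field /
  GFP / tracer stacks with exact ground truth, so the whole chain is
  testable closed-loop without any measured data.

A thin CLI (`porecolony simulate|classify|flow|quantify|profile|model|run-all`)
orchestrates end-to-end runs from a YAML config; `porecolony.pipeline`
exposes the same as a function.

## Worked example

`examples/` holds one short script per capability. For instance,
`examples/05_glucose_qs_model.py` prints:

```
AI-2 diffusivity (Stokes-Einstein)  6.653e-04 mm^2/s
glucose consumption time tau_U      16.7 s
scaling length sqrt(D tau_U)        100 um
t =    60 s  simulated lsrR front at  88.8 um
t =   200 s  simulated lsrR front at  88.0 um
t =   600 s  simulated lsrR front at  88.0 um
final front / scaling ratio         0.88
```

With the default biomass (0.03 g/L dry mass) glucose is consumed faster
than diffusion can resupply beyond about 0.1 mm: the simulated lsrR front
settles at 88 µm, in agreement with the √(D·τ_U) estimate — QS induction
is confined to the back of the dead-end pore.

And `examples/03_biomass_retention.py` (2 h synthetic colonization with 1%
read noise):

```
time(min)  PV    C_dep/C_tp  truth   DEP partition
     10   0.4      1.003   1.00         0.082
     40   1.7      1.412   1.41         0.111
     80   3.3      1.957   1.95         0.148
    120   5.0      2.499   2.50         0.181
```

The recovered retention curve tracks the imposed DEP enrichment within a
few per cent.

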