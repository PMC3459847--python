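# Methods

`omgrowth` simulates the growth of the Gram-negative outer membrane (OM) as
a two-dimensional, incompressible, viscous fluid on the cylindrical part of
the cell surface, driven by bursty, spatially random insertion of new
material. It also implements the virtual widefield microscope and the
puncta analytics used to compare such simulations with labelled-porin
(e.g. LamB) time-lapse experiments. This note records the model, its
assumptions, the numerical choices, and what the synthetic data do and do
not demonstrate.

## The physical model

The OM is treated as a 2D Stokes fluid without diffusion: on the time
scale of a cell cycle, membrane proteins and LPS are effectively immobile,
so the only motion of material is advection by the flow created by growth.
The cylindrical geometry is held fixed in radius (R = 0.5 µm by default);
insertion elongates the cell. The hemispherical poles are not simulated:
the flow converges symmetrically onto inert polar regions at the two ends
of the growing cylindrical domain, and material swept past the domain ends
never re-enters — the mechanism of polar retention.

Insertion is a three-parameter stochastic process:

* events initiate as a Poisson process with areal rate `k_on` (µm⁻² s⁻¹),
  uniformly over the current cylindrical surface;
* an active event injects membrane area at rate `k_ins` (µm² s⁻¹);
* each event lives for an exponentially distributed duration with mean `τ`
  (a single kinetic termination step), so the mean area inserted per event
  is `τ·k_ins` — the patchiness scale of the model.

### Mean-field law and the doubling-time constraint

Averaging over realizations, the area A and active-site count n obey the
linear system

    dA/dt = k_ins · n
    dn/dt = k_on · A − n/τ

whose dominant eigenvalue λ solves λ² + λ/τ = k_on·k_ins; growth is
asymptotically exponential with doubling time t₂ = ln2/λ, and the
site concentration on the dominant eigenvector is n/A = λ/k_ins.
Fixing t₂ pins τ = λ/(k_on·k_ins − λ²), which requires
k_on·k_ins > λ²; `solve_tau` raises an explicit infeasibility error
otherwise. For the headline parameters (k_on = 0.004 µm⁻² s⁻¹,
k_ins = 0.00064 µm² s⁻¹, t₂ = 90 min) this gives τ ≈ 50 s and a mean
insertion size of ≈ 0.032 µm². `meanfield_trajectory` evaluates the
matrix exponential of the 2×2 system, so it is exact rather than a
discretized integration.

### Flow field on the wrapped cylinder

On the unwrapped strip (x axial, y circumferential with period P = 2πR) an
active event is a 2D point source of area flux Q: v = (Q/2π)·r̂/|r|.
Periodicity is enforced by the method of images — summing the source's
copies displaced by kP in y. The implementation truncates the image stack
symmetrically at 21 terms (k = −10…10) and then adds the analytic
remainder of the infinite series: the integral tail in closed form
(arctan/log) plus the next Euler–Maclaurin boundary term. This matters
because the naive truncated monopole sum converges only like 1/k_max in
the axial component (≈5% error one circumference away from the source);
with the analytic remainder, the field matches the exact closed form

    v_x = (Q/2P)·sinh(2πΔx/P) / (cosh(2πΔx/P) − cos(2πΔy/P))
    v_y = (Q/2P)·sin(2πΔy/P)  / (cosh(2πΔx/P) − cos(2πΔy/P))

to better than one part in 10⁴ everywhere tested (measured worst case
8×10⁻⁶). The closed form itself is kept as an independent oracle in the
tests, not as the production path, so the two derivations check each
other. `tail_correction=False` recovers the naive truncated sum for
fidelity studies.

Far from all sources the field tends to a uniform axial outflow ±ΣQ/(2P),
so the total flux budget is conserved exactly: domain area always equals
initial area plus cumulative inserted area (the "area ledger", exact to
rounding in the simulator).

## Simulation mechanics

Time stepping uses dt = min(τ/20, 1/(20·k_on·A), 0.5 s): at least ~20
steps per mean event lifetime and initiation interval, capped at 0.5 s.
Within a step, each active source carries flux Q = k_ins scaled by the
fraction of the step its event is alive, so each event inserts exactly
k_ins·duration regardless of dt.

* **Event birth.** A new event seeds a regular polygon of area
  k_ins·min(dt, duration) at its site. The seed area is also injected as
  flux so the ledger stays exact, but the newborn polygon's own vertices
  exclude their own source for that one step (their area was already
  granted); without this the ledger leaks k_ins·dt per event (≈1% at the
  headline parameters), enough to bias doubling-time comparisons.
* **Vertex count.** A ring of n material points on a circle encloses only
  n·sin(2π/n)/2π of the enclosed material (straight-edge deficit
  ≈ (2π/n)²/6). The vertex count n = clamp(round(20 + 8·log₁₀(m/10⁻³)),
  8, 64), with m the expected patch area, keeps this representation error
  below ~1% at the headline insertion size (n = 32 → 0.3%).
* **Self-advection.** A source is advected by the other sources only: its
  own monopole is singular at its position and its own periodic images
  cancel there exactly, so the self term is excluded outright. Its patch,
  by contrast, expands under the full field including the patch's own
  source — that is what converts flux into patch area.
* **Domain ends.** The ends move with the circumferentially averaged axial
  flow, which is exactly ±ΣQ/(2P) per source (signed away from it). This
  is the collective motion of the end ring and makes the ledger exact; a
  single-point sample would add noise without physical content.
* **Integration.** Explicit Euler by default; midpoint (RK2) behind
  `scheme="rk2"`. Passive-polygon area drift is dominated by polygon
  resolution rather than the integrator (measured <0.1% over 100 steps at
  dt = 0.1 s for a 16-gon).
* **Labels.** New material is labelled per the light/dark schedule
  (default 15 min light, 75 min dark, mimicking label-and-chase). Later
  events landing inside an existing patch grow as islands that the host's
  simple polygon cannot exclude; `material_area` therefore reports label
  areas as polygon unions minus cross-label overlap. With that correction,
  light material is conserved after the light phase to ≲0.1%.
* **Decoupling for area observables.** Patch polygons are passive tracers:
  the joint law of (A(t), n(t), event areas) is independent of patch
  geometry. `track_patches=False` exploits this to run large ensembles
  (e.g. 100 replicates of 90-minute growth in ~25 s) for doubling-time
  and mean-field comparisons.

## Virtual microscope

Light-labelled polygons are rasterized at sub-pixel resolution (17 nm
default) on the strip as fluorophore density, with each polygon's
deposited mass normalized to its exact shoelace area to suppress raster
quantization. The strip is wrapped onto the cylinder: arc coordinate θ
maps to projected lateral position R·sinθ at defocus R·cosθ (focal plane
through the axis). The density is partitioned into z-bands (13 by
default), each convolved with a defocus-dependent Gaussian PSF
σ(z) = σ₀√(1+(z/z_R)²), σ₀ = 0.21·λ/NA ≈ 86 nm, z_R = 2λn/NA² (n = 1.515),
attenuated by a Strehl-like factor 1/(1+(z/z_R)²), summed, and integrated
onto 68 nm camera pixels (6.8 µm physical pixels at 100×). The arc-to-η
compression near the tangent lines makes the cell periphery bright, as in
real widefield images of surface-labelled cells. A Born–Wolf scalar PSF is
left as an explicit extension stub; puncta metrics depend mainly on the
lateral width, which the Gaussian model captures.

Noise: expected photon counts are Poisson-sampled, then a constant
background offset and Gaussian read noise (sd 2 counts) are added; pixel
variance on flat fields is signal + read² by construction. The photon
scale (counts per µm² of labelled material) defaults to 5×10⁴ so that a
headline-size punctum carries ~1600 photons (peak SNR ~12); all noise
parameters are configurable and no analysis depends on absolute
intensities.

## Puncta analytics

* **Detection**: local maxima above median + 5·MAD (scale-invariant),
  merged below a minimum separation defaulting to the Rayleigh radius
  0.61·λ/NA ≈ 250 nm, refined by a symmetric 2D Gaussian fit (weighted
  centroid as fallback).
* **Linking**: greedy shortest-first nearest-neighbour assignment within
  300 nm per frame step. A spot that appears within the split radius of
  where a continuing track was one frame earlier is annotated as that
  track's split child — the signature of a dark wedge bisecting a punctum.
* **Kymographs**: intensity along the top cell edge (η = +R), taken as the
  maximum over a ±1 pixel band because the edge generally falls between
  camera rows; axial coordinate either absolute or rescaled to the growing
  cylindrical region.
* **Count curves and sigmoid metrics**: per-frame counts (top-edge or
  whole-cell convention, both exposed) averaged over replicates; a
  logistic N_max/(1+exp(−(t−t₀)/s)) is fit, reporting N_max and the
  initial appearance rate as the maximum slope N_max/(4s), optionally per
  µm of cell perimeter (projected outline 2L + 4R). Degenerate inputs
  (plateau-only, unresolved rise) are flagged ill-conditioned rather than
  silently accepted.
* **Divergence**: adjacent track pairs (ordered axially) contribute
  separation-versus-time series and an exponential-rate fit; pairs near
  the domain ends are labelled polar. Uniform exponential growth implies
  material-point separations grow at λ = ln2/t₂; the simulation
  reproduces this within ensemble error, and the k_on = 0 (growth
  arrested, rifampin-like) limit gives bitwise-static geometry and zero
  divergence.

## Parameter screen

The screen fixes the doubling time and varies the kinetics over a grid
that is log-spaced in the natural axes τ (0.1–200 s) and mean insertion
size τ·k_ins (2×10⁻⁴–1 µm²), mapping each node back to the unique
(k_on, k_ins) pair — every node is feasible by construction, and the
default 10×10 grid plus the headline pair gives 101 parameter sets, with
21 replicates each by default. Each pair runs the full
simulate → render → detect → count → fit pipeline deterministically
(replicate r of pair i uses seed base + 1000·i + r). Classification
against experiment-derived intervals of appearance rate and maximum count
is plain interval membership; the bounds are user input (shipping
hard-coded "truth" would misrepresent graphically read experimental
levels), and the summary reports the k_on and τ·k_ins extent of the
doubly-consistent region.

## What the synthetic data show — and what they do not

The generator produces exactly the study conditions the model defines:
headline kinetics, 90-minute doubling, 15/75-minute light/dark schedule,
R = 0.5 µm, L₀ = 2 µm. Tests demonstrate internal consistency (ledger,
mean-field equivalence, oracle agreement) and the optical phenomenology
(merging below the Rayleigh separation, splitting by PSF-width dark
wedges, rise-then-plateau counts, patchiness ordering in τ·k_ins). They
do not validate the model against real micrographs: real cells add
septation, pole geometry, labelling chemistry, focus drift and camera
artifacts that the virtual microscope deliberately omits, and numeric
experimental puncta-per-cell levels are not bundled with the package.

## Problem sizes used in the shipped checks

Ensembles are sized to keep the full suite fast while leaving comfortable
statistical margins: 100 replicates for area observables (doubling time,
mean-field checkpoints; ~20,000 insertion events), 2–3 replicates for
image-pipeline behaviours, and three-pair mini-screens for the scan
mechanism. All are driven by explicit seeds and scale up by changing one
argument.

## Known limitations

* Explicit Euler vertex advection under-resolves strong local shear when a
  new event fires very close to an existing patch boundary; island
  bookkeeping corrects areas but vertex rings can become locally coarse
  over multi-generation runs.
* Greedy linking has no global assignment or gap closing; it is adequate
  for the sparse, slowly moving puncta regimes the model produces.
* The Gaussian defocus PSF ignores vectorial high-NA effects and treats
  the Strehl attenuation phenomenologically.
* The simulator covers one cylindrical compartment: no division,
  septation, or explicit pole caps.
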