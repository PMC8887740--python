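# Model and numerical methods

`acam` simulates a 2D epithelial tissue in which every cell's junctional
actomyosin cortex is an explicit, continuous viscoelastic rope-loop, and
neighbouring cortices are coupled by discrete, turning-over adhesion
bonds.  Cell vertices are *geometric* meeting points, not material ones:
cortical material can flow past a vertex from one bicellular junction to
the next, and neighbour exchanges (T1 transitions) are continuous
processes rather than discrete topological moves.

## The cortex rod

Each cortex is a closed planar rod with bending and stretching
resistance.  Lengths are nondimensionalised by the adhesion bond rest
length δ₀ (the equilibrium inter-cortical spacing, ~30–40 nm in
epithelia), energies by the cortex extensional stiffness, and time by the
cortical turnover timescale τ_cor (~50 s).  The instantaneous elastic
energy of a cortex is

    U = ∮ [ ½ κ² c(S)² + ½ ε(S)² ] dS ,

with curvature c = ∂θ/∂S, strain ε = α − 1, and κ² the dimensionless
ratio of bending to stretching moduli.  Activity enters
morphoelastically: the undeformed configuration (natural lengths ℓ̂) is
first contracted by an active factor γ ∈ (0, 1] — loading a region with
motors is equivalent to substituting segments of shorter rest length —
and external forces then impose an elastic stretch α, so the total
stretch factorises as λ = γα and only α generates stress.  A free rod
contracts stress-free (λ = γ, ε = 0); a held rod builds tension
ε = (1−γ)/γ.

Discretely, a loop is a polygon of nodes; segments carry ℓ̂ and γ, hinges
carry turning angles, and the energy is the standard discrete-rod sum
(turning angle per reference arc length for the curvature).  Nodal forces
are the exact analytic gradient of this energy (verified against central
differences to 1e-6 relative), so energy minimisation and force balance
are one and the same.

## Adhesion bonds

A bond is a saturating Hookean spring between a cortex node and a node of
a *different* cell (or a fixed boundary wall):

    W(δ) = ½ ω (δ − 1)²  for δ ≤ δ_max,   constant beyond,

so bonds never transmit force beyond the maximum binding length δ_max,
and push apart below the rest length, maintaining the inter-cortical
spacing.  Per-bond stiffness is ω · h, where h is the node spacing, so
that the adhesion energy *per unit cortex length* is ω(δ−1)²/2 regardless
of discretisation (verified by an h-independence test).

Unpaired nodes re-bind instantaneously: a seeking node's candidates are
the nearest point of each foreign cortex within δ_max (adhesion molecules
link apposed membranes — a candidate whose bond would cross a third
cell's cortex is occluded), and the partner cortex is chosen with
probability proportional to the inverse candidate distance.  Bonds are
therefore born near-normal at the local gap; shear angles grow only by
subsequent cortex–cortex sliding.  Each bond lives for an exponentially
distributed time of mean τ_adh drawn at birth, realising the relaxation
of the bond-density field towards its rebinding distribution at rate
1/τ_adh.  Bonds crossed by an intervening cortex are severed at turnover.
A sheared, turning-over bond population produces an emergent viscous
friction between apposed cortices with coefficient μ_adh = ω τ_adh
(verified: linear in ω and in τ_adh over a decade each).

Three adhesion modes are used:

* **agent-based** (default, τ_adh ≥ τ_cor): explicit bonds with turnover;
* **fast-turnover** (τ_adh < one step): the whole transient bond set is
  resampled from the binding kernel every step;
* **deterministic instantaneous rebinding** (static fixed-point problems):
  every node holds fractional bonds to the nearest point of each
  reachable foreign cortex, weighted by the kernel — the deterministic
  expectation of the stochastic scheme, used where a reproducible,
  seed-free equilibrium is required (vertex-geometry map, fracture ramp).

## Quasi-static viscoelastic dynamics

One simulation step corresponds to one cortical turnover time and runs:

1. the activity protocol re-imposes its γ field (background pre-stress
   γ₀ everywhere, active values on sensed regions);
2. bond turnover and re-binding (or resampling in the fast regime);
3. energy minimisation over all node positions (L-BFGS on the assembled
   energy; bond topology and rest lengths frozen; energy non-increasing;
   residual per-node force below the tolerance at convergence);
4. observables are recorded;
5. viscoelastic relaxation: every undeformed segment length is set to the
   current length and γ resets to 1 — complete relaxation of residual
   elastic stress within one cortical turnover time.  Sustained activity
   therefore maintains a steady strain (1−γ)/γ while transient stress
   drains away.

Static problems (the vertex-geometry map) iterate steps 2–3–5 until the
total cortex length changes by less than 1e-4 per cycle, with the
rest-length update under-relaxed (factor 0.5) to damp the rebinding
limit cycle; the fixed point is unchanged.

### Numerical regularisation

Two closures stabilise long runs; both are ours (the model's printed
energy contains neither), both are documented limitations:

* **Continuum re-discretisation.** After each step the loop is resampled
  at uniform current arclength with a light circular Gaussian smoothing
  (σ = 0.5 δ₀, the physical thickness scale of the cortex rod, below
  which shape features are meaningless).  Total undeformed length is
  conserved exactly, material labels ride along by interpolation, bonds
  re-attach by material label, and the small area perturbation from
  smoothing is absorbed by the areal elasticity (an exact isotropic
  restore was tried and rejected: it re-inflates freshly contracted cell
  tips into the vertex and blocks junction extension).  Without this
  re-discretisation, discrete bond churn
  under complete stress relaxation locks sub-resolution zig-zags into the
  rest lengths (a ratchet) and multicell runs degrade into tangles;
  κ = 0.01 bending is far too weak to iron node-scale wiggles.
* **Weak areal elasticity.** Each cell carries
  E_A = (k_A/2)(A/A₀ − 1)² A₀ with k_A = 0.03 (3 % of the cortex
  extensional modulus).  The value follows a Laplace balance: the active
  tension scale (1−γ) ≈ 0.06 over a cell radius ≈ 8 δ₀ gives a pressure
  that at k_A = 0.03 corresponds to transient area strains of a few tens
  of percent, the scale intercalating epithelial cells exhibit in vivo —
  junctional forces, not the stabiliser, govern the area response.  Without it, bond turnover
  under complete stress relaxation performs net mechanical work and the
  tissue coarsens: neighbours wet around any cell that loses area, and
  the intercalating pair collapses.

## Tissue fixtures

Cells are laid out on a hexagonal packing; each cortex is the cell
polygon offset half a rest length inward, so apposed cortices start one
rest length apart, near mechanical equilibrium.  There is no canonical
cell size for this model class, so the package picks, once:
hexagon edge 8 δ₀ for the 14-cell neighbour-exchange fixture (junction
length ≈ 6–8 δ₀, comfortably larger than the sensing range δ_γ = 4 so
contractility stays junction-localised), edge 6 δ₀ for the 3-cell
fixture, wall hexagon side 10 δ₀ for the single-cell fixture.  Node
spacing is 0.4 δ₀ for multicell dynamics, 0.15–0.25 δ₀ for statics.  A
run of the standard T1 at these sizes takes a few minutes on one CPU.
The outer boundary of the 14-cell patch is a fixed wall; cortex nodes
adhere to it by ordinary bonds, and wall angular points carry permanent
extra-stiff pins (50 ω) that hold tissue vertices at the boundary
corners.

Default parameters: κ = 0.01, ω = 0.05, δ_max = δ_γ = 4, τ_adh = 10,
γ₀ = 1 − 2·10⁻⁴ background pre-stress (mimicking tissue-scale tension;
it also regularises the zero-tension degeneracy of a fluid rod), active
contractility γ = 0.94 on the shrinking junction.

## Identity-sensing contractility

Contractility on a junction pair is purely range-based: a cortex segment
of either cell becomes contractile when it lies within the receptor range
δ_γ of the partner cell's cortex.  The contractile region shrinks with
the junction, persists across the 4-way configuration (where it drives
resolution), and empties once the new junction's extension separates the
pair beyond δ_γ.  Removing the protocol freezes γ at the background γ₀,
which is how the stall experiment is realised.

## Junction and vertex bookkeeping

Each node is labelled by its nearest bonded partner cell; maximal cyclic
runs of a common partner (bridging unbonded gaps of up to 2 nodes) are
junction intervals.  Runs shorter than L_min = 2 δ₀ — about the vertex
diameter scale — count as part of a vertex, because bonds legitimately
form across an open vertex and raw bond topology cannot distinguish a
short junction from a 4-way.  Partner transitions and sub-threshold runs
contribute vertex candidates, clustered within 2 δ₀ (with a centroid
refinement pass against single-linkage chaining).  The vertex opening
δ^vert is the radius of the largest circle inscribed in the cortex-free
region, found by maximising the minimal distance to the member cortices
from the vertex position (Nelder–Mead), cross-checked against shapely's
maximal inscribed circle where the free region is a polygon.

## What the fixtures do and do not emulate

The synthetic fixtures are regular hexagonal packings with identical
cells and a rigid pinned boundary; real germ-band tissue has disordered
polygonal packings, heterogeneous cell sizes, fluctuating activity and
medial (non-junctional) myosin pools, none of which are modelled.
Passing the package's tests therefore demonstrates the junctional
mechanisms — contraction, slippage-limited shrinkage, passive extension,
friction-controlled rosette formation — in a clean geometry, not
quantitative agreement with any particular embryo.

## Known limitations

* The passive vertex opening at (κ, ω) = (0.01, 0.05) converges to
  ≈ 0.55 δ₀ here (the wall-offset geometry plus a weak bending
  correction), and the uniform-contraction fracture threshold lands near
  γ ≈ 0.96.  Other realisations of this model class report substantially
  larger openings (≈ 1.4 δ₀) and earlier fracture (γ ≈ 0.93): the vertex
  compliance is sensitive to binding-kernel and relaxation details for
  which the model family admits several defensible choices, and this
  package's declared choices land on the stiff side.  The isoline
  structure (equal openings at equal κ²/ω, openings decreasing with ω)
  is robust to that choice.
* For the same reason the shrinking junction does not rupture at the
  default contractility even at δ_max = 2: rupture requires vertex
  openings to reach δ_max, and these vertices are stiff.
* Simulations are reliable over the neighbour-exchange window (a few
  hundred steps at the default sizes); over much longer windows a slow
  residual adhesion-ratchet drift remains visible in passive tissues.
* The solver is quasi-static; step counts map to time only through the
  one-step-per-τ_cor convention, so time axes of dynamic curves are
  comparable between runs of this package, not across implementations.
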