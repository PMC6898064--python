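# Methods

This note records the models, numerical choices and known limitations behind
`valvenet`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what passing tests do and do not establish.

## Problem setting

Surgical bioprosthetic aortic valves (BHVs) are tri-leaflet tissue valves
sutured to a stent. Their closed-state mechanics — how far the leaflets
deflect under diastolic pressure and how large an area over which they press
against each other (the *coaptation area*) — are key performance measures for
valve design, normally obtained from shell finite-element or isogeometric
(IGA) closure simulations that take minutes to hours per design. `valvenet`
implements the surrogate-learning alternative: a convolutional autoencoder
that maps the valve's exact CAD representation (NURBS control grids), the
transvalvular pressure and the leaflet material properties directly to the
closed-state displacement field and the coaptation area.

## Geometry

Each leaflet is one tensor-product NURBS patch on the parameter domain
[0, 1]², open uniform knots, cubic by default, with an m x n control grid in
cm (default 8 x 8). Generated leaflets use unit weights (plain B-splines);
the rational machinery is retained and exercised with exact conic test
shapes. Grid axis 0 runs circumferentially, axis 1 from the attachment
(annulus) edge to the free edge; the m x n x 3 stack of x/y/z coordinates is
the "texture" the network convolves. These conventions are load-bearing:
convolution semantics and the fixed-boundary mask both assume them.

The parametric design space has five parameters: diameter D (default
2.3 cm, the population-average aortic valve), belly curve parameter
b ∈ [0, 1] (radial sag of the leaflet belly), free-edge curve parameter
f ∈ [0, 1], free-edge height h (0.6–1.2 cm) and commissure height
H_c (1.2 cm). The closed-form construction in `design.build_leaflet` was
chosen so each parameter has a monotone, localized effect (e.g. mid-belly
radius strictly decreases in b), which makes downstream latent-space
analyses interpretable. Leaflet k is leaflet 0 rotated by 2πk/3; the stent
is modeled purely as the fixed attachment boundary (grid edges i = 0,
i = m−1, j = 0).

## Surrogate closure simulator

Training corpora of IGA closure solutions are far too expensive to produce
at desk scale, so the package ships a closed-form surrogate with the same
interface a shell solver would have. It is *not* a mechanical model; it is a
displacement law engineered to exhibit, with known ground truth, the
structure the learning task relies on:

    dr(i, j) = g(i, j) · S(L) · ρ · r,    S(L) = L / (L + L₀),
    L = p R / (k_eff t),                  k_eff = c₀ + c₁ c₂,

with envelope g(i, j) = sin(π i/(m−1)) · j/(n−1) vanishing on all attachment
edges, reference radius r per control point, R = D/2, and ρ = 0.95 < 1 so no
point can reach the valve axis. Points move radially inward; angle and
height are unchanged, which makes zero fixed-edge displacement, three-fold
equivariance and sector containment (no interpenetration) *exact* rather
than approximate. A smooth multiplicative field (amplitude 2%, bilinear
interpolation of a seeded coarse grid, shared by the three leaflets) keeps
the task non-degenerate without breaking any invariant.

Units: pressure stays in mmHg; L₀ = 1 absorbs the unit conversion. Material
coefficients are model-scale stiffness numbers with default ranges
c₀ ∈ [200, 600], c₁ ∈ [100, 300], c₂ ∈ [0.5, 1.5] and thickness
t ∈ [0.03, 0.07] cm, chosen once so that L spans ≈1–14 over the corpus
(S ≈ 0.5–0.93) and peak displacements are sub-centimeter on a 2.3 cm valve,
matching the scale of real closure deflections. Pressure is uniform in the
physiological diastolic range 70–90 mmHg.

### Coaptation area

How coaptation area is extracted from a contact solution is not standardized;
the definition here is a proximity measure. The deformed surface area measure
is integrated over samples that (a) lie within ε = 0.05 cm of either of the
leaflet's two sector-boundary half-planes (the planes through the valve axis
where neighbors meet; the distance of a point at radius r′, angle φ to the
plane at angle φ_b is r′·|sin(φ − φ_b)|), and (b) have moved by more than
u_c = 0.01 cm (excluding undisplaced attachment/commissure points). Areas
are counted one-sided per leaflet and summed, and the same definition is
applied to simulated targets and to any re-measurement of predicted
surfaces.

Both windows are C¹ smoothstep ramps (widths 0.2ε and 0.2u_c) rather than
hard indicators. With a hard indicator on a fixed quadrature grid the area
is a step function of the load, which destroys the monotone
pressure/stiffness response the corpus is supposed to exhibit; with compact
smoothstep windows the response is smooth and the exact-zero cases
(undeformed valve, ε → 0) are preserved. The default sampling grid is
480 x 36 midpoint samples per leaflet — dense circumferentially because the
contact band is thin in that direction — which agrees with a 1000 x 200
dense-sampling reference to within ≈1.5% across the design space.

## Network

Channels-last numpy implementation with explicit backpropagation (dense,
stride-1 same-padding convolutions, ReLU, Adam); every layer and the full
model are finite-difference gradient-checked in the test suite. The
default architecture for the 8 x 8 grid:

* per-leaflet encoder (shared across leaflets, exploiting the valve's
  symmetry; configurable): conv 3→16→32 (3 x 3, stride 1), flatten, dense to
  a 64-dim embedding;
* fusion: the three embeddings, the standardized material vector
  (c₀, c₁, c₂, t) and the standardized pressure repeated into a length-10
  vector are concatenated and mapped by a dense ReLU layer to the 128-dim
  code layer;
* decoder: per-leaflet dense layer from the code back to 8 x 8 x 32, then
  shared convolutions 32→16→3 with linear output — the three displacement
  grids in cm (stride-1 transposed convolution coincides with convolution,
  so the decoder mirrors the encoder with the same layer type);
* coaptation head: dense 128→32→1. The head predicts the *standardized*
  area and the output map ReLU(μ_A + σ_A·z) restores cm² and enforces
  non-negativity. Predicting on the raw scale behind an output ReLU is
  fragile: the standardized loss then injects O(1/σ²) gradients and one
  early step can push every pre-activation negative, killing the head
  permanently (observed as constant predictions). The standardized
  parametrization keeps head gradients O(1) with an identical contract.

On an 8 x 8 grid two conv blocks per stack (16/32 channels) are used;
deeper stacks with stride-2 downsampling only pay off on finer grids.

### Boundary conditions

Fixed attachment nodes have exactly zero displacement in every simulation.
The training loss follows the boundary-condition-weighted scheme: each
node's squared error is scaled by w = |u_true| / max |u_true| (computed per
sample and per leaflet), so fixed nodes carry exactly zero weight and the
optimizer is never penalized for small non-zero predictions there. The
weight is *nodal*: |u_true| is the displacement magnitude of the node,
shared by its three components. A strictly per-component weight would leave
any identically-zero component channel (the z-channel of the radial
surrogate law) completely unsupervised; the nodal form supervises every
component of every moving node while preserving exact fixed-node
suppression. When a target tensor is entirely zero (below τ = 1e−12) the
loss falls back to unweighted MSE.

Because zero-weight outputs are unconstrained, whatever the decoder emits at
fixed nodes is never corrected; empirically those outputs converge to
O(0.05 cm) artifacts. The essential boundary conditions are therefore also
imposed *strongly* on the output: the decoder's displacement grids are
multiplied by the fixed-edge mask (known a priori from the data schema), the
same way essential boundary conditions are imposed in a finite-element
solve. This touches nothing the loss ever sees and can be disabled
(`enforce_fixed_boundary=False`) to study the soft-only behavior.

The total loss is the sum over leaflets of the BC-weighted MSE plus
λ_c (default 1) times the squared coaptation error on the standardized
scale. Training uses Adam (lr 1e−3, batch 32), up to 50 epochs by default,
with checkpoint selection at the minimum validation loss, and is fully
seeded (initialization, shuffling, augmentation). Data augmentation
translates the whole reference valve by a uniform vector in [−0.5, 0.5] cm
per axis with probability 0.5 per sample; displacement and coaptation
targets are translation-invariant and are left untouched.

## Metrics

Predicted and simulated closed shapes are compared by mean Euclidean
distance over matched control points, symmetric Hausdorff distance over
dense 50 x 50 surface samples per leaflet (control points do not lie on the
surface), and partial Procrustes RMSD (optimal translation + proper
rotation, no scaling — the statistic stays in cm). Corpus tables report
max/mean/median of the per-valve values per split plus coaptation RMSE and
Pearson R. Strains are membrane Green–Lagrange: E = (Ā − A)/2 from the
first-derivative metric tensors of reference and deformed surfaces, with
the maximum in-plane principal value the larger eigenvalue of A⁻¹E;
degenerate-metric points are flagged NaN.

## Scaled-down experiment sizes

The reference experiment used throughout the tests and the acceptance
script is 2,000 simulations, split 0.8/0.1/0.1, trained for 50 epochs on
one CPU (a few minutes). This is the package's standard desk-scale
configuration: large enough for the surrogate task to be learned to a few
percent error and for latent-space structure to emerge, small enough to be
rerun routinely. Dense sweeps use 1,000 points per parameter; t-SNE
embeddings (perplexity 30, seeded) use up to 500 test-split codes.

## What the synthetic corpus does and does not show

The surrogate reproduces the *structure* of a closure corpus — fixed edges,
symmetry, saturating monotone load response, non-interpenetration, smooth
design-space dependence, a noise floor — so passing tests demonstrate that
the learning pipeline can recover a smooth displacement/coaptation response
from NURBS textures under realistic signal scales. They do not demonstrate
accuracy on real shell-mechanics solutions: bending boundary layers, contact
flattening of the coaptation zone, anisotropic tissue response and
off-radial motion are all absent from the surrogate, and real corpora would
also be orders of magnitude larger. The network, losses, metrics and
pipeline are independent of the simulator behind `simulate_closure`, which
is the intended substitution point for a real solver.

## Known limitations

* Single-patch leaflets only: no trimmed NURBS, knot refinement or
  multi-patch continuity.
* The coaptation definition is a proximity threshold, not a contact-traction
  area; its absolute values are definition-dependent (and small, since the
  radial law only brings leaflet flanks near the sector planes).
* Quasi-static closure only; no opening phase, no fluid–structure
  interaction, no stresses (strains only).
* The numpy network is CPU-bound and intended for control grids of order
  10 x 10, not for fine meshes.
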