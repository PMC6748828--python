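# Methods

`wallmech` couples two components: (i) a 3D large-deformation finite-element
model of a turgid meristematic plant cell whose wall is a fiber-reinforced
hyperelastic composite with independently tunable edge and face mechanics,
and (ii) the morphometric statistics used to quantify growth anisotropy and
edge-localised signals in microscopy data, exercised here on seeded synthetic
fixtures with known ground truth.

## Constitutive model of the wall

The wall composite is described by seven parameters: bulk modulus `K`, shear
moduli of the matrix `mu_m`, the cellulose microfibrils `mu_f` and the
microfibril cross-links `mu_c`, the microfibril volume fraction `theta_f`,
the mean microfibril direction `a0` and the fractional anisotropy `fa`
(0 = random array, 1 = perfectly parallel).  Default face values are
K = 10 GPa, mu_m = 18 MPa, mu_f = 1.2 GPa, mu_c = 18 MPa, theta_f = 0.5.
Internally the package works in micrometre–megapascal units for conditioning
at cell scale; configs may supply SI values with a `units: Pa` field.

The strain energy density is additive:

    Psi = Psi_vol + (1 - theta_f) Psi_matrix + theta_f Psi_fibre + Psi_cross

with the specific forms

    Psi_vol    = K/2 (ln J)^2
    Psi_matrix = mu_m/2 (I1_iso - 3)          (neo-Hookean, isochoric)
    Psi_cross  = mu_c/2 (I1_iso - 3)          (isotropic cross-linking)
    Psi_fibre  = mu_f/2 (I4* - 1)^2           (standard reinforcing model)

where `I1_iso` is the isochoric first invariant and `I4* = tr(H C_iso)` the
generalized fibre invariant built from the structure tensor
`H = fa a0⊗a0 + (1-fa)/3 I`.  These are the simplest forms consistent with
the stated isotropic-matrix + isotropic-crosslink + dispersed-oriented-fibre
decomposition; they are a modelling choice of this package (the matrix and
cross-link terms are weighted by `(1-theta_f)` and 1 respectively, the fibre
term by `theta_f`).  The FA-weighted mixture form of `H` reproduces the
second moment of a fibre-direction distribution in which a fraction `fa` of
fibres is perfectly aligned and the remainder uniformly random; it gives the
exact isotropic (`H = I/3`) and aligned (`H = a0⊗a0`) limits with a single
parameter.  The fibre term is active in both tension and compression by
default (instantaneous inflation puts the wall in tension); a
`fibre_compression=False` flag drops it when `I4* < 1`.

Cauchy stress and the referential tangent are the analytic first and second
derivatives of `Psi`; both are verified against finite differences of the
energy in the test suite (relative 1e-5 / 1e-4), together with objectivity
under 100 random rotations (1e-10), exact isotropy at `fa = 0`, monotone
stiffening in `fa`, and linear scaling of the deviatoric stress in the shear
moduli.

## Cell geometry and mesh

The idealised cell is a rectangular box aligned with the organ axes
(L = longitudinal = x, T = transverse = y, R = radial = z), default
20 × 10 × 10 µm with a uniform wall 0.5 µm thick.  These dimensions and the
0.8 MPa default turgor are assumptions of this package (chosen at the
typical meristematic-cell and root-turgor scale); all are configurable.
The wall shell is meshed with trilinear hexahedra: `n_thickness` layers
through the wall (default 2) and a graded in-plane discretisation that
resolves a 1 µm edge band explicitly (mirroring the 0–1 µm edge definition
used in the image analysis).  Edges are sharp; the mechanical distinction is
carried by labelling every element whose centroid lies within `edge_band` of
one of the twelve geometric edge lines as an edge element (nearest edge
wins; corner elements tie toward edges).  The cavity surface is recorded as
an oriented facet list.

Material assignment: faces designated anisotropic by the scenario case carry
`fa_aniso` with the transverse in-plane fibril direction (perpendicular to
the organ axis); all other faces and the edge bands carry `fa_iso` (the
direction convention there is irrelevant at `fa ≈ 0`).  The scenario's
`edge_factor` multiplies `mu_m`, `mu_f`, `mu_c` jointly in the edge bands
and never touches `K` or `theta_f`.

## Finite-element solver

Total-Lagrangian trilinear hexahedra with 2×2×2 Gauss quadrature.  Near
incompressibility (K/mu up to 10^3–10^4) is treated with a mean-dilatation
(Q1P0) formulation: the volumetric energy is evaluated at the
element-average dilatation, removing volumetric locking while keeping a
displacement-only system; the pressure–dilatation coupling enters the
tangent as a rank-one per-element update, so the tangent stays consistent.
The guard for this choice is the thin-sphere benchmark: a nearly
incompressible sphere (R/t = 25, K/mu = 1000) must reproduce the membrane
hoop stress pR/2t within 5%.

Turgor is a follower pressure on the cavity facets; its (nonsymmetric) load
stiffness is assembled from per-facet central finite differences of the
facet nodal force, which keeps Newton convergence quadratic near the
solution at negligible cost.  A dead-load option exists for debugging.

Globalisation.  Inflating a *flat*-walled shell from rest is the awkward
regime: bending stiffness is tiny, membrane forces grow quadratically along
the Newton direction, and a residual-norm line search stalls.  The solver
therefore uses the total potential energy Π = ∫Psi dV − p·V_cavity (the
follower pressure on a closed cavity is conservative) as line-search merit
with an Armijo condition, switching to plain Newton steps once the residual
is within 10^-3 of the load scale (energy differences become numerically
unresolvable close to equilibrium).  Where the tangent goes indefinite
(soft-edge hinge regions) a Levenberg-style diagonal regularisation restores
a descent direction.  Loading is applied with a quadratic ramp (small early
increments), a secant predictor extrapolates each new step from the two
previous converged states, and increments are bisected adaptively on
failure.  Convergence demands a relative residual of 1e-8 (configurable).

Constraints.  The pressure on a closed cavity is self-equilibrated, so the
free shell needs only a statically determinate rigid-body gauge.  The pin
components are chosen on mid-plane nodes so that they vanish identically in
the mirror-symmetric deformation, making the gauge tilt-free; an alternate
pin set exists to verify readout invariance.  An "in-tissue" mode with the
inner-periclinal face fully fixed is available.  Scenario runs default to a
quarter model with symmetry boundary conditions (all scenario cases are
mirror-symmetric in L and T): this both quarters the system and pins the
solution to the symmetric branch — full-shell runs at high turgor can
otherwise wander onto asymmetric lobed equilibria of the flat-face inflation
problem, which are not the states of interest here.  For the quarter model
the cavity-volume potential uses the flux of (x − x0) with x0 on the
intersection of the cut planes, which makes the open cut contribute exactly
zero for symmetric deformations.

Discretisation sizes.  The scenario suites run the quarter model at the
default discretisation (two element layers through the wall, ≈2 µm in-plane
spacing away from the edge bands, ≈290 elements); the refinement study uses
in-plane spacings of 1.5 µm and 1.0 µm at fixed through-thickness
resolution, where the maximum-displacement readout drifts below 2% between
successive levels.  These sizes are the package's accuracy/cost compromise
for property-level comparisons; absolute displacement values carry a
discretisation error of a few percent.

## Scenario readouts

* `max_outer_displacement`: maximum displacement magnitude over the nodes of
  the outer-periclinal face (the swelling readout; a whole-cell variant is
  also reported).
* `edge_stress_concentration`: mean element von Mises stress over edge
  elements divided by the mean over face elements.

The qualitative results reproduced by the test suite at default parameters:
soft edges (edge factor 0.1) swell, stiff edges (10) do not and concentrate
stress at edges; transverse face anisotropy (case 2 and case 3) reduces
soft-edge swelling, anisotropy at the outer face adds a further reduction;
the measured FA increase 0.08 → 0.2 also reduces swelling; and halving the
fibre fraction changes the readout far less than the edge-factor or FA
changes do.

## Morphometric statistics

* **Nematic texture anisotropy**: per-pixel fibril directions (normals to the
  intensity gradient) averaged as a 2×2 orientation-order tensor over the
  ROI; anisotropy is the eigenvalue difference (0 random, 1 parallel), the
  angle the principal eigenvector.  Constant images are reported as
  anisotropy 0 with a degeneracy flag.  This raw score is distinct from the
  **per-cell normalisation** `(Amax − Amin)/(Amax + Amin)` applied to a
  cell's extreme anisotropy readings; both are exposed and the examples
  print them side by side.
* **Hysteresis filter**: keeps connected components containing a voxel above
  the high threshold, extended down to the low threshold.  The default
  thresholds derive from image statistics as low = mean and
  high = min(mean + 2 SD, max): the wording "mean and maximum intensity
  + 2 SD" admits several parses, and this is the one that guarantees
  low ≤ high; both thresholds are arguments.
* **Manders colocalisation** per edge region, with the exclusion flag raised
  when either channel occupies less than 10% of the region's pixels.
* **Root diameter**: mean nearest-neighbour distance between two traced
  outlines (both directions pooled) after excluding points within a given
  arc length (default 100 µm) of the tip.
* **Growth decomposition**: volume ratio from watertight surface-mesh
  volumes; directional ratios from cell extents along the organ frame axes
  (exact for affine growth, which is the intended regime; a principal-strain
  decomposition is deliberately not used).  Zone classification at 1.5-fold
  volume growth per observation interval.
* **Edge enrichment**: analysis restricted to the 0–2 µm shell below the
  cell surface; voxels within 1 µm of a geometric edge line form that edge's
  band (nearest edge wins).  Per-edge mean intensity is normalised by the
  voxel-weighted mean over all edge voxels of the cell, so the weighted mean
  of the reported enrichments is 1 by construction.  (Averaging over edges
  instead of voxels is a plausible alternative normalisation; the
  voxel-weighted form is the default because it makes the invariant exact.)
  Edges are classified transverse when their direction is within 45° of the
  organ transverse axis, else longitudinal.

Pixel/voxel coordinates are 0-based pixel centers; physical units enter via
the supplied pixel/voxel size.

## Synthetic data

Each generator forms a closed loop with its statistic (generate → estimate →
compare to truth): oriented band-pass textures with a coherence dial
(superposed plane waves normal to the fibril direction, blended with
isotropic filtered noise), binary colocalisation pairs with controlled
support overlap, tapering root outlines with an analytic retained-region
mean diameter, affinely grown box-cell surface meshes, and edge-enriched
intensity volumes with per-class intensity ratios.  All randomness flows
through one explicit seeded generator; noise is additive Gaussian clipped at
zero (vertex jitter for meshes, off by default).  What these fixtures do
*not* emulate: optics (PSF, z-anisotropy), photon noise statistics, real
segmentation errors, or curved organ geometry — passing the recovery suite
shows the statistics are implemented correctly, not that they are robust to
real microscopy artefacts.

## Known limitations

* The wall is elastic: inflation is instantaneous, with no growth,
  viscoelasticity or wall-synthesis feedback.
* Sharp box edges with band labelling stand in for the real rounded edge
  geometry; the edge band carries the mechanical distinction.
* Trilinear hexahedra under-resolve bending with thin walls; readouts are
  used comparatively (orderings) rather than as absolute displacements.
* The energy forms above are the simplest consistent with the composite
  decomposition; other dispersion encodings (e.g. a concentration-parameter
  distribution mapped to FA) would alter quantitative, not qualitative,
  behaviour.
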