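# Methods

This note records the model choices, conventions, and numerical decisions
behind `polembed`, and what the synthetic fixtures do and do not establish
about real systems.

## Classical layer: FQ and FQFμ

Atomic charges equilibrate by the electronegativity-equalization principle:
the energy is quadratic in the charges q (and, with fluctuating dipoles, in
μ), with per-element electronegativity χ and hardness η, and per-molecule
total-charge constraints Q enforced by Lagrange multipliers so charge never
flows between molecules. Stationarity yields one symmetric indefinite (KKT)
linear system over (q, λ, μ), solved by a direct symmetric factorization
(`scipy.linalg.solve(..., assume_a="sym")`). Direct solution is the right
tool at this scale — the intended systems stay well below 10⁴ unknowns —
and makes the per-fragment charge sums exact rows of the solution rather
than a convergence criterion.

Kernels:

* **Ohno** (FQ): T(r) = η̄/√(1+η̄²r²), η̄ = (η_i+η_j)/2. Equals the mean
  hardness at contact, decays to 1/r. The diagonal of the charge block is
  the atomic hardness itself.
* **Gaussian / erf** (FQFμ): charges and dipoles are spherical Gaussians of
  widths R_q, R_μ; two sites interact through erf(r/R̄)/r with
  R̄ = √(R_i²+R_j²), and the charge–dipole and dipole–dipole tensors are
  its first and second derivatives (−∇T, −∇∇T). The dipole block diagonal
  is 1/α, so an isolated site in a uniform field F acquires μ = αF exactly.

Sign conventions: the external source enters as E^int = Σ q_iV(r_i) −
μ_i·E(r_i); the right-hand side of the linear system is (−χ−V, Q, +E).

Degenerate geometry (two MM sites closer than 0.1 Å) is an error, never a
warning: a near-singular KKT system would otherwise return silently huge
charges.

The potential the MM layer hands back to the quantum side uses the same
kernel family as assembly. For Gaussian systems the probe point is a point
charge, so the combined width collapses to the site width and the potential
is finite everywhere; for Ohno systems the potential is bare Coulomb and a
probe coincident with a site is a hard error. The same erf screening, with
a caller-chosen width, is available for all density–point Coulomb sums
(`damping=` arguments); this short-range damping regularizes numerically
integrated density–MM interactions near grid nodes. The width is exposed
rather than fixed because the appropriate value tracks the backend's grid
resolution.

## FDE layer

Densities are data on caller-supplied quadrature grids — points, weights,
values, and (for GGA functionals) gradients stored as an independent array.
The module never generates production grids: the backend owns its
integration scheme. Fixtures use Gauss–Hermite product grids, which
integrate the Gaussian model densities essentially exactly.

Kinetic functionals: Thomas–Fermi, E = C_TF∫ρ^{5/3} with
C_TF = (3/10)(3π²)^{2/3}; and PW91k, the TF integrand times the
Lembarki–Chermette enhancement factor F(s) with
s = |∇ρ|/(2(3π²)^{1/3}ρ^{4/3}). The F(s) constants live in one auditable
block (`fde.PW91K_PARAMS`). F(0) = 1, and the implementation is arranged so
the zero-gradient potential reproduces the TF potential bit-for-bit.

**Definition of the GGA potential on a grid.** A scattered quadrature grid
carries no differentiation structure, so the divergence term
∇·(∂e/∂∇ρ) of the textbook GGA potential cannot be formed without the
backend's basis machinery. The potential returned here is ∂e/∂ρ at fixed
stored gradients — exactly the functional derivative of the implemented
energy with respect to the value array, which is the object a backend
contracts for and the object the finite-difference consistency tests
verify. Non-additive potentials are differences of these,
v^nadd = v[ρ_I+ρ_II] − v[ρ_I].

Density values are clipped at 1e−12 before fractional powers; quadrature
noise below that level is physically meaningless but would generate NaNs.

The embedding potential assembles linearly:
v_emb = v_elst[ρ_II + nuclei_II] + v_T^nadd + v_xc^nadd + v_MM, with the
electron density entering the electrostatic term with charge −1
(positive-test-charge convention throughout; a backend that wants the
potential energy of an electron multiplies by −1 once). The non-additive
xc evaluator is pluggable (`xc_functional=` takes any
`rho -> (energy, potential)` callable) so a backend-native functional can
be injected; the packaged kinetic functionals double as the test vehicle.

Freeze-and-thaw alternates which density is frozen, relaxing the other via
the backend callback, until the integrated absolute change Σw|Δρ| of both
densities in a full cycle falls below `tol` (default 1e−6 electrons).
Non-convergence sets a flag and returns the history — never silent.

## Mutual polarization

The coupled quantum/classical problem is solved by outer-loop alternation:
solve the classical response in the current QM potential and field, rebuild
the density in the resulting MM potential, repeat until max|Δq|, |Δμ| <
tol (defaults 1e−6, 50 cycles). Whether a production code interleaves
charge updates inside its SCF is an implementation detail of the backend;
the outer loop is the contract here, and on linear-response backends it
contracts geometrically to the same fixed point as a direct solve of the
coupled linear system (verified to 1e−8 in the tests by probing the affine
map and solving (I−B)x = c).

Magnetic properties: shielding and spin–spin coupling tensors have no
explicit dependence on the polarizable shell because the shell's degrees of
freedom do not couple to nuclear magnetic moments; the embedding therefore
enters only implicitly, through the static one-electron potential under
which the orbitals were converged. `request_magnetic_properties` passes the
backend's tensors through unmodified and attaches isotropic values
(trace/3). The gauge treatment and the coupled-perturbed machinery for the
coupling operators are entirely backend territory.

The frozen FDE density is prepared by a helper pattern rather than a
special code path: run the backend on the shell molecules alone, optionally
inside the outer MM potential (skipping it gives the variant in which the
frozen density never feels the bulk).

## Snapshot protocol

* Spherical cut at 22 Å from the solute center of mass, **molecule-wise**
  with an any-atom criterion — molecules are never split, so fragment
  charge constraints stay meaningful.
* FDE shell: a retained molecule joins the frozen layer iff its minimum
  interatomic distance to the solute is ≤ cutoff (3 or 5 Å); distances are
  inclusive, matching "within", which makes FDE(3 Å) ⊆ FDE(5 Å) structural.
* Averaging is arithmetic over snapshots, then over equivalence groups;
  referencing (δ = σ_ref − σ_iso) commutes with averaging because both are
  linear, and the tests pin that identity. Half-differences
  ((max−min)/2 of the averaged shifts within a group) quantify how
  equivalent the "equivalent" nuclei actually came out. A running-mean
  trace per group is retained for convergence inspection.
* The J ≥ 0.5 Hz filter applies to the **averaged** couplings (after
  snapshot and equivalence averaging), not per snapshot.
* Spectrum synthesis is first-order: each retained coupling splits a
  group's lines into a binomial (n+1)-multiplet spaced J/field ppm; lines
  are unit-area Lorentzians (FWHM 0.002 ppm default) scaled by proton
  count, so integrals are proportional to proton numbers as in standard
  NMR presentation. No spin-Hamiltonian diagonalization is attempted:
  strongly coupled (second-order) patterns are out of scope.
* Polarity analysis: K(ε) = (ε−1)/(2ε+1) (rounded to 3 decimals for table
  comparison), plus ordinary least squares of group shifts against any of
  the tabulated polarity scales, with degenerate-abscissa flagging.

Nuclei are 0-indexed internally, 1-indexed where reports are formatted.
Magnetogyric ratios: ¹H from CODATA via scipy; ¹³C, ¹⁵N, ¹⁷O, ¹⁹F, ³¹P
from standard NMR tables (CODATA does not list them), in one constant
block (`units.GYROMAGNETIC_RATIOS`). Reduced couplings are taken in SI.

## Synthetic fixtures: what they do and do not show

The fixture module generates every input at run time: rigid TIP3P-geometry
water clusters (shell or box placement, O–O overlap rejection at 1.5 Å,
seed-deterministic), Gaussian model densities with closed-form potentials
and gradients, noisy per-snapshot shielding tables (group mean + i.i.d.
Gaussian noise), and mock backends (`fixed`, `linear_response`). The
packaged FQa/FQb/FQFmu parameter files are synthetic placeholders with
plausible magnitudes, labelled as such in the files.

These fixtures exercise the mathematics — constrained minimization,
functional derivatives, fixed points, protocol identities — not the
physics of real solvation: cluster geometries have no liquid structure,
model densities are not molecular densities, the linear-response backend
has none of a real SCF's nonlinearity, and placeholder parameters carry no
fitted accuracy. Passing tests certify the machinery, and plugging in a
real backend plus fitted parameters is exactly the supported path the
backend contract defines.

The brute-force solver oracle shares no code with the production path: it
writes the energy with inline kernel formulas, eliminates the constraints
through a null-space parametrization, extracts the gradient and Hessian of
the (exactly quadratic) reduced energy by central differences — which are
exact for quadratics at any step size — and performs one dense solve. It
is restricted to ≲20 unknowns by design.

Problem sizes throughout the suite (2–6-site random systems, ≤50-water
shells, 8–16-point-per-dimension grids, 200-snapshot synthetic ensembles)
were chosen as the smallest sizes at which each property is
non-trivially exercised.

## Known limitations

* No periodic boundary conditions, no force-field fitting, no analytic
  nuclear gradients.
* The GGA potential definition above means backend codes that require the
  full ∇·(∂e/∂∇ρ) term must supply it themselves (they own the basis).
* First-order multiplets only; second-order spectral features are not
  reproduced.
* The MM↔density screening width is a free parameter, not a fitted law;
  reciprocity of interaction energies is exact only when both directions
  use matching widths (the tests construct that case explicitly).
* No quantum backend ships with the package; all shipped "QM" results come
  from mocks and are labelled accordingly.
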