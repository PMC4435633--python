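# Methods

## Scope and model

`semicell` implements closed-shell restricted Hartree–Fock in the NDDO
(neglect of diatomic differential overlap) approximation with the MNDO and
AM1 parametrizations, for nonperiodic molecules and for cells with 1–3
periodic lattice vectors treated as a single real-space cyclic cluster
(Born–von Karman boundary conditions, Γ point only, no reciprocal-space
sums).  The valence basis is minimal Slater sp: one 1s function on hydrogen,
four (ns, np) functions on every other supported element
(C, N, O, F, Na, P, S, Cl, Zn).

## Parameters

All element constants are embedded (`semicell.parameters`), transcribed from
the original MNDO/AM1 method literature.  Derived quantities are computed
rather than transcribed, which both removes transcription-error surface and
documents the model:

* charge separations `D1`, `D2` from the Slater exponents and the principal
  quantum number (the `D1` closed form is tested against the independent
  ⟨ns|z|npz⟩ matrix element);
* additive Klopman radii: `rho0 = 1/(2 g_ss)` (a.u.), `rho1` solved from the
  one-center hybrid limit `h_sp`, `rho2` from the square-quadrupole
  one-center limit `(g_pp − g_p2)/2` (scipy `brentq`, tolerance 1e-14);
* the isolated-atom electronic energy from the one-center terms and the
  Hund-rule ground occupation (reproduces the published E_isol tables
  exactly for the elements where both are known);
* legacy conversion constants (a₀ = 0.529167 Å, 1 ha = 27.21 eV,
  1 eV = 23.061 kcal/mol) because the parametrizations were calibrated with
  them; with modern CODATA values the published reference heats of formation
  are *not* reproduced.

Sodium has no original MNDO/AM1 parametrization; an AM1-type alkali sp set
is served under both Hamiltonian tags so that rocksalt test lattices are
self-contained.  Sodium energetics are qualitative (correct ionicity sign
and magnitude, converged SCF); nothing quantitative is asserted about them.

## Two-electron integrals

Orbital-pair charge distributions are represented by point-charge multipole
configurations: a monopole for (ss) and the spherical part of (pp); a
two-charge dipole (±½e at ±D1) for (sp); a three-charge linear quadrupole
(+¼e at ±2D2, −½e at center) for (pp); a four-charge square quadrupole for
(pp′).  Each charge pair interacts through the Klopman kernel
q₁q₂/[r₁₂² + (ρ_A + ρ_B)²]^(−1/2).  The 22 unique integrals of an sp–sp pair
are evaluated in the local diatomic frame (z along the internuclear axis)
and rotated to the global frame.

Two numerical choices matter here:

* **Azimuthal invariance.**  The finite square-quadrupole configuration is
  not invariant under rotations about the local z axis, so the
  (p_x p_y|p_x p_y)-type channel is defined by the identity
  (xy|xy) = [(xx|xx) + (yy|yy) − (xx|yy) − (yy|xx)]/4; with it, rotated
  integral blocks are exactly frame-independent (tested to 1e-14).  `rho2`
  is still fixed by the square-configuration one-center limit — the
  combination that reproduces the published molecular heats of formation.
* **Degenerate frames.**  The (x′, y′) completion of the local frame uses a
  fixed reference axis (ẑ, or x̂ when the bond is within 45° of ẑ), so runs
  are bitwise reproducible.

The lattice-image evaluation is vectorized: per ordered element pair a flat
term table (charge products, offsets, channel radii) is built once, then
evaluated for whole arrays of image distances and rotated with batched
einsums.

## Periodic adjustments

* **Gaussian damping.**  Beyond `c_cut` (default 10 bohr) every channel's
  additive radius is multiplied by exp(−0.25 (r − c_cut)²), taken at the
  center separation.  γ is then exactly continuous and C¹ at the cutoff,
  monotone, and reaches 1/r, so distant residuals cannot accumulate.  Two
  alternative published-form parses of the damped tail are switchable
  (`integrals.GAMMA_TAIL_CONVENTIONS`) for comparison; they are *not*
  continuous at the cutoff and are not used.
* **Screening.**  Center separations are replaced by r_eff(r) and multipole
  offsets scaled by λ(r) (three zones; α from `ScreeningR` = 2α, default
  30 Å ⇒ α = 15 Å).  Screening acts on atom-center distances, never on
  individual point charges.  Core–core repulsion and electron–core
  attraction are screened identically (internal consistency).
* **Lattice sums.**  Image translations are enumerated out to
  2α + cell diameter + 2 Å, and every enumerated translation contributes
  *all* atom pairs.  Beyond 2α the kernel is exactly the constant
  γ_c = 1/(1.5α) in every monopole channel and zero in all others, so each
  complete distant cell contributes γ_c·q_A·Σ_B q_B = 0 for a neutral cell:
  results are rigorously independent of the enumeration radius, and a
  molecule in a box larger than 2α reproduces its gas-phase energy to
  machine precision.  The constant terms shift the core Hamiltonian and the
  core–core energy individually; all observables (Fock matrix, total
  energy, populations) are unaffected.
* **Exchange.**  Each atom pair exchanges once, at its minimum image; this
  is the Wigner–Seitz restriction.  On-boundary ties are broken
  deterministically (lexicographic, largest-components image) and the pair
  orientation used for tie-breaking is geometric (position-lexicographic),
  which makes the choice independent of atom ordering.  On very small
  high-symmetry cells the single-image choice slightly breaks point-group
  equivalence between atoms (≈0.007 e charge spread on the 8-atom diamond
  cell); the effect vanishes with cell size, which is one more reason the
  convergence-with-cell-size check matters.
* **Resonance.**  β-weighted overlaps are evaluated at the minimum image
  only and floored at |S| < 1e-8 (beyond 20 bohr they are set to zero).
  Neglected resonance to farther images is exponentially small for cells
  meeting the ≥7–8 Å guideline.

## Overlaps

Two-center Slater overlaps are computed exactly in prolate spheroidal
coordinates: after factoring e^(−pξ−qη), the sp integrands are polynomials,
so an 18-point Gauss–Laguerre × 64-point Gauss–Legendre rule is exact to
machine precision for every supported (n, l, ζ) combination (verified
against the closed-form 1s–1s overlap at 1e-12 and direct 3-D quadrature at
2e-4).  No Gaussian expansion of the Slater functions is involved.

## SCF

Initial guess: diagonal atomic densities Z_v/n_basis (no randomness
anywhere; runs are bitwise reproducible).  The first 5 iterations use 50%
density damping, then DIIS over up to 8 Fock matrices (error FP − PF).
Convergence requires max|ΔP| < 1e-6 and |ΔE| < 1e-6 eV (configurable);
non-convergence after `max_iter` (200) returns a flagged state whose heat of
formation is refused.  Final energies are assembled with Neumaier
compensated summation over magnitude-ordered terms (`compensated_sum`,
tested against `math.fsum`, which is exact in double precision); this
replaces extended-precision hardware arithmetic with an agreement contract
rather than a bit-width.

Heat of formation: ΔH_f = (E_elec + E_core − Σ_A E_isol)·23.061 + Σ_A
ΔH_f,atom.  Coulson charges q_A = Z_v(A) − Σ_{μ∈A} P_μμ accompany every
run.  Dipole moments (nonperiodic) combine the point-charge term with the
hybridization term −2 D1 P_sp per atom.

## Local properties

* **Density**: ZDO-consistent one-center products
  ρ(r) = Σ_A φ_A(r)ᵀ P_AA φ_A(r); non-negative by construction and
  integrates to the electron count exactly (up to grid quadrature; a 44³
  grid on water is ~1% low).
* **MEP**: the same screened, damped, distributed-multipole machinery as the
  energy — cores enter as their ss monopole (Klopman kernel with ρ₀), the
  electron term contracts the one-center density blocks with the canonical
  charge sets in the local frame of each grid point, images summed
  cell-complete to 2α.  Consequently the potential of a neutral system
  vanishes at long range like its leading multipole (water: dipole, 1/r²).
* **IE_L / EA_L**: orbital-density-weighted means of occupied / virtual
  orbital energies, IE_L = −Σ ρ_i ε_i / Σ ρ_i, with MO densities formed by
  applying the orthogonal-basis MO coefficients directly to the Slater
  functions (no deorthogonalization — a documented approximation).  The
  EA_L weighting variant is the plain virtual-orbital density
  (`localprops.EA_WEIGHTING = "orbital_density"`); electronegativity and
  hardness are the half-sum and half-difference grids.  Where every basis
  function has decayed below range (points ≳12 bohr from all atoms) the
  weighted mean is 0/0 and the frontier-orbital limit (−ε_HOMO or −ε_LUMO)
  is substituted.
* Grids span exactly one lattice vector per periodic axis (endpoint
  exclusive); export is standard Gaussian cube (bohr header, z-fastest
  data) plus tab-separated slices.

## What the fixtures do and do not show

The programmatic fixtures (diamond, rocksalt NaCl, wurtzite ZnO, molecular
water boxes) use standard literature lattice constants and exercise
covalent, ionic and molecular limits of the periodic machinery: SCF
convergence, charge-transfer direction, symmetry invariances, cell-size
convergence of ΔH_f, and exact gas-phase decoupling.  They do not probe
geometry relaxation (no forces are implemented), d-electron chemistry
(sp basis only — ZnO with sp zinc is qualitatively, not quantitatively,
ionic), open shells, or thermal disorder.  Quantitative agreement with
published method output is established on gas-phase H₂, H₂O and CH₄
(≤0.05 kcal/mol at the published geometries); periodic absolute energies
inherit whatever accuracy the underlying parametrization has for solids.

## Problem sizes

The default verification runs use the conventional diamond cell at 1×, 2×
and 3× replication (8–216 atoms, 32–864 orbitals) with the full default
screening radius (2α = 30 Å; ≈390 enumerated image translations per pair at
216 atoms), a 70 Å decoupling box for the gas-phase equivalence check, and
4–8-atom cells for the invariance battery.  A 216-atom SCF completes in
about 1.5 minutes on one CPU core.

## Known limitations

* No analytic gradients, geometry optimization, MD coupling, UHF, excited
  states, or d orbitals.
* Charged cells are allowed only nonperiodically (a charged periodic cell
  has a divergent electrostatic energy in this scheme).
* For 1-D and 2-D periodicity the same radial screening is applied along
  all directions; the symmetry-cancellation argument is exact only along
  the periodic directions, so aperiodic-direction tails rely on the
  Gaussian damping alone (documented limitation).
* The Wigner–Seitz single-image exchange makes energies of very small
  cells slightly dependent on the deterministic boundary tie-break; use
  cells ≥ 7–8 Å per repeat vector, as the convergence checks recommend.
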