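# semicell

A self-contained real-space **cyclic-cluster periodic NDDO** engine:
MNDO/AM1 semiempirical molecular-orbital SCF for molecules and for crystals,
surfaces and condensed-phase boxes with 1-, 2- or 3-dimensional periodic
boundary conditions — plus local-property grids (electron density, molecular
electrostatic potential, local ionization energy / electron affinity) over
the cell.

## Who it is for

Computational chemists and materials modellers who want fast quantum-chemical
(valence sp basis) electronic structure for large or disordered unit cells —
molecular crystals, ionic and covalent solids, slabs, solvated biomolecular
boxes — without reciprocal-space machinery, and who want the wavefunction in
a form from which real-space local property maps can be generated directly.

## The model

The system is a single supercell under Born–von Karman boundary conditions,
treated entirely in real space (Γ-point only; the cell should be ≳ 7–8 Å per
periodic direction).  Three adjustments make the standard closed-shell NDDO
SCF well-defined under periodicity:

1. **Damped two-electron integrals.**  The two-center Coulomb integral
   γ_AB(r) = [r² + (ρ₀A+ρ₀B)²]^(−1/2) (Klopman form, ρ₀ = 1/(2G) with G the
   one-center Coulomb integral in hartree) never reaches the bare 1/r, so an
   infinite lattice sum of its residuals diverges.  Beyond a cutoff c_cut
   (default 10 bohr) the additive length is switched off by a Gaussian,
   γ → [r² + (e^(−0.25(r−c_cut)²)(ρ₀A+ρ₀B))²]^(−1/2), smoothly reaching 1/r.
2. **Wigner–Seitz exchange.**  Exchange terms for an orbital on a given atom
   are evaluated only within the Wigner–Seitz cell around it: each atom pair
   exchanges once, at its nearest periodic image (boundary ties broken
   deterministically so exactly one image is accepted).
3. **Three-zone electrostatic screening.**  Distant multipole–multipole
   interactions are relocated to an effective distance r_eff(r) — equal to r
   below α, −α/2 + 2r − r²/(2α) between α and 2α, and constant 1.5α beyond —
   while the distributed point-charge multipoles are contracted by
   λ(r) = d(r_eff)/dr = 2 − r/α (1 below α, 0 beyond 2α).  Beyond 2α every
   interaction sits at the same radius, so complete neutral cells cancel by
   symmetry and all lattice sums terminate.  The keyword `ScreeningR` sets
   2α in Å (default 30.0).

Everything else is standard MNDO/AM1: distributed-multipole two-electron
integrals (charge separations D₁/D₂, additive radii ρ₀/ρ₁/ρ₂), exact Slater
overlaps with resonance ½(β_μ+β_ν)S_μν, MNDO/AM1 core–core repulsion, RHF
with density damping + DIIS, heats of formation referenced to isolated-atom
energies, and a Coulson population analysis with every run.  Parameter
tables are embedded for H, C, N, O, F, Na, P, S, Cl, Zn.

## Worked example

```bash
# an 8-atom conventional diamond cell, AM1, default screening
semicell fixture diamond -o c8.xyz
semicell scf c8.xyz -d run/
```

The report (`run/report.txt`) ends with:

```
hamiltonian            AM1
atoms                  8
periodic dimensions    3
valence electrons      32
converged              True
iterations             39
electronic energy (eV) -1875120.524442
core-core energy (eV)  1874099.539202
total energy (eV)      -1020.985241
heat of formation      111.243572 kcal/mol
HOMO (eV)              -8.718770
LUMO (eV)              -3.448250
```

The electronic and core–core components individually carry large constant
lattice-image potentials that cancel exactly in the total (they are the
price of the terminating screened lattice sums); the total energy, gap and
charges are the well-defined quantities.  111.2 kcal/mol for 8 carbons is
+13.9 kcal/mol per atom: the 3.57 Å cell is
far below the recommended cell size, so the Γ-only cyclic cluster is still
badly converged.  Repeating with `--repeat 2 2 2` and `--repeat 3 3 3` gives
7.12 and 6.89 kcal/mol per atom — the heat of formation converges
monotonically with cell volume, which is the check one should always run.
Gas-phase molecules reproduce the published MNDO/AM1 numbers: e.g. AM1 water
at its equilibrium geometry gives ΔH_f = −59.24 kcal/mol, dipole 1.86 D,
q(O) = −0.383 e.

Local properties from the saved state:

```bash
semicell grid run/state.npz --kind mep --shape 24 24 24 -o mep.cube
semicell grid run/state.npz --kind ie_local --shape 24 24 24 \
         --slice-axis 3 -o iel.cube
```

writes Gaussian cube files (and a tab-separated mid-cell slice) of the
screened multipole electrostatic potential and the local ionization energy,
both in kcal/mol.

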