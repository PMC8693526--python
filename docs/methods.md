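# Methods

`lipobrush` simulates a pair of opposed DPPC bilayers whose facing leaflets
carry grafted cationic chitosan chains, with Cl⁻ counterions, at the
coarse-grained (Martini-type, ~4 heavy atoms per bead) level, and measures
the structural and dynamic observables that characterize the
polyelectrolyte layer and the membrane it decorates.

## Interaction model

Beads: Q0 (choline, +1), Qa (phosphate, −1), Na (glycerol), C1
(hydrocarbon), MW (4:1 water), R1/R2/R3⁺ (chitosan hydroxyl side chain,
backbone, protonated amino sub-monomer, +1), Cl⁻.  All masses default to
72 Da (the standard 4:1 mapping); every mass is configurable per species in
the parameter file.

* **Nonbonded.** 12-6 Lennard-Jones plus Coulomb at relative dielectric
  ε_r = 15, cutoff 12 Å.  Missing pairs combine by Lorentz–Berthelot
  (arithmetic σ, geometric ε); a printed table entry always overrides a
  mixed one.  The simulation engine defaults to GROMACS-style force
  switching (LJ switched 9 → 12 Å, Coulomb switched from 0), the
  convention under which this parameter family is used in practice; a
  plain energy-shifted LJ with shifted-force Coulomb is available as
  `pair_style="shift"` and is the form of the scalar reference helpers.
  The switch choice was validated against bulk CG water: 0.119 nm³ per
  bead at 300 K / 1 atm (reference 0.12).
* **Bonded.** Harmonic bonds and two angle styles: cosine-squared for the
  lipid, harmonic-in-θ for chitosan, plus a single-term Fourier dihedral
  V = K[1 + cos(nφ − φ₀)] on the chitosan backbone.  The tabulated
  bond/angle constants are GROMACS-convention values (defined against
  V = (K/2)x²); assembled systems therefore carry K/2
  (`builder.BONDED_PREFACTOR`).  Taking the no-½ reading literally doubles
  every bonded stiffness relative to the parameter set's provenance and
  freezes the bilayer solid at 300 K, inconsistent with the fluid-phase
  observables this model is known to produce.  The scalar helpers
  (`bond_energy`, `angle_energy`, `dihedral_energy`) evaluate the printed
  functional forms directly.
* **Exclusions.** Directly bonded (1–2) pairs are excluded everywhere.
  Within chitosan chains 1–3 pairs are excluded as well: the printed
  repeat-unit geometry (side-bead bonds of 1.9–2.5 Å at the printed
  angles) places second neighbors deep inside the LJ core.  Lipid 1–3
  pairs must *interact*: no bending term spans the choline bead, and the
  1–3 LJ is what keeps the head from folding onto the glycerol.
* **Chitosan connectivity.** Each repeat unit is R1–R2–R3⁺ with the R2
  beads forming the backbone.  The bond table prints an "R1–R1" row but no
  R1–R2 row, while the angle table requires R1–R2 connectivity; the R1
  side bead is therefore bonded to its unit's R2 with the printed "R1–R1"
  parameters.  The label "BR0" in one dihedral row is read as R2:0.
  Grafting uses one harmonic bond (R2–R2 parameters) from the lipid
  choline bead to the chain's first backbone bead.  At ionization fraction
  f < 1 a rounded subset of units keeps the +1 charge (default f = 1).

## System construction

Two bilayers normal to z; the facing leaflets carry `round(X_p · N_leaflet)`
grafted chains each.  Lipids start on a jittered lattice at 0.49 nm² per
lipid; chains start roughly extended along the normal with small random
kinks, making smooth hairpin turns when they would leave the gap; one Cl⁻
per protonated unit is scattered through the gap; the total charge is
exactly zero.  A geometric push-apart pass then removes any residual
hard-core contact (< 0.7 σ) while keeping bond lengths within 15 % of r₀.
Builds are bit-reproducible under a fixed seed.

Solvent modes: `explicit` floods the gaps with MW beads at 0.12 nm³/bead;
`shell` (preset default) lays 1.2 nm hydration slabs against every head
plane and fills the outer gap, leaving the chain/ion region between the
slabs open; `implicit` adds no water (the Langevin bath supplies friction
and noise).  The shell mode is the desk-scale compromise: a flooded gap
freezes the membrane–membrane distance (water has no lateral reservoir to
escape to in a small periodic patch), whereas hydrated head planes plus a
compressible chain region let the barostat find the equilibrium spacing.
Hydration thermodynamics beyond the first shell is thereby approximated;
runs using it are flagged in their manifests.

Presets (`scaled_preset`): X_p = 0.005 / 0.014 / 0.1 ("mushroom", "critic",
"brush"), n_p = 45, A_l(init) = 0.49 nm², gap ≥ 2.5× the theoretical layer
height, 210/210/100 lipids per leaflet, fixed seeds.  These stand in for
the full-size production system (4624 lipids per monolayer, 10⁵ water
beads, 10⁶ steps), which desk-scale hardware cannot reach; patch sizes and
step counts were chosen for tractable wall time, not tuned to any target.

## Protocols

1. **Minimize** — steepest descent with backtracking line search;
   stopping tolerances E_stop = 10⁻⁷ (relative energy change) and
   F_stop = 10⁻⁸ kcal/(mol·Å) (force norm), iteration-capped.
2. **Pre-melt** — 2500–3000 steps of barostatted Langevin dynamics at
   400 K.  The lattice start is deep in the ordered basin; a short hot
   stage decorrelates the tails before target-temperature equilibration.
3. **NPT equilibration** — Langevin thermostat (BAOAB velocity Verlet,
   exact Ornstein–Uhlenbeck refresh, damp = 100 fs) at 300 K with a
   Berendsen-style weak-coupling barostat at 1 atm, lateral (xy) and
   normal (z) dimensions coupled to their own pressure components.
   8000 steps (13000 for the brush preset, whose gap excursion is
   larger), dt = 10 fs.  The coupling gain (compressibility 2·10⁻³ atm⁻¹,
   τ_p = 500 fs, strain cap 5·10⁻⁴/step) is deliberately stronger than a
   physical liquid compressibility so that partly open gaps relax within
   affordable step counts; it sets the relaxation rate, not the fixed
   point.  Equilibration is declared when the trailing-window mean of
   box-z varies by < 1 %.
4. **NVT production** — Langevin over a velocity-Verlet core, no barostat,
   2500 steps (5000 for the brush preset), frames every 50 steps with
   wrapped coordinates plus image counts (image counters are reset at the
   production start so MSDs unwrap cleanly).

The NVE integrator (no thermostat) conserves energy to |ΔE|/⟨KE⟩ < 10⁻⁴
over 10⁴ steps at dt = 10 fs and is time-reversible; it backs the
production integrator and the conservation diagnostics.

## Observables

* **Density profiles** along z, centered on the box midplane, 0.1 nm bins
  (configurable); bin integral × area recovers the group size exactly.
* **Chitosan layer L_DM** = d/2, with d the distance between the two
  facing phosphate (Qa) density maxima of the inner leaflets (quadratic
  peak refinement); a 5 %-of-maximum extent estimator is reported
  alongside.  Block-style frame averaging over the production stage.
* **Bilayer thickness D_B**: Q0 peak-to-peak distance of one bilayer;
  **hydrocarbon thickness D_HH**: FWHM of the C1 profile by linear
  interpolation.
* **Area per lipid** A_l = Lx·Ly/N_leaflet averaged over the final third
  of the barostatted stage; expansion = (A_l − A_l0)/A_l0.
* **RDF** with minimum image and ideal-gas normalization, 0.2 Å bins
  (0.1–0.5 configurable); intra-molecular bonded pairs are included — the
  4.7–5.2 Å bonded shell is part of the measured structure.
* **MSD** with all time origins; 2-D (xy) for lipid centers of mass, 3-D
  for chitosan monomers and ions.  **fit_diffusion** does least squares in
  log₁₀–log₁₀ space per window: the slope is α and
  D_α = ⟨MSD/(2 d t^α)⟩ converted to cm²·s^−α.  Default windows are
  user-configurable because scaled systems shift the crossovers.

## Theory

Ideal-chain (mushroom) height R₀ = a√n_p; mean-field brush height
R = n_p a (a² X_p / A_l)^{1/3}, the exact minimizer of
F/kT = 3R²/(2 n_p a²) + 3 a³ n_p² X_p/(A_l R) (coefficients 3/2 and 3 are a
convention fixed so the minimizer reproduces the reference heights 3.47 and
6.68 nm at a = 0.47 nm, A_l = 0.7 nm²).  Crossover
X_p* = g·A_l/(π R₀²) with the geometric factor g exposed (g = 1 gives
≈ 0.020 at A_l = 0.62; g = 0.70 places the crossover at the observed
0.014); classification uses a ±30 % "critic" band.  Scaling-regime heights
(osmotic R ~ a n_p; Pincus with ν = 3/5) carry unit prefactors and an
explicit scaling-only flag; the Pincus regime is flagged inapplicable at
f = 1 (condensed counterions).  Membrane expansion is the parametric
virial form coefficient·X_p·n_p^{m_F} with m_F selectable and a one-point
calibration helper — only its zero and monotonicity are load-bearing.

The GLE solver integrates dC/dt = −γC − ∫κ(t−s)C(s)ds for the VACF with a
trapezoidal Volterra scheme (exact exponential integration of the γ part,
so κ = 0 reproduces the Langevin closed form to < 10⁻⁴ over four decades)
and double-integrates for the MSD; it raises on divergence rather than
returning garbage.  The kernel factory builds
κ(t) = Bγ²(t/τ₂)^{α−1}(1−e^{−t/τ₃})e^{−t/τ₁}; arbitrary tabulated kernels
are accepted.  The Rouse monomer MSD is the piecewise t^{1/2} → 2dDt form,
continuous at the crossover time.

## What the generator emulates, and what it does not

The synthetic systems reproduce the study's composition and conditions
(grafting fractions, chain length, initial area per lipid, neutralizing
counterions, 300 K / 1 atm) at patch sizes 20–50× smaller, with scaled
solvent and ~50× shorter trajectories.  They do not reproduce: full
hydration thermodynamics (shell solvent), long-wavelength membrane
undulations (small patches), electrostatic lattice sums (screened,
switched Coulomb at ε_r = 15), or slow lateral phase equilibration.
Passing the scaled-run checks shows the machinery reproduces the study's
observable pipeline and its leading-order physics, not that a desk-scale
patch is quantitatively equivalent to the production system.

## Known limitations

* At 300 K the faithful reimplementation sits near or below the bilayer's
  ordering transition: the tails stay more ordered than the study reports
  (D_HH high by ~0.5 nm, A_l low by ~0.15 nm²) even after pre-melting,
  the ½-convention correction and full-hydration control runs.  DPPC's
  melting behavior is outside this model's validated range.
* The brush-regime inter-membrane distance relaxes slowly under the
  weak-coupling barostat; at the documented stage lengths it is still
  ~15 % above the reported layer thickness.
* Ion diffusion coefficients in implicit/shell solvent exceed the
  explicit-solvent values (no solvent collisions); the diffusion
  *exponent* is unaffected.
* The minimizer is plain steepest descent: robust, but slow near flat
  minima; the dynamics stages do the real relaxation.
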