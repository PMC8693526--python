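"""Physical constants and unit conventions.

The package works in "real" MD units throughout:

===========  =======================
quantity     unit
===========  =======================
length       angstrom (Å)
time         femtosecond (fs)
mass         dalton (g/mol)
energy       kcal/mol
charge       elementary charge (e)
temperature  kelvin
pressure     atmosphere
===========  =======================

Velocities are Å/fs and forces kcal/(mol·Å).  The two conversion factors
below link the mechanical units: ``FORCE_TO_ACC`` turns kcal/(mol·Å) per
dalton into Å/fs², and ``MVV_TO_ENERGY`` turns Da·(Å/fs)² into kcal/mol.
"""

# Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

# Coulomb constant k_e = 1/(4 pi eps0), kcal·Å/(mol·e²)
COULOMB = 332.06371

# acceleration [Å/fs²] = FORCE_TO_ACC * force [kcal/(mol·Å)] / mass [Da]
FORCE_TO_ACC = 4.184e-4

# energy [kcal/mol] = MVV_TO_ENERGY * mass [Da] * velocity[Å/fs]²
MVV_TO_ENERGY = 1.0 / FORCE_TO_ACC  # 2390.057...

# pressure [atm] = PRESS_TO_ATM * (energy density) [kcal/(mol·Å³)]
PRESS_TO_ATM = 68568.415

# handy length conversions
NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0

# MSD unit conversion: Å²/fs^alpha -> cm²/s^alpha is 1e-16 * (1e15)^alpha;
# done in observables.fit_diffusion where alpha is known.
CM2_PER_A2 = 1.0e-16
FS_PER_S = 1.0e15
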