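# Coarse-grained force-field parameter set for DPPC bilayers with grafted
# cationic chitosan chains and Cl- counterions (Martini-style mapping).
#
# Species: Q0 (choline), Qa (phosphate), Na (glycerol), C1 (hydrocarbon
# tail), MW (water, 4:1 mapping), R1/R2/R3p (chitosan hydroxyl side chain /
# backbone / protonated amino sub-monomer), Cl (chloride counterion).
#
# Chitosan bonded terms carry repeat-unit offsets: "R2:1" means the R2 bead
# of the next repeat unit along the chain.  "BR0" is accepted as an alias
# for "R2:0" in dihedral rows.
#
# Units: sigma, r0 in angstrom; epsilon, Kb (per A^2), Ka1, Ki in kcal/mol;
# Ka2 in kcal/(mol rad^2); theta0, phi0 in degrees.

schema = 1
version = "1.0"
dielectric = 15.0
cutoff = 12.0

[integrity]
sha256 = "7159cf618e80208aca7cc442f8d66e333440e60c7f6f9d67459abf94b21b4959"

[[species]]
name = "Q0"
mass = 72.0
charge = 1

[[species]]
name = "Qa"
mass = 72.0
charge = -1

[[species]]
name = "Na"
mass = 72.0
charge = 0

[[species]]
name = "C1"
mass = 72.0
charge = 0

[[species]]
name = "MW"
mass = 72.0
charge = 0

[[species]]
name = "R1"
mass = 72.0
charge = 0

[[species]]
name = "R2"
mass = 72.0
charge = 0

[[species]]
name = "R3p"
mass = 72.0
charge = 1

[[species]]
name = "Cl"
mass = 72.0
charge = -1

# ---- nonbonded pair coefficients (printed rows; missing pairs mix) -------

[[pairs]]
species = [["Q0", "Q0"], ["C1", "C1"]]
sigma = 4.7
epsilon = 0.836521

[[pairs]]
species = [["Qa", "Qa"], ["MW", "MW"]]
sigma = 4.7
epsilon = 1.195030

[[pairs]]
species = [["Na", "Na"], ["Q0", "Na"], ["Qa", "Na"]]
sigma = 4.7
epsilon = 0.956024

[[pairs]]
species = [["Q0", "Qa"]]
sigma = 4.7
epsilon = 1.075527

[[pairs]]
species = [["Q0", "C1"], ["Qa", "C1"]]
sigma = 6.2
epsilon = 0.478012

[[pairs]]
species = [["MW", "C1"]]
sigma = 4.7
epsilon = 0.478012

[[pairs]]
species = [["Na", "C1"]]
sigma = 4.7
epsilon = 0.645316

[[pairs]]
species = [["Q0", "MW"], ["Qa", "MW"]]
sigma = 4.7
epsilon = 1.338434

[[pairs]]
species = [["Na", "MW"]]
sigma = 4.7
epsilon = 0.956024

[[pairs]]
species = [["R1", "R1"], ["R2", "R2"], ["R1", "R2"]]
sigma = 4.7
epsilon = 1.195030

[[pairs]]
species = [["R1", "R3p"], ["R2", "R3p"], ["R3p", "R3p"]]
sigma = 4.7
epsilon = 1.338434

[[pairs]]
species = [["R1", "MW"], ["R2", "MW"], ["R1", "Qa"], ["R2", "Qa"]]
sigma = 4.7
epsilon = 1.195030

[[pairs]]
species = [["R1", "C1"], ["R2", "C1"], ["R1", "Q0"], ["R2", "Q0"]]
sigma = 4.7
epsilon = 0.999834

[[pairs]]
species = [["R1", "Na"], ["R2", "Na"]]
sigma = 4.7
epsilon = 1.068867

[[pairs]]
species = [["R3p", "MW"], ["R3p", "Qa"]]
sigma = 4.7
epsilon = 1.264701

[[pairs]]
species = [["R3p", "C1"], ["R3p", "Q0"]]
sigma = 4.7
epsilon = 1.058124

[[pairs]]
species = [["R3p", "Na"]]
sigma = 4.7
epsilon = 1.131183

[[pairs]]
species = [["Cl", "Cl"]]
sigma = 4.83
epsilon = 0.012785

[[pairs]]
species = [["Cl", "C1"], ["Cl", "Q0"]]
sigma = 4.765
epsilon = 0.103416

[[pairs]]
species = [["Cl", "MW"], ["Cl", "Qa"]]
sigma = 4.765
epsilon = 0.123606

[[pairs]]
species = [["Cl", "Na"]]
sigma = 4.765
epsilon = 0.110556

# printed twice in the source table ("Cl-R2, Cl-R2"); the second entry is
# presumed Cl-R1, whose Lorentz-Berthelot value is identical to 6 decimals,
# so only the Cl-R2 row is kept and Cl-R1 resolves through mixing.
[[pairs]]
species = [["Cl", "R2"]]
sigma = 4.765
epsilon = 0.123606

[[pairs]]
species = [["Cl", "R3p"]]
sigma = 4.765
epsilon = 0.130812

# ---- harmonic bonds  V = Kb (r - r0)^2 -----------------------------------

[[bonds]]
species = ["Q0", "Qa"]
r0 = 4.7
Kb = 2.98

[[bonds]]
species = ["Qa", "Na"]
r0 = 4.7
Kb = 2.98

[[bonds]]
species = ["Na", "Na"]
r0 = 3.7
Kb = 2.98

[[bonds]]
species = ["Na", "C1"]
r0 = 4.7
Kb = 2.98

[[bonds]]
species = ["C1", "C1"]
r0 = 4.7
Kb = 2.98

[[bonds]]
species = ["R2", "R2"]
r0 = 5.212
Kb = 7.17

[[bonds]]
species = ["R2", "R3p"]
r0 = 1.934
Kb = 7.17

# printed as "R1-R1"; used for the R1 side-bead link to its unit's R2
# (the angle table implies R1-R2 connectivity; see package docs)
[[bonds]]
species = ["R1", "R2"]
r0 = 2.494
Kb = 7.17
printed_as = "R1-R1"

# ---- DPPC angles  V = Ka1 (cos(theta) - cos(theta0))^2 -------------------

[[angles_cos2]]
species = ["Qa", "Na", "Na"]
theta0 = 120.0
Ka1 = 5.97

[[angles_cos2]]
species = ["Na", "C1", "C1"]
theta0 = 180.0
Ka1 = 5.97

[[angles_cos2]]
species = ["C1", "C1", "C1"]
theta0 = 180.0
Ka1 = 5.97

# ---- chitosan angles  V = Ka2 (theta - theta0)^2, theta in rad -----------

[[angles_harmonic]]
species = ["R1:0", "R2:0", "R3p:0"]
theta0 = 123.76
Ka2 = 107.553

[[angles_harmonic]]
species = ["R2:0", "R2:1", "R2:2"]
theta0 = 163.78
Ka2 = 83.652

[[angles_harmonic]]
species = ["R2:0", "R2:1", "R1:1"]
theta0 = 70.94
Ka2 = 107.553

[[angles_harmonic]]
species = ["R1:0", "R2:0", "R2:1"]
theta0 = 90.88
Ka2 = 23.9006

[[angles_harmonic]]
species = ["R3p:0", "R2:0", "R2:1"]
theta0 = 135.94
Ka2 = 71.7017

[[angles_harmonic]]
species = ["R3p:1", "R2:1", "R2:0"]
theta0 = 58.01
Ka2 = 191.205

# ---- chitosan dihedrals  V = Ki [1 + cos(ni*phi - phi0)] -----------------

[[dihedrals]]
species = ["R1:0", "R2:0", "R2:1", "R1:1"]
phi0 = 175.62
Ki = 1.91205
ni = 3
printed_as = "R10-BR0-R21-R11"

[[dihedrals]]
species = ["R1:0", "R2:0", "R2:1", "R3p:1"]
phi0 = -28.59
Ki = 2.39006
ni = 3

[[dihedrals]]
species = ["R3p:0", "R2:0", "R2:1", "R1:1"]
phi0 = 36.57
Ki = 4.3021
ni = 3
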