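# Default reaction scheme for aerated Fricke / Fricke-cystamine solutions at 25 C.
#
# Species: d = diffusion coefficient in 1e-9 m^2/s; charge in elementary charges;
# formula used for element/charge balance checks.  Cystamine (RSSR) is the doubly
# protonated diamino-disulfide (net +2 below pH 8); R = +NH3-CH2-CH2.
#
# Reactions: k25 in M^-1 s^-1 at infinite dilution.  Ids 2-3 and 6-21 carry the
# customary numbering of the Fricke-cystamine reaction scheme; 101-126 are the
# standard compiled pure-water radiolysis set (Elliot/Buxton-style constants);
# 201 is the standard thiyl self-termination.  "implicit_hplus" = +n means the
# reaction consumes n protons from the acid background (written "(+ H+)" in the
# scheme); water is always allowed implicitly.

[[species]]
name = "e_aq"
charge = -1
d = 4.9
formula = {}

[[species]]
name = "H"
charge = 0
d = 7.0
formula = { H = 1 }

[[species]]
name = "OH"
charge = 0
d = 2.2
formula = { H = 1, O = 1 }

[[species]]
name = "H2"
charge = 0
d = 4.8
formula = { H = 2 }

[[species]]
name = "H2O2"
charge = 0
d = 2.3
formula = { H = 2, O = 2 }

[[species]]
name = "H3O+"
charge = 1
d = 9.46
formula = { H = 3, O = 1 }
is_bulk = true

[[species]]
name = "OH-"
charge = -1
d = 5.27
formula = { H = 1, O = 1 }

[[species]]
name = "O2"
charge = 0
d = 2.4
formula = { O = 2 }
is_bulk = true

[[species]]
name = "O2-"
charge = -1
d = 1.75
formula = { O = 2 }

[[species]]
name = "HO2"
charge = 0
d = 2.3
formula = { H = 1, O = 2 }

[[species]]
name = "HO2-"
charge = -1
d = 1.4
formula = { H = 1, O = 2 }

[[species]]
name = "O3P"
charge = 0
d = 2.0
formula = { O = 1 }

[[species]]
name = "O3"
charge = 0
d = 1.75
formula = { O = 3 }

[[species]]
name = "Fe2+"
charge = 2
d = 0.72
formula = { Fe = 1 }
is_bulk = true

[[species]]
name = "Fe3+"
charge = 3
d = 0.6
formula = { Fe = 1 }

[[species]]
name = "RSSR"
charge = 2
d = 0.56
formula = { C = 4, H = 14, N = 2, S = 2 }
is_bulk = true

[[species]]
name = "RSSR-"
charge = 1
d = 0.56
formula = { C = 4, H = 14, N = 2, S = 2 }

[[species]]
name = "RSSR+"
charge = 3
d = 0.56
formula = { C = 4, H = 14, N = 2, S = 2 }

[[species]]
name = "RSSR2+"
charge = 4
d = 0.56
formula = { C = 4, H = 14, N = 2, S = 2 }

[[species]]
name = "RS"
charge = 1
d = 0.66
formula = { C = 2, H = 7, N = 1, S = 1 }

[[species]]
name = "RS-"
charge = 0
d = 0.66
formula = { C = 2, H = 7, N = 1, S = 1 }

[[species]]
name = "RSH"
charge = 1
d = 0.66
formula = { C = 2, H = 8, N = 1, S = 1 }

[[species]]
name = "RSOO"
charge = 1
d = 0.6
formula = { C = 2, H = 7, N = 1, O = 2, S = 1 }

[[species]]
name = "RSOOH"
charge = 1
d = 0.6
formula = { C = 2, H = 8, N = 1, O = 2, S = 1 }

[[species]]
name = "RSSSR"
charge = 2
d = 0.5
formula = { C = 4, H = 14, N = 2, S = 3 }

[[species]]
name = "R"
charge = 1
d = 0.8
formula = { C = 2, H = 7, N = 1 }

[[species]]
name = "RR"
charge = 2
d = 0.6
formula = { C = 4, H = 14, N = 2 }

[[species]]
name = "ROO"
charge = 1
d = 0.7
formula = { C = 2, H = 7, N = 1, O = 2 }

[[species]]
name = "ROOH"
charge = 1
d = 0.7
formula = { C = 2, H = 8, N = 1, O = 2 }

# ---------------------------------------------------------------- Fricke core

[[reactions]]
id = 6
reactants = ["OH", "Fe2+"]
products = ["Fe3+", "OH-"]
k25 = 3.4e8
kinetic_class = "partially-diffusion-controlled"
note = "ferrous oxidation by hydroxyl radical"

[[reactions]]
id = 7
reactants = ["HO2", "Fe2+"]
products = ["Fe3+", "HO2-"]
k25 = 7.9e5
kinetic_class = "bulk-pseudo-first-order"
note = "ferrous oxidation by hydroperoxyl radical"

[[reactions]]
id = 8
reactants = ["H2O2", "Fe2+"]
products = ["Fe3+", "OH", "OH-"]
k25 = 52.0
kinetic_class = "bulk-pseudo-first-order"
note = "Fenton step; regenerates OH"

[[reactions]]
id = 9
reactants = ["H", "Fe2+"]
products = ["Fe3+", "H2"]
k25 = 1.3e7
kinetic_class = "bulk-pseudo-first-order"
implicit_hplus = 1
note = "minor direct H-atom oxidation of Fe2+"

# ------------------------------------------------------------- cystamine set

[[reactions]]
id = 10
reactants = ["RSSR", "e_aq"]
products = ["RSSR-"]
k25 = 4.1e10
kinetic_class = "fully-diffusion-controlled"
note = "electron attachment to the disulfide"

[[reactions]]
id = 11
reactants = ["RSSR", "H"]
products = ["RS", "RSH"]
k25 = 8.0e9
kinetic_class = "fully-diffusion-controlled"
note = "H-atom induced S-S cleavage"

[[reactions]]
id = 12
reactants = ["RSSR", "OH"]
products = ["RSSR+"]
k25 = 1.7e10
kinetic_class = "fully-diffusion-controlled"
implicit_hplus = 1
note = "OH oxidation of the disulfide to the radical cation"

[[reactions]]
id = 13
reactants = ["RSSR-", "H3O+"]
products = ["RS", "RSH"]
k25 = 4.2e9
kinetic_class = "bulk-pseudo-first-order"
note = "protonation-assisted dissociation of the radical anion"

[[reactions]]
id = 14
reactants = ["RS", "O2"]
products = ["RSOO"]
k25 = 2.0e9
kinetic_class = "bulk-pseudo-first-order"
note = "thiyl peroxidation"

[[reactions]]
id = 15
reactants = ["RSOO", "Fe2+"]
products = ["Fe3+", "RSOOH"]
k25 = 1.0e7
kinetic_class = "bulk-pseudo-first-order"
implicit_hplus = 1
note = "ferrous oxidation by thiylperoxyl"

[[reactions]]
id = 16
reactants = ["RS", "Fe2+"]
products = ["Fe3+", "RS-"]
k25 = 2.5e8
kinetic_class = "bulk-pseudo-first-order"
note = "ferrous oxidation by thiyl"

[[reactions]]
id = 17
reactants = ["RS", "RSSR"]
products = ["RSSSR", "R"]
k25 = 1.0e6
kinetic_class = "bulk-pseudo-first-order"
note = "thiyl attack on the disulfide"

[[reactions]]
id = 18
reactants = ["R", "O2"]
products = ["ROO"]
k25 = 2.0e9
kinetic_class = "bulk-pseudo-first-order"
note = "carbon-radical peroxidation"

[[reactions]]
id = 19
reactants = ["ROO", "Fe2+"]
products = ["Fe3+", "ROOH"]
k25 = 7.9e5
kinetic_class = "bulk-pseudo-first-order"
implicit_hplus = 1
note = "ferrous oxidation by alkylperoxyl"

[[reactions]]
id = 20
reactants = ["RSSR+", "Fe2+"]
products = ["Fe3+", "RSSR"]
k25 = 2.0e6
kinetic_class = "bulk-pseudo-first-order"
note = "ferrous oxidation by the disulfide radical cation"

[[reactions]]
id = 21
reactants = ["RSSR+", "RSSR+"]
products = ["RSSR2+", "RSSR"]
k25 = 2.5e9
kinetic_class = "partially-diffusion-controlled"
note = "radical-cation disproportionation"

[[reactions]]
id = 201
reactants = ["RS", "RS"]
products = ["RSSR"]
k25 = 1.5e9
kinetic_class = "partially-diffusion-controlled"
note = "standard aminothiol thiyl self-termination"

[[reactions]]
id = 202
reactants = ["R", "R"]
products = ["RR"]
k25 = 1.0e9
kinetic_class = "partially-diffusion-controlled"
note = "standard alkyl-radical self-recombination"

# ------------------------------------------------- multiple-ionization chemistry

[[reactions]]
id = 2
reactants = ["O3P", "OH"]
products = ["HO2"]
k25 = 2.0e10
kinetic_class = "fully-diffusion-controlled"
note = "oxygen-atom + hydroxyl, HO2 source in high-LET tracks"

[[reactions]]
id = 126
reactants = ["O3P", "O2"]
products = ["O3"]
k25 = 3.7e9
kinetic_class = "bulk-pseudo-first-order"
note = "ozone formation; O3 treated as terminal at trace level"

[[reactions]]
id = 127
reactants = ["O3P", "H"]
products = ["OH"]
k25 = 2.0e10
kinetic_class = "fully-diffusion-controlled"
note = "oxygen-atom + hydrogen atom"

[[reactions]]
id = 128
reactants = ["O3P", "H2O2"]
products = ["OH", "HO2"]
k25 = 1.6e9
kinetic_class = "partially-diffusion-controlled"
note = "oxygen-atom + peroxide"

# ---------------------------------------------------- pure-water radiolysis set

[[reactions]]
id = 101
reactants = ["e_aq", "e_aq"]
products = ["H2", "OH-", "OH-"]
k25 = 5.5e9
kinetic_class = "fully-diffusion-controlled"
ionic_strength_exempt = true
note = "hydrated-electron self-recombination; no ionic-strength effect"

[[reactions]]
id = 102
reactants = ["e_aq", "H"]
products = ["H2", "OH-"]
k25 = 2.5e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 103
reactants = ["e_aq", "OH"]
products = ["OH-"]
k25 = 3.0e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 104
reactants = ["e_aq", "H2O2"]
products = ["OH", "OH-"]
k25 = 1.1e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 105
reactants = ["e_aq", "H3O+"]
products = ["H"]
k25 = 2.3e10
kinetic_class = "bulk-pseudo-first-order"
note = "acid conversion of the hydrated electron"

[[reactions]]
id = 106
reactants = ["e_aq", "O2"]
products = ["O2-"]
k25 = 1.9e10
kinetic_class = "bulk-pseudo-first-order"

[[reactions]]
id = 107
reactants = ["e_aq", "HO2"]
products = ["HO2-"]
k25 = 2.0e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 108
reactants = ["e_aq", "O2-"]
products = ["HO2-", "OH-"]
k25 = 1.3e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 109
reactants = ["H", "H"]
products = ["H2"]
k25 = 7.8e9
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 110
reactants = ["H", "OH"]
products = []
k25 = 7.0e9
kinetic_class = "fully-diffusion-controlled"
note = "water reformation"

[[reactions]]
id = 111
reactants = ["H", "H2O2"]
products = ["OH"]
k25 = 9.0e7
kinetic_class = "partially-diffusion-controlled"

[[reactions]]
id = 112
reactants = ["H", "O2"]
products = ["HO2"]
k25 = 2.1e10
kinetic_class = "bulk-pseudo-first-order"

[[reactions]]
id = 113
reactants = ["H", "HO2"]
products = ["H2O2"]
k25 = 1.0e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 114
reactants = ["H", "O2-"]
products = ["HO2-"]
k25 = 1.0e10
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 3
reactants = ["OH", "OH"]
products = ["H2O2"]
k25 = 5.5e9
kinetic_class = "fully-diffusion-controlled"
note = "intratrack peroxide formation"

[[reactions]]
id = 116
reactants = ["OH", "H2"]
products = ["H"]
k25 = 4.2e7
kinetic_class = "partially-diffusion-controlled"

[[reactions]]
id = 117
reactants = ["OH", "H2O2"]
products = ["HO2"]
k25 = 2.7e7
kinetic_class = "partially-diffusion-controlled"

[[reactions]]
id = 118
reactants = ["OH", "HO2"]
products = ["O2"]
k25 = 7.9e9
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 119
reactants = ["OH", "O2-"]
products = ["O2", "OH-"]
k25 = 8.0e9
kinetic_class = "fully-diffusion-controlled"

[[reactions]]
id = 120
reactants = ["HO2", "HO2"]
products = ["H2O2", "O2"]
k25 = 8.3e5
kinetic_class = "partially-diffusion-controlled"

[[reactions]]
id = 121
reactants = ["HO2", "O2-"]
products = ["HO2-", "O2"]
k25 = 9.7e7
kinetic_class = "partially-diffusion-controlled"

[[reactions]]
id = 122
reactants = ["OH-", "H3O+"]
products = []
k25 = 1.43e11
kinetic_class = "bulk-pseudo-first-order"
note = "neutralization"

[[reactions]]
id = 123
reactants = ["O2-", "H3O+"]
products = ["HO2"]
k25 = 4.78e10
kinetic_class = "bulk-pseudo-first-order"
note = "superoxide protonation, pKa 4.8; effectively instantaneous at pH 0.46"

[[reactions]]
id = 124
reactants = ["HO2-", "H3O+"]
products = ["H2O2"]
k25 = 5.0e10
kinetic_class = "bulk-pseudo-first-order"

[equilibria]
"O2-/HO2" = 4.8
"HO2-/H2O2" = 11.6
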