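# trackchem

Monte Carlo track chemistry of the aerated ferrous sulfate (Fricke)
dosimeter under fast carbon-ion irradiation, with the radioprotector
cystamine and an optional double-ionization (MI) channel.

`trackchem` is for radiation chemists and radiobiology modellers who want
to predict how the radiolytic ferric yield G(Fe³⁺) of the Fricke dosimeter
— and its suppression by a radical-scavenging radioprotector — depends on
the linear energy transfer (LET) of the beam.  Carbon ions from 6 to
500 MeV per nucleon (LET ≈ 248 down to 9.3 keV/µm) and cystamine
concentrations from 10⁻⁶ to 1 M are covered.

## The model

The aerated dosimeter (1 mM FeSO₄, 0.4 M H₂SO₄, 2.5×10⁻⁴ M O₂) converts
every escaping radical into ferric ions with fixed stoichiometry:

    G(Fe³⁺) = 3·[g(H•) + g(HO₂•)] + g(•OH) + 2·g(H₂O₂)

where the g's are the escape (primary) yields per 100 eV.  LET controls
those escape yields through track structure: low-LET tracks are strings of
isolated spurs that mostly emit radicals; high-LET tracks are dense
columns in which radicals recombine into molecular products before they
can escape.  Cystamine (RSSR, doubly protonated below pH 8) competes with
Fe²⁺ for e⁻aq, H• and •OH (k = 4.1×10¹⁰, 8×10⁹ and 1.7×10¹⁰ M⁻¹ s⁻¹),
diverting the oxidizing equivalents into thiyl/disulfide-radical channels
that yield fewer ferric ions — the chemical signature of its
radioprotective action.

The pipeline has three stages:

1. **`trackchem.track`** — a parametric 1-ps track generator: energy
   deposition events along the ion path (spacing set by the LET), each
   spawning charge-balanced decomposition patterns, with a δ-ray penumbra
   deposited as strings of ~25 eV sub-spurs following the classical 1/r²
   amorphous-track dose profile.  The geometry was calibrated once against
   the no-cystamine dosimeter yields and is frozen.
2. **`trackchem.irt`** — an independent-reaction-times (IRT) stochastic
   engine for the nonhomogeneous stage (1 ps–1 µs): pairwise first-passage
   times W(t) = (R/r₀)·erfc((r₀−R)/2√(Dt)), pseudo-first-order scavenging
   by the bulk solutes, earliest-event execution, full event logs.
3. **`trackchem.bulk`** — the homogeneous continuation to 200 s as an
   exact linear pseudo-first-order cascade (matrix exponential), carrying
   per-reaction ferric extents (HO₂• in ~10 ms, H₂O₂ and RSSR•⁺ by
   ~200 s).

The reaction scheme (45+ reactions: ferrous oxidation, twelve cystamine
channels, a standard pure-water set, oxygen-atom chemistry for MI) ships
as an editable TOML file with element/charge balance validation and
ionic-strength-corrected rate constants.

## Worked example

```python
import trackchem as tc

beam = tc.BeamSpec(energy_per_nucleon=500.0)       # 9.3 keV/um carbon ions
res = tc.run_kinetics_experiment(beam, cystamine_conc=1e-3,
                                 replicates=10, seed=1)
print(f"G(Fe3+) at 200 s: {res.g_fe3_200s:.2f} "
      f"+- {res.stderr_200s:.2f} molecules/100 eV")
for rid, ext in res.table.fe3_channels(tc.load_scheme()).items():
    print(f"  reaction {rid:3d}: dG = {ext[-1]:.2f}")
```

prints (seed 1):

```
G(Fe3+) at 200 s: 9.10 +- 0.07 molecules/100 eV
  reaction   6: dG = 0.10
  reaction   7: dG = 1.30
  reaction   8: dG = 1.88
  reaction   9: dG = 0.00
  reaction  15: dG = 0.46
  reaction  16: dG = 1.49
  reaction  19: dG = 0.01
  reaction  20: dG = 3.86
```

Without cystamine the same beam gives G ≈ 13.0; the drop to ≈9.1 at
10⁻³ M is cystamine protecting Fe²⁺, and the channel decomposition shows
where the remaining ferric ions come from: the fast thiyl route
(reaction 16, microseconds), the thiylperoxyl and hydroperoxyl routes
(15 and 7, up to ~10 ms), and the interlinked peroxide / radical-cation
pair (8 and 20) that completes on the tens-of-seconds scale.  One
molecule/100 eV equals 0.10364 µmol/J (`tc.convert_gvalue_units`).

A command-line layer wraps the same drivers:

```
trackchem simulate --energy 500 --cystamine 1e-3 --replicates 10 --out results/
trackchem scan --energy 500 --energy 6 --conc 0 --conc 1e-3 --conc 1
trackchem mi-compare --energy 6 --conc 1e-3 --mi 0.1
trackchem calibrate
```

Every run writes CSV tables plus JSON metadata containing the resolved
configuration hash and seeds; deterministic stages replay bit-identically.

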