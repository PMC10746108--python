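# Methods

`trackchem` predicts the radiolytic ferric-ion yield G(Fe³⁺) of the aerated
ferrous sulfate (Fricke) dosimeter — optionally containing the
radioprotector cystamine — under irradiation by fast carbon ions
(6–500 MeV per nucleon, LET ≈ 9.3–248 keV/µm).  The prediction chains three
stages; this note documents the model of each stage, its assumptions, the
parameters that matter, and what the synthetic track generator does and
does not capture.

## 1. Chemical system

The standard dosimeter is 1 mM FeSO₄ in air-saturated (2.5×10⁻⁴ M O₂)
aqueous 0.4 M H₂SO₄.  Sulfuric acid speciation assumes a complete first
dissociation and a second dissociation governed by Ka₂ = 1.2×10⁻²,
giving [H₃O⁺] ≈ 0.41 M and ionic strength I ≈ 0.43 M.  (The classical
"pH 0.46" of this recipe corresponds to the proton *activity*; with a
complete first dissociation the proton concentration cannot be below
0.4 M, so we keep the thermodynamic speciation and record both numbers.)
Cystamine (RSSR) is the doubly protonated diamino-disulfide (net charge +2
below pH 8); concentrations from 10⁻⁶ to 1 M are supported.

The reaction scheme (`data/default_scheme.toml`) combines:

* the ferrous-oxidation core — ⁠•OH, HO₂•, H₂O₂ and (minor) H• attacking
  Fe²⁺ (k = 3.4×10⁸, 7.9×10⁵, 52 and 1.3×10⁷ M⁻¹ s⁻¹ at 25 °C);
* the twelve cystamine channels most important for ferric production
  (electron attachment to the disulfide, H-atom and •OH attack,
  protonation-assisted dissociation of RSSR•⁻, thiyl chemistry through
  O₂ / Fe²⁺ / RSSR, the radical cation RSSR•⁺ and its disproportionation),
  plus two standard self-terminations, RS• + RS• → RSSR (1.5×10⁹) and
  R• + R• → R–R (1×10⁹), without which the cystamine-radical pool formed
  inside a track at high scavenger loading would have no termination
  channel at all;
* a standard compiled pure-water radiolysis set (Elliot/Buxton-style 25 °C
  constants) for the intratrack chemistry of e⁻aq, H•, •OH, H₂, H₂O₂,
  HO₂•/O₂•⁻, OH⁻;
* the oxygen-atom set active only when double ionization is enabled:
  O(³P) + •OH → HO₂•, + H• → •OH, + H₂O₂ → •OH + HO₂•, + O₂ → O₃.

Acid–base conversions (O₂•⁻→HO₂•, HO₂⁻→H₂O₂, OH⁻ neutralization) are
ordinary pseudo-first-order reactions with the 0.41 M proton background;
their 10–50 ps time constants make them effectively instantaneous while
keeping the bookkeeping uniform.  The electron's acid conversion
e⁻aq + H₃O⁺ → H• is likewise explicit, so cystamine can compete for the
electron at high concentration.

Every reaction is validated for element and charge balance (implicit H₂O
always allowed; implicit H⁺ only where declared), and the engine audits the
same balance event-by-event in the executed logs.

**Ionic strength.**  Rate constants between ions are corrected with the
25 °C Brønsted–Bjerrum / extended Debye–Hückel factor
10^(1.02 z_a z_b √I/(1+√I)) (Davies −0.3 I term available as an option);
the hydrated-electron self-recombination is exempt.  Two guard rails stem
from the formula's limited validity domain: (i) corrected constants are
capped at diffusion control for a 1.0 nm encounter radius (charge products
up to +9 would otherwise "enhance" rates 10³–10⁴-fold); (ii) by default I
counts the acid + FeSO₄ background only (≈0.43 M) — including a molar
cystamine salt would push I to ≈3.4 M, far outside any Debye–Hückel-type
description.  Both behaviours are configurable.

## 2. Synthetic 1-ps track model

A full physical-stage transport code is deliberately out of scope; the
generator is a parametric stand-in that reproduces the *chemical
consequences* of carbon-ion track structure.  This is the central
approximation of the package.

Energy deposition events are placed along the ion path with exponential
spacing of mean E_event/LET.  Each event spawns Poisson numbers of three
charge-balanced decomposition patterns per 100 eV: ionization
{e⁻aq, •OH, H₃O⁺} (4.5), dissociative excitation {H•, •OH} (0.6), and a
molecular channel {H₂, H₂O₂} (0.15) — the 1-ps yield table.  Species are
placed with Gaussian scale σ around the event center; electrons wider
(×2.2) to mimic thermalization.

A fraction f of each event's energy is carried into the penumbra by δ
rays, sampled from a 1/T² energy spectrum (25 eV–2 keV): each δ ray is
anchored at a radial distance following the classical amorphous-track 1/r²
dose profile (between σ and r_max) and deposits its energy as a *string*
of ~25 eV sub-spurs spaced 3 nm apart.  The string structure matters: at
high scavenger loading the captured radicals terminate against their
δ-ray siblings, while for the pure dosimeter the strings behave like
isolated small spurs.  A Gaussian or independently-scattered penumbra
cannot reproduce both regimes at once.

The LET of a beam follows a four-point log–log table
(500 → 9.3, 300 → 11.7, 70 → 34.5, 6 → 248 keV/µm for ¹²C⁶⁺); segments are
sized to hold ≈6000 species at low LET and ≈9000 at 248 keV/µm, with a
100 nm guard region beyond both ends (roughly 3× the diffusion length over
the intratrack recombination window).  Only species born of central events
are scored; reaction products inherit the mean centrality weight of their
parents, making edge bias second order.

**Multiple ionization.**  With probability `mi_probability` an ionization
is a double ionization.  Since a double ionization costs roughly two
single-ionization quanta, each upgrade replaces *two* ionization patterns
by one {2 e⁻aq, 2 H₃O⁺, O(³P)} pattern — net −2 •OH + O(³P) per event,
energy-conserving and charge-balanced.  (Naively replacing a single
pattern would mint an extra electron and *raise* the ferric yield,
contradicting the known MI mechanism of reduced •OH/H₂O₂ production.)
The MI fraction is not measurable from this package's inputs; the default
0.10 reflects the order of magnitude of double/single outer-shell
ionization cross-section ratios for slow carbon ions and is exposed in the
configuration.  Higher-multiplicity ionizations are not modelled.

**Calibration.**  The geometry parameters are global — never per-LET —
and were calibrated *once* against the no-cystamine yields
(15.5 at the ⁶⁰Co-equivalent LET 0.3 keV/µm via the escape-yield identity,
and 13.3 / 11.2 / 7.2 at 9.3 / 34.5 / 248 keV/µm), then frozen:

| parameter | value | role |
|---|---|---|
| mean energy per event | 140 eV | inter-event spacing, spur size |
| spur σ | 1.0 nm | core radial scale |
| electron σ factor | 2.2 | thermalization distance |
| δ-ray energy fraction | 0.66 | core/penumbra split |
| δ-spur energy | 25 eV | penumbra granularity |
| penumbra r_max | 2000 nm | δ-ray range |

With these values the LET-series anchors are reproduced within ~3–4%
(the ⁶⁰Co-equivalent anchor sits ~6% low, the price of a single global
geometry across a 30-fold LET range) and the low-LET escape yields are
near the classical acid-dosimeter values (g(H•) ≈ 3.43 vs 3.70,
g(•OH) ≈ 3.06 vs 2.90, g(H₂O₂) ≈ 0.61 vs 0.80).
All cystamine-containing and MI predictions are out-of-sample.
`calibrate_track_model` re-runs the grid search programmatically.

## 3. IRT engine (nonhomogeneous stage, 1 ps – 1 µs)

The chemistry of the track is simulated with the independent reaction
times method: no trajectories are followed.  Each reactive pair receives a
first-passage time drawn by inverse transform from the free Brownian-pair
contact distribution W(t) = (R/r₀)·erfc((r₀−R)/2√(D_mut t)); the ultimate
reaction probability is R/r₀ and overlapping births react immediately.
Every particle additionally carries an exponential pseudo-first-order time
against each bulk solute (H₃O⁺, O₂, Fe²⁺, RSSR) with rate k_eff·c.  The
globally earliest event executes; products are placed at the encounter
point (single product) or at the consumed reactants' positions, receive
freshly sampled channels against the survivors, and existing independent
times are retained.  Ties are broken by creation order (simultaneous
independent events commute unless they share a particle, in which case the
order is deterministic anyway).

Numerical choices:

* **Encounter radii.**  All channels use R = k′/(4π D_mut) from the
  ionic-strength-corrected rate constant — the contact radius for fully
  diffusion-controlled reactions, a smaller Collins–Kimball-style
  effective radius for partially controlled ones.  Ultimate pair reaction
  probabilities are exact under this mapping; only sub-ns timing shifts.
* **Neighbour cutoff.**  Pair channels are generated within a per-pair-type
  cutoff R + 4√(2 D_mut t_eff), where t_eff is the expected joint survival
  time against scavenging (capped by the handoff time), globally capped at
  120 nm.  Pairs farther apart cannot diffuse into contact while both
  partners live.  A fixed small cutoff would silently truncate the
  microsecond-scale mutual termination of slow cystamine radicals.
* **Late products.**  When a product samples channels against survivors,
  partner positions are taken as their birth positions diffused by
  √(2 D Δt); the no-reaction conditioning of the partner's past motion is
  ignored (standard IRT approximation).
* **Coulomb corrections** to first-passage times are not applied: at
  I ≈ 0.43 M the Debye length (~0.45 nm) is below or near the encounter
  radii, and the net electrostatic effect is carried by the
  ionic-strength-corrected rate constants.
* **Handoff** at 1 µs (configurable): track expansion of the dosimeter is
  complete by ~0.2 µs at low LET; 1 µs adds margin for dense columns.
  Extending to 10 µs changes the 200-s yields by less than the replicate
  scatter.
* Bulk species in the 1-ps inventory (H₃O⁺) are counted but not simulated;
  species without channels ride to handoff untouched.

The engine was validated against the closed form W(t) and an independent
Brownian-dynamics walker (absorbing contact sphere with Brownian-bridge
crossing correction) at the 3σ level on 10⁵ samples, and audits
element/charge conservation on every event log.

## 4. Bulk stage (1 µs – 200 s)

After handoff the survivors are dilute relative to every background solute,
so the remaining kinetics is a linear pseudo-first-order cascade: each
trace species decays through its bulk channels and feeds its trace
products (e.g. H₂O₂ → Fe³⁺ + •OH at τ ≈ 19 s, the regenerated •OH
re-partitioning between Fe²⁺ and cystamine 1:50 at equal millimolar).
The cascade is propagated *analytically* with a matrix exponential on an
augmented system that accumulates exact per-reaction extents; an
independent stiff-ODE integration agrees to the solver's tolerance.
Trace–trace reactions are neglected here (single-track, low-dose-rate
limit); consequently the RSSR•⁺ disproportionation acts only inside the
track and ferric production from the radical cation proceeds through
Fe²⁺.  Cyclic cascades without decay are detected and rejected.

For a cystamine-free, MI-free run the asymptotic bulk yield reproduces the
stoichiometric identity G(Fe³⁺) = 3[g(H•)+g(HO₂•)] + g(•OH) + 2 g(H₂O₂)
from the handoff yields to machine precision (the audit excludes the minor
direct H• + Fe²⁺ channel, whose single-ferric stoichiometry the classical
relation ignores).

Channel completion times reproduce the canonical ordering: RS• + Fe²⁺ in
microseconds, HO₂• + Fe²⁺ around 10 ms, H₂O₂ + Fe²⁺ and the
production-limited RSSR•⁺ channel on the tens-of-seconds scale, complete
by ~200 s.  "200 s" readouts are the last grid point at exactly 200 s.

## 5. Experiment drivers and statistics

Replicate policy: ≥10 independent segments per condition at low LET, ≥5
shorter segments at 248 keV/µm; the mean and standard error of the 200-s
yield are reported (single-replicate runs are flagged as bar-less).  MI
comparisons pair the arms by seed.  Every result carries the resolved
configuration hash, seeds and package version; deterministic stages replay
bit-identically.

Problem sizes (≈6000–9000 species per segment, 5–10 replicates per
condition) were chosen so a full acceptance recomputation completes in
minutes on one core while keeping the replicate standard error of the
200-s yield below ~2%.

## 6. What the synthetic tracks do and do not capture

The generator reproduces: the spur-string → column transition with LET,
escape-yield magnitudes of the acid dosimeter, the scavenging-time scales
of cystamine capture, δ-ray clustering, and (optionally) the double
ionization channel.  It does not transport actual cross sections: the
spatial structure is a calibrated effective geometry, so agreement on the
calibration anchors says nothing about predictive power there (the
cystamine and MI results are the genuine out-of-sample tests).  It also
omits: local O₂/Fe²⁺ depletion inside dense columns (all bulk solutes are
held at fixed concentration, as in the pseudo-first-order treatment),
dry-electron scavenging above ~1 M cystamine, direct energy deposition in
solutes, dose-rate/multi-track effects, Bragg-peak depth structure, and
nuclear fragmentation.

## 7. Known limitations

* At 1 M cystamine the predicted 200-s yields run ~15–25% above the
  reference values (≈5.4 vs 4.4 at 9.3 keV/µm).  The regime is dominated
  by mutual termination of cystamine radicals inside the track, and the
  default scheme carries only the printed disproportionation plus the two
  standard self-terminations; additional cross-termination channels of the
  full (unpublished) cystamine table would lower this plateau.  The
  moderate-concentration regime (≤10⁻² M) does not suffer from this.
* The MI-induced reduction at 10⁻³ M is reproduced in sign but is weaker
  (≈2–4%) than the reference ≈5%; in an aerated system the O(³P) → HO₂•
  pathway offsets most of the •OH loss, and the net effect depends on the
  branching of O(³P) among •OH, H•, H₂O₂ and O₂ at high local density.
  At 1 M cystamine the paired difference is small (≈5%) but of opposite
  sign — removing •OH in the dense track spares reducing radicals that
  each become a ferric-producing thiyl radical — where the reference calls
  it almost negligible.  MI-off/MI-on pairs share their random streams
  (per-event counter-based substreams), so these differences are resolved
  well below the replicate scatter.
* Debye–Hückel-type corrections at I ≈ 0.43 M are extrapolations; all
  ionic-strength handling is explicit and configurable (form, Davies term,
  cap radius, solute accounting).
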