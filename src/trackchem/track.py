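"""Parametric 1-ps track model for carbon-ion segments.

This module stands in for the event-by-event physical/physicochemical
transport stage of a full track-structure code: it places energy-deposition
events along the ion path with exponential inter-event spacing set by the
LET, and spawns the ~1 ps species inventory of each event from a small set of
charge-balanced decomposition patterns:

* single ionization  ->  e_aq + OH + H3O+          (proton transfer)
* double ionization  ->  2 e_aq + 2 H3O+ + O(3P)   (when MI is enabled)
* dissociative excitation -> H + OH
* molecular channel  ->  H2 + H2O2

Species are scattered around each event center with a Gaussian radial scale
(electrons wider, to mimic thermalization).  A fraction of each event's
energy is carried off by delta rays into the classical amorphous-track
"penumbra": that energy is deposited as compact satellite sub-spurs
(~40 eV clusters, the Magee spur scale) whose centers are displaced
radially following the 1/r^2 penumbra dose profile between the core radius
and an outer radius set by the delta-ray range.  Penumbra species therefore
remain locally clustered (delta rays make track structure, not a diffuse
mist) while being dilute with respect to the track core.  The geometry
parameters are calibrated once against the known escape yields of the acid
dosimeter and then frozen; see :func:`calibrate_track_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: anchor table (energy MeV/u, LET keV/um) for 12C6+ ions
LET_TABLE = ((6.0, 248.0), (70.0, 34.5), (300.0, 11.7), (500.0, 9.3))

SINGLE_IONIZATION = ("e_aq", "OH", "H3O+")
DOUBLE_IONIZATION = ("e_aq", "e_aq", "H3O+", "H3O+", "O3P")
EXCITATION = ("H", "OH")
MOLECULAR = ("H2", "H2O2")


def let_for_energy(energy_per_nucleon: float) -> float:
    """LET (keV/um) of a carbon ion of the given energy (MeV/u).

    Tabulated at the four anchor energies, log-log interpolated between them;
    monotone decreasing in energy over 6-500 MeV/u.
    """
    e = float(energy_per_nucleon)
    energies = np.array([row[0] for row in LET_TABLE])
    lets = np.array([row[1] for row in LET_TABLE])
    if not energies[0] <= e <= energies[-1]:
        raise ValueError(
            f"energy {e} MeV/u outside the tabulated range "
            f"[{energies[0]}, {energies[-1]}]; supply the LET directly"
        )
    return float(
        np.exp(np.interp(np.log(e), np.log(energies), np.log(lets)))
    )


@dataclass(frozen=True)
class BeamSpec:
    """Ion beam described by energy per nucleon or directly by LET."""

    ion: str = "12C6+"
    energy_per_nucleon: float | None = None  # MeV/u
    let_value: float | None = None  # keV/um
    segment_length: float | None = None  # um; default chosen per LET

    def __post_init__(self) -> None:
        if (self.energy_per_nucleon is None) == (self.let_value is None):
            raise ValueError(
                "specify exactly one of energy_per_nucleon / let_value"
            )

    @property
    def let(self) -> float:
        """LET in keV/um (equivalently eV/nm)."""
        if self.let_value is not None:
            return self.let_value
        return let_for_energy(self.energy_per_nucleon)

    def resolved_length_um(self, target_particles: float, yield_per_ev: float) -> float:
        """Segment length: explicit, or sized so the segment holds roughly
        ``target_particles`` species."""
        if self.segment_length is not None:
            return self.segment_length
        energy_ev = target_particles / yield_per_ev
        return energy_ev / (self.let * 1000.0)


#: frozen defaults from the one-time geometry calibration against the
#: no-cystamine acid-dosimeter yields (see docs/methods.md)
DEFAULT_MEAN_ENERGY_PER_EVENT = 140.0
DEFAULT_SPUR_RADIUS_SIGMA = 1.0
DEFAULT_ELECTRON_SIGMA_FACTOR = 2.2
DEFAULT_PENUMBRA_FRACTION = 0.66
DEFAULT_PENUMBRA_R_MAX_NM = 2000.0
DEFAULT_DELTA_SPUR_ENERGY = 25.0
#: upper end of the sampled 1/T^2 delta-ray energy spectrum (eV)
DELTA_RAY_T_MAX = 2000.0
#: spacing of sub-spurs along a delta-ray string (nm)
DELTA_SPUR_SPACING_NM = 3.0

DEFAULT_INITIAL_YIELDS = {
    "e_aq": 4.5,
    "OH": 5.1,
    "H": 0.6,
    "H2": 0.15,
    "H2O2": 0.15,
    "H3O+": 4.5,
}


@dataclass(frozen=True)
class TrackModelParams:
    """Geometry and stoichiometry of the parametric 1-ps track model.

    ``initial_yields_1ps`` are molecules per 100 eV at 1 ps.  The pattern
    structure constrains them: g(OH) = g(e_aq) + g(H), g(H3O+) = g(e_aq) and
    g(H2O2) = g(H2); the independent entries are e_aq (ionization channel),
    H (excitation channel) and H2 (molecular channel).
    """

    mean_energy_per_event: float = DEFAULT_MEAN_ENERGY_PER_EVENT  # eV
    spur_radius_sigma: float = DEFAULT_SPUR_RADIUS_SIGMA  # nm
    electron_sigma_factor: float = DEFAULT_ELECTRON_SIGMA_FACTOR
    penumbra_fraction: float = DEFAULT_PENUMBRA_FRACTION
    penumbra_r_max_nm: float = DEFAULT_PENUMBRA_R_MAX_NM
    delta_spur_energy: float = DEFAULT_DELTA_SPUR_ENERGY  # eV
    initial_yields_1ps: dict = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_YIELDS)
    )
    mi_probability: float = 0.0
    guard_length_nm: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_energy_per_event <= 0:
            raise ValueError("mean_energy_per_event must be > 0")
        if self.spur_radius_sigma <= 0:
            raise ValueError("spur_radius_sigma must be > 0")
        if not 0.0 <= self.mi_probability <= 1.0:
            raise ValueError("mi_probability must be in [0, 1]")
        y = self.initial_yields_1ps
        for name, g in y.items():
            if g < 0:
                raise ValueError(f"initial yield of {name} must be >= 0")
        for derived, expected in (
            ("OH", y.get("e_aq", 0.0) + y.get("H", 0.0)),
            ("H3O+", y.get("e_aq", 0.0)),
            ("H2O2", y.get("H2", 0.0)),
        ):
            if derived in y and not np.isclose(y[derived], expected, rtol=1e-6):
                raise ValueError(
                    f"initial_yields_1ps[{derived!r}] = {y[derived]} inconsistent "
                    f"with the event patterns (expected {expected})"
                )

    @property
    def channel_yields(self) -> dict:
        """Per-100-eV yields of the three decomposition channels."""
        y = self.initial_yields_1ps
        return {
            "ionization": y.get("e_aq", 0.0),
            "excitation": y.get("H", 0.0),
            "molecular": y.get("H2", 0.0),
        }

    @property
    def total_yield_per_ev(self) -> float:
        """Expected species (incl. H3O+) per eV of deposited energy."""
        ch = self.channel_yields
        per_100ev = 3 * ch["ionization"] + 2 * ch["excitation"] + 2 * ch["molecular"]
        return per_100ev / 100.0

    def as_dict(self) -> dict:
        return {
            "mean_energy_per_event": self.mean_energy_per_event,
            "spur_radius_sigma": self.spur_radius_sigma,
            "electron_sigma_factor": self.electron_sigma_factor,
            "penumbra_fraction": self.penumbra_fraction,
            "penumbra_r_max_nm": self.penumbra_r_max_nm,
            "delta_spur_energy": self.delta_spur_energy,
            "initial_yields_1ps": dict(self.initial_yields_1ps),
            "mi_probability": self.mi_probability,
            "guard_length_nm": self.guard_length_nm,
            "rng_seed": self.rng_seed,
        }


@dataclass
class TrackSegment:
    """The 1-ps inventory of a track segment.

    ``weights`` flags particles born inside the central scoring region (1.0)
    versus the guard regions beyond both segment ends (0.0); yields are
    normalized to the energy deposited in the central region only.
    ``species`` is an integer-coded array with lookup ``species_names``.
    """

    beam: BeamSpec
    let_value: float  # keV/um
    segment_length_nm: float
    deposited_energy: float  # eV, central region
    total_energy: float  # eV, incl. guard
    species_names: list
    species: np.ndarray  # (N,) int codes
    positions: np.ndarray  # (N, 3) nm, axis = x
    weights: np.ndarray  # (N,)
    birth_time: float = 1.0e-12  # s
    params: TrackModelParams | None = None

    @property
    def n_particles(self) -> int:
        return len(self.species)

    def species_of(self, i: int) -> str:
        return self.species_names[self.species[i]]

    def counts(self, central_only: bool = False) -> dict:
        """Particle counts per species (optionally weighted by centrality)."""
        out: dict = {}
        for code, name in enumerate(self.species_names):
            mask = self.species == code
            n = float(self.weights[mask].sum()) if central_only else int(mask.sum())
            if n:
                out[name] = n
        return out

    def initial_yields(self) -> dict:
        """G values (per 100 eV) of the 1-ps inventory in the central region."""
        return {
            name: 100.0 * n / self.deposited_energy
            for name, n in self.counts(central_only=True).items()
        }


def generate_track(
    beam: BeamSpec,
    params: TrackModelParams,
    *,
    seed: int | None = None,
    target_particles: float = 6000.0,
) -> TrackSegment:
    """Generate the 1-ps species inventory of one track segment.

    Events are placed along the x axis with exponential inter-event spacing
    of mean ``mean_energy_per_event / LET``; each event spawns Poisson counts
    of the three decomposition patterns, with a fraction ``mi_probability``
    of ionizations upgraded to double ionizations.  Identical seed and
    parameters give identical output.

    Randomness is split into three streams so that paired runs differing
    only in ``mi_probability`` share as much of the realization as possible
    (common-random-numbers coupling): the main stream drives event geometry
    and pattern counts, a dedicated stream drives the MI upgrades, and
    species placement uses counter-based per-event substreams.
    """
    seed_val = params.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed_val)
    key0 = np.random.SeedSequence(seed_val).generate_state(1, np.uint64)[0]
    rng_mi = np.random.default_rng((seed_val, 0x4D49))
    let_ev_nm = beam.let  # keV/um == eV/nm
    if let_ev_nm <= 0:
        raise ValueError("LET must be > 0")
    ch = params.channel_yields
    if ch["ionization"] <= 0 and ch["excitation"] <= 0 and ch["molecular"] <= 0:
        raise ValueError("all initial yields are zero")

    length_nm = 1000.0 * beam.resolved_length_um(
        target_particles, params.total_yield_per_ev
    )
    guard = params.guard_length_nm
    e_event = params.mean_energy_per_event
    spacing = e_event / let_ev_nm  # nm

    # event centers along the axis, covering [-guard, length + guard]
    n_expected = (length_nm + 2 * guard) / spacing
    n_draw = int(n_expected + 6.0 * np.sqrt(n_expected) + 20)
    gaps = rng.exponential(spacing, size=n_draw)
    x_events = -guard + np.cumsum(gaps)
    while x_events[-1] < length_nm + guard:  # pragma: no cover - rare top-up
        extra = rng.exponential(spacing, size=n_draw)
        x_events = np.concatenate([x_events, x_events[-1] + np.cumsum(extra)])
    x_events = x_events[x_events < length_nm + guard]
    n_primary = len(x_events)

    # split each primary event into a core deposition on the axis and
    # delta-ray energy carried into the penumbra.  Delta rays are sampled
    # from a 1/T^2 spectrum; each ray is anchored at a radial distance
    # following the 1/r^2 penumbra dose profile and deposits its energy as a
    # short *string* of sub-spurs along a random direction (low-energy
    # electrons make dense spur strings, not isolated blobs).
    f_pen = params.penumbra_fraction
    e_core = e_event * (1.0 - f_pen)
    centers = [np.column_stack([x_events, np.zeros((n_primary, 2))])]
    energies = [np.full(n_primary, e_core)]
    if f_pen > 0:
        e_delta = params.delta_spur_energy
        t_min, t_max = e_delta, DELTA_RAY_T_MAX
        # mean delta-ray energy of the 1/T^2 spectrum
        t_mean = t_min * np.log(t_max / t_min) / (1.0 - t_min / t_max)
        n_rays = rng.poisson(f_pen * e_event / t_mean, size=n_primary)
        total_rays = int(n_rays.sum())
        parent = np.repeat(np.arange(n_primary), n_rays)
        u = rng.random(total_rays)
        t_ray = t_min / (1.0 - u * (1.0 - t_min / t_max))
        n_spur = 1 + rng.poisson(np.maximum(t_ray / e_delta - 1.0, 0.0))
        total_sub = int(n_spur.sum())
        ray_of = np.repeat(np.arange(total_rays), n_spur)
        # ray anchor: radial 1/r^2 dose profile around the parent event
        r_min = params.spur_radius_sigma
        r_max = max(params.penumbra_r_max_nm, r_min * (1 + 1e-9))
        rho = r_min * (r_max / r_min) ** rng.random(total_rays)
        phi = rng.uniform(0.0, 2.0 * np.pi, total_rays)
        anchor = np.column_stack(
            [x_events[parent], rho * np.cos(phi), rho * np.sin(phi)]
        )
        # spur string along an isotropic direction, ~ a few nm per spur
        direction = rng.normal(size=(total_rays, 3))
        direction /= np.linalg.norm(direction, axis=1)[:, None]
        step_idx = np.concatenate([np.arange(n) for n in n_spur]) if total_sub else np.empty(0)
        centers.append(
            anchor[ray_of]
            + direction[ray_of] * (DELTA_SPUR_SPACING_NM * step_idx)[:, None]
        )
        energies.append(np.full(total_sub, e_delta))
    ev_center = np.vstack(centers)
    ev_energy = np.concatenate(energies)
    n_events = len(ev_energy)
    central = (ev_center[:, 0] >= 0.0) & (ev_center[:, 0] < length_nm)

    # per-event Poisson pattern counts
    lam = ev_energy / 100.0
    n_ion = rng.poisson(lam * ch["ionization"])
    n_exc = rng.poisson(lam * ch["excitation"])
    n_mol = rng.poisson(lam * ch["molecular"])
    if params.mi_probability > 0.0:
        # a double ionization costs roughly two single-ionization quanta:
        # each upgrade replaces TWO single ionizations by one
        # {2 e_aq, 2 H3O+, O(3P)} pattern, so MI removes OH yield (the
        # proton-transfer channel is bypassed) without minting electrons
        n_double = rng_mi.binomial(n_ion, params.mi_probability)
        n_double = np.minimum(n_double, n_ion // 2)
    else:
        n_double = np.zeros(n_events, dtype=int)
    n_single = n_ion - 2 * n_double

    names: list = []
    codes: dict = {}
    sp_chunks, ev_chunks, rank_chunks = [], [], []

    def emit(pattern, counts, rank):
        total = int(counts.sum())
        if total == 0:
            return
        for sp in pattern:
            code = codes.setdefault(sp, len(names))
            if code == len(names):
                names.append(sp)
            sp_chunks.append(np.full(total, code, dtype=np.int32))
            ev_chunks.append(np.repeat(np.arange(n_events), counts))
            rank_chunks.append(np.full(total, rank, dtype=np.int8))

    # patterns untouched by the MI upgrade come first, so that the
    # per-event placement streams stay aligned between paired runs
    emit(EXCITATION, n_exc, 0)
    emit(MOLECULAR, n_mol, 1)
    emit(SINGLE_IONIZATION, n_single, 2)
    emit(DOUBLE_IONIZATION, n_double, 3)

    species = np.concatenate(sp_chunks) if sp_chunks else np.empty(0, np.int32)
    ev_idx = np.concatenate(ev_chunks) if ev_chunks else np.empty(0, np.int64)
    rank = np.concatenate(rank_chunks) if rank_chunks else np.empty(0, np.int8)

    order = np.lexsort((species, rank, ev_idx))
    species, ev_idx = species[order], ev_idx[order]

    # Gaussian placement around event centers (electrons wider), drawn from
    # counter-based per-event substreams
    sigma = np.full(len(species), params.spur_radius_sigma)
    e_code = codes.get("e_aq")
    if e_code is not None:
        sigma[species == e_code] *= params.electron_sigma_factor
    positions = np.empty((len(species), 3))
    bounds = np.searchsorted(ev_idx, np.arange(n_events + 1))
    for ev in range(n_events):
        a, b = bounds[ev], bounds[ev + 1]
        if a == b:
            continue
        sub = np.random.Generator(
            np.random.Philox(key=np.array([key0, np.uint64(ev)]))
        )
        positions[a:b] = sub.normal(size=(b - a, 3))
    positions *= sigma[:, None]
    positions += ev_center[ev_idx]

    weights = central[ev_idx].astype(float)
    deposited = float(ev_energy[central].sum())
    total = float(ev_energy.sum())

    return TrackSegment(
        beam=beam,
        let_value=let_ev_nm,
        segment_length_nm=length_nm,
        deposited_energy=deposited,
        total_energy=total,
        species_names=names,
        species=species,
        positions=positions,
        weights=weights,
        params=params,
    )


# ------------------------------------------------------------- calibration


@dataclass
class CalibrationResult:
    params: TrackModelParams
    objective: float
    history: list
    converged: bool


def calibrate_track_model(
    targets: dict,
    *,
    network,
    solution,
    base_params: TrackModelParams | None = None,
    grid: dict | None = None,
    replicates: int = 2,
    target_particles: float = 4000.0,
    t_handoff: float = 1.0e-6,
    seed: int = 12345,
    max_evals: int = 60,
) -> CalibrationResult:
    """One-time grid calibration of the global track-geometry parameters.

    ``targets`` maps an LET value (keV/um) to the stoichiometric dosimeter
    yield (3[g(H)+g(HO2)] + g(OH) + 2 g(H2O2), per 100 eV) that the escape
    yields at ``t_handoff`` should reproduce in the cystamine-free solution.
    The search is an exhaustive scan of ``grid`` (mean_energy_per_event,
    spur_radius_sigma, electron_sigma_factor, penumbra_fraction, ...); the
    best parameter set is returned and is meant to be frozen thereafter for
    all LETs, cystamine concentrations and MI settings.
    """
    from itertools import product

    from .experiments import fricke_stoichiometric_yield, PrimaryYields
    from .irt import run_track_stage, survivor_yields

    if max_evals <= 0:
        raise ValueError("calibration needs a positive evaluation budget")
    if not targets:
        raise ValueError("no calibration targets supplied")
    base = base_params or TrackModelParams()
    grid = grid or {
        "mean_energy_per_event": [40.0, 52.0, 65.0],
        "spur_radius_sigma": [2.0, 2.4, 3.0],
    }
    keys = sorted(grid)
    combos = list(product(*(grid[k] for k in keys)))[:max_evals]

    def simulated_sum(params: TrackModelParams, let: float, rep_seed: int) -> float:
        beam = BeamSpec(let_value=let)
        seg = generate_track(
            beam, params, seed=rep_seed, target_particles=target_particles
        )
        log = run_track_stage(
            seg, network, solution, t_handoff, np.random.default_rng(rep_seed + 1)
        )
        g = survivor_yields(log)
        return fricke_stoichiometric_yield(
            PrimaryYields(
                g_h=g.get("H", 0.0) + g.get("e_aq", 0.0),
                g_oh=g.get("OH", 0.0),
                g_h2o2=g.get("H2O2", 0.0),
                g_ho2=g.get("HO2", 0.0) + g.get("O2-", 0.0),
            )
        )

    history = []
    best = None
    for combo in combos:
        params = replace(base, **dict(zip(keys, combo)))
        sse = 0.0
        for let, target in targets.items():
            vals = [
                simulated_sum(params, let, seed + 1000 * rep)
                for rep in range(replicates)
            ]
            sse += ((np.mean(vals) - target) / target) ** 2
        history.append((dict(zip(keys, combo)), sse))
        if best is None or sse < best[1]:
            best = (params, sse)

    params, sse = best
    converged = sse < len(targets) * 0.01  # every anchor within ~10%
    return CalibrationResult(
        params=params, objective=sse, history=history, converged=converged
    )
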