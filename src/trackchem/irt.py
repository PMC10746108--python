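"""Independent-reaction-times (IRT) stochastic chemistry engine.

The nonhomogeneous (track) stage is simulated without following diffusive
trajectories: every reactive pair is assigned a first-passage reaction time
drawn from the free Brownian-pair contact distribution

    W(t) = (R / r0) * erfc((r0 - R) / (2 sqrt(D t))),

every particle additionally carries an exponential pseudo-first-order
"scavenging" time against the bulk solutes (H3O+, O2, Fe2+, cystamine), and
the globally earliest event is executed repeatedly until the handoff time.
Reaction products are placed at the encounter point and receive freshly
sampled channels against the surviving particles; existing independent times
are retained (standard IRT prescription).

All channel radii derive from the ionic-strength-corrected rate constants
via ``R = k' / (4 pi D_mutual)``, i.e. Collins-Kimball-style effective radii
for partially diffusion-controlled channels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfcinv

from .network import ReactionNetwork, effective_k
from .solution import BulkSolution
from .units import k_molar_to_per_molecule

#: upper bound (nm) on the per-pair-type neighbour cutoff; the cutoff of a
#: species pair is R + 4 sqrt(2 D_mut t_eff), where t_eff is the expected
#: joint survival time against pseudo-first-order scavenging (capped by the
#: handoff time) — pairs farther apart cannot diffuse into contact while
#: both partners are still alive
DEFAULT_CUTOFF_MAX_NM = 120.0

#: diffusion coefficient (nm^2/s) of the fastest simulated species (H atom),
#: used for the query margin when sampling channels for late-born products
_D_MAX_NM2_S = 7.0e9


def sample_pair_reaction_time(r0: float, big_r: float, d_mutual: float, rng) -> float:
    """First-passage reaction time of one Brownian pair (seconds, relative
    to the birth of the later particle), or ``inf`` ("never").

    Inverse-transform sampling of W(t); the ultimate reaction probability is
    ``R/r0``.  Overlapping birth (``r0 <= R``) reacts immediately (time 0).
    """
    if big_r <= 0 or d_mutual <= 0:
        raise ValueError("R and D_mutual must be > 0")
    if r0 <= big_r:
        return 0.0
    u = rng.random()
    p = big_r / r0
    if u >= p:
        return np.inf
    arg = float(erfcinv(u / p))
    if arg <= 0:
        return np.inf
    return ((r0 - big_r) / (2.0 * arg)) ** 2 / d_mutual


def _sample_pair_times(r0, big_r, d_mutual, u) -> np.ndarray:
    """Vectorized inverse-transform of W(t); ``inf`` where no reaction."""
    t = np.full(np.shape(r0), np.inf)
    contact = r0 <= big_r
    t[contact] = 0.0
    live = (~contact) & (u * r0 < big_r)
    if np.any(live):
        arg = erfcinv(u[live] * r0[live] / big_r[live])
        tt = np.full(arg.shape, np.inf)
        good = arg > 0
        dm = d_mutual[live] if np.ndim(d_mutual) else d_mutual
        dmg = dm[good] if np.ndim(dm) else dm
        tt[good] = ((r0[live][good] - big_r[live][good]) / (2.0 * arg[good])) ** 2 / dmg
        t[live] = tt
    return t


def sample_scavenging_time(scavenging_power: float, rng) -> float:
    """Exponential pseudo-first-order reaction time (s); ``inf`` when the
    scavenging power k*c (1/s) is zero."""
    if scavenging_power < 0:
        raise ValueError("scavenging power must be >= 0")
    if scavenging_power == 0:
        return np.inf
    return float(rng.exponential(1.0 / scavenging_power))


# ---------------------------------------------------------------- event log


@dataclass
class EventLog:
    """Executed reaction events of one track-stage run plus the bookkeeping
    needed to derive yields: initial inventory, per-event species deltas and
    the survivor inventory at handoff.  All counts are centrality-weighted
    (guard-region particles carry weight 0)."""

    species_names: list
    initial_counts: np.ndarray  # weighted counts per species code at 1 ps
    deposited_energy: float  # eV, central region
    t_handoff: float
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reaction_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    # flattened per-event species deltas (+1 produced / -1 consumed)
    delta_event: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    delta_code: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    delta_count: np.ndarray = field(default_factory=lambda: np.empty(0))
    provenance: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def code_of(self, name: str) -> int:
        return self.species_names.index(name)

    def inventory(self, t: float | None = None) -> np.ndarray:
        """Weighted net inventory per species code at time ``t``
        (default: handoff)."""
        inv = self.initial_counts.astype(float).copy()
        if self.n_events:
            mask = np.ones(self.n_events, bool) if t is None else self.times <= t
            keep = mask[self.delta_event]
            np.add.at(
                inv,
                self.delta_code[keep],
                self.delta_count[keep] * self.weights[self.delta_event[keep]],
            )
        return inv

    def survivor_yields(self) -> dict:
        """G values (per 100 eV) of the species inventory at handoff."""
        inv = self.inventory()
        return {
            name: 100.0 * inv[code] / self.deposited_energy
            for code, name in enumerate(self.species_names)
            if abs(inv[code]) > 1e-12
        }

    def to_frame(self):
        """Event table (time, reaction id, weight) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "reaction_id": self.reaction_ids,
                "weight": self.weights,
            }
        )


def survivor_yields(log: EventLog) -> dict:
    return log.survivor_yields()


def verify_conservation(log: EventLog, network: ReactionNetwork) -> None:
    """Audit element and charge conservation event-by-event.

    Every executed event's species deltas (including bulk co-reactants and
    implicit protons) must sum to an integer number of water molecules.
    Raises ``AssertionError`` on the first violating event.
    """
    from .species import ELEMENTS

    comp = np.array(
        [network.spec(s).composition_vector() for s in log.species_names],
        dtype=float,
    )  # (n_species, 1 + n_elements): charge first
    if not log.n_events:
        return
    n_ev = log.n_events
    totals = np.zeros((n_ev, comp.shape[1]))
    np.add.at(totals, log.delta_event, comp[log.delta_code] * log.delta_count[:, None])
    charge = totals[:, 0]
    elems = {el: totals[:, 1 + i] for i, el in enumerate(ELEMENTS)}
    bad = (
        (np.abs(charge) > 1e-9)
        | (np.abs(elems["H"] - 2 * elems["O"]) > 1e-9)
        | sum(
            (np.abs(elems[el]) > 1e-9)
            for el in ELEMENTS
            if el not in ("H", "O")
        ).astype(bool)
    )
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise AssertionError(
            f"event {i} (reaction {log.reaction_ids[i]}) violates "
            f"element/charge balance"
        )


# -------------------------------------------------------------- yield table


@dataclass
class YieldTable:
    """Time-dependent G values and per-reaction cumulative extents
    (molecules per 100 eV)."""

    times: np.ndarray
    species_names: list
    g_species: np.ndarray  # (n_species, n_times)
    reaction_ids: list
    g_extent: np.ndarray  # (n_reactions, n_times)

    def g(self, name: str) -> np.ndarray:
        return self.g_species[self.species_names.index(name)]

    def extent(self, rid: int) -> np.ndarray:
        return self.g_extent[self.reaction_ids.index(rid)]

    def fe3_channels(self, network: ReactionNetwork) -> dict:
        """Cumulative ferric-ion extents of each Fe3+-producing reaction."""
        return {
            rid: self.extent(rid)
            for rid in self.reaction_ids
            if "Fe3+" in network.reaction(rid).products
        }

    def to_frame(self):
        import pandas as pd

        data = {"t_s": self.times}
        for i, name in enumerate(self.species_names):
            data[f"G_{name}"] = self.g_species[i]
        for i, rid in enumerate(self.reaction_ids):
            data[f"dG_r{rid}"] = self.g_extent[i]
        return pd.DataFrame(data)


def time_dependent_yields(
    log: EventLog, deposited_energy: float, t_grid
) -> YieldTable:
    """G_X(t) = 100 * (net amount of X present/created by t) / E_dep, plus
    per-reaction cumulative extents, on a grid of times (seconds)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and t_grid.max() > log.t_handoff * (1 + 1e-9):
        raise ValueError("requested times beyond the simulated handoff")
    n_sp = len(log.species_names)
    n_t = len(t_grid)
    rids = sorted(set(log.reaction_ids.tolist()))

    g_species = np.zeros((n_sp, n_t))
    birth_bin = np.searchsorted(t_grid, 1.0e-12 * (1.0 - 1e-9))
    g_species[:, birth_bin:] += log.initial_counts[:, None]

    g_extent = np.zeros((len(rids), n_t))
    if log.n_events:
        ev_bin = np.searchsorted(t_grid, log.times)
        inside = ev_bin < n_t
        d_ev = log.delta_event
        keep = inside[d_ev]
        steps = np.zeros((n_sp, n_t + 1))
        np.add.at(
            steps,
            (log.delta_code[keep], ev_bin[d_ev[keep]]),
            log.delta_count[keep] * log.weights[d_ev[keep]],
        )
        g_species += np.cumsum(steps[:, :-1], axis=1)

        rid_index = {rid: i for i, rid in enumerate(rids)}
        rows = np.array([rid_index[r] for r in log.reaction_ids.tolist()])
        steps_r = np.zeros((len(rids), n_t + 1))
        np.add.at(
            steps_r, (rows[inside], ev_bin[inside]), log.weights[inside]
        )
        g_extent = np.cumsum(steps_r[:, :-1], axis=1)

    scale = 100.0 / deposited_energy
    return YieldTable(
        times=t_grid,
        species_names=list(log.species_names),
        g_species=g_species * scale,
        reaction_ids=rids,
        g_extent=g_extent * scale,
    )


# ------------------------------------------------------------------ engine


class _PairTable:
    """Per species-code-pair channel data: effective radius, mutual D,
    diffusion-horizon cutoff and the contributing reactions (several
    reactions sharing a reactant pair are combined; the executed channel is
    then chosen by rate)."""

    def __init__(
        self,
        network: ReactionNetwork,
        names: list,
        ionic_strength: float,
        scav_rate: np.ndarray,
        t_handoff: float,
        cutoff_max_nm: float,
    ):
        n = len(names)
        self.radius = np.zeros((n, n))  # 0 = no channel
        self.d_mutual = np.zeros((n, n))
        self.cutoff = np.zeros((n, n))
        self.rids: dict = {}
        idx = {name: i for i, name in enumerate(names)}
        for r in network.pair_reactions():
            a, b = r.reactants
            if a not in idx or b not in idx:
                continue
            i, j = idx[a], idx[b]
            k_eff = effective_k(network, r, ionic_strength)
            d_mut = network.spec(a).d_nm2_s + network.spec(b).d_nm2_s
            for key in {(i, j), (j, i)}:
                self.rids.setdefault(key, []).append((r, k_eff))
                self.d_mutual[key] = d_mut
        for (i, j), lst in self.rids.items():
            k_tot = sum(k for _, k in lst)
            big_r = k_molar_to_per_molecule(k_tot) / (
                4.0 * np.pi * self.d_mutual[i, j]
            )
            self.radius[i, j] = big_r
            lam = scav_rate[i] + scav_rate[j]
            t_eff = min(t_handoff, 1.0 / lam) if lam > 0 else t_handoff
            self.cutoff[i, j] = min(
                cutoff_max_nm,
                big_r + 4.0 * np.sqrt(2.0 * self.d_mutual[i, j] * t_eff),
            )
        self.cutoff_max = float(self.cutoff.max()) if n else 0.0

    def pick_reaction(self, i: int, j: int, rng):
        lst = self.rids[(i, j)]
        if len(lst) == 1:
            return lst[0][0]
        ks = np.array([k for _, k in lst])
        return lst[int(rng.choice(len(lst), p=ks / ks.sum()))][0]


def _build_scavenging(network, names, bulk, ionic_strength):
    """Per species code: total pseudo-first-order rate (1/s) and channels."""
    idx = {name: i for i, name in enumerate(names)}
    rates = np.zeros(len(names))
    channels: list = [[] for _ in names]
    for r in network.bulk_reactions():
        trace = network.trace_reactant_of(r)
        partner = network.bulk_reactant_of(r)
        c = bulk.conc(partner)
        if trace not in idx or c <= 0:
            continue
        lam = effective_k(network, r, ionic_strength) * c
        i = idx[trace]
        rates[i] += lam
        channels[i].append((r, lam))
    return rates, channels


class _ParticleStore:
    """Growing particle arrays with amortized appends."""

    def __init__(self, pos, spc, wgt, birth):
        n = len(spc)
        cap = max(2 * n, 1024)
        self.n = n
        self.pos = np.empty((cap, 3))
        self.spc = np.empty(cap, np.int32)
        self.wgt = np.empty(cap)
        self.birth = np.empty(cap)
        self.alive = np.zeros(cap, bool)
        self.pos[:n] = pos
        self.spc[:n] = spc
        self.wgt[:n] = wgt
        self.birth[:n] = birth
        self.alive[:n] = True

    def append(self, pos, spc, wgt, birth) -> int:
        if self.n == len(self.spc):
            cap = 2 * self.n
            for name in ("pos", "spc", "wgt", "birth", "alive"):
                old = getattr(self, name)
                new = np.empty((cap,) + old.shape[1:], old.dtype)
                new[: self.n] = old[: self.n]
                if name == "alive":
                    new[self.n:] = False
                setattr(self, name, new)
        i = self.n
        self.pos[i] = pos
        self.spc[i] = spc
        self.wgt[i] = wgt
        self.birth[i] = birth
        self.alive[i] = True
        self.n += 1
        return i


def run_track_stage(
    track,
    network: ReactionNetwork,
    bulk: BulkSolution,
    t_handoff: float,
    rng,
    *,
    cutoff_max_nm: float = DEFAULT_CUTOFF_MAX_NM,
) -> EventLog:
    """Simulate the nonhomogeneous chemistry of one track segment up to
    ``t_handoff`` (seconds); returns the complete :class:`EventLog`.

    ``track`` provides the 1-ps inventory (species, positions in nm,
    centrality weights).  Bulk species in the inventory (H3O+) are counted
    but not simulated as particles; species without any channel are carried
    untouched to handoff.
    """
    from scipy.spatial import cKDTree

    if t_handoff < track.birth_time:
        raise ValueError("t_handoff must be >= the 1 ps birth time")
    for name in track.species_names:
        if name not in network.species:
            raise ValueError(f"track species {name!r} unknown to the network")

    ionic_strength = bulk.ionic_strength or 0.0
    names = list(network.species)
    idx = {name: i for i, name in enumerate(names)}
    n_sp = len(names)
    h3o_code = idx.get("H3O+")

    # --- initial inventory -----------------------------------------------
    track_codes = np.array([idx[s] for s in track.species_names], dtype=np.int32)
    all_codes = track_codes[track.species]
    initial = np.zeros(n_sp)
    np.add.at(initial, all_codes, track.weights)

    is_bulk = np.array([network.spec(s).is_bulk for s in names])
    sim_mask = ~is_bulk[all_codes]
    store = _ParticleStore(
        np.ascontiguousarray(track.positions[sim_mask], dtype=float),
        all_codes[sim_mask],
        track.weights[sim_mask].astype(float),
        np.full(int(sim_mask.sum()), track.birth_time),
    )
    n0 = store.n
    t0 = track.birth_time

    scav_rate, scav_channels = _build_scavenging(network, names, bulk, ionic_strength)
    pair_table = _PairTable(
        network, names, ionic_strength, scav_rate, t_handoff, cutoff_max_nm
    )
    d_nm2 = np.array([network.spec(s).d_nm2_s for s in names])

    # --- initial channel sampling ----------------------------------------
    spc0 = store.spc[:n0]
    pos0 = store.pos[:n0]

    lam0 = scav_rate[spc0]
    scav_times = np.full(n0, np.inf)
    has_scav = lam0 > 0
    if np.any(has_scav):
        scav_times[has_scav] = t0 + rng.exponential(1.0 / lam0[has_scav])

    # widest cutoff among pair types that can actually occur at 1 ps
    present = np.unique(spc0)
    query_r = (
        float(pair_table.cutoff[np.ix_(present, present)].max())
        if len(present)
        else 0.0
    )
    tree = cKDTree(pos0)
    pairs = tree.query_pairs(query_r, output_type="ndarray") if query_r else []
    if len(pairs):
        si, sj = spc0[pairs[:, 0]], spc0[pairs[:, 1]]
        reactive = pair_table.radius[si, sj] > 0
        pairs = pairs[reactive]
        si, sj = si[reactive], sj[reactive]
        r0 = np.linalg.norm(pos0[pairs[:, 0]] - pos0[pairs[:, 1]], axis=1)
        within = r0 <= pair_table.cutoff[si, sj]
        pairs, si, sj, r0 = pairs[within], si[within], sj[within], r0[within]
        big_r = pair_table.radius[si, sj]
        d_mut = pair_table.d_mutual[si, sj]
        u = rng.random(len(pairs))
        tp = _sample_pair_times(r0, big_r, d_mut, u)
        finite = np.isfinite(tp)
        pair_times = t0 + tp[finite]
        pair_i = pairs[finite, 0].astype(np.int64)
        pair_j = pairs[finite, 1].astype(np.int64)
    else:
        pair_times = np.empty(0)
        pair_i = pair_j = np.empty(0, np.int64)

    fin = np.isfinite(scav_times)
    ev_t = np.concatenate([pair_times, scav_times[fin]])
    ev_i = np.concatenate([pair_i, np.flatnonzero(fin)])
    ev_j = np.concatenate([pair_j, np.full(int(fin.sum()), -1, np.int64)])
    order = np.argsort(ev_t, kind="stable")
    ev_t, ev_i, ev_j = ev_t[order], ev_i[order], ev_j[order]

    # --- event loop -------------------------------------------------------
    heap: list = []
    seq = 0
    out_t: list = []
    out_rid: list = []
    out_w: list = []
    d_ev: list = []
    d_code: list = []
    d_cnt: list = []

    def record(t, reaction, w, consumed_codes, produced_codes, bulk_code):
        ev = len(out_t)
        out_t.append(t)
        out_rid.append(reaction.id)
        out_w.append(w)
        for c in consumed_codes:
            d_ev.append(ev), d_code.append(c), d_cnt.append(-1.0)
        for c in produced_codes:
            d_ev.append(ev), d_code.append(c), d_cnt.append(1.0)
        if bulk_code is not None:
            d_ev.append(ev), d_code.append(bulk_code), d_cnt.append(-1.0)
        if reaction.implicit_hplus and h3o_code is not None:
            d_ev.append(ev), d_code.append(h3o_code)
            d_cnt.append(-float(reaction.implicit_hplus))

    def sample_channels_for(pid: int, t: float) -> None:
        """Fresh channels for a newly created particle vs the survivors."""
        nonlocal seq
        code = int(store.spc[pid])
        lam = scav_rate[code]
        if lam > 0:
            ts = t + rng.exponential(1.0 / lam)
            if ts <= t_handoff:
                heapq.heappush(heap, (ts, seq, pid, -1))
                seq += 1
        radius_row = pair_table.radius[code]
        cutoff_row = pair_table.cutoff[code]
        n = store.n
        cand = np.flatnonzero(store.alive[:n] & (radius_row[store.spc[:n]] > 0))
        cand = cand[cand != pid]
        if not len(cand):
            return
        dts = np.maximum(t - store.birth[cand], 0.0)
        margin = 4.0 * np.sqrt(2.0 * _D_MAX_NM2_S * float(dts.max()))
        dvec = store.pos[cand] - store.pos[pid]
        cut = cutoff_row[store.spc[cand]]
        close = np.einsum("ij,ij->i", dvec, dvec) <= (cut + margin) ** 2
        cand, dts = cand[close], dts[close]
        if not len(cand):
            return
        # partner positions diffused from birth to now (approximation: the
        # no-reaction conditioning of the partner's motion is ignored)
        sig = np.sqrt(2.0 * d_nm2[store.spc[cand]] * dts)
        moved = store.pos[cand] + rng.normal(size=(len(cand), 3)) * sig[:, None]
        r0 = np.linalg.norm(moved - store.pos[pid], axis=1)
        big_r = radius_row[store.spc[cand]]
        keep = r0 <= cutoff_row[store.spc[cand]]
        cand, r0, big_r = cand[keep], r0[keep], big_r[keep]
        if not len(cand):
            return
        d_mut = pair_table.d_mutual[code, store.spc[cand]]
        u = rng.random(len(cand))
        tp = _sample_pair_times(r0, big_r, d_mut, u)
        for k in np.flatnonzero(np.isfinite(tp)):
            te = t + tp[k]
            if te <= t_handoff:
                heapq.heappush(heap, (te, seq, pid, int(cand[k])))
                seq += 1

    def spawn(reaction, t, w, parent_ids):
        """Create product particles; returns all produced species codes."""
        parents = np.asarray(parent_ids)
        ppos = store.pos[parents]
        center = ppos.mean(axis=0)
        produced = [idx[name] for name in reaction.products]
        trace_products = [c for c in produced if not is_bulk[c]]
        if len(trace_products) <= 1:
            placements = [center] * len(trace_products)
        else:
            order_p = np.argsort(np.linalg.norm(ppos - center, axis=1))
            placements = [
                ppos[order_p[k % len(parents)]] for k in range(len(trace_products))
            ]
        for code, base in zip(trace_products, placements):
            pid = store.append(base, code, w, t)
            sample_channels_for(pid, t)
        return produced

    ptr = 0
    n_init = len(ev_t)
    while True:
        t_init = ev_t[ptr] if ptr < n_init else np.inf
        t_heap = heap[0][0] if heap else np.inf
        t_next = min(t_init, t_heap)
        if t_next > t_handoff or not np.isfinite(t_next):
            break
        if t_init <= t_heap:
            t, i, j = t_init, int(ev_i[ptr]), int(ev_j[ptr])
            ptr += 1
        else:
            t, _, i, j = heapq.heappop(heap)
        if not store.alive[i] or (j >= 0 and not store.alive[j]):
            continue
        if j < 0:
            code = int(store.spc[i])
            chans = scav_channels[code]
            if len(chans) == 1:
                reaction = chans[0][0]
            else:
                lams = np.array([lam for _, lam in chans])
                reaction = chans[int(rng.choice(len(chans), p=lams / lams.sum()))][0]
            store.alive[i] = False
            w = float(store.wgt[i])
            produced = spawn(reaction, t, w, [i])
            record(
                t, reaction, w, [code], produced,
                idx[network.bulk_reactant_of(reaction)],
            )
        else:
            ci, cj = int(store.spc[i]), int(store.spc[j])
            reaction = pair_table.pick_reaction(ci, cj, rng)
            store.alive[i] = store.alive[j] = False
            w = 0.5 * float(store.wgt[i] + store.wgt[j])
            produced = spawn(reaction, t, w, [i, j])
            record(t, reaction, w, [ci, cj], produced, None)

    return EventLog(
        species_names=names,
        initial_counts=initial,
        deposited_energy=track.deposited_energy,
        t_handoff=t_handoff,
        times=np.array(out_t),
        reaction_ids=np.array(out_rid, dtype=int),
        weights=np.array(out_w),
        delta_event=np.array(d_ev, dtype=int),
        delta_code=np.array(d_code, dtype=int),
        delta_count=np.array(d_cnt),
        provenance={
            "cutoff_max_nm": cutoff_max_nm,
            "query_radius_nm": query_r,
            "ionic_strength": ionic_strength,
            "n_initial_particles": int(n0),
            "t_handoff": t_handoff,
        },
    )
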