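"""Simulation orchestration: initial bundles, alternating chemistry/mechanics
evolution, flexible volume, steady-state detection, condition grids."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import chemistry as chem
from .chemistry import (NextReactionEngine, SpeciesField, SystemStalled,
                        catch_unbinding_rate, eligible_binding_pairs,
                        motor_walk_velocity, ratcheted_polymerization_rate,
                        slip_unbinding_rate)
from .mechanics import (LINKER, MOTOR, BoundElement, Filament, NetworkState,
                        boundary_load_force, linker_tension, minimize_network)
from .params import (MOLECULES_PER_UM_NM3, MONOMER_SIZE, MONOMERS_PER_CYLINDER,
                     ChemistryParams, MechanicalParams,
                     apply_treadmilling_factor)

UNIPOLAR = "unipolar"
APOLAR = "apolar"


@dataclass
class SimulationConfig:
    polarity: str = UNIPOLAR
    n_filaments: int = 30
    bundle_length: float = 2000.0          # nm
    lattice_spacing: float = 35.0          # nm
    box: tuple[float, float, float] = (3000.0, 1000.0, 1000.0)
    actin_concentration_uM: float = 5.0
    alpha_ratio: float = 0.1               # α:A mole ratio
    motor_ratio: float = 0.0225            # M:A (myosin head : actin)
    chi: float = 1.0
    treadmilling: bool = False
    duration_s: float = 2000.0
    snapshot_interval_s: float = 10.0
    dt_chem: float = 0.05
    seed: int = 0
    flexible_volume: bool = False
    volume_margin: float = 500.0
    force_tolerance: float = 1.0
    max_cg_iter: int = 500
    mech: MechanicalParams = field(default_factory=MechanicalParams)
    chem: ChemistryParams = field(default_factory=ChemistryParams)

    def __post_init__(self) -> None:
        errors = []
        if self.polarity not in (UNIPOLAR, APOLAR):
            errors.append(f"polarity must be unipolar|apolar, got {self.polarity!r}")
        if self.n_filaments < 1:
            errors.append("n_filaments must be >= 1")
        if self.bundle_length <= 0:
            errors.append("bundle_length must be > 0")
        if self.alpha_ratio <= 0 or self.motor_ratio <= 0:
            errors.append("mole ratios must be > 0")
        if self.duration_s <= 0:
            errors.append("duration_s must be > 0")
        if self.chi <= 0 and self.treadmilling:
            errors.append("chi must be > 0 when treadmilling")
        if self.snapshot_interval_s <= 0 or self.dt_chem <= 0:
            errors.append("snapshot_interval_s and dt_chem must be > 0")
        if errors:
            raise ValueError("; ".join(errors))

    def effective_chem(self) -> ChemistryParams:
        p = self.chem
        if not self.treadmilling:
            return p.replace(k_poly_plus=0.0, k_depoly_plus=0.0,
                             k_poly_minus=0.0, k_depoly_minus=0.0)
        return apply_treadmilling_factor(p, self.chi)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# initial geometry

def hex_lattice_positions(n: int, spacing: float) -> np.ndarray:
    """First ``n`` sites of a hexagonal lattice filled in concentric rings
    (1, 6, 12, ...) about the origin; nearest-neighbor distance = spacing."""
    pts = [(0, 0)]
    K = 1
    while len(pts) < n:
        for i in range(-K, K + 1):
            for j in range(-K, K + 1):
                if (i, j) == (0, 0) or max(abs(i), abs(j), abs(i + j)) != K:
                    continue
                pts.append((i, j))
        K += 1
    # axial -> cartesian
    out, cols = [], []
    for i, j in pts:
        x = spacing * (i + j / 2.0)
        y = spacing * (math.sqrt(3) / 2.0) * j
        out.append((x, y))
        cols.append(i)
    xy = np.array(out)
    ring = np.array([max(abs(i), abs(j), abs(i + j)) for i, j in pts])
    ang = np.arctan2(xy[:, 1], xy[:, 0])
    order = np.lexsort((ang, ring))
    xy = xy[order][:n]
    columns = np.array(cols)[order][:n]
    return xy, columns


def _straight_filament(x0: float, yz: np.ndarray, length: float,
                       sign: int) -> Filament:
    """A straight filament along ±X; beads run minus → plus end."""
    total = max(int(round(length / MONOMER_SIZE)), MONOMERS_PER_CYLINDER + 1)
    n_full, rem = divmod(total, MONOMERS_PER_CYLINDER)
    monomers = [MONOMERS_PER_CYLINDER] * n_full + ([rem] if rem else [])
    xs = np.concatenate([[0.0], np.cumsum(np.array(monomers) * MONOMER_SIZE)])
    if sign < 0:
        xs = -xs  # beads still minus->plus, but pointing toward -X
    beads = np.zeros((len(xs), 3))
    beads[:, 0] = x0 + xs - xs.min()
    beads[:, 1] = yz[0]
    beads[:, 2] = yz[1]
    return Filament(beads, np.array(monomers))


def build_initial_bundle(config: SimulationConfig) -> NetworkState:
    """Straight filaments of ``bundle_length`` on a hexagonal YZ lattice,
    aligned with X. Unipolar: all plus ends toward +X. Apolar: orientation
    alternates by lattice column, rebalanced to an even split."""
    box = np.asarray(config.box, dtype=float)
    xy, columns = hex_lattice_positions(config.n_filaments, config.lattice_spacing)
    span = np.ptp(xy, axis=0) if len(xy) > 1 else np.zeros(2)
    if np.any(span > box[1:] - 2 * config.lattice_spacing):
        raise ValueError("lattice cross-section does not fit the box")
    yz = xy + box[1:] / 2.0
    if config.polarity == UNIPOLAR:
        signs = np.ones(config.n_filaments, dtype=int)
    else:
        signs = np.where(columns % 2 == 0, 1, -1)
        want_plus = (config.n_filaments + 1) // 2
        excess = int(np.sum(signs == 1)) - want_plus
        flip_to = -1 if excess > 0 else 1
        idx = np.nonzero(signs == -flip_to)[0]
        for i in idx[: abs(excess)]:
            signs[i] = flip_to
    x0 = (box[0] - config.bundle_length) / 2.0
    fils = [_straight_filament(x0, yz[i], config.bundle_length, int(signs[i]))
            for i in range(config.n_filaments)]
    return NetworkState(fils, [], box)


def plus_end_direction_signs(state: NetworkState) -> np.ndarray:
    """Sign of each filament's plus-end direction along X."""
    return np.array([int(np.sign(f.plus_end[0] - f.minus_end[0]) or 1)
                     for f in state.filaments])


# ---------------------------------------------------------------------------
# steady state

@dataclass
class SteadyStateReport:
    observable: str
    times: np.ndarray
    values: np.ndarray
    onset_time: float | None    # None == not reached


def detect_steady_state(times: np.ndarray, values: np.ndarray, window: int,
                        rel_tol: float,
                        observable: str = "radius_of_gyration") -> SteadyStateReport:
    """Earliest time from which every subsequent sliding-window mean differs
    from the final-window mean by at most ``rel_tol`` (relative)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(values) < 2 * window:
        raise ValueError("series shorter than 2*window")
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    ref = means[-1]
    scale = abs(ref) if ref != 0 else 1.0
    ok = np.abs(means - ref) / scale <= rel_tol
    onset = None
    # the final window matches itself trivially; require at least one
    # additional window of steady data so a pure ramp is "not reached"
    for i in range(len(ok) - 1):
        if ok[i:].all():
            onset = float(times[i])
            break
    return SteadyStateReport(observable, times, values, onset)


# ---------------------------------------------------------------------------
# evolution engine

@dataclass
class Trajectory:
    config: SimulationConfig
    times: list[float] = field(default_factory=list)
    snapshots: list[NetworkState] = field(default_factory=list)
    free_totals: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    n_events: int = 0


class Simulation:
    """Alternates next-reaction chemistry spans with mechanical equilibration."""

    def __init__(self, config: SimulationConfig,
                 initial_state: NetworkState | None = None):
        self.config = config
        self.mech = config.mech
        self.chem = config.effective_chem()
        self.rng = np.random.default_rng(config.seed)
        if initial_state is not None:
            self.state = initial_state
            preloaded = list(initial_state.bound)
            initial_state.bound = []
        else:
            self.state = build_initial_bundle(config)
            preloaded = []
        self.engine = NextReactionEngine(self.rng)
        self.elements: dict[int, BoundElement] = {}
        self._next_eid = 0
        self.occupied: set = set()
        self.pair_cache: dict[str, list] = {LINKER: [], MOTOR: []}
        self.flags: list[str] = []
        self._init_species()
        self._init_channels()
        for e in preloaded:
            self._adopt_element(e)

    def _adopt_element(self, e: BoundElement) -> None:
        """Register a pre-bound element, drawing it from the free pool."""
        key = "linker" if e.species == LINKER else "motor"
        if self.field.total(key) == 0:
            raise ValueError(f"no free {key} available for preloaded element")
        self._take_free(key, 1)
        eid = self._next_eid
        self._next_eid += 1
        self.elements[eid] = e
        self.occupied.add(e.a)
        self.occupied.add(e.b)
        self.engine.add(("unbind", eid), "unbind", 0.0)
        if e.species == MOTOR:
            self.engine.add(("walk", eid, "a"), "walk", 0.0)
            self.engine.add(("walk", eid, "b"), "walk", 0.0)
        self._element_rates(eid)

    # -- species bookkeeping ------------------------------------------------
    def _init_species(self) -> None:
        box = self.state.box
        volume = float(np.prod(box))
        total_actin = int(round(self.config.actin_concentration_uM * volume
                                * MOLECULES_PER_UM_NM3))
        f_monomers = sum(f.total_monomers() for f in self.state.filaments)
        self.total_actin = max(total_actin, f_monomers)
        self.total_linker = int(round(self.config.alpha_ratio * self.total_actin))
        heads = self.chem.heads_per_minifilament
        self.total_motor = max(1, int(round(
            self.config.motor_ratio * self.total_actin / heads)))
        self.field = SpeciesField(box, self.chem.voxel_edge)
        self.field.set_uniform("actin", self.total_actin - f_monomers)
        self.field.set_uniform("linker", self.total_linker)
        self.field.set_uniform("motor", self.total_motor)

    def conservation_totals(self) -> dict:
        f_monomers = sum(f.total_monomers() for f in self.state.filaments)
        bound_l = sum(1 for e in self.elements.values() if e.species == LINKER)
        bound_m = sum(1 for e in self.elements.values() if e.species == MOTOR)
        return {
            "actin": self.field.total("actin") + f_monomers,
            "linker": self.field.total("linker") + bound_l,
            "motor": self.field.total("motor") + bound_m,
        }

    def free_totals(self) -> dict:
        return {s: self.field.total(s) for s in ("actin", "linker", "motor")}

    # -- channel setup ------------------------------------------------------
    def _init_channels(self) -> None:
        for fid in range(len(self.state.filaments)):
            for end in ("plus", "minus"):
                self.engine.add(("poly", fid, end), "poly", 0.0)
                self.engine.add(("depoly", fid, end), "depoly", 0.0)
        self.engine.add(("bind", LINKER), "bind", 0.0)
        self.engine.add(("bind", MOTOR), "bind", 0.0)
        self._hops_from: dict[tuple, list] = {}
        if self.field.n_voxels > 1:
            for (va, vb) in self.field.neighbor_pairs():
                axis = int(np.nonzero(np.subtract(vb, va))[0][0])
                for sp in ("actin", "linker", "motor"):
                    for src, dst in ((va, vb), (vb, va)):
                        cid = ("hop", sp, src, dst)
                        self.engine.add(cid, "hop", 0.0, payload=(sp, src, dst, axis))
                        self._hops_from.setdefault((sp, src), []).append(cid)
        self.refresh_mechanosensitive_rates()

    def _local_conc(self, species: str) -> float:
        """Free concentration (μM); exact for a single voxel."""
        vol = float(np.prod(self.state.box))
        return self.field.total(species) / (vol * MOLECULES_PER_UM_NM3)

    def _end_cylinder(self, f: Filament, end: str) -> int:
        return f.n_cylinders - 1 if end == "plus" else 0

    def _update_poly_rates(self) -> None:
        if (self.chem.k_poly_plus == 0 and self.chem.k_poly_minus == 0
                and self.chem.k_depoly_plus == 0 and self.chem.k_depoly_minus == 0):
            return
        conc = self._local_conc("actin")
        batch = max(1, self.chem.monomers_per_event)
        for fid, f in enumerate(self.state.filaments):
            for end in ("plus", "minus"):
                kon = (self.chem.k_poly_plus if end == "plus"
                       else self.chem.k_poly_minus)
                koff = (self.chem.k_depoly_plus if end == "plus"
                        else self.chem.k_depoly_minus)
                rate_on = kon * conc
                if rate_on > 0:
                    load = boundary_load_force(self.state, self.mech, f, end,
                                               self.chem.ratchet_range)
                    rate_on = ratcheted_polymerization_rate(
                        rate_on, load, self.chem, self.mech.kBT)
                if f.total_monomers() <= MONOMERS_PER_CYLINDER // 2 + batch:
                    koff = 0.0  # filaments cannot vanish (no re-nucleation)
                self.engine.set_rate(("poly", fid, end), rate_on / batch)
                self.engine.set_rate(("depoly", fid, end), koff / batch)

    def _update_hop_rates(self, only: list | None = None) -> None:
        if self.field.n_voxels <= 1:
            return
        cids = only if only is not None else [
            cid for cid, ch in self.engine.channels.items() if ch.kind == "hop"]
        for cid in cids:
            sp, va, vb, axis = self.engine.channels[cid].payload
            n = self.field.counts[sp][va]
            self.engine.set_rate(cid, n * self.field.hop_rate(sp, axis, self.chem))

    def _update_bind_rates(self) -> None:
        for species, key in ((LINKER, "linker"), (MOTOR, "motor")):
            pairs = eligible_binding_pairs(self.state, species, self.chem,
                                           self.occupied)
            self.pair_cache[species] = pairs
            kon = (self.chem.k_on_linker if species == LINKER
                   else self.chem.k_on_motor)
            rate = kon * self._local_conc(key) * len(pairs)
            self.engine.set_rate(("bind", species), rate)

    def _element_rates(self, eid: int) -> None:
        e = self.elements[eid]
        tension = linker_tension(e, self.state, self.mech)
        if e.species == LINKER:
            rate = slip_unbinding_rate(self.chem.k_off_linker, tension, self.chem)
            self.engine.set_rate(("unbind", eid), rate)
        else:
            rate = catch_unbinding_rate(self.chem.k_off_motor, max(tension, 0.0),
                                        self.chem.heads_per_side, self.chem)
            self.engine.set_rate(("unbind", eid), rate)
            for side in ("a", "b"):
                self.engine.set_rate(("walk", eid, side),
                                     self._walk_rate(e, side))

    def _walk_rate(self, e: BoundElement, side: str) -> float:
        att = e.a if side == "a" else e.b
        other = e.b if side == "a" else e.a
        fid, ci, frac = att
        f = self.state.filaments[fid]
        if ci >= f.n_cylinders - 1 and frac >= 1.0 - 1e-9:
            return 0.0  # parked at the plus tip
        pa = self.state.resolve(att)
        pb = self.state.resolve(other)
        d = np.linalg.norm(pa - pb)
        tension = self.mech.k_stretch_motor * (d - e.rest_length)
        u = f.tangent(min(ci, f.n_cylinders - 1))
        load = 0.0
        if d > 1e-9:
            dd_ds = float(np.dot(u, (pa - pb) / d))
            load = max(0.0, tension * dd_ds)
        v = motor_walk_velocity(self.chem.v_motor, load, self.chem.stall_force)
        return v / self.chem.walk_step

    def refresh_mechanosensitive_rates(self) -> None:
        self._update_poly_rates()
        self._update_bind_rates()
        self._update_hop_rates()
        for eid in list(self.elements):
            self._element_rates(eid)

    # -- event handlers -----------------------------------------------------
    def _handle(self, cid) -> None:
        kind = cid[0]
        if kind == "poly":
            self._do_poly(cid[1], cid[2])
        elif kind == "depoly":
            self._do_depoly(cid[1], cid[2])
        elif kind == "bind":
            self._do_bind(cid[1])
        elif kind == "unbind":
            self._do_unbind(cid[1])
        elif kind == "walk":
            self._do_walk(cid[1], cid[2])
        elif kind == "hop":
            sp, va, vb, _axis = self.engine.channels[cid].payload
            if self.field.counts[sp][va] > 0:
                self.field.counts[sp][va] -= 1
                self.field.counts[sp][vb] += 1
            # only channels leaving the two touched voxels change; totals
            # (hence well-mixed concentrations) are unaffected
            self._update_hop_rates(self._hops_from.get((sp, va), [])
                                   + self._hops_from.get((sp, vb), []))

    def _do_poly(self, fid: int, end: str) -> None:
        f = self.state.filaments[fid]
        batch = max(1, self.chem.monomers_per_event)
        avail = self.field.total("actin")
        n = min(batch, avail)
        if n == 0:
            self._update_poly_rates()
            return
        # remove monomers from the tip's voxel (well-mixed fallback)
        self._take_free("actin", n)
        remaining = n
        while remaining > 0:
            ci = self._end_cylinder(f, end)
            room = MONOMERS_PER_CYLINDER - f.monomers[ci]
            if room == 0:
                self._add_cylinder(fid, end)  # seeds with 1 monomer
                remaining -= 1
                continue
            add = min(room, remaining)
            f.monomers[ci] += add
            remaining -= add
        self._update_poly_rates()

    def _add_cylinder(self, fid: int, end: str) -> None:
        f = self.state.filaments[fid]
        seed_mon = 1
        if end == "plus":
            u = f.tangent(f.n_cylinders - 1)
            new = f.plus_end + u * seed_mon * MONOMER_SIZE
            f.beads = np.vstack([f.beads, new])
            f.monomers = np.append(f.monomers, seed_mon)
        else:
            u = f.tangent(0)
            new = f.minus_end - u * seed_mon * MONOMER_SIZE
            f.beads = np.vstack([new, f.beads])
            f.monomers = np.insert(f.monomers, 0, seed_mon)
            self._shift_attachments(fid, +1)

    def _do_depoly(self, fid: int, end: str) -> None:
        f = self.state.filaments[fid]
        batch = max(1, self.chem.monomers_per_event)
        floor = MONOMERS_PER_CYLINDER // 2
        removable = f.total_monomers() - floor
        n = min(batch, max(removable, 0))
        if n <= 0:
            self._update_poly_rates()
            return
        remaining = n
        while remaining > 0:
            ci = self._end_cylinder(f, end)
            take = min(int(f.monomers[ci]) - (1 if f.n_cylinders == 1 else 0),
                       remaining)
            if take <= 0:
                break
            f.monomers[ci] -= take
            remaining -= take
            if f.monomers[ci] == 0:
                self._remove_cylinder(fid, end)
        self._give_free("actin", n - remaining)
        self._update_poly_rates()

    def _remove_cylinder(self, fid: int, end: str) -> None:
        f = self.state.filaments[fid]
        ci = self._end_cylinder(f, end)
        for eid, e in list(self.elements.items()):
            for att in (e.a, e.b):
                if att[0] == fid and att[1] == ci:
                    self._do_unbind(eid, forced=True)
                    break
        if end == "plus":
            f.beads = f.beads[:-1]
            f.monomers = f.monomers[:-1]
        else:
            f.beads = f.beads[1:]
            f.monomers = f.monomers[1:]
            self._shift_attachments(fid, -1)

    def _shift_attachments(self, fid: int, delta: int) -> None:
        self.occupied = {(f2, c + delta, fr) if f2 == fid else (f2, c, fr)
                         for (f2, c, fr) in self.occupied}
        for e in self.elements.values():
            if e.a[0] == fid:
                e.a = (fid, e.a[1] + delta, e.a[2])
            if e.b[0] == fid:
                e.b = (fid, e.b[1] + delta, e.b[2])

    def _take_free(self, species: str, n: int) -> None:
        c = self.field.counts[species]
        flat = c.reshape(-1)
        for _ in range(n):
            idx = int(np.argmax(flat))
            flat[idx] -= 1

    def _give_free(self, species: str, n: int) -> None:
        flat = self.field.counts[species].reshape(-1)
        flat[int(np.argmin(flat))] += n

    def _do_bind(self, species: str) -> None:
        pairs = self.pair_cache[species]
        key = "linker" if species == LINKER else "motor"
        if not pairs or self.field.total(key) == 0:
            self._update_bind_rates()
            return

        def valid(site):
            fid, ci, _fr = site
            return ci < self.state.filaments[fid].n_cylinders

        for _ in range(20):
            sa, sb = pairs[self.rng.integers(len(pairs))]
            # the cache may be stale w.r.t. depolymerization since the last
            # mechanics refresh; skip pairs whose cylinders vanished
            if (sa not in self.occupied and sb not in self.occupied
                    and valid(sa) and valid(sb)):
                break
        else:
            self._update_bind_rates()
            return
        self._take_free(key, 1)
        rest = (self.mech.rest_length_linker if species == LINKER
                else self.mech.rest_length_motor)
        heads = None if species == LINKER else self.chem.heads_per_side
        eid = self._next_eid
        self._next_eid += 1
        e = BoundElement(species, sa, sb, rest, heads)
        self.elements[eid] = e
        self.occupied.add(sa)
        self.occupied.add(sb)
        self.engine.add(("unbind", eid), "unbind", 0.0)
        if species == MOTOR:
            self.engine.add(("walk", eid, "a"), "walk", 0.0)
            self.engine.add(("walk", eid, "b"), "walk", 0.0)
        self._element_rates(eid)
        # free count and available pairs changed
        self.pair_cache[species] = [p for p in pairs
                                    if sa not in p and sb not in p]
        self._rescale_bind(species)

    def _rescale_bind(self, species: str) -> None:
        key = "linker" if species == LINKER else "motor"
        kon = (self.chem.k_on_linker if species == LINKER
               else self.chem.k_on_motor)
        rate = kon * self._local_conc(key) * len(self.pair_cache[species])
        self.engine.set_rate(("bind", species), rate)

    def _do_unbind(self, eid: int, forced: bool = False) -> None:
        e = self.elements.pop(eid)
        key = "linker" if e.species == LINKER else "motor"
        self._give_free(key, 1)
        self.occupied.discard(e.a)
        self.occupied.discard(e.b)
        self.engine.remove(("unbind", eid))
        if e.species == MOTOR:
            self.engine.remove(("walk", eid, "a"))
            self.engine.remove(("walk", eid, "b"))
        if not forced:
            # the freed sites can rebind immediately; geometry is frozen
            # until the next mechanics refresh, so their pair is still in band
            self.pair_cache[e.species].append((e.a, e.b))
        self._rescale_bind(e.species)

    def _do_walk(self, eid: int, side: str) -> None:
        e = self.elements.get(eid)
        if e is None:
            return
        att = e.a if side == "a" else e.b
        fid, ci, frac = att
        f = self.state.filaments[fid]
        self.occupied.discard(att)
        step_left = self.chem.walk_step
        rl = f.rest_lengths()
        while step_left > 0:
            room = (1.0 - frac) * rl[ci]
            if step_left < room or ci >= f.n_cylinders - 1:
                frac = min(frac + step_left / rl[ci], 1.0)
                break
            step_left -= room
            ci += 1
            frac = 0.0
        new_att = (fid, ci, float(frac))
        if side == "a":
            e.a = new_att
        else:
            e.b = new_att
        self.occupied.add(new_att)
        self._element_rates(eid)

    # -- main loop ----------------------------------------------------------
    def _sync_bound(self) -> None:
        self.state.bound = list(self.elements.values())

    def mechanics_step(self) -> None:
        self._sync_bound()
        res = minimize_network(self.state, self.mech,
                               force_tolerance=self.config.force_tolerance,
                               max_iter=self.config.max_cg_iter)
        if not res.converged:
            self.flags.append(
                f"t={self.engine.t:.2f}s mechanics not converged "
                f"(max force {res.max_force:.2f} pN)")
        if self.config.flexible_volume:
            self.update_flexible_volume(self.config.volume_margin)
        self.refresh_mechanosensitive_rates()

    def update_flexible_volume(self, margin: float) -> None:
        """Resize the box X-extent to filament span + 2*margin; recenter the
        network; retile voxels conserving all free totals."""
        X = self.state.all_beads()
        span = X[:, 0].max() - X[:, 0].min()
        new_x = span + 2 * margin
        shift = margin - X[:, 0].min()
        for f in self.state.filaments:
            f.beads[:, 0] += shift
        box = self.state.box.copy()
        box[0] = new_x
        self.state.box = box
        self.field = self.field.retile(box, self.chem.voxel_edge)
        # the voxel graph may have changed shape: rebuild hop channels
        for cid, ch in list(self.engine.channels.items()):
            if ch.kind == "hop":
                self.engine.remove(cid)
        self._hops_from = {}
        if self.field.n_voxels > 1:
            for (va, vb) in self.field.neighbor_pairs():
                axis = int(np.nonzero(np.subtract(vb, va))[0][0])
                for sp in ("actin", "linker", "motor"):
                    for src, dst in ((va, vb), (vb, va)):
                        cid = ("hop", sp, src, dst)
                        self.engine.add(cid, "hop", 0.0,
                                        payload=(sp, src, dst, axis))
                        self._hops_from.setdefault((sp, src), []).append(cid)

    def chemistry_span(self, t_end: float) -> int:
        n = 0
        while True:
            t_next = self.engine.peek_time()
            if t_next > t_end:
                self.engine.t = t_end
                break
            cid, _wait = self.engine.next_event()
            self._handle(cid)
            n += 1
        return n

    def snapshot(self) -> NetworkState:
        self._sync_bound()
        return self.state.copy()

    def run(self) -> Trajectory:
        cfg = self.config
        traj = Trajectory(cfg)
        self.mechanics_step()
        traj.times.append(0.0)
        traj.snapshots.append(self.snapshot())
        traj.free_totals.append(self.free_totals())
        t = 0.0
        next_snap = cfg.snapshot_interval_s
        while t < cfg.duration_s - 1e-9:
            t_target = min(t + cfg.dt_chem, cfg.duration_s)
            traj.n_events += self.chemistry_span(t_target)
            t = t_target
            self.mechanics_step()
            if t + 1e-9 >= next_snap:
                traj.times.append(t)
                traj.snapshots.append(self.snapshot())
                traj.free_totals.append(self.free_totals())
                next_snap += cfg.snapshot_interval_s
        traj.flags = list(self.flags)
        return traj


def evolve(config: SimulationConfig,
           initial_state: NetworkState | None = None) -> Trajectory:
    """Run one trajectory; fully reproducible from (config, seed)."""
    return Simulation(config, initial_state).run()


# ---------------------------------------------------------------------------
# condition grids

@dataclass
class GridSpec:
    alpha_ratios: list[float]
    motor_ratios: list[float]
    chis: list[float] | None = None
    replicates: int = 8
    base: SimulationConfig = field(default_factory=SimulationConfig)
    seed0: int = 0

    def conditions(self) -> list[tuple]:
        if self.chis is None:
            return [(a, m) for m in self.motor_ratios for a in self.alpha_ratios]
        return [(a, m, c) for m in self.motor_ratios
                for a in self.alpha_ratios for c in self.chis]


def condition_id(cond: tuple) -> str:
    if len(cond) == 2:
        return f"aA{cond[0]:g}_MA{cond[1]:g}"
    return f"aA{cond[0]:g}_MA{cond[1]:g}_chi{cond[2]:g}"


def run_condition_grid(spec: GridSpec, progress=None):
    """Run every (condition, replicate); returns (results, failures).

    ``results`` maps condition id -> list of Trajectory; failures are
    recorded per condition and the grid continues.
    """
    results: dict[str, list[Trajectory]] = {}
    failures: dict[str, str] = {}
    for ci, cond in enumerate(spec.conditions()):
        cid = condition_id(cond)
        results[cid] = []
        for rep in range(spec.replicates):
            try:
                cfg = spec.base.replace(
                    alpha_ratio=cond[0], motor_ratio=cond[1],
                    chi=cond[2] if len(cond) == 3 else spec.base.chi,
                    treadmilling=len(cond) == 3 or spec.base.treadmilling,
                    seed=spec.seed0 + 1000 * ci + rep)
                results[cid].append(evolve(cfg))
            except Exception as exc:  # grid continues on partial failure
                failures[cid] = f"replicate {rep}: {exc!r}"
        if progress is not None:
            progress(cid)
    return results, failures
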