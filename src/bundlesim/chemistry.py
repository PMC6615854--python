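"""Stochastic reaction–diffusion machinery.

A next-reaction-method engine over explicit channels, the mechanochemical
rate laws (Brownian ratchet, slip bond, parallel-cluster catch bond, linear
force–velocity), the voxelized diffusing-species field, and the geometric
binding-site search.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable

import numpy as np

from .mechanics import LINKER, MOTOR, NetworkState
from .params import MOLECULES_PER_UM_NM3, ChemistryParams


class SystemStalled(Exception):
    """All propensities are zero: no reaction can fire."""


@dataclass
class ReactionChannel:
    kind: str
    rate: float                      # current propensity (1/s)
    payload: object = None           # opaque handle for the orchestrator
    tentative: float = math.inf
    _version: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("propensity must be >= 0")


class NextReactionEngine:
    """Gibson–Bruck next reaction method over a dynamic channel set.

    Tentative absolute firing times live in a lazy heap; rate updates rescale
    the remaining exponential budget so each channel's unit-exponential draw
    is reused, which is what makes the scheme statistically exact.
    """

    def __init__(self, rng: np.random.Generator, t0: float = 0.0):
        self.rng = rng
        self.t = t0
        self.channels: dict[Hashable, ReactionChannel] = {}
        self._heap: list[tuple[float, int, Hashable]] = []
        self._counter = itertools.count()

    def add(self, cid: Hashable, kind: str, rate: float, payload=None) -> None:
        if cid in self.channels:
            raise ValueError(f"duplicate channel id {cid!r}")
        ch = ReactionChannel(kind, 0.0, payload)
        self.channels[cid] = ch
        self.set_rate(cid, rate)

    def remove(self, cid: Hashable) -> None:
        del self.channels[cid]

    def set_rate(self, cid: Hashable, rate: float) -> None:
        if rate < 0:
            raise ValueError("propensity must be >= 0")
        ch = self.channels[cid]
        old = ch.rate
        if rate == old and math.isfinite(ch.tentative):
            return
        if rate == 0.0:
            ch.rate = 0.0
            ch.tentative = math.inf
            ch._version += 1
            return
        if old > 0.0 and math.isfinite(ch.tentative):
            remaining = (ch.tentative - self.t) * old / rate
        else:
            remaining = self.rng.exponential(1.0) / rate
        ch.rate = rate
        ch.tentative = self.t + remaining
        ch._version += 1
        heapq.heappush(self._heap, (ch.tentative, ch._version, cid))

    def next_event(self) -> tuple[Hashable, float]:
        """Pop the channel with minimal tentative time; advance the clock.

        Returns ``(channel id, waiting time)``. The fired channel's clock is
        redrawn from its current rate. Raises :class:`SystemStalled` if no
        channel can fire.
        """
        while self._heap:
            tent, ver, cid = heapq.heappop(self._heap)
            ch = self.channels.get(cid)
            if ch is None or ch._version != ver or not math.isfinite(ch.tentative):
                continue
            wait = tent - self.t
            self.t = tent
            # redraw the fired channel
            ch.tentative = math.inf
            ch._version += 1
            if ch.rate > 0:
                ch.tentative = self.t + self.rng.exponential(1.0) / ch.rate
                heapq.heappush(self._heap, (ch.tentative, ch._version, cid))
            return cid, wait
        raise SystemStalled("all propensities are zero")

    def peek_time(self) -> float:
        for tent, ver, cid in self._heap:
            ch = self.channels.get(cid)
            if ch is not None and ch._version == ver and math.isfinite(ch.tentative):
                return tent
        return math.inf


def next_reaction_step(engine: NextReactionEngine) -> tuple[Hashable, float]:
    """One next-reaction event; see :meth:`NextReactionEngine.next_event`."""
    return engine.next_event()


# ---------------------------------------------------------------------------
# mechanochemical rate laws

def ratcheted_polymerization_rate(base_rate: float, boundary_load_force: float,
                                  params: ChemistryParams,
                                  kBT: float = 4.1) -> float:
    """Brownian-ratchet slowdown: base · exp(−F·δ/kBT), F ≥ 0."""
    if boundary_load_force < 0:
        raise ValueError("boundary load force must be >= 0")
    return base_rate * math.exp(-boundary_load_force * params.ratchet_delta / kBT)


def slip_unbinding_rate(base_rate: float, tension: float,
                        params: ChemistryParams) -> float:
    """Slip bond: base · exp(F/F_slip) for stretched (F>0) springs only.

    The exponent is capped at 50 — unbinding is instantaneous on the
    simulated timescale long before that.
    """
    return base_rate * math.exp(min(max(tension, 0.0) / params.slip_force, 50.0))


def _catch_chain_rates(force: float, n_heads: int, params: ChemistryParams):
    """Birth–death rates over bound-head number n = 1..N under shared load."""
    n = np.arange(1, n_heads + 1, dtype=float)
    up = (n_heads - n) * params.head_attach_rate
    down = n * params.head_detach_rate * np.exp(
        -max(force, 0.0) / (n * params.catch_force))
    return up, down

def _catch_mfpt(force: float, n_heads: int, params: ChemistryParams) -> float:
    """Mean first passage time to full detachment, starting from one head.

    Closed-form birth–death absorption sum (numerically stable at any force):
    T(1→0) = Σ_{k=1}^{N} (1/μ_k) Π_{j=1}^{k-1} (λ_j/μ_j).
    """
    up, down = _catch_chain_rates(force, n_heads, params)
    T = 0.0
    prod = 1.0
    for k in range(n_heads):
        if down[k] <= 0.0:
            return math.inf
        T += prod / down[k]
        prod *= up[k] / down[k]
        if not math.isfinite(T) or prod > 1e290:
            return math.inf
    return T


_MFPT_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def catch_unbinding_rate(base_rate: float, tension: float, n_heads: int,
                         params: ChemistryParams) -> float:
    """Ensemble catch-bond off rate from the parallel-cluster head chain.

    ``base_rate`` is the zero-force ensemble rate; the force dependence is
    the exact ratio of mean first-passage (full-detachment) times of the
    bound-head birth–death chain: k(F) = base · T(0) / T(F). Values are
    interpolated from a per-parameter force grid (exact at grid nodes).
    """
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    if base_rate == 0.0 or params.head_detach_rate == 0.0:
        return 0.0
    key = (n_heads, params.head_attach_rate, params.head_detach_rate,
           params.catch_force)
    cached = _MFPT_CACHE.get(key)
    if cached is None:
        fgrid = np.linspace(0.0, 50.0 * params.catch_force, 201)
        tgrid = np.array([_catch_mfpt(f, n_heads, params) for f in fgrid])
        _MFPT_CACHE[key] = cached = (fgrid, tgrid)
    fgrid, tgrid = cached
    f = min(max(tension, 0.0), fgrid[-1])
    tf = float(np.interp(f, fgrid, tgrid))
    return base_rate * tgrid[0] / tf


def motor_walk_velocity(stall_free_velocity: float, tension: float,
                        stall_force: float) -> float:
    """Linear force–velocity: v = v0 · max(0, 1 − F/F_stall)."""
    if stall_force <= 0:
        raise ValueError("stall_force must be > 0")
    return stall_free_velocity * max(0.0, 1.0 - max(tension, 0.0) / stall_force)


# ---------------------------------------------------------------------------
# diffusing species field

SPECIES = ("actin", "linker", "motor")


class SpeciesField:
    """Per-voxel integer copy numbers of the diffusing species."""

    def __init__(self, box: np.ndarray, voxel_edge: float):
        box = np.asarray(box, dtype=float)
        self.box = box
        self.shape = tuple(max(1, int(round(b / voxel_edge))) for b in box)
        self.edges = box / np.array(self.shape)
        self.counts = {s: np.zeros(self.shape, dtype=int) for s in SPECIES}

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_volume(self) -> float:
        return float(np.prod(self.edges))

    def total(self, species: str) -> int:
        return int(self.counts[species].sum())

    def set_uniform(self, species: str, total: int,
                    rng: np.random.Generator | None = None) -> None:
        """Distribute ``total`` copies uniformly (multinomially if rng given)."""
        c = self.counts[species]
        c[:] = 0
        flat = c.reshape(-1)
        if rng is None:
            q, r = divmod(total, flat.size)
            flat[:] = q
            flat[:r] += 1
        else:
            flat[:] = rng.multinomial(total, np.full(flat.size, 1.0 / flat.size))

    def concentration(self, species: str, voxel: tuple[int, ...]) -> float:
        """Local concentration in μM."""
        return self.counts[species][voxel] / (
            self.voxel_volume() * MOLECULES_PER_UM_NM3)

    def voxel_of(self, point: np.ndarray) -> tuple[int, ...]:
        idx = np.floor(np.asarray(point) / self.edges).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(idx)

    def neighbor_pairs(self) -> list[tuple[tuple, tuple]]:
        out = []
        nx, ny, nz = self.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if i + 1 < nx:
                        out.append(((i, j, k), (i + 1, j, k)))
                    if j + 1 < ny:
                        out.append(((i, j, k), (i, j + 1, k)))
                    if k + 1 < nz:
                        out.append(((i, j, k), (i, j, k + 1)))
        return out

    def hop_rate(self, species: str, axis: int, params: ChemistryParams) -> float:
        D = {"actin": params.diffusion_actin,
             "linker": params.diffusion_linker,
             "motor": params.diffusion_motor}[species]
        return D / float(self.edges[axis]) ** 2

    def retile(self, new_box: np.ndarray, voxel_edge: float,
               rng: np.random.Generator | None = None) -> "SpeciesField":
        """New tiling for a resized box; totals are conserved exactly."""
        nf = SpeciesField(new_box, voxel_edge)
        for s in SPECIES:
            nf.set_uniform(s, self.total(s), rng)
        return nf


# ---------------------------------------------------------------------------
# binding geometry

#: fractional positions of candidate binding sites on each cylinder
SITE_FRACTIONS = (0.25, 0.5, 0.75)


def binding_sites(network: NetworkState) -> tuple[np.ndarray, np.ndarray]:
    """All candidate sites: coordinates (n,3) and (filament, cyl, frac) rows."""
    pts, ids = [], []
    for fid, f in enumerate(network.filaments):
        b = f.beads
        for frac in SITE_FRACTIONS:
            p = b[:-1] + frac * (b[1:] - b[:-1])
            pts.append(p)
            for c in range(f.n_cylinders):
                ids.append((fid, c, frac))
    if not pts:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.concatenate(pts, axis=0), np.array(ids)


def eligible_binding_pairs(network: NetworkState, species: str,
                           params: ChemistryParams,
                           occupied: set | None = None) -> list[tuple]:
    """Unordered site pairs on distinct filaments within the species band.

    Returns ``[((fid, cyl, frac), (fid, cyl, frac)), ...]``. ``occupied``
    optionally excludes sites already carrying a bound element.
    """
    lo, hi = (params.linker_band if species == LINKER else params.motor_band)
    pts, ids = binding_sites(network)
    if len(pts) < 2:
        return []
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    pairs = tree.query_pairs(hi, output_type="ndarray")
    if pairs.size == 0:
        return []
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    keep = d >= lo
    pairs = pairs[keep]
    out = []
    for i, j in pairs:
        fa, ca, ra = ids[i]
        fb, cb, rb = ids[j]
        if int(fa) == int(fb):
            continue
        sa = (int(fa), int(ca), float(ra))
        sb = (int(fb), int(cb), float(rb))
        if occupied and (sa in occupied or sb in occupied):
            continue
        out.append((sa, sb))
    return out
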