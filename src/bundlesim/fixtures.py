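"""Seeded generators of labeled synthetic networks and toy reaction systems.

These exist so the classification pipeline and the stochastic engine can be
exercised without running the simulator; they target geometric/connectivity
structure, not mechanical or chemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import NextReactionEngine
from .mechanics import LINKER, MOTOR, BoundElement, Filament, NetworkState
from .morphology import ABI, AL, BL, CATASTROPHE_A, CATASTROPHE_B
from .protocol import hex_lattice_positions

FIXTURE_CLASSES = ("bundle", "aster", "intermediate", "sarcomere",
                   "fragmented", "sparse")

FIXTURE_LABELS = {
    "bundle": BL,
    "aster": AL,
    "intermediate": ABI,
    "sarcomere": BL,
    "fragmented": CATASTROPHE_A,
    "sparse": CATASTROPHE_B,
}


@dataclass
class FixtureSpec:
    fixture_class: str
    n_filaments: int = 30
    length: float = 2000.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixture_class not in FIXTURE_CLASSES:
            raise ValueError(f"unknown fixture class {self.fixture_class!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_filaments < 2:
            raise ValueError("need >= 2 filaments")


def _straight(beads0: np.ndarray, direction: np.ndarray, length: float,
              n_beads: int = 8) -> Filament:
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0.0, length, n_beads)
    beads = beads0[None, :] + s[:, None] * direction[None, :]
    n_cyl = n_beads - 1
    per = length / n_cyl / 2.7
    monomers = np.full(n_cyl, max(1, int(round(per))))
    return Filament(beads, monomers)


def _jitter(state: NetworkState, noise: float, rng: np.random.Generator) -> None:
    if noise <= 0:
        return
    for f in state.filaments:
        f.beads += rng.normal(0.0, noise, size=f.beads.shape)
        c = f.beads.mean(axis=0)
        ang = rng.normal(0.0, noise / 2000.0, size=3)
        R = _rotation(ang)
        f.beads = (f.beads - c) @ R.T + c


def _rotation(ang: np.ndarray) -> np.ndarray:
    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _chain_links(pairs, species=LINKER, per_pair=2, n_cyl=7):
    """Bound elements between filament pairs at spread axial positions."""
    out = []
    for a, b in pairs:
        for k in range(per_pair):
            ci = min(int((k + 1) * n_cyl / (per_pair + 1)), n_cyl - 1)
            heads = 16 if species == MOTOR else None
            out.append(BoundElement(species, (a, ci, 0.5), (b, ci, 0.5),
                                    35.0 if species == LINKER else 200.0, heads))
    return out


def _bundle_pairs(xy: np.ndarray, spacing: float) -> list[tuple[int, int]]:
    pairs = []
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if np.linalg.norm(xy[i] - xy[j]) < 1.5 * spacing:
                pairs.append((i, j))
    return pairs


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    th = phi * i
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def make_fixture(spec: FixtureSpec) -> tuple[NetworkState, str]:
    """Generate a labeled synthetic network. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_filaments, spec.length
    box = np.array([4 * L, 4 * L, 4 * L])
    c = box / 2.0
    fils: list[Filament] = []
    bound: list[BoundElement] = []
    cls = spec.fixture_class

    if cls in ("bundle", "sarcomere"):
        xy, cols = hex_lattice_positions(n, 35.0)
        for i in range(n):
            sign = 1 if (cls == "bundle" or cols[i] % 2 == 0) else -1
            origin = np.array([c[0] - sign * L / 2.0, c[1] + xy[i, 0],
                               c[2] + xy[i, 1]])
            fils.append(_straight(origin, [sign, 0, 0], L))
        if cls == "bundle":
            bound = _chain_links(_bundle_pairs(xy, 35.0), LINKER, per_pair=3)
        else:
            # motors banded near minus-end overlaps (bundle middle),
            # crosslinkers toward the outer thirds
            pairs = _bundle_pairs(xy, 35.0)
            for a, b in pairs:
                bound.append(BoundElement(MOTOR, (a, 3, 0.5), (b, 3, 0.5),
                                          200.0, 16))
                bound.append(BoundElement(LINKER, (a, 0, 0.5), (b, 0, 0.5), 35.0))
                bound.append(BoundElement(LINKER, (a, 6, 0.5), (b, 6, 0.5), 35.0))

    elif cls == "aster":
        dirs = _fibonacci_sphere(n)
        r0 = 0.05 * L
        for i in range(n):
            # plus end (last bead) at the core, minus end outward
            fils.append(_straight(c + dirs[i] * (r0 + L), -dirs[i], L))
        ring = [(i, (i + 1) % n) for i in range(n)]
        for a, b in ring:
            bound.append(BoundElement(MOTOR, (a, 6, 0.9), (b, 6, 0.9), 200.0, 16))
            bound.append(BoundElement(LINKER, (a, 6, 0.5), (b, 6, 0.5), 35.0))

    elif cls == "intermediate":
        # half bundle, half radial fan: the fan opens as a forward cone from
        # the bundle's plus end, so orientational order stays between the
        # bundle (S~1) and aster (S~0) regimes
        nb = n // 2
        xy, _ = hex_lattice_positions(nb, 35.0)
        for i in range(nb):
            origin = np.array([c[0] - L, c[1] + xy[i, 0], c[2] + xy[i, 1]])
            fils.append(_straight(origin, [1, 0, 0], L))
        nr = n - nb
        core = c + np.array([0.05 * L, 0, 0])
        half_angle = np.deg2rad(35.0)
        ang = 2.0 * np.pi * np.arange(nr) / nr
        dirs = np.stack([np.full(nr, np.cos(half_angle)),
                         np.sin(half_angle) * np.cos(ang),
                         np.sin(half_angle) * np.sin(ang)], axis=1)
        for i in range(nr):
            fils.append(_straight(core + dirs[i] * (0.05 * L + L), -dirs[i], L))
        bound = _chain_links(_bundle_pairs(xy, 35.0), LINKER, per_pair=2)
        for i in range(nr):
            a = nb + i
            b = nb + (i + 1) % nr
            bound.append(BoundElement(MOTOR, (a, 6, 0.9), (b, 6, 0.9), 200.0, 16))
        bound.append(BoundElement(MOTOR, (0, 6, 0.9), (nb, 6, 0.9), 200.0, 16))

    elif cls == "fragmented":
        half = n // 2
        for part, count in ((0, half), (1, n - half)):
            xy, _ = hex_lattice_positions(count, 35.0)
            shift = np.array([-1.5 * L, 0, 0]) if part == 0 else np.array([1.5 * L, 0, 0])
            for i in range(count):
                origin = c + shift + np.array([0.0, xy[i, 0], xy[i, 1]])
                ang = rng.normal(0, 0.3, 3)
                d = _rotation(ang) @ np.array([1.0, 0, 0])
                fils.append(_straight(origin, d, L))
            offset = 0 if part == 0 else half
            for a, b in _bundle_pairs(xy, 35.0):
                bound.append(BoundElement(LINKER, (a + offset, 3, 0.5),
                                          (b + offset, 3, 0.5), 35.0))

    elif cls == "sparse":
        for i in range(n):
            origin = c + rng.uniform(-L, L, 3)
            d = rng.normal(size=3)
            fils.append(_straight(origin, d, L))
        n_tree = max(int(np.ceil(0.6 * n)), 2)
        for i in range(1, n_tree):
            bound.append(BoundElement(LINKER, (i - 1, 3, 0.5), (i, 3, 0.5), 35.0))

    state = NetworkState(fils, bound, box)
    _jitter(state, spec.noise, rng)
    # shift into the positive octant and size the box to fit with a margin
    X = state.all_beads()
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    margin = 50.0
    for f in state.filaments:
        f.beads += (margin - lo)[None, :]
    state.box = hi - lo + 2 * margin
    return state, FIXTURE_LABELS[cls]


# ---------------------------------------------------------------------------
# toy reaction systems

@dataclass
class ToyReactionSummary:
    rates: tuple[float, ...]
    firing_probabilities: tuple[float, ...]
    mean_waiting_time: float


def make_toy_reaction_system(rates, seed: int
                             ) -> tuple[NextReactionEngine, ToyReactionSummary]:
    """Constant-propensity channels with known event statistics."""
    rates = tuple(float(r) for r in rates)
    if any(r <= 0 for r in rates):
        raise ValueError("rates must be > 0")
    rng = np.random.default_rng(seed)
    engine = NextReactionEngine(rng)
    for i, r in enumerate(rates):
        engine.add(i, "toy", r)
    tot = sum(rates)
    summary = ToyReactionSummary(rates, tuple(r / tot for r in rates), 1.0 / tot)
    return engine, summary
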