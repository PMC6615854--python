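"""Bead–cylinder mechanics: filaments, bound springs, energies and minimization.

Filaments are chains of beads (hinges) joined by cylinders. Bead order runs
from the pointed (minus) end at index 0 to the barbed (plus) end at the last
index. Energies are pN·nm, coordinates nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from .params import MONOMER_SIZE, MONOMERS_PER_CYLINDER, MechanicalParams

LINKER = "alpha_actinin"
MOTOR = "motor_minifilament"

# Gauss–Legendre nodes/weights mapped to [0, 1]
_GL_X, _GL_W = leggauss(8)
_GL_U = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


class Filament:
    """Ordered bead chain; bead 0 is the minus end, the last bead the plus end."""

    def __init__(self, beads: np.ndarray, monomers: np.ndarray | None = None):
        beads = np.array(beads, dtype=float)
        if beads.ndim != 2 or beads.shape[1] != 3 or beads.shape[0] < 2:
            raise ValueError("filament needs >= 2 beads of shape (n, 3)")
        self.beads = beads
        n_cyl = beads.shape[0] - 1
        if monomers is None:
            monomers = np.full(n_cyl, MONOMERS_PER_CYLINDER, dtype=int)
        monomers = np.asarray(monomers, dtype=int)
        if monomers.shape != (n_cyl,) or np.any(monomers < 1):
            raise ValueError("monomers must give a positive count per cylinder")
        self.monomers = monomers

    @property
    def n_beads(self) -> int:
        return self.beads.shape[0]

    @property
    def n_cylinders(self) -> int:
        return self.beads.shape[0] - 1

    @property
    def plus_end_index(self) -> int:
        return self.n_beads - 1

    @property
    def minus_end_index(self) -> int:
        return 0

    @property
    def plus_end(self) -> np.ndarray:
        return self.beads[-1]

    @property
    def minus_end(self) -> np.ndarray:
        return self.beads[0]

    def cylinder_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.beads, axis=0), axis=1)

    def rest_lengths(self) -> np.ndarray:
        """Equilibrium cylinder lengths; shrink with partial monomer fill."""
        return self.monomers * MONOMER_SIZE

    def total_monomers(self) -> int:
        return int(self.monomers.sum())

    def tangent(self, cyl: int) -> np.ndarray:
        t = self.beads[cyl + 1] - self.beads[cyl]
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("zero-length cylinder has no tangent")
        return t / n

    def copy(self) -> "Filament":
        return Filament(self.beads.copy(), self.monomers.copy())

    def validate(self, params: MechanicalParams) -> None:
        ls = self.cylinder_lengths()
        if np.any(ls <= 0):
            raise ValueError("degenerate (zero-length) cylinder")
        if np.any(ls > 2 * params.l0_cylinder):
            raise ValueError("cylinder longer than 2*l0_cylinder")


@dataclass
class BoundElement:
    """A crosslinker or minifilament spring between two filament sites.

    Attachments are ``(filament index, cylinder index, fraction in [0, 1])``.
    """

    species: str
    a: tuple[int, int, float]
    b: tuple[int, int, float]
    rest_length: float
    n_heads: int | None = None

    def __post_init__(self) -> None:
        if self.species not in (LINKER, MOTOR):
            raise ValueError(f"unknown species {self.species!r}")
        if self.a[0] == self.b[0]:
            raise ValueError("bound element must join two distinct filaments")
        for att in (self.a, self.b):
            if not 0.0 <= att[2] <= 1.0:
                raise ValueError("attachment fraction must be in [0, 1]")
        if self.species == MOTOR:
            if self.n_heads is None or self.n_heads < 1:
                raise ValueError("motor needs n_heads >= 1")
        elif self.n_heads is not None:
            raise ValueError("n_heads is motor-only")


@dataclass
class NetworkState:
    """Filaments plus bound elements inside an axis-aligned box ([0, box])."""

    filaments: list[Filament]
    bound: list[BoundElement] = field(default_factory=list)
    box: np.ndarray = field(default_factory=lambda: np.array([2000.0, 2000.0, 2000.0]))

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)

    def copy(self) -> "NetworkState":
        return NetworkState([f.copy() for f in self.filaments],
                            [BoundElement(e.species, e.a, e.b, e.rest_length, e.n_heads)
                             for e in self.bound],
                            self.box.copy())

    def all_beads(self) -> np.ndarray:
        return np.concatenate([f.beads for f in self.filaments], axis=0)

    def resolve(self, att: tuple[int, int, float]) -> np.ndarray:
        fid, ci, frac = att
        try:
            f = self.filaments[fid]
            p0, p1 = f.beads[ci], f.beads[ci + 1]
        except IndexError as exc:
            raise ValueError(f"dangling attachment {att}") from exc
        return p0 + frac * (p1 - p0)

    def validate(self) -> None:
        for e in self.bound:
            self.resolve(e.a)
            self.resolve(e.b)


# ---------------------------------------------------------------------------
# energies

def stretching_energy(filament: Filament, params: MechanicalParams) -> float:
    ls = filament.cylinder_lengths()
    if np.any(ls == 0):
        raise ValueError("degenerate cylinder")
    d = ls - filament.rest_lengths()
    return float(0.5 * params.k_stretch_filament * np.sum(d * d))


def bending_energy(filament: Filament, params: MechanicalParams) -> float:
    if filament.n_beads < 3:
        return 0.0
    t = np.diff(filament.beads, axis=0)
    n = np.linalg.norm(t, axis=1)
    if np.any(n == 0):
        raise ValueError("zero-length tangent")
    cos = np.sum(t[:-1] * t[1:], axis=1) / (n[:-1] * n[1:])
    cos = np.clip(cos, -1.0, 1.0)
    return float(params.k_bend * np.sum(1.0 - cos))


def excluded_volume_energy(cyl_a: tuple[np.ndarray, np.ndarray],
                           cyl_b: tuple[np.ndarray, np.ndarray],
                           params: MechanicalParams) -> float:
    """Double line integral of k_vol / r^4 over the two segments (8x8 GL)."""
    a0, a1 = (np.asarray(p, float) for p in cyl_a)
    b0, b1 = (np.asarray(p, float) for p in cyl_b)
    e, _g, _capped = _ev_pair_batch(a0[None], a1[None], b0[None], b1[None], params)
    return float(e[0])


_MID_U = np.array([0.5])
_MID_W = np.array([1.0])
_GL4_X, _GL4_W = leggauss(4)
_GL4 = (0.5 * (_GL4_X + 1.0), 0.5 * _GL4_W)


def _ev_pair_batch(a0, a1, b0, b1, params, nodes=None):
    """Energies and endpoint gradients for P cylinder pairs.

    Returns (E (P,), grads (P, 4, 3) ordered a0,a1,b0,b1, capped (P,) bool).
    ``nodes`` overrides the quadrature rule (used for the far-field midpoint
    approximation, where the energy is negligible anyway).
    """
    u, w = nodes if nodes is not None else (_GL_U, _GL_W)
    da = a1 - a0
    db = b1 - b0
    La = np.linalg.norm(da, axis=1)
    Lb = np.linalg.norm(db, axis=1)
    pa = a0[:, None, :] + u[None, :, None] * da[:, None, :]      # (P,8,3)
    pb = b0[:, None, :] + u[None, :, None] * db[:, None, :]
    # |pa_i - pb_j|^2 without materializing the (P,8,8,3) difference tensor
    aa = np.einsum("pik,pik->pi", pa, pa)
    bb = np.einsum("pjk,pjk->pj", pb, pb)
    ab = pa @ pb.transpose(0, 2, 1)                               # (P,8,8)
    r2 = aa[:, :, None] + bb[:, None, :] - 2.0 * ab
    cap2 = params.ev_cap_r ** 2
    capped_pts = r2 < cap2
    r2c = np.maximum(r2, cap2)
    inv2 = 1.0 / r2c
    inv4 = inv2 * inv2
    ww = w[:, None] * w[None, :]
    S = np.einsum("ij,pij->p", ww, inv4)
    pref = params.k_vol * La * Lb
    E = pref * S

    # dS/dpa_i = sum_j c_ij (pa_i - pb_j) with c = -4 w_i w_j / r^6
    coef = -4.0 * inv4 * inv2 * ww[None, :, :]
    coef[capped_pts] = 0.0                                        # capped: no force
    rs_a = coef.sum(axis=2)                                       # (P,8)
    rs_b = coef.sum(axis=1)
    ga = pa * rs_a[:, :, None] - coef @ pb                        # (P,8,3)
    gb = pb * rs_b[:, :, None] - coef.transpose(0, 2, 1) @ pa
    one_m_u = 1.0 - u
    g_a0 = pref[:, None] * np.einsum("i,pik->pk", one_m_u, ga)
    g_a1 = pref[:, None] * np.einsum("i,pik->pk", u, ga)
    g_b0 = pref[:, None] * np.einsum("j,pjk->pk", one_m_u, gb)
    g_b1 = pref[:, None] * np.einsum("j,pjk->pk", u, gb)

    # length-prefactor gradient
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = da / La[:, None]
        ub = db / Lb[:, None]
    kS = params.k_vol * S
    g_a0 += -(kS * Lb)[:, None] * ua
    g_a1 += (kS * Lb)[:, None] * ua
    g_b0 += -(kS * La)[:, None] * ub
    g_b1 += (kS * La)[:, None] * ub

    grads = np.stack([g_a0, g_a1, g_b0, g_b1], axis=1)
    return E, grads, capped_pts.any(axis=(1, 2))


def linker_energy(element: BoundElement, network: NetworkState,
                  params: MechanicalParams) -> float:
    k = (params.k_stretch_linker if element.species == LINKER
         else params.k_stretch_motor)
    d = np.linalg.norm(network.resolve(element.a) - network.resolve(element.b))
    return float(0.5 * k * (d - element.rest_length) ** 2)


def linker_tension(element: BoundElement, network: NetworkState,
                   params: MechanicalParams) -> float:
    """Signed spring tension k·(d − rest); positive when stretched."""
    k = (params.k_stretch_linker if element.species == LINKER
         else params.k_stretch_motor)
    d = np.linalg.norm(network.resolve(element.a) - network.resolve(element.b))
    return float(k * (d - element.rest_length))


# ---------------------------------------------------------------------------
# whole-network energy/gradient machinery

class _System:
    """Flattened index arrays for one network, fixed during a minimization."""

    def __init__(self, network: NetworkState, params: MechanicalParams,
                 include_excluded_volume: bool = True,
                 include_boundary: bool = True):
        self.network = network
        self.params = params
        self.include_boundary = include_boundary
        offsets = []
        off = 0
        for f in network.filaments:
            offsets.append(off)
            off += f.n_beads
        self.offsets = offsets
        self.n_beads = off

        ci, cj, l0, fid = [], [], [], []
        for k, f in enumerate(network.filaments):
            o = offsets[k]
            rl = f.rest_lengths()
            for c in range(f.n_cylinders):
                ci.append(o + c)
                cj.append(o + c + 1)
                l0.append(rl[c])
                fid.append(k)
        self.ci = np.array(ci, dtype=int)
        self.cj = np.array(cj, dtype=int)
        self.l0 = np.array(l0)
        self.cyl_fid = np.array(fid, dtype=int)

        hi, hj, hk = [], [], []
        for k, f in enumerate(network.filaments):
            o = offsets[k]
            for c in range(f.n_beads - 2):
                hi.append(o + c)
                hj.append(o + c + 1)
                hk.append(o + c + 2)
        self.hi = np.array(hi, dtype=int)
        self.hj = np.array(hj, dtype=int)
        self.hk = np.array(hk, dtype=int)

        # springs
        sa_i, sa_j, sa_fi, sa_fj, s_k, s_l0 = [], [], [], [], [], []
        for e in network.bound:
            fa, ca, fra = e.a
            fb, cb, frb = e.b
            sa_i.append(offsets[fa] + ca)
            sa_fi.append(fra)
            sa_j.append(offsets[fb] + cb)
            sa_fj.append(frb)
            s_k.append(params.k_stretch_linker if e.species == LINKER
                       else params.k_stretch_motor)
            s_l0.append(e.rest_length)
        self.s_i = np.array(sa_i, dtype=int)
        self.s_j = np.array(sa_j, dtype=int)
        self.s_fi = np.array(sa_fi)
        self.s_fj = np.array(sa_fj)
        self.s_k = np.array(s_k)
        self.s_l0 = np.array(s_l0)

        self.ev_pairs = (self._ev_pair_list(network)
                         if include_excluded_volume else
                         np.empty((0, 2), dtype=int))
        self._ev_near2 = (0.75 * params.l0_cylinder) ** 2
        self._ev_mid2 = (1.6 * params.l0_cylinder) ** 2
        self.ev_capped = False

    def _ev_pair_list(self, network: NetworkState) -> np.ndarray:
        X = network.all_beads()
        mids = 0.5 * (X[self.ci] + X[self.cj])
        n = len(self.ci)
        if n < 2:
            return np.empty((0, 2), dtype=int)
        d2 = np.sum((mids[:, None, :] - mids[None, :, :]) ** 2, axis=-1)
        cut2 = self.params.ev_cutoff ** 2
        ii, jj = np.nonzero(np.triu(d2 < cut2, k=1))
        same = self.cyl_fid[ii] == self.cyl_fid[jj]
        adjacent = same & (np.abs(ii - jj) <= 1)
        keep = ~adjacent
        return np.stack([ii[keep], jj[keep]], axis=1)

    def scatter(self, X: np.ndarray) -> None:
        for k, f in enumerate(self.network.filaments):
            o = self.offsets[k]
            f.beads[:] = X[o:o + f.n_beads]

    def energy_grad(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.params
        G = np.zeros_like(X)
        E = 0.0

        # stretching
        d = X[self.cj] - X[self.ci]
        ls = np.linalg.norm(d, axis=1)
        dl = ls - self.l0
        E += 0.5 * p.k_stretch_filament * float(np.sum(dl * dl))
        with np.errstate(invalid="ignore", divide="ignore"):
            fvec = (p.k_stretch_filament * dl / ls)[:, None] * d
        np.add.at(G, self.cj, fvec)
        np.add.at(G, self.ci, -fvec)

        # bending
        if len(self.hi):
            u = X[self.hj] - X[self.hi]
            v = X[self.hk] - X[self.hj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            inv = 1.0 / (nu * nv)
            c = np.sum(u * v, axis=1) * inv
            c = np.clip(c, -1.0, 1.0)
            E += p.k_bend * float(np.sum(1.0 - c))
            dcdu = v * inv[:, None] - (c / nu ** 2)[:, None] * u
            dcdv = u * inv[:, None] - (c / nv ** 2)[:, None] * v
            gu = -p.k_bend * dcdu
            gv = -p.k_bend * dcdv
            np.add.at(G, self.hi, -gu)
            np.add.at(G, self.hj, gu - gv)
            np.add.at(G, self.hk, gv)

        # bound springs
        if len(self.s_i):
            pa = X[self.s_i] + self.s_fi[:, None] * (X[self.s_i + 1] - X[self.s_i])
            pb = X[self.s_j] + self.s_fj[:, None] * (X[self.s_j + 1] - X[self.s_j])
            dv = pa - pb
            dd = np.linalg.norm(dv, axis=1)
            ext = dd - self.s_l0
            E += float(np.sum(0.5 * self.s_k * ext * ext))
            with np.errstate(invalid="ignore", divide="ignore"):
                fv = (self.s_k * ext / np.maximum(dd, 1e-12))[:, None] * dv
            np.add.at(G, self.s_i, fv * (1 - self.s_fi)[:, None])
            np.add.at(G, self.s_i + 1, fv * self.s_fi[:, None])
            np.add.at(G, self.s_j, -fv * (1 - self.s_fj)[:, None])
            np.add.at(G, self.s_j + 1, -fv * self.s_fj[:, None])

        # excluded volume: full quadrature near contact, midpoint far field
        if len(self.ev_pairs):
            ii = self.ev_pairs[:, 0]
            jj = self.ev_pairs[:, 1]
            a0, a1 = X[self.ci[ii]], X[self.cj[ii]]
            b0, b1 = X[self.ci[jj]], X[self.cj[jj]]
            mid2 = np.sum((0.5 * (a0 + a1) - 0.5 * (b0 + b1)) ** 2, axis=1)
            near = mid2 < self._ev_near2
            mid = ~near & (mid2 < self._ev_mid2)
            far = ~near & ~mid
            for mask, nodes in ((near, None), (mid, _GL4),
                                (far, (_MID_U, _MID_W))):
                if not mask.any():
                    continue
                Ev, grads, capped = _ev_pair_batch(
                    a0[mask], a1[mask], b0[mask], b1[mask], p, nodes)
                E += float(Ev.sum())
                if nodes is None and capped.any():
                    self.ev_capped = True
                np.add.at(G, self.ci[ii][mask], grads[:, 0])
                np.add.at(G, self.cj[ii][mask], grads[:, 1])
                np.add.at(G, self.ci[jj][mask], grads[:, 2])
                np.add.at(G, self.cj[jj][mask], grads[:, 3])

        # boundary walls
        if self.include_boundary:
            box = self.network.box
            low = np.minimum(X, 0.0)
            high = np.maximum(X - box[None, :], 0.0)
            E += 0.5 * p.k_boundary * float(np.sum(low ** 2) + np.sum(high ** 2))
            G += p.k_boundary * (low + high)

        return E, G


def network_energy(network: NetworkState, params: MechanicalParams,
                   include_excluded_volume: bool = True,
                   include_boundary: bool = True) -> float:
    sys = _System(network, params, include_excluded_volume, include_boundary)
    e, _ = sys.energy_grad(network.all_beads())
    return e


@dataclass
class MinimizeResult:
    network: NetworkState
    converged: bool
    iterations: int
    energy: float
    max_force: float
    ev_capped: bool = False


def minimize_network(network: NetworkState, params: MechanicalParams,
                     force_tolerance: float = 1.0, max_iter: int = 2000,
                     include_excluded_volume: bool = True,
                     include_boundary: bool = True) -> MinimizeResult:
    """Polak–Ribière conjugate gradient with backtracking line search.

    Mutates bead coordinates in place; never accepts an energy increase.
    Non-convergence is reported via ``converged=False``, not raised.
    """
    sys = _System(network, params, include_excluded_volume, include_boundary)
    X = network.all_beads().copy()
    E, G = sys.energy_grad(X)
    if not np.isfinite(E):
        raise ValueError("non-finite initial energy")
    d = -G
    step = 1e-2
    it = 0
    for it in range(1, max_iter + 1):
        fmax = float(np.abs(G).max()) if G.size else 0.0
        if fmax <= force_tolerance:
            break
        gd = float(np.sum(G * d))
        if gd >= 0:  # restart on a non-descent direction
            d = -G
            gd = float(np.sum(G * d))
        # backtracking Armijo
        t = step
        accepted = False
        for _ in range(40):
            Xn = X + t * d
            En, Gn = sys.energy_grad(Xn)
            if np.isfinite(En) and En <= E + 1e-4 * t * gd:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        step = min(t * 2.0, 1.0)
        beta = float(np.sum(Gn * (Gn - G)) / max(np.sum(G * G), 1e-300))
        beta = max(beta, 0.0)
        X, E = Xn, En
        dG = Gn - G
        G = Gn
        d = -G + beta * d
        if it % (3 * max(X.shape[0], 1)) == 0:
            d = -G
    fmax = float(np.abs(G).max()) if G.size else 0.0
    sys.scatter(X)
    return MinimizeResult(network, fmax <= force_tolerance, it, E, fmax,
                          sys.ev_capped)


def boundary_load_force(network: NetworkState, params: MechanicalParams,
                        filament: Filament, end: str,
                        ratchet_range: float) -> float:
    """Compressive wall load (pN) on a filament tip, for ratchet feedback.

    Zero unless the tip is within ``ratchet_range`` of (or beyond) a wall
    along its growth direction; penetration gives the harmonic wall force.
    """
    tip = filament.plus_end if end == "plus" else filament.minus_end
    if end == "plus":
        direction = filament.tangent(filament.n_cylinders - 1)
    else:
        direction = -filament.tangent(0)
    load = 0.0
    for ax in range(3):
        if direction[ax] > 1e-6:
            gap = network.box[ax] - tip[ax]
            if gap < 0:
                load += params.k_boundary * (-gap) * direction[ax]
        elif direction[ax] < -1e-6:
            if tip[ax] < 0:
                load += params.k_boundary * (-tip[ax]) * (-direction[ax])
    return load
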