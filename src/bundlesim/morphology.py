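"""Morphology classification: end-distance distributions, Jensen–Shannon
dissimilarity, complete-linkage clustering, order parameters, catastrophe
taxonomy, and axial species distributions."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mechanics import LINKER, MOTOR, NetworkState

BL = "BL"
AL = "AL"
ABI = "ABI"
CATASTROPHE_A = "catastrophe_A"
CATASTROPHE_B = "catastrophe_B"

#: default histogram bin width for end-distance distributions (nm)
DEFAULT_BIN_WIDTH = 50.0


@dataclass
class EndDistanceDistributions:
    """Normalized Dis++, Dis−−, Dis+− histograms pooled over snapshots."""

    bins: np.ndarray
    pp: np.ndarray
    mm: np.ndarray
    pm: np.ndarray
    condition: str = ""
    n_snapshots: int = 0
    empty: bool = False


def default_bins(box_diagonal: float, width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    n = max(2, int(np.ceil(box_diagonal / width)))
    return np.linspace(0.0, n * width, n + 1)


def end_distance_distributions(snapshots: list[NetworkState],
                               bins: np.ndarray,
                               condition: str = "") -> EndDistanceDistributions:
    """Pool all cross-filament end-pair distances over the snapshots.

    ++ and −− use each unordered filament pair once; +− uses both ordered
    cross-polarity combinations (plus of i to minus of j, and vice versa)
    once per unordered pair.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    pp, mm, pm = [], [], []
    for s in snapshots:
        plus = np.array([f.plus_end for f in s.filaments])
        minus = np.array([f.minus_end for f in s.filaments])
        n = len(s.filaments)
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, k=1)
        pp.append(np.linalg.norm(plus[iu] - plus[ju], axis=1))
        mm.append(np.linalg.norm(minus[iu] - minus[ju], axis=1))
        pm.append(np.linalg.norm(plus[iu] - minus[ju], axis=1))
        pm.append(np.linalg.norm(minus[iu] - plus[ju], axis=1))
    empty = not pp

    def hist(vals):
        if not vals:
            return np.zeros(len(bins) - 1)
        h, _ = np.histogram(np.concatenate(vals), bins=bins)
        tot = h.sum()
        return h / tot if tot else h.astype(float)

    return EndDistanceDistributions(np.asarray(bins, float), hist(pp), hist(mm),
                                    hist(pm), condition, len(snapshots), empty)


def jensen_shannon_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Base-2 JSD in [0, 1]: mean KL divergence to the midpoint mixture."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("histograms must share bins")
    M = 0.5 * (P + Q)

    def kl(A, B):
        mask = A > 0
        return float(np.sum(A[mask] * np.log2(A[mask] / B[mask])))

    return 0.5 * kl(P, M) + 0.5 * kl(Q, M)


@dataclass
class DissimilarityMatrix:
    conditions: list[str]
    matrix: np.ndarray


def build_dissimilarity_matrix(
        dists: dict[str, EndDistanceDistributions]) -> DissimilarityMatrix:
    """Mean of the three per-distribution JSDs, pairwise over conditions.

    Conditions with empty distributions are excluded (and recorded by their
    absence from ``conditions``).
    """
    names = [k for k, v in dists.items() if not v.empty]
    n = len(names)
    ref_bins = dists[names[0]].bins if names else None
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dists[names[i]], dists[names[j]]
            if a.bins.shape != b.bins.shape or not np.allclose(a.bins, b.bins):
                raise ValueError("conditions must share histogram bins")
            v = (jensen_shannon_divergence(a.pp, b.pp)
                 + jensen_shannon_divergence(a.mm, b.mm)
                 + jensen_shannon_divergence(a.pm, b.pm)) / 3.0
            M[i, j] = M[j, i] = v
    return DissimilarityMatrix(names, M)


@dataclass
class ClusterTree:
    """Agglomerative merge list; clusters are numbered n, n+1, ... as merged."""

    n_leaves: int
    merges: list[tuple[int, int, float]]  # (cluster id, cluster id, height)
    leaves: list[str] = field(default_factory=list)

    def cut(self, k: int) -> np.ndarray:
        """Leaf assignments (0..k-1) after undoing the last k−1 merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError("k out of range")
        parent = list(range(n + len(self.merges)))
        for idx, (a, b, _h) in enumerate(self.merges[: n - k]):
            parent[a] = n + idx
            parent[b] = n + idx

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        roots: dict[int, int] = {}
        out = np.empty(n, dtype=int)
        for leaf in range(n):
            r = find(leaf)
            out[leaf] = roots.setdefault(r, len(roots))
        return out

    def to_newick(self) -> str:
        names = self.leaves or [str(i) for i in range(self.n_leaves)]
        node = {i: names[i] for i in range(self.n_leaves)}
        height = {i: 0.0 for i in range(self.n_leaves)}
        nid = self.n_leaves
        for a, b, h in self.merges:
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[nid] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[nid] = h
            nid += 1
        return node[nid - 1] + ";" if self.merges else f"({names[0]});"


def complete_linkage(dm: DissimilarityMatrix | np.ndarray,
                     labels: list[str] | None = None) -> ClusterTree:
    """Naive O(n³) complete-linkage agglomeration, lowest-index tie-breaking."""
    if isinstance(dm, DissimilarityMatrix):
        M = dm.matrix
        labels = labels or dm.conditions
    else:
        M = np.asarray(dm, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or not np.allclose(M, M.T) or np.any(np.diag(M) != 0):
        raise ValueError("need a symmetric matrix with zero diagonal")
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = M[i, j]
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                best = (d, i, j)
        d, i, j = best
        members = active[i] + active[j]
        del active[i], active[j]
        newd = {}
        for k, mem in active.items():
            dd = max(M[np.ix_(members, mem)].max(), 0.0)
            newd[k] = dd
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        for k, dd in newd.items():
            dist[(min(k, next_id), max(k, next_id))] = dd
        active[next_id] = members
        merges.append((i, j, d))
        next_id += 1
    return ClusterTree(n, merges, list(labels) if labels else [])


# ---------------------------------------------------------------------------
# features and labels

@dataclass
class MorphologyFeatures:
    nematic_order: float
    radius_of_gyration: float
    asphericity: float
    polarity_sorting: float
    largest_component_fraction: float
    mean_linker_degree: float
    radial_profile: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _gyration_eigenvalues(X: np.ndarray) -> np.ndarray:
    c = X.mean(axis=0)
    Y = X - c
    T = Y.T @ Y / len(Y)
    return np.sort(np.linalg.eigvalsh(T))[::-1]


def morphology_features(snapshot: NetworkState, n_radial_bins: int = 10
                        ) -> MorphologyFeatures:
    """Order parameters of one snapshot.

    Nematic order S is the largest eigenvalue of the length-weighted
    Q-tensor (3/2)⟨uu⟩ − (1/2)I; the polarity-sorting score is positive when
    plus ends sit closer to the centroid than minus ends.
    """
    if not snapshot.filaments:
        raise ValueError("need at least one filament")
    segs, lens = [], []
    for f in snapshot.filaments:
        d = np.diff(f.beads, axis=0)
        L = np.linalg.norm(d, axis=1)
        ok = L > 0
        segs.append(d[ok] / L[ok][:, None])
        lens.append(L[ok])
    u = np.concatenate(segs)
    w = np.concatenate(lens)
    w = w / w.sum()
    Q = 1.5 * np.einsum("i,ij,ik->jk", w, u, u) - 0.5 * np.eye(3)
    S = float(np.max(np.linalg.eigvalsh(Q)))

    X = snapshot.all_beads()
    lam = _gyration_eigenvalues(X)
    rg = float(np.sqrt(lam.sum()))
    tr = lam.sum()
    asph = float(np.sum((lam - tr / 3.0) ** 2) / (tr ** 2) * 1.5) if tr > 0 else 0.0

    c = X.mean(axis=0)
    dplus = np.mean([np.linalg.norm(f.plus_end - c) for f in snapshot.filaments])
    dminus = np.mean([np.linalg.norm(f.minus_end - c) for f in snapshot.filaments])
    sorting = float((dminus - dplus) / rg) if rg > 0 else 0.0

    G = filament_graph(snapshot)
    comps = list(nx.connected_components(G))
    lcf = max(len(cc) for cc in comps) / len(snapshot.filaments)
    degree = 2.0 * G.number_of_edges() / len(snapshot.filaments)

    r = np.linalg.norm(X - c, axis=1)
    rmax = r.max() if r.max() > 0 else 1.0
    prof, _ = np.histogram(r, bins=np.linspace(0, rmax, n_radial_bins + 1))
    prof = prof / prof.sum()

    return MorphologyFeatures(S, rg, asph, sorting, lcf, degree, prof)


def filament_graph(snapshot: NetworkState) -> nx.MultiGraph:
    """One node per filament, one edge per bound linker or motor."""
    G = nx.MultiGraph()
    G.add_nodes_from(range(len(snapshot.filaments)))
    for e in snapshot.bound:
        G.add_edge(e.a[0], e.b[0])
    return G


def detect_catastrophe(snapshot: NetworkState, f_A: float = 0.6,
                       d_B: float = 1.4) -> str | None:
    """Type A: fragmented (largest component < f_A of filaments);
    Type B: connected enough but sparse (mean degree < d_B); else None."""
    n = len(snapshot.filaments)
    if n == 0:
        return None
    G = filament_graph(snapshot)
    lcf = max(len(cc) for cc in nx.connected_components(G)) / n
    if lcf < f_A:
        return CATASTROPHE_A
    if 2.0 * G.number_of_edges() / n < d_B:
        return CATASTROPHE_B
    return None


#: medoid-feature thresholds for semantic cluster labels
LABEL_THRESHOLDS = {"S_bundle": 0.6, "sorting_bundle": 0.2,
                    "sorting_aster": 0.2, "asphericity_aster": 0.1,
                    "S_aster": 0.55}


def _semantic_label(f: MorphologyFeatures,
                    thresholds: dict = LABEL_THRESHOLDS) -> str:
    """BL: aligned with unsorted polarity; AL: polarity-sorted and either
    near-spherical or orientationally disordered; ABI: the remainder."""
    if (f.nematic_order >= thresholds["S_bundle"]
            and abs(f.polarity_sorting) <= thresholds["sorting_bundle"]):
        return BL
    if f.polarity_sorting > thresholds["sorting_aster"] and (
            f.asphericity < thresholds["asphericity_aster"]
            or f.nematic_order < thresholds["S_aster"]):
        return AL
    return ABI


def cut_and_label(tree: ClusterTree,
                  features: dict[str, MorphologyFeatures],
                  k: int = 3) -> dict[str, str]:
    """Cut the tree into ``k`` clusters and name each by its medoid features.

    BL: aligned/elongated; AL: disordered, near-spherical, plus-ends central;
    ABI: the remainder. Falls back to k−1 clusters on a degenerate cut.
    """
    if tree.n_leaves < k:
        k = tree.n_leaves
    assign = tree.cut(k)
    counts = np.bincount(assign, minlength=k)
    if np.any(counts == 0):
        if k <= 1:
            raise ValueError("degenerate cut")
        return cut_and_label(tree, features, k - 1)
    names = tree.leaves or [str(i) for i in range(tree.n_leaves)]
    labels: dict[str, str] = {}
    for cl in range(k):
        members = [names[i] for i in range(tree.n_leaves) if assign[i] == cl]
        feats = [features[m] for m in members]
        # medoid in (S, sorting, asphericity) space
        vec = np.array([[f.nematic_order, f.polarity_sorting, f.asphericity]
                        for f in feats])
        d = np.linalg.norm(vec[:, None, :] - vec[None, :, :], axis=-1).sum(axis=1)
        medoid = feats[int(np.argmin(d))]
        lab = _semantic_label(medoid)
        for m in members:
            labels[m] = lab
    return labels


def classify_conditions(snapshots_by_condition: dict[str, list[NetworkState]],
                        bins: np.ndarray,
                        f_A: float = 0.6, d_B: float = 1.4,
                        features_from: str = "last") -> dict[str, str]:
    """Full pipeline over conditions: catastrophes preempt, the rest are
    clustered into three morphology classes via JSD + complete linkage."""
    labels: dict[str, str] = {}
    healthy: dict[str, list[NetworkState]] = {}
    for cond, snaps in snapshots_by_condition.items():
        cat = detect_catastrophe(snaps[-1], f_A, d_B)
        if cat is not None:
            labels[cond] = cat
        else:
            healthy[cond] = snaps
    if not healthy:
        return labels
    feats = {c: morphology_features(s[-1]) for c, s in healthy.items()}
    if len(healthy) < 3:
        for c in healthy:
            labels[c] = _semantic_label(feats[c])
        return labels
    dists = {c: end_distance_distributions(s, bins, c)
             for c, s in healthy.items()}
    dm = build_dissimilarity_matrix(dists)
    tree = complete_linkage(dm)
    labels.update(cut_and_label(tree, feats, k=3))
    # conditions dropped for empty distributions fall back to features
    for c in healthy:
        if c not in labels:
            labels[c] = _semantic_label(feats[c])
    return labels


def axial_species_distribution(snapshot: NetworkState, species: str,
                               bins: int | np.ndarray = 20) -> tuple[np.ndarray, np.ndarray, bool]:
    """Histogram of bound-element midpoints along the first principal axis.

    Returns ``(probabilities, bin_edges, empty_flag)``.
    """
    mids = [0.5 * (snapshot.resolve(e.a) + snapshot.resolve(e.b))
            for e in snapshot.bound if e.species == species]
    X = snapshot.all_beads()
    c = X.mean(axis=0)
    Y = X - c
    _w, V = np.linalg.eigh(Y.T @ Y / len(Y))
    axis = V[:, -1]
    proj_all = Y @ axis
    lo, hi = proj_all.min(), proj_all.max()
    if np.isscalar(bins):
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, float)
    if not mids:
        return np.zeros(len(edges) - 1), edges, True
    proj = (np.array(mids) - c) @ axis
    h, _ = np.histogram(proj, bins=edges)
    return h / h.sum(), edges, False


def available_crosslink_sites(snapshot: NetworkState, params) -> int:
    """Unbound site pairs inside the crosslinker band (S4-style diagnostic)."""
    from .chemistry import eligible_binding_pairs
    occupied = set()
    for e in snapshot.bound:
        occupied.add(e.a)
        occupied.add(e.b)
    return len(eligible_binding_pairs(snapshot, LINKER, params, occupied))
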