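import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import jensenshannon, squareform

from bundlesim.fixtures import FixtureSpec, make_fixture
from bundlesim.mechanics import LINKER, MOTOR, BoundElement, Filament, NetworkState
from bundlesim.morphology import (ABI, AL, BL, CATASTROPHE_A, CATASTROPHE_B,
                                  DissimilarityMatrix,
                                  available_crosslink_sites,
                                  axial_species_distribution,
                                  build_dissimilarity_matrix,
                                  complete_linkage, cut_and_label,
                                  default_bins, detect_catastrophe,
                                  end_distance_distributions,
                                  jensen_shannon_divergence,
                                  morphology_features)
from bundlesim.params import ChemistryParams


def _two_parallel(sep=35.0, L=540.0, n_beads=6):
    b1 = np.zeros((n_beads, 3))
    b1[:, 0] = np.linspace(0, L, n_beads)
    b2 = b1.copy()
    b2[:, 1] = sep
    return NetworkState([Filament(b1), Filament(b2)],
                        box=np.array([2000.0, 2000, 2000]))


class TestEndDistances:
    def test_hand_geometry_two_parallel(self):
        L = 540.0
        s = _two_parallel(35.0, L)
        bins = np.arange(0, 1000.0, 50.0)
        d = end_distance_distributions([s], bins)
        # ++ and -- all mass in the bin containing 35
        assert d.pp[0] == 1.0 and d.mm[0] == 1.0
        diag = np.hypot(35.0, L)
        k = np.searchsorted(bins, diag) - 1
        assert d.pm[k] == 1.0

    def test_all_ends_coincident(self):
        b = np.zeros((3, 3))
        b[:, 0] = [0, 108, 216]
        f1 = Filament(b)
        f2 = Filament(b.copy())
        s = NetworkState([f1, f2], box=np.array([500.0, 500, 500]))
        bins = np.array([0.0, 50.0, 100.0, 150.0, 200.0, 250.0])
        d = end_distance_distributions([s], bins)
        # coincident like-polarity ends -> all mass in the zero-distance bin
        assert d.pp[0] == 1.0 and d.mm[0] == 1.0
        # +- pairs are the 216-nm ordered combos
        assert d.pm[4] == pytest.approx(1.0)

    def test_matches_brute_force_scan(self, rng):
        fils = []
        for _ in range(10):
            b = rng.uniform(100, 1900, size=(4, 3))
            b = np.sort(b, axis=0)
            fils.append(Filament(b))
        s = NetworkState(fils, box=np.array([2000.0, 2000, 2000]))
        bins = default_bins(np.linalg.norm(s.box))
        d = end_distance_distributions([s], bins)
        pp, mm, pm = [], [], []
        for i in range(10):
            for j in range(i + 1, 10):
                pp.append(np.linalg.norm(fils[i].plus_end - fils[j].plus_end))
                mm.append(np.linalg.norm(fils[i].minus_end - fils[j].minus_end))
                pm.append(np.linalg.norm(fils[i].plus_end - fils[j].minus_end))
                pm.append(np.linalg.norm(fils[i].minus_end - fils[j].plus_end))
        for got, vals in ((d.pp, pp), (d.mm, mm), (d.pm, pm)):
            ref, _ = np.histogram(vals, bins=bins)
            assert np.allclose(got, ref / ref.sum())

    def test_single_filament_flagged_empty(self):
        b = np.zeros((3, 3))
        b[:, 0] = [0, 108, 216]
        s = NetworkState([Filament(b)], box=np.array([500.0, 500, 500]))
        d = end_distance_distributions([s], np.array([0.0, 50, 100]))
        assert d.empty


class TestJSD:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_divergence(p, p) == 0.0

    def test_disjoint_supports_max(self):
        assert jensen_shannon_divergence(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_worked_value(self):
        got = jensen_shannon_divergence(np.array([0.5, 0.5]),
                                        np.array([0.25, 0.75]))
        assert got == pytest.approx(0.0488, abs=5e-4)

    def test_mismatched_bins_error(self):
        with pytest.raises(ValueError):
            jensen_shannon_divergence(np.array([1.0]), np.array([0.5, 0.5]))

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_properties_random_histograms(self, a, b):
        n = min(len(a), len(b))
        P = np.array(a[:n]) / np.sum(a[:n])
        Q = np.array(b[:n]) / np.sum(b[:n])
        d1 = jensen_shannon_divergence(P, Q)
        d2 = jensen_shannon_divergence(Q, P)
        assert d1 == pytest.approx(d2, abs=1e-12)       # symmetry
        assert -1e-12 <= d1 <= 1.0 + 1e-12              # bounded
        # agreement with the scipy oracle (sqrt of base-2 JSD)
        assert d1 == pytest.approx(jensenshannon(P, Q, base=2) ** 2, abs=1e-9)
        if not np.allclose(P, Q):
            assert d1 > 0                                # indiscernibles


class TestDissimilarityMatrix:
    def _dist(self, pp, mm, pm, cond):
        from bundlesim.morphology import EndDistanceDistributions
        bins = np.arange(len(pp) + 1, dtype=float)
        return EndDistanceDistributions(bins, np.array(pp), np.array(mm),
                                        np.array(pm), cond, 1)

    def test_identical_conditions_zero(self):
        d = self._dist([0.5, 0.5], [1, 0], [0, 1], "a")
        d2 = self._dist([0.5, 0.5], [1, 0], [0, 1], "b")
        m = build_dissimilarity_matrix({"a": d, "b": d2})
        assert m.matrix[0, 1] == 0.0

    def test_hand_computed_mean_of_three(self):
        a = self._dist([0.5, 0.5], [0.5, 0.5], [0.5, 0.5], "a")
        b = self._dist([0.25, 0.75], [1.0, 0.0], [0.5, 0.5], "b")
        m = build_dissimilarity_matrix({"a": a, "b": b})
        j1 = jensen_shannon_divergence(a.pp, b.pp)
        j2 = jensen_shannon_divergence(a.mm, b.mm)
        expected = (j1 + j2 + 0.0) / 3.0
        assert m.matrix[0, 1] == pytest.approx(expected)

    def test_symmetric_42(self, rng):
        dists = {}
        for i in range(42):
            h = rng.dirichlet(np.ones(8))
            dists[f"c{i}"] = self._dist(h, h[::-1], h, f"c{i}")
        m = build_dissimilarity_matrix(dists)
        assert m.matrix.shape == (42, 42)
        assert np.allclose(m.matrix, m.matrix.T)
        assert np.all(np.diag(m.matrix) == 0)


class TestCompleteLinkage:
    def test_hand_agglomeration(self):
        D = np.array([[0.0, 1, 4], [1, 0, 3], [4, 3, 0]])
        tree = complete_linkage(D)
        (a, b, h1), (c, d, h2) = tree.merges
        assert {a, b} == {0, 1} and h1 == 1.0
        assert h2 == 4.0

    def test_duplicate_leaves_merge_first_at_zero(self):
        D = np.array([[0.0, 0, 2], [0, 0, 2], [2, 2, 0]])
        tree = complete_linkage(D)
        assert tree.merges[0][2] == 0.0
        assert {tree.merges[0][0], tree.merges[0][1]} == {0, 1}

    def test_monotone_heights_and_scipy_oracle(self, rng):
        for _ in range(8):
            n = 8
            M = rng.uniform(0.1, 1.0, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            tree = complete_linkage(M)
            hs = [m[2] for m in tree.merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(hs, hs[1:]))
            Z = linkage(squareform(M), method="complete")
            assert np.allclose(sorted(hs), sorted(Z[:, 2]))

    def test_cut_counts(self):
        D = np.array([[0.0, 1, 4], [1, 0, 3], [4, 3, 0]])
        tree = complete_linkage(D)
        assert len(set(tree.cut(2))) == 2
        assert len(set(tree.cut(3))) == 3

    def test_newick_export(self):
        D = np.array([[0.0, 1, 4], [1, 0, 3], [4, 3, 0]])
        tree = complete_linkage(D, labels=["x", "y", "z"])
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "x" in nwk and "z" in nwk


class TestFeatures:
    def test_parallel_S_one(self):
        s = _two_parallel()
        f = morphology_features(s)
        assert f.nematic_order == pytest.approx(1.0, abs=1e-9)

    def test_perpendicular_pair_S_quarter(self):
        f1 = Filament(np.array([[0.0, 0, 0], [108, 0, 0]]))
        f2 = Filament(np.array([[200.0, 0, 0], [200, 108, 0]]))
        s = NetworkState([f1, f2], box=np.array([500.0, 500, 500]))
        f = morphology_features(s)
        # Q eigenvalues for two equal perpendicular rods: (1/4, 1/4, -1/2)
        assert f.nematic_order == pytest.approx(0.25, abs=1e-9)

    def test_two_beads_rg(self):
        f1 = Filament(np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        f2 = Filament(np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        s = NetworkState([f1, f2], box=np.array([500.0, 500, 500]))
        f = morphology_features(s)
        assert f.radius_of_gyration == pytest.approx(50.0)

    def test_aster_positive_sorting(self):
        s, _ = make_fixture(FixtureSpec("aster", n_filaments=12, length=500))
        f = morphology_features(s)
        assert f.polarity_sorting > 0.2
        assert f.asphericity < 0.1

    def test_frame_invariance(self, rng):
        s, _ = make_fixture(FixtureSpec("intermediate", n_filaments=10,
                                        length=500, seed=3))
        f0 = morphology_features(s)
        th = 1.1
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        for fil in s.filaments:
            fil.beads = fil.beads @ R.T + np.array([10.0, 20.0, -5.0])
        f1 = morphology_features(s)
        for attr in ("nematic_order", "radius_of_gyration", "asphericity",
                     "polarity_sorting"):
            assert getattr(f1, attr) == pytest.approx(getattr(f0, attr),
                                                      rel=1e-9, abs=1e-9)


class TestCatastrophe:
    def test_two_disjoint_components_type_a(self):
        s, label = make_fixture(FixtureSpec("fragmented", n_filaments=30,
                                            length=500))
        assert detect_catastrophe(s) == CATASTROPHE_A == label

    def test_chain_of_30_no_catastrophe(self):
        fils = [Filament(np.array([[0.0, 0, 0], [108, 0, 0]]) + i)
                for i in range(30)]
        bound = [BoundElement(LINKER, (i, 0, 0.5), (i + 1, 0, 0.5), 35.0)
                 for i in range(29)]
        s = NetworkState(fils, bound, box=np.array([500.0, 500, 500]))
        # mean degree 2*29/30 = 1.93 >= threshold -> none
        assert detect_catastrophe(s) is None

    def test_fully_crosslinked_bundle_none(self):
        s, _ = make_fixture(FixtureSpec("bundle", n_filaments=20, length=500))
        assert detect_catastrophe(s) is None

    def test_sparse_type_b(self):
        s, label = make_fixture(FixtureSpec("sparse", n_filaments=30, length=500))
        assert detect_catastrophe(s) == CATASTROPHE_B == label


class TestCutAndLabel:
    def test_fixture_classes_recovered(self):
        snaps = {}
        truth = {}
        for cls in ("bundle", "aster", "intermediate"):
            for k in range(5):
                cond = f"{cls}{k}"
                s, lab = make_fixture(FixtureSpec(cls, n_filaments=20,
                                                  length=500, noise=5.0,
                                                  seed=k))
                snaps[cond] = [s]
                truth[cond] = lab
        bins = default_bins(4000.0)
        dists = {c: end_distance_distributions(s, bins, c)
                 for c, s in snaps.items()}
        dm = build_dissimilarity_matrix(dists)
        tree = complete_linkage(dm)
        feats = {c: morphology_features(s[0]) for c, s in snaps.items()}
        labels = cut_and_label(tree, feats, k=3)
        assert labels == truth

    def test_all_identical_single_cluster(self):
        s, _ = make_fixture(FixtureSpec("bundle", n_filaments=10, length=500))
        bins = default_bins(4000.0)
        dists = {c: end_distance_distributions([s], bins, c)
                 for c in ("a", "b", "c")}
        dm = build_dissimilarity_matrix(dists)
        tree = complete_linkage(dm)
        feats = {c: morphology_features(s) for c in ("a", "b", "c")}
        labels = cut_and_label(tree, feats, k=3)
        assert set(labels.values()) == {BL}

    def test_leaf_order_invariance(self):
        specs = [("bundle", 0), ("bundle", 1), ("aster", 0), ("aster", 1),
                 ("intermediate", 0), ("intermediate", 1)]
        snaps = {f"{c}{k}": [make_fixture(FixtureSpec(c, n_filaments=16,
                                                      length=500, seed=k))[0]]
                 for c, k in specs}
        bins = default_bins(4000.0)

        def run(order):
            dists = {c: end_distance_distributions(snaps[c], bins, c)
                     for c in order}
            dm = build_dissimilarity_matrix(dists)
            feats = {c: morphology_features(snaps[c][0]) for c in order}
            return cut_and_label(complete_linkage(dm), feats, k=3)

        keys = list(snaps)
        assert run(keys) == run(keys[::-1])


class TestAxialDistribution:
    def test_normalized(self):
        s, _ = make_fixture(FixtureSpec("sarcomere", n_filaments=12, length=500))
        h, edges, empty = axial_species_distribution(s, MOTOR, bins=10)
        assert not empty
        assert h.sum() == pytest.approx(1.0)

    def test_sarcomere_bands_hold_motor_mass(self):
        s, _ = make_fixture(FixtureSpec("sarcomere", n_filaments=20, length=700))
        h, edges, _ = axial_species_distribution(s, MOTOR, bins=7)
        # motors are placed in the central cylinder band by construction
        assert h.max() >= 0.9

    def test_uniform_fixture_bounded(self, rng):
        f1 = Filament(np.stack([np.linspace(0, 1080, 11),
                                np.zeros(11), np.zeros(11)], axis=1))
        f2 = f1.copy()
        f2.beads[:, 1] = 35.0
        bound = []
        for _ in range(1000):
            ci = int(rng.integers(0, 10))
            fr = float(rng.random())
            bound.append(BoundElement(LINKER, (0, ci, fr), (1, ci, fr), 35.0))
        s = NetworkState([f1, f2], bound, box=np.array([2000.0, 500, 500]))
        h, _, _ = axial_species_distribution(s, LINKER, bins=10)
        assert h.max() <= 3.0 * 0.1

    def test_no_elements_flagged_empty(self):
        s = _two_parallel()
        h, _, empty = axial_species_distribution(s, MOTOR, bins=5)
        assert empty and h.sum() == 0


class TestAvailableSites:
    def test_bundle_matches_brute_force(self, chem_params):
        s, _ = make_fixture(FixtureSpec("bundle", n_filaments=7, length=500))
        from bundlesim.chemistry import eligible_binding_pairs
        occ = set()
        for e in s.bound:
            occ.add(e.a)
            occ.add(e.b)
        n = available_crosslink_sites(s, chem_params)
        assert n == len(eligible_binding_pairs(s, LINKER, chem_params, occ))
        assert n > 0

    def test_far_apart_zero(self, chem_params):
        s = _two_parallel(sep=150.0)
        assert available_crosslink_sites(s, chem_params) == 0

    def test_non_increasing_with_spacing(self, chem_params):
        counts = [available_crosslink_sites(_two_parallel(sep=s), chem_params)
                  for s in (35.0, 45.0, 60.0)]
        assert counts[0] >= counts[1] >= counts[2]
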