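"""geometry_metrics: Kabsch, automorphisms, best RMSD, TFD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ffbench.errors import FFBenchError, MetricError
from ffbench.geometry_metrics import (
    best_rmsd,
    build_torsion_set,
    dihedral_angle,
    enumerate_automorphisms,
    kabsch_superpose,
    min_rmsd_matrix,
    tfd,
)
from conftest import brute_force_automorphisms, make_graph, random_heavy_graph


def rigid_copy(coords, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    return coords @ rot.T + rng.normal(size=3)


class TestKabsch:
    def test_identity(self):
        coords = np.random.default_rng(0).normal(size=(7, 3))
        rmsd, rot, trans = kabsch_superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        coords = np.random.default_rng(1).normal(size=(9, 3))
        moved = rigid_copy(coords, seed=2)
        rmsd, rot, trans = kabsch_superpose(coords, moved)
        assert rmsd < 1e-6
        np.testing.assert_allclose(coords @ rot.T + trans, moved, atol=1e-8)

    def test_hand_case_two_points(self):
        # centred: a -> {(-1,0,0),(1,0,0)}, b -> {(-2,0,0),(2,0,0)};
        # optimal overlay leaves per-atom error 1 -> rmsd 1.0
        a = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        rmsd, *_ = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(1.0, abs=1e-10)

    def test_mismatched_counts_error(self):
        with pytest.raises(FFBenchError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_no_reflection(self):
        coords = np.random.default_rng(3).normal(size=(6, 3))
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        _rmsd, rot, _t = kabsch_superpose(coords, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestAutomorphisms:
    def test_water_has_two(self, water_graph):
        autos = enumerate_automorphisms(water_graph)
        assert len(autos) == 2 and not autos.truncated

    def test_benzene_ring_twelve(self, benzene_graph):
        assert len(enumerate_automorphisms(benzene_graph)) == 12

    def test_asymmetric_chain_single(self, chain_cno_graph):
        assert len(enumerate_automorphisms(chain_cno_graph)) == 1

    def test_identity_first(self, ethane_graph):
        autos = enumerate_automorphisms(ethane_graph)
        np.testing.assert_array_equal(
            autos.permutations[0], np.arange(ethane_graph.n_atoms)
        )

    def test_cap_truncation_flagged(self, ethane_graph):
        autos = enumerate_automorphisms(ethane_graph, cap=5)
        assert autos.truncated and len(autos) == 5
        np.testing.assert_array_equal(
            autos.permutations[0], np.arange(ethane_graph.n_atoms)
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_heavy_graph(rng, int(rng.integers(3, 8)))
        got = {tuple(p) for p in enumerate_automorphisms(graph).permutations}
        expected = set(brute_force_automorphisms(graph))
        assert got == expected

    def test_leaf_factoring_counts(self, ethane_graph):
        # 2 (swap the carbons) x 3! x 3! hydrogen permutations
        assert len(enumerate_automorphisms(ethane_graph)) == 72


class TestBestRmsd:
    def test_equivalent_hydrogen_swap_absorbed(self, water_graph):
        coords = np.array(
            [[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]
        )
        swapped = coords[[0, 2, 1]]
        res = best_rmsd(water_graph, coords, swapped)
        assert res.value < 1e-9

    def test_asymmetric_equals_plain_kabsch(self, chain_cno_graph):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        expected, *_ = kabsch_superpose(a, b)
        assert best_rmsd(chain_cno_graph, a, b).value == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_minimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        graph = random_heavy_graph(rng, 6)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.3, size=(6, 3))
        expected = min(
            kabsch_superpose(a, b[list(p)])[0]
            for p in brute_force_automorphisms(graph)
        )
        assert best_rmsd(graph, a, b).value == pytest.approx(expected, abs=1e-8)

    def test_symmetric_never_exceeds_fixed_correspondence(self, ethane_graph):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.5, size=(8, 3))
        fixed, *_ = kabsch_superpose(a, b)
        assert best_rmsd(ethane_graph, a, b).value <= fixed + 1e-12

    def test_symmetry_in_arguments(self, ethane_graph):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert best_rmsd(ethane_graph, a, b).value == pytest.approx(
            best_rmsd(ethane_graph, b, a).value, abs=1e-9
        )

    def test_truncation_marks_upper_bound(self, ethane_graph):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.2, size=(8, 3))
        capped = best_rmsd(ethane_graph, a, b, cap=2)
        full = best_rmsd(ethane_graph, a, b)
        assert capped.upper_bound and not full.upper_bound
        assert capped.value >= full.value - 1e-12

    def test_heavy_only_subset(self, ethane_graph):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(8, 3))
        b = a.copy()
        b[2:] += rng.normal(scale=1.0, size=(6, 3))  # move hydrogens only
        heavy = best_rmsd(ethane_graph, a, b, include_hydrogens=False)
        assert heavy.value < best_rmsd(ethane_graph, a, b).value

    def test_min_rmsd_matrix_agrees_with_best_rmsd(self, ethane_graph):
        rng = np.random.default_rng(12)
        qs = [rng.normal(size=(8, 3)) for _ in range(3)]
        fs = [rng.normal(size=(8, 3)) for _ in range(4)]
        autos = enumerate_automorphisms(ethane_graph)
        mat = min_rmsd_matrix(qs, fs, autos.permutations)
        for i, q in enumerate(qs):
            for j, f in enumerate(fs):
                assert mat[i, j] == pytest.approx(
                    best_rmsd(ethane_graph, q, f, automorphisms=autos).value,
                    abs=1e-9,
                )


class TestTorsionSet:
    def test_ethane_like_single_entry_period_120(self, ethane_graph):
        ts = build_torsion_set(ethane_graph)
        assert len(ts) == 1
        assert ts.entries[0].period == pytest.approx(120.0)
        assert ts.entries[0].weight == pytest.approx(1.0)

    def test_heavy_chain_single_central_entry(self, heavy_chain_graph):
        ts = build_torsion_set(heavy_chain_graph)
        assert len(ts) == 1
        assert ts.entries[0].central_bond == (1, 2)
        assert ts.entries[0].period == pytest.approx(360.0)
        assert ts.entries[0].weight == pytest.approx(1.0)

    def test_chain_plus_ring(self):
        # cyclobutane ring with a 3-atom heavy chain attached
        elements = ["C"] * 7
        bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1),  # ring
                 (0, 4, 1), (4, 5, 1), (5, 6, 1)]  # chain
        g = make_graph(elements, bonds)
        ts = build_torsion_set(g)
        kinds = sorted(e.kind for e in ts.entries)
        assert kinds == ["dihedral", "dihedral", "ring"]
        assert sum(e.weight for e in ts.entries) == pytest.approx(1.0)

    def test_diatomic_empty(self):
        g = make_graph(["C", "O"], [(0, 1, 3)])
        assert len(build_torsion_set(g)) == 0

    def test_weights_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            g = random_heavy_graph(rng, int(rng.integers(4, 9)))
            ts = build_torsion_set(g)
            if len(ts):
                assert sum(e.weight for e in ts.entries) == pytest.approx(1.0)


def _twist(graph, coords, bond, angle_deg):
    from ffbench.synthetic_data import _apply_torsion_kicks

    return _apply_torsion_kicks(graph, coords, [(bond, angle_deg)])


class TestTfd:
    @pytest.fixture
    def chain_coords(self, heavy_chain_graph):
        return np.array(
            [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.0, 1.4, 0.0],
             [3.5, 1.5, 0.5]]
        )

    def test_identity_zero(self, heavy_chain_graph, chain_coords):
        ts = build_torsion_set(heavy_chain_graph)
        assert tfd(ts, chain_coords, chain_coords) == pytest.approx(0.0)

    def test_single_torsion_180_gives_one(self, heavy_chain_graph, chain_coords):
        ts = build_torsion_set(heavy_chain_graph)
        twisted = _twist(heavy_chain_graph, chain_coords, (1, 2), 180.0)
        assert tfd(ts, chain_coords, twisted) == pytest.approx(1.0, abs=1e-9)

    def test_single_torsion_90_gives_half(self, heavy_chain_graph, chain_coords):
        ts = build_torsion_set(heavy_chain_graph)
        twisted = _twist(heavy_chain_graph, chain_coords, (1, 2), 90.0)
        assert tfd(ts, chain_coords, twisted) == pytest.approx(0.5, abs=1e-9)

    def test_rigid_motion_invariance(self, heavy_chain_graph, chain_coords):
        ts = build_torsion_set(heavy_chain_graph)
        assert tfd(ts, chain_coords, rigid_copy(chain_coords, 5)) \
            == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_single_torsion(self, heavy_chain_graph, chain_coords):
        ts = build_torsion_set(heavy_chain_graph)
        scores = [
            tfd(ts, chain_coords,
                _twist(heavy_chain_graph, chain_coords, (1, 2), a))
            for a in np.linspace(0.0, 180.0, 19)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_empty_set_error(self):
        g = make_graph(["C", "O"], [(0, 1, 3)])
        ts = build_torsion_set(g)
        with pytest.raises(MetricError):
            tfd(ts, np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_range_property(self, seed):
        graph = make_graph(
            ["C", "N", "O", "S"], [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
        )
        rng = np.random.default_rng(seed)
        ts = build_torsion_set(graph)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        assert 0.0 <= tfd(ts, a, b) <= 1.0


class TestDihedral:
    def test_right_angle_magnitude_and_reversal(self):
        coords = np.array(
            [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
             [1.0, 0.0, 1.0]]
        )
        angle = dihedral_angle(coords, (0, 1, 2, 3))
        assert abs(angle) == pytest.approx(90.0)
        # dihedral is invariant under reversing the quadruple
        assert dihedral_angle(coords, (3, 2, 1, 0)) == pytest.approx(angle)

    def test_colinear_returns_none(self):
        coords = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]
        )
        assert dihedral_angle(coords, (0, 1, 2, 3)) is None
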