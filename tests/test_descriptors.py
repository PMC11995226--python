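import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chamscope.core import MoleculeTopology
from chamscope.descriptors import (
    FoldThresholds,
    PolarScheme,
    classify_polar_atoms,
    count_imhb,
    etr,
    fibonacci_sphere,
    fold_class,
    partition_sasa,
    radius_of_gyration,
    shrake_rupley_sasa,
)

# ---------------------------------------------------------------------------
# independent oracles


def rgyr_direct(coords, weights):
    """Direct evaluation of the defining sum, independent of the library path."""
    w = np.asarray(weights, float)
    centroid = sum(wi * ci for wi, ci in zip(w, coords)) / w.sum()
    s = sum(wi * np.dot(ci - centroid, ci - centroid) for wi, ci in zip(w, coords))
    return np.sqrt(s / w.sum())


def two_sphere_area_exact(r1, r2, d):
    """Closed-form accessible areas of two intersecting spheres (cap formula)."""
    if d >= r1 + r2:
        return 4 * np.pi * r1**2, 4 * np.pi * r2**2
    if d <= abs(r1 - r2):
        if r1 > r2:
            return 4 * np.pi * r1**2, 0.0
        return 0.0, 4 * np.pi * r2**2
    x1 = (d**2 + r1**2 - r2**2) / (2 * d)
    x2 = d - x1
    a1 = 4 * np.pi * r1**2 - 2 * np.pi * r1 * (r1 - x1)
    a2 = 4 * np.pi * r2**2 - 2 * np.pi * r2 * (r2 - x2)
    return a1, a2


def sasa_monte_carlo(coords, radii, probe, n_samples, seed):
    """Surface-rejection Monte Carlo SASA, independent of the lattice code."""
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * pts
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        areas[i] = free.mean() * 4 * np.pi * expanded[i] ** 2
    return areas


# ---------------------------------------------------------------------------
# radius of gyration


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_point_analytic(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords, mode="geometric") == pytest.approx(1.0)

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(10, 3)) * 4
        masses = rng.uniform(1, 16, 10)
        got = radius_of_gyration(coords, masses)
        assert got == pytest.approx(rgyr_direct(coords, masses), rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(8, 3)) * 5
        masses = rng.uniform(1, 32, 8)
        ref = radius_of_gyration(coords, masses)
        # random proper rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = coords @ q.T + rng.normal(size=3) * 100
        assert radius_of_gyration(moved, masses) == pytest.approx(ref, rel=1e-9)

    def test_heavy_only_and_errors(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        masses = np.array([12.0, 1.008, 12.0])
        rg = radius_of_gyration(coords, masses, heavy_only=True, elements=["C", "H", "C"])
        assert rg == pytest.approx(1.0)
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)), np.array([]))
        with pytest.raises(ValueError, match="positive"):
            radius_of_gyration(coords, np.array([0.0, 1.0, 1.0]))


# ---------------------------------------------------------------------------
# SASA


class TestShrakeRupley:
    def test_isolated_atom_analytic(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.70]), 1.4, 960)
        exact = 4 * np.pi * 3.10**2
        assert area[0] == pytest.approx(exact, rel=5e-3)

    def test_fully_buried_atom(self):
        coords = np.zeros((2, 3))
        radii = np.array([1.0, 3.0])
        areas = shrake_rupley_sasa(coords, radii, 1.4, 960)
        assert areas[0] == 0.0

    def test_two_sphere_closed_form(self):
        r = np.array([1.7, 1.5])
        probe = 1.4
        d = 2.5
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        got = shrake_rupley_sasa(coords, r, probe, 4096)
        want = two_sphere_area_exact(r[0] + probe, r[1] + probe, d)
        assert got[0] == pytest.approx(want[0], rel=0.01)
        assert got[1] == pytest.approx(want[1], rel=0.01)

    def test_monte_carlo_oracle_random_cluster(self, random_cluster):
        coords, radii = random_cluster(5, seed=11)
        got = shrake_rupley_sasa(coords, radii, 1.4, 4096)
        want = sasa_monte_carlo(coords, radii, 1.4, 200_000, seed=5)
        exposed = want > 1.0  # relative comparison is meaningless at ~0 area
        np.testing.assert_allclose(got[exposed], want[exposed], rtol=0.01)

    def test_distant_atom_leaves_areas_unchanged(self, random_cluster):
        coords, radii = random_cluster(4, seed=3)
        base = shrake_rupley_sasa(coords, radii, 1.4, 960)
        coords2 = np.vstack([coords, [[500.0, 0, 0]]])
        radii2 = np.append(radii, 1.7)
        grown = shrake_rupley_sasa(coords2, radii2, 1.4, 960)
        np.testing.assert_allclose(grown[:4], base, rtol=1e-12)

    def test_overlapping_atom_never_increases_area(self, random_cluster):
        coords, radii = random_cluster(4, seed=9, spread=1.5)
        base = shrake_rupley_sasa(coords, radii, 1.4, 960)
        coords2 = np.vstack([coords, coords.mean(axis=0, keepdims=True)])
        radii2 = np.append(radii, 1.7)
        grown = shrake_rupley_sasa(coords2, radii2, 1.4, 960)
        assert np.all(grown[:4] <= base + 1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="NaN|finite"):
            shrake_rupley_sasa(np.array([[np.nan, 0, 0]]), np.array([1.7]))
        with pytest.raises(ValueError, match="32"):
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]), n_sphere_points=8)

    def test_lattice_is_deterministic_and_unit(self):
        a = fibonacci_sphere(960)
        b = fibonacci_sphere(960)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# polarity and partition


class TestPolarityPartition:
    def test_methane_all_nonpolar(self):
        topo = MoleculeTopology(
            elements=["C", "H", "H", "H", "H"], bonds=[(0, i) for i in range(1, 5)]
        )
        assert not classify_polar_atoms(topo).any()

    def test_water_all_polar(self):
        topo = MoleculeTopology(elements=["O", "H", "H"], bonds=[(0, 1), (0, 2)])
        assert classify_polar_atoms(topo).all()

    def test_peg_fragment_oxygens_only(self):
        topo = MoleculeTopology(
            elements=["C", "C", "O", "C", "C", "O"],
            bonds=[(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)],
        )
        mask = classify_polar_atoms(topo)
        np.testing.assert_array_equal(mask, [False, False, True, False, False, True])

    def test_sulfur_scheme_toggle(self):
        topo = MoleculeTopology(elements=["C", "S"], bonds=[(0, 1)])
        assert not classify_polar_atoms(topo)[1]
        assert classify_polar_atoms(topo, PolarScheme(include_sulfur=True))[1]

    def test_hydrogen_without_bond_record_rejected(self):
        topo = MoleculeTopology(elements=["O", "H"], bonds=[])
        with pytest.raises(ValueError, match="bond record"):
            classify_polar_atoms(topo)

    def test_partition_identity_and_extremes(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(0, 30, 20)
        mask = rng.random(20) < 0.5
        psa, npsa = partition_sasa(areas, mask)
        assert psa == pytest.approx(areas[mask].sum())
        assert npsa == pytest.approx(areas[~mask].sum())
        assert psa + npsa == pytest.approx(areas.sum(), abs=1e-6)
        assert partition_sasa(areas, np.ones(20, bool)) == (pytest.approx(areas.sum()), 0.0)
        assert partition_sasa(areas, np.zeros(20, bool)) == (0.0, pytest.approx(areas.sum()))
        with pytest.raises(ValueError, match="mask"):
            partition_sasa(areas, mask[:-1])


# ---------------------------------------------------------------------------
# IMHB


def _dha_topology():
    # O(donor)-H ... O(acceptor) with a 4-carbon bridge for bond separation
    elements = ["O", "H", "C", "C", "C", "O"]
    bonds = [(0, 1), (0, 2), (2, 3), (3, 4), (4, 5)]
    return MoleculeTopology(elements=elements, bonds=bonds)


class TestIMHB:
    def test_linear_geometry_counts_one(self):
        topo = _dha_topology()
        coords = np.array(
            [
                [0.0, 0, 0],  # O donor
                [1.0, 0, 0],  # H
                [-0.5, 1.2, 0],
                [0.2, 2.5, 0],
                [1.5, 3.0, 0],
                [3.0, 0, 0],  # acceptor, H...A = 2.0 Å, angle 180°
            ]
        )
        assert count_imhb(coords, topo) == 1

    def test_distant_acceptor_not_counted(self):
        topo = _dha_topology()
        coords = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [-0.5, 1.2, 0], [0.2, 2.5, 0], [1.5, 3.0, 0], [5.5, 0, 0]]
        )
        assert count_imhb(coords, topo) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        n = 20
        elements = [["C", "O", "N", "H"][i % 4] for i in range(n)]
        bonds = [(i, i + 1) for i in range(n - 1)]
        topo = MoleculeTopology(elements=elements, bonds=bonds)
        coords = rng.uniform(-4, 4, size=(n, 3))

        # exhaustive oracle over all D-H...A triples
        import networkx as nx

        g = nx.Graph(bonds)
        expected = 0
        for h in range(n):
            if elements[h] != "H":
                continue
            donors = [j for j in g.neighbors(h) if elements[j] in "NO"]
            if not donors:
                continue
            d = donors[0]
            for a in range(n):
                if elements[a] not in "NO" or a == d:
                    continue
                if nx.shortest_path_length(g, h, a) < 3:
                    continue
                ha = np.linalg.norm(coords[a] - coords[h])
                if ha > 2.5:
                    continue
                v1, v2 = coords[d] - coords[h], coords[a] - coords[h]
                ang = np.degrees(
                    np.arccos(
                        np.clip(
                            v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1
                        )
                    )
                )
                if ang >= 120.0:
                    expected += 1
        assert count_imhb(coords, topo) == expected

    def test_no_hydrogens_returns_zero_with_warning(self, caplog):
        topo = MoleculeTopology(elements=["C", "O"], bonds=[(0, 1)])
        with caplog.at_level("WARNING"):
            assert count_imhb(np.zeros((2, 3)), topo) == 0
        assert "no hydrogens" in caplog.text


# ---------------------------------------------------------------------------
# fold classes and ETR


class TestFoldClassEtr:
    def test_bands_for_degrader_scale_molecules(self):
        assert fold_class(5.5) == "folded"  # compact ensembles sit near 5-7 Å
        assert fold_class(8.0) == "semifolded"
        assert fold_class(11.0) == "extended"  # fully stretched chains

    def test_boundaries_resolve_compact(self):
        th = FoldThresholds(7.0, 9.5)
        assert fold_class(7.0, th) == "folded"
        assert fold_class(9.5, th) == "extended"
        assert fold_class(7.0000001, th) == "semifolded"

    def test_monotone_in_r_gyr(self):
        order = {"folded": 0, "semifolded": 1, "extended": 2}
        classes = [order[fold_class(r)] for r in np.linspace(0, 15, 200)]
        assert classes == sorted(classes)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            FoldThresholds(9.5, 7.0)

    @pytest.mark.parametrize(
        "epsa,tpsa,expected", [(100, 200, 0.5), (150, 150, 1.0), (0, 150, 0.0)]
    )
    def test_etr_values(self, epsa, tpsa, expected):
        assert etr(epsa, tpsa) == pytest.approx(expected)

    def test_etr_rejects_nonpositive_tpsa(self):
        with pytest.raises(ValueError, match="TPSA"):
            etr(100, 0)
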