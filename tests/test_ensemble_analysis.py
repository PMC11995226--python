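import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from chamscope.core import Conformer, Ensemble, MoleculeTopology
from chamscope.ensemble_analysis import (
    CongruenceConfig,
    LandscapeGrid,
    boltzmann_populations,
    cluster_ensemble,
    cluster_populations,
    compare_solvent_ensembles,
    identify_mec,
    kabsch_rmsd,
    landscape_overlap,
    low_energy_subset,
    property_landscape,
)


def rmsd_by_numeric_optimization(a, b):
    """Oracle: minimize RMSD over rotation vectors with a generic optimizer."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def f(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((ac @ r.T - bc) ** 2).sum() / len(a))

    best = min(
        (minimize(f, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
         for x0 in [np.zeros(3), np.array([3.0, 0, 0]), np.array([0, 3.0, 0]), np.array([1.5, 1.5, 1.5])]),
        key=lambda r: r.fun,
    )
    return best.fun


class TestKabschRMSD:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).normal(size=(6, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3)) * 3
        rot = Rotation.random(random_state=7).as_matrix()
        b = a @ rot.T + np.array([10.0, -5.0, 2.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-8)

    def test_matches_numeric_optimizer(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(7, 3)) * 3
        b = rng.normal(size=(7, 3)) * 3
        got = kabsch_rmsd(a, b)
        want = rmsd_by_numeric_optimization(a, b)
        assert got == pytest.approx(want, abs=1e-5)
        assert got <= want + 1e-8  # closed form is the true minimum

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), rel=1e-12)

    def test_collinear_rejected(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="non-collinear"):
            kabsch_rmsd(a, a)


def _ensemble_from_coords(coord_list, energies=None):
    n = coord_list[0].shape[0]
    topo = MoleculeTopology(elements=["C"] * n, bonds=[(i, i + 1) for i in range(n - 1)])
    confs = [
        Conformer(c, energy=(energies[k] if energies is not None else None), conformer_id=str(k))
        for k, c in enumerate(coord_list)
    ]
    return Ensemble(topology=topo, conformers=confs)


class TestClustering:
    def test_identical_conformers_single_cluster(self):
        base = np.random.default_rng(1).normal(size=(5, 3))
        ens = _ensemble_from_coords([base.copy() for _ in range(4)])
        res = cluster_ensemble(ens, rmsd_cutoff=0.5)
        assert res.n_clusters == 1
        assert set(res.labels) == {0}

    def test_zero_cutoff_distinct_conformers(self):
        rng = np.random.default_rng(8)
        ens = _ensemble_from_coords([rng.normal(size=(5, 3)) * 3 for _ in range(4)])
        res = cluster_ensemble(ens, rmsd_cutoff=0.0)
        assert res.n_clusters == 4

    def test_two_separated_bundles(self):
        rng = np.random.default_rng(5)
        compact = rng.normal(size=(6, 3))
        extended = compact * 4.0  # far beyond any 1 Å cutoff after superposition
        coords = [compact + 0.02 * rng.normal(size=(6, 3)) for _ in range(5)]
        coords += [extended + 0.02 * rng.normal(size=(6, 3)) for _ in range(5)]
        ens = _ensemble_from_coords(coords)
        res = cluster_ensemble(ens, rmsd_cutoff=1.0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1

    def test_representatives_pairwise_beyond_cutoff(self):
        rng = np.random.default_rng(13)
        ens = _ensemble_from_coords(
            [rng.normal(size=(6, 3)) * 2 for _ in range(12)],
            energies=rng.normal(size=12),
        )
        cutoff = 1.5
        res = cluster_ensemble(ens, rmsd_cutoff=cutoff)
        reps = res.representatives
        coords = ens.coordinates
        subset = ens.topology.heavy_atom_indices()
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert kabsch_rmsd(coords[reps[i]], coords[reps[j]], subset) > cutoff

    def test_representative_is_lowest_energy_member(self):
        base = np.random.default_rng(3).normal(size=(5, 3))
        coords = [base + 0.01 * k for k in range(3)]
        ens = _ensemble_from_coords(coords, energies=[3.0, 1.0, 2.0])
        res = cluster_ensemble(ens, rmsd_cutoff=5.0)
        assert res.representatives == [1]

    def test_negative_cutoff_rejected(self, toy_ensemble):
        with pytest.raises(ValueError):
            cluster_ensemble(toy_ensemble, rmsd_cutoff=-1.0)


class TestBoltzmann:
    def test_equal_energies_uniform(self):
        np.testing.assert_allclose(boltzmann_populations([2.0] * 4), 0.25)

    def test_rt_ln2_two_state(self):
        rt = 1.987204e-3 * 300.0
        p = boltzmann_populations([0.0, rt * np.log(2.0)], 300.0)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_matches_unshifted_formula(self):
        rng = np.random.default_rng(5)
        e = rng.uniform(-3, 3, 12)
        beta = 1.0 / (1.987204e-3 * 300.0)
        direct = np.exp(-beta * e) / np.exp(-beta * e).sum()
        np.testing.assert_allclose(boltzmann_populations(e), direct, rtol=1e-12)

    def test_offset_invariance(self):
        e = np.array([0.3, 1.7, -0.2, 0.9])
        np.testing.assert_allclose(
            boltzmann_populations(e), boltzmann_populations(e + 123.4), atol=1e-12
        )

    def test_monotone_and_high_t_limit(self):
        e = np.array([0.1, 0.5, 1.2, 2.0])
        p = boltzmann_populations(e)
        assert np.all(np.diff(p) <= 0)
        np.testing.assert_allclose(boltzmann_populations(e, 1e9), 0.25, atol=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            boltzmann_populations([])
        with pytest.raises(ValueError):
            boltzmann_populations([1.0], temperature=0.0)


class TestSubsetAndMEC:
    def test_threshold_is_strict(self):
        assert list(low_energy_subset([0.5, 0.3, 0.2])) == [0, 1, 2]
        assert list(low_energy_subset([0.995, 0.005])) == [0]
        assert list(low_energy_subset([0.99, 0.01])) == [0]  # 0.01 not > 0.01

    def test_empty_result_logged(self, caplog):
        with caplog.at_level("WARNING"):
            out = low_energy_subset(np.full(200, 0.005))
        assert out.size == 0
        assert "threshold" in caplog.text

    def test_mec_is_most_populated_cluster_representative(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(5, 3))
        b = a * 4
        coords = [a, a + 0.01, b]
        ens = _ensemble_from_coords(coords, energies=[0.0, 0.1, 0.05])
        res = cluster_ensemble(ens, rmsd_cutoff=1.0)
        pops = boltzmann_populations(ens.energies)
        mec = identify_mec(res, pops, ens.energies)
        assert mec == 0  # cluster {0,1} holds most population; rep = lowest E
        cpop = cluster_populations(res, pops)
        assert cpop.sum() == pytest.approx(1.0)

    def test_mec_tie_breaks_to_lower_energy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) * 5
        ens = _ensemble_from_coords([a, b], energies=[1.0, 2.0])
        res = cluster_ensemble(ens, rmsd_cutoff=0.5)
        mec = identify_mec(res, [0.5, 0.5], ens.energies)
        assert mec == 0


class TestLandscape:
    def test_single_conformer_single_cell(self):
        table = pd.DataFrame({"r_gyr": [5.0], "sa3d_psa": [200.0]})
        grid = property_landscape(table, bins=10)
        assert grid.density.sum() == pytest.approx(1.0)
        assert (grid.density == 1.0).sum() == 1

    def test_weighted_bundles(self):
        table = pd.DataFrame(
            {"r_gyr": [5.0, 5.1, 11.0, 11.1], "sa3d_psa": [200.0, 201.0, 240.0, 241.0]}
        )
        grid = property_landscape(table, bins=2, weights=[0.35, 0.35, 0.15, 0.15])
        masses = sorted(grid.density[grid.density > 0].tolist())
        assert masses == pytest.approx([0.3, 0.7])

    def test_normalization_always_holds(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame(
            {"r_gyr": rng.uniform(4, 12, 50), "sa3d_psa": rng.uniform(150, 260, 50)}
        )
        grid = property_landscape(table, bins=7, weights=rng.uniform(0.1, 1, 50))
        assert grid.density.sum() == pytest.approx(1.0)

    def test_invalid_bins(self):
        table = pd.DataFrame({"r_gyr": [5.0], "sa3d_psa": [200.0]})
        with pytest.raises(ValueError):
            property_landscape(table, bins=0)

    def test_overlap_self_is_one_and_symmetric(self):
        rng = np.random.default_rng(17)
        d = rng.uniform(size=(5, 5))
        d /= d.sum()
        edges = np.linspace(0, 1, 6)
        g1 = LandscapeGrid(edges, edges, d)
        d2 = rng.uniform(size=(5, 5))
        d2 /= d2.sum()
        g2 = LandscapeGrid(edges, edges, d2)
        assert landscape_overlap(g1, g1) == pytest.approx(1.0)
        assert landscape_overlap(g1, g2) == pytest.approx(landscape_overlap(g2, g1))

    def test_mismatched_grids_rejected(self):
        d = np.ones((4, 4)) / 16
        g1 = LandscapeGrid(np.linspace(0, 1, 5), np.linspace(0, 1, 5), d)
        g2 = LandscapeGrid(np.linspace(0, 2, 5), np.linspace(0, 1, 5), d)
        with pytest.raises(ValueError, match="common binning"):
            landscape_overlap(g1, g2)


class TestSolventComparison:
    def test_identical_ensembles_congruent(self):
        rng = np.random.default_rng(23)
        table = pd.DataFrame(
            {"r_gyr": rng.uniform(5, 7, 80), "sa3d_psa": rng.uniform(190, 230, 80)}
        )
        cmp = compare_solvent_ensembles(table, table.copy())
        assert cmp.delta_r_gyr == pytest.approx(0.0)
        assert cmp.delta_sa3d_psa == pytest.approx(0.0)
        assert cmp.overlap == pytest.approx(1.0)
        assert cmp.congruent

    def test_disjoint_support_zero_overlap(self):
        a = pd.DataFrame({"r_gyr": [5.0, 5.2], "sa3d_psa": [200.0, 202.0]})
        b = pd.DataFrame({"r_gyr": [11.0, 11.2], "sa3d_psa": [240.0, 242.0]})
        cmp = compare_solvent_ensembles(a, b)
        assert cmp.overlap == 0.0
        assert not cmp.congruent

    def test_centroid_shift_matches_analytic(self):
        a = pd.DataFrame(
            {"r_gyr": [5.0, 6.0], "sa3d_psa": [200.0, 210.0], "population": [0.75, 0.25]}
        )
        b = pd.DataFrame(
            {"r_gyr": [10.0, 12.0], "sa3d_psa": [230.0, 250.0], "population": [0.5, 0.5]}
        )
        cmp = compare_solvent_ensembles(a, b)
        # population-weighted centroids: 5.25 vs 11.0; 202.5 vs 240
        assert cmp.delta_r_gyr == pytest.approx(11.0 - 5.25)
        assert cmp.delta_sa3d_psa == pytest.approx(240.0 - 202.5)

    def test_empty_table_rejected(self):
        a = pd.DataFrame({"r_gyr": [], "sa3d_psa": []})
        b = pd.DataFrame({"r_gyr": [5.0], "sa3d_psa": [200.0]})
        with pytest.raises(ValueError, match="non-empty"):
            compare_solvent_ensembles(a, b)
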