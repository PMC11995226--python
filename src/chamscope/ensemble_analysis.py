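"""Clustering, Boltzmann population analysis, MEC identification and
property landscapes.

The workflow mirrors how low-energy conformational landscapes are usually
summarized: conformers are clustered on heavy-atom RMSD after optimal rigid
superposition (Kabsch), each cluster is assigned the summed Boltzmann weight
of its members, clusters above a population threshold are reported, and the
representative of the most-populated cluster is the minimum-energy
conformation (MEC). Property landscapes are weighted 2D histograms over
(R_gyr, SA 3D PSA); comparing the landscapes of the same molecule in a polar
and an apolar solvent quantifies chameleonicity: congruent ensembles have a
small population-weighted centroid shift and large landscape overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Ensemble, GAS_CONSTANT_KCAL

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "LandscapeGrid",
    "SolventComparison",
    "CongruenceConfig",
    "kabsch_rmsd",
    "cluster_ensemble",
    "boltzmann_populations",
    "low_energy_subset",
    "identify_mec",
    "cluster_populations",
    "property_landscape",
    "landscape_overlap",
    "compare_solvent_ensembles",
]


def kabsch_rmsd(
    conformer_a: np.ndarray,
    conformer_b: np.ndarray,
    atom_subset: Optional[Sequence[int]] = None,
) -> float:
    """Minimal RMSD (Å) between two conformers over rigid superpositions.

    Both coordinate sets are centered and the optimal rotation is obtained
    in closed form from the SVD of the covariance matrix, with the
    determinant sign flipped when needed so only proper rotations are used.
    Symmetric in its arguments. Requires at least three non-collinear atoms
    in the selection, otherwise the rotation is not well conditioned.
    """
    a = np.asarray(conformer_a, dtype=float)
    b = np.asarray(conformer_b, dtype=float)
    if atom_subset is not None:
        idx = np.asarray(atom_subset, dtype=int)
        a = a[idx]
        b = b[idx]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("conformers must share an (n, 3) shape over the subset")
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if n < 3 or min(np.linalg.matrix_rank(ac, tol=1e-10), np.linalg.matrix_rank(bc, tol=1e-10)) < 2:
        raise ValueError(
            "Kabsch superposition needs at least 3 non-collinear atoms in the subset"
        )
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    # proper-rotation correction: reflect the smallest singular direction
    d = np.array([1.0, 1.0, sign])
    rot = vt.T @ np.diag(d) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff**2).sum() / n))


@dataclass
class ClusterResult:
    """Outcome of leader clustering.

    ``labels[k]`` is the cluster index of conformer ``k`` (original ensemble
    order); ``representatives[c]`` is the conformer index representing
    cluster ``c`` — its lowest-energy member, by construction of the
    energy-ordered visit sequence.
    """

    labels: np.ndarray
    representatives: list[int]
    rmsd_cutoff: float
    representative_ids: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def cluster_ensemble(
    ensemble: Ensemble,
    rmsd_cutoff: float = 1.0,
    atom_subset: Optional[Sequence[int]] = None,
) -> ClusterResult:
    """Deterministic leader clustering on Kabsch RMSD.

    Conformers are visited in ascending energy order (ties and missing
    energies fall back to conformer index); each joins the first existing
    cluster whose representative lies within ``rmsd_cutoff``, otherwise it
    founds a new cluster and becomes its representative. Representatives are
    therefore local energy minima and pairwise separated by more than the
    cutoff. ``atom_subset`` defaults to the heavy atoms.
    """
    if rmsd_cutoff < 0:
        raise ValueError("RMSD cutoff must be non-negative")
    if atom_subset is None:
        atom_subset = ensemble.topology.heavy_atom_indices()
    energies = ensemble.energies
    n = ensemble.n_conformers
    if energies is None:
        order = list(range(n))
    else:
        order = sorted(range(n), key=lambda k: (energies[k], k))
    coords = ensemble.coordinates
    labels = np.full(n, -1, dtype=int)
    representatives: list[int] = []
    for k in order:
        assigned = False
        for c, rep in enumerate(representatives):
            if kabsch_rmsd(coords[k], coords[rep], atom_subset) <= rmsd_cutoff:
                labels[k] = c
                assigned = True
                break
        if not assigned:
            labels[k] = len(representatives)
            representatives.append(k)
    rep_ids = [ensemble.conformers[r].conformer_id for r in representatives]
    return ClusterResult(
        labels=labels,
        representatives=representatives,
        rmsd_cutoff=rmsd_cutoff,
        representative_ids=rep_ids,
    )


def boltzmann_populations(energies: Sequence[float], temperature: float = 300.0) -> np.ndarray:
    """Boltzmann weights pᵢ ∝ exp(−Eᵢ/RT) normalized over the ensemble.

    Energies in kcal/mol, R = 1.987204e-3 kcal mol⁻¹ K⁻¹. The minimum energy
    is subtracted before exponentiation for numerical stability, which leaves
    the populations unchanged (offset invariance).
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("cannot compute populations of an empty energy list")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (GAS_CONSTANT_KCAL * temperature)
    shifted = e - e.min()
    w = np.exp(-beta * shifted)
    return w / w.sum()


def low_energy_subset(
    populations: Sequence[float], threshold: float = 0.01
) -> np.ndarray:
    """Indices of conformers with population strictly above ``threshold``.

    The default 1% cut matches the convention of reporting only clusters
    with a population of >1%. An empty result is allowed (and logged).
    """
    p = np.asarray(populations, dtype=float)
    idx = np.nonzero(p > threshold)[0]
    if idx.size == 0:
        logger.warning(
            "low_energy_subset: no conformer exceeds the %.3g population threshold",
            threshold,
        )
    return idx


def cluster_populations(cluster_result: ClusterResult, populations: Sequence[float]) -> np.ndarray:
    """Summed member population per cluster."""
    p = np.asarray(populations, dtype=float)
    out = np.zeros(cluster_result.n_clusters)
    for c in range(cluster_result.n_clusters):
        out[c] = p[cluster_result.members(c)].sum()
    return out


def identify_mec(
    cluster_result: ClusterResult,
    populations: Sequence[float],
    energies: Optional[Sequence[float]] = None,
) -> int:
    """Conformer index of the minimum-energy conformation.

    The MEC is the representative of the most-populated cluster — the
    cluster-level object marked by the largest circle on a property
    landscape. Population ties break toward the representative with lower
    energy, then toward the lower conformer index.
    """
    if cluster_result.n_clusters == 0:
        raise ValueError("empty clustering")
    cpop = cluster_populations(cluster_result, populations)
    reps = cluster_result.representatives
    if energies is not None:
        e = np.asarray(energies, dtype=float)
        keys = [(-cpop[c], e[reps[c]], reps[c]) for c in range(len(reps))]
    else:
        keys = [(-cpop[c], 0.0, reps[c]) for c in range(len(reps))]
    best = min(range(len(reps)), key=lambda c: keys[c])
    return reps[best]


@dataclass
class LandscapeGrid:
    """Normalized 2D property-space density over (x, y) bins."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("landscape density must be non-negative")
        total = self.density.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"landscape density sums to {total!r}, expected 1")


def property_landscape(
    property_table: pd.DataFrame,
    x: str = "r_gyr",
    y: str = "sa3d_psa",
    bins: int | tuple[int, int] = 40,
    weights: Optional[Sequence[float]] = None,
    range_: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
) -> LandscapeGrid:
    """Weighted 2D histogram of a property table, normalized to unit mass.

    Bins follow the usual right-open convention with the last bin closed.
    Weights default to the table's ``population`` column when present and
    finite, else to uniform.
    """
    if isinstance(bins, int):
        if bins < 1:
            raise ValueError("bins must be >= 1")
    else:
        if min(bins) < 1:
            raise ValueError("bins must be >= 1")
    xs = np.asarray(property_table[x], dtype=float)
    ys = np.asarray(property_table[y], dtype=float)
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ValueError("landscape properties must be finite")
    if weights is None:
        if "population" in property_table.columns and np.isfinite(
            property_table["population"].to_numpy(dtype=float)
        ).all():
            weights = property_table["population"].to_numpy(dtype=float)
        else:
            weights = np.ones_like(xs)
    w = np.asarray(weights, dtype=float)
    if w.shape != xs.shape:
        raise ValueError("weights length must match table length")
    hist, x_edges, y_edges = np.histogram2d(xs, ys, bins=bins, range=range_, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("landscape has zero total weight")
    return LandscapeGrid(x_edges=x_edges, y_edges=y_edges, density=hist / total)


def landscape_overlap(a: LandscapeGrid, b: LandscapeGrid) -> float:
    """Overlap coefficient Σ min(density_a, density_b) on a common grid.

    1 for identical densities, 0 for disjoint support; symmetric. Raises when
    the two grids were not built on identical bin edges — rebuild both
    landscapes on a shared binning first.
    """
    if a.density.shape != b.density.shape or not (
        np.allclose(a.x_edges, b.x_edges) and np.allclose(a.y_edges, b.y_edges)
    ):
        raise ValueError(
            "landscape grids have different bin edges; recompute both on a "
            "common binning (shared range and bin count) before comparing"
        )
    return float(np.minimum(a.density, b.density).sum())


@dataclass(frozen=True)
class CongruenceConfig:
    """Thresholds for the congruence verdict.

    An ensemble pair is congruent when the population-weighted R_gyr
    centroid shift does not exceed ``max_delta_r_gyr`` (Å) and the landscape
    overlap is at least ``min_overlap``. Defaults are calibrated on the
    synthetic degrader mimics so that the PEG-linker mimic is judged
    congruent and the alkyl-linker mimic is not; they are qualitative knobs,
    not universal constants. The bin count is deliberately coarse so the
    overlap statistic is stable for ensembles of a few hundred conformers.
    """

    bins: int = 12
    max_delta_r_gyr: float = 1.0
    min_overlap: float = 0.25


@dataclass
class SolventComparison:
    """Cross-solvent ensemble comparison summary.

    Deltas are apolar minus polar, so a positive ``delta_r_gyr`` means the
    molecule is more extended in the apolar environment (the chameleonic
    signature of solvent-exposed lipophilic linkers).
    """

    delta_r_gyr: float
    delta_sa3d_psa: float
    overlap: float
    congruent: bool
    config: CongruenceConfig = field(default_factory=CongruenceConfig)

    def to_dict(self) -> dict:
        return {
            "delta_r_gyr": self.delta_r_gyr,
            "delta_sa3d_psa": self.delta_sa3d_psa,
            "overlap": self.overlap,
            "congruent": self.congruent,
            "thresholds": {
                "max_delta_r_gyr": self.config.max_delta_r_gyr,
                "min_overlap": self.config.min_overlap,
                "bins": self.config.bins,
            },
        }


def _weighted_centroid(table: pd.DataFrame, column: str) -> float:
    v = table[column].to_numpy(dtype=float)
    if "population" in table.columns:
        w = table["population"].to_numpy(dtype=float)
        if np.isfinite(w).all() and w.sum() > 0:
            return float((v * w).sum() / w.sum())
    return float(v.mean())


def compare_solvent_ensembles(
    props_polar: pd.DataFrame,
    props_apolar: pd.DataFrame,
    config: CongruenceConfig = CongruenceConfig(),
) -> SolventComparison:
    """Compare the property ensembles of one molecule in two solvents.

    Both tables need ``r_gyr`` and ``sa3d_psa`` columns (``population``
    optional). Landscapes are rebuilt on the pooled min–max range of both
    ensembles so the overlap is well defined; centroid shifts are
    population-weighted and reported as apolar minus polar.
    """
    if len(props_polar) == 0 or len(props_apolar) == 0:
        raise ValueError("both property tables must be non-empty")
    d_rg = _weighted_centroid(props_apolar, "r_gyr") - _weighted_centroid(props_polar, "r_gyr")
    d_psa = _weighted_centroid(props_apolar, "sa3d_psa") - _weighted_centroid(
        props_polar, "sa3d_psa"
    )
    pooled_x = np.concatenate(
        [props_polar["r_gyr"].to_numpy(float), props_apolar["r_gyr"].to_numpy(float)]
    )
    pooled_y = np.concatenate(
        [props_polar["sa3d_psa"].to_numpy(float), props_apolar["sa3d_psa"].to_numpy(float)]
    )
    span = ((pooled_x.min(), pooled_x.max()), (pooled_y.min(), pooled_y.max()))
    grid_p = property_landscape(props_polar, bins=config.bins, range_=span)
    grid_a = property_landscape(props_apolar, bins=config.bins, range_=span)
    ov = landscape_overlap(grid_p, grid_a)
    congruent = abs(d_rg) <= config.max_delta_r_gyr and ov >= config.min_overlap
    return SolventComparison(
        delta_r_gyr=d_rg,
        delta_sa3d_psa=d_psa,
        overlap=ov,
        congruent=congruent,
        config=config,
    )
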