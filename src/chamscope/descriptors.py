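"""Per-conformer 3D size/polarity descriptors.

The two descriptors at the heart of chameleonicity analysis are the radius
of gyration (R_gyr — molecular size/compactness) and the solvent-accessible
3D polar surface area (SA 3D PSA — polarity of a conformation). SASA is
computed with the Shrake–Rupley test-point algorithm on a deterministic
Fibonacci sphere lattice and partitioned into polar and nonpolar parts by a
configurable element-based scheme (default: N, O plus attached hydrogens).
The complementary nonpolar area (SA 3D NPSA) quantifies exposed hydrophobic
surface, the driver of hydrophobic collapse in water.

Fold classes (folded / semifolded / extended) discretize R_gyr; the default
thresholds suit degrader-sized molecules, where ensembles center near
5–7 Å when folded, ~8 Å when semifolded and ~11 Å when extended, and are
fully configurable since the bands scale with molecular size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Ensemble, MoleculeTopology

logger = logging.getLogger(__name__)

__all__ = [
    "PolarScheme",
    "FoldThresholds",
    "radius_of_gyration",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "classify_polar_atoms",
    "partition_sasa",
    "count_imhb",
    "fold_class",
    "etr",
    "conformer_properties",
]

FOLD_CLASSES = ("folded", "semifolded", "extended")
#: ordering used for monotonicity checks: more compact < more extended
FOLD_ORDER = {name: k for k, name in enumerate(FOLD_CLASSES)}


@dataclass(frozen=True)
class PolarScheme:
    """Element-based polarity assignment, a pure function of topology.

    Defaults classify N and O (plus hydrogens bonded to them) as polar.
    Sulfur is excluded by default — its polarity contribution is
    scheme-dependent across SASA tools — but can be switched on.
    """

    polar_elements: frozenset[str] = frozenset({"N", "O"})
    include_attached_hydrogens: bool = True
    include_sulfur: bool = False

    def to_dict(self) -> dict:
        return {
            "polar_elements": sorted(self.polar_elements),
            "include_attached_hydrogens": self.include_attached_hydrogens,
            "include_sulfur": self.include_sulfur,
        }


@dataclass(frozen=True)
class FoldThresholds:
    """R_gyr cut points separating fold classes (Å).

    A conformer with R_gyr ≤ ``folded_max`` is folded, with
    R_gyr ≥ ``extended_min`` extended, and semifolded in between. Boundary
    ties resolve toward the more compact class.
    """

    folded_max: float = 7.0
    extended_min: float = 9.5

    def __post_init__(self) -> None:
        if not self.folded_max < self.extended_min:
            raise ValueError(
                f"folded_max ({self.folded_max}) must be < extended_min ({self.extended_min})"
            )

    def to_dict(self) -> dict:
        return {"folded_max": self.folded_max, "extended_min": self.extended_min}


def radius_of_gyration(
    coordinates: np.ndarray,
    masses: Optional[np.ndarray] = None,
    mode: str = "mass_weighted",
    heavy_only: bool = False,
    elements: Optional[Sequence[str]] = None,
) -> float:
    """Radius of gyration sqrt(Σ wᵢ|rᵢ − r̄|² / Σ wᵢ) in Å.

    ``mode='mass_weighted'`` uses atomic masses as weights (requires
    ``masses``); ``mode='geometric'`` uses unit weights. ``heavy_only``
    drops hydrogens (requires ``elements``). Invariant under rigid
    rotations and translations.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must have shape (n_atoms, 3)")
    n = coords.shape[0]
    if n == 0:
        raise ValueError("radius of gyration of an empty atom set is undefined")
    if mode not in ("mass_weighted", "geometric"):
        raise ValueError(f"unknown mode {mode!r}")
    if heavy_only:
        if elements is None:
            raise ValueError("heavy_only requires element symbols")
        keep = np.array([e.upper() != "H" for e in elements])
        if not keep.any():
            raise ValueError("heavy_only selected but no heavy atoms present")
        coords = coords[keep]
        if masses is not None:
            masses = np.asarray(masses, dtype=float)[keep]
    if mode == "mass_weighted":
        if masses is None:
            raise ValueError("mass_weighted mode requires masses")
        w = np.asarray(masses, dtype=float)
        if heavy_only is False and w.shape[0] != coords.shape[0]:
            raise ValueError("masses length must match atom count")
        if np.any(w <= 0):
            raise ValueError("masses must be positive")
    else:
        w = np.ones(coords.shape[0])
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    centroid = (w[:, None] * coords).sum(axis=0) / total
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / total))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform lattice of ``n_points`` unit vectors.

    The golden-angle spiral construction; identical output for identical n.
    """
    if n_points < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n_points, dtype=float)
    # offset by 0.5 keeps points away from the poles
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden_angle = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden_angle * k
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def shrake_rupley_sasa(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²), Shrake–Rupley style.

    Each atom is expanded by the probe radius and covered with a
    deterministic Fibonacci lattice of test points; a point is accessible if
    it lies outside every other atom's expanded sphere. The per-atom area is
    4π(rᵢ+probe)² × (accessible points / total points). Coincident atoms of
    identical radius occlude each other completely and both report zero —
    they are counted, not deduplicated.
    """
    coords = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must have shape (n_atoms, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain NaN or infinite values")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii length must match atom count")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if n_sphere_points < 32:
        raise ValueError("need at least 32 sphere points for a meaningful quadrature")

    n = coords.shape[0]
    expanded = radii + probe_radius
    lattice = fibonacci_sphere(n_sphere_points)
    areas = np.zeros(n)
    # pairwise distances once, for neighbor pruning
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    for i in range(n):
        # only atoms whose expanded spheres can reach atom i's surface matter
        reach = dist[i] < (expanded[i] + expanded)
        reach[i] = False
        neighbors = np.nonzero(reach)[0]
        if neighbors.size == 0:
            areas[i] = 4.0 * np.pi * expanded[i] ** 2
            continue
        points = coords[i] + expanded[i] * lattice  # (P, 3)
        d2 = ((points[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=-1)
        buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
        frac = 1.0 - buried.mean()
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def classify_polar_atoms(
    topology: MoleculeTopology, scheme: PolarScheme = PolarScheme()
) -> np.ndarray:
    """Boolean polar mask over atoms according to ``scheme``.

    An atom is polar iff its element is in ``scheme.polar_elements``, or it
    is S with ``include_sulfur``, or it is an H bonded to a polar heavy atom
    when ``include_attached_hydrogens`` is set. With the attached-hydrogen
    rule active, every hydrogen must have a bond record.
    """
    n = topology.n_atoms
    polar_heavy = set(scheme.polar_elements)
    if scheme.include_sulfur:
        polar_heavy.add("S")
    mask = np.array([el in polar_heavy for el in topology.elements])
    if scheme.include_attached_hydrogens:
        adj = topology.bond_adjacency()
        for i, el in enumerate(topology.elements):
            if el != "H":
                continue
            if not adj[i]:
                raise ValueError(
                    f"hydrogen atom {i} has no bond record; cannot apply the "
                    "attached-hydrogen polarity rule"
                )
            if any(topology.elements[j] in polar_heavy for j in adj[i]):
                mask[i] = True
    return mask


def partition_sasa(
    per_atom_areas: np.ndarray, polar_mask: np.ndarray
) -> tuple[float, float]:
    """Split per-atom SASA into (SA 3D PSA, SA 3D NPSA).

    The polar area is the sum over polar atoms, the nonpolar area the sum
    over the rest; the two add up to the total exactly.
    """
    areas = np.asarray(per_atom_areas, dtype=float)
    mask = np.asarray(polar_mask, dtype=bool)
    if areas.shape != mask.shape:
        raise ValueError(
            f"mask length {mask.shape} does not match area length {areas.shape}"
        )
    psa = float(areas[mask].sum())
    npsa = float(areas[~mask].sum())
    return psa, npsa


def _bond_separation_within(topology: MoleculeTopology, src: int, limit: int) -> dict[int, int]:
    """Breadth-first bond counts from ``src`` up to ``limit`` bonds."""
    adj = topology.bond_adjacency()
    dist = {src: 0}
    frontier = [src]
    for depth in range(1, limit + 1):
        nxt = []
        for a in frontier:
            for b in adj[a]:
                if b not in dist:
                    dist[b] = depth
                    nxt.append(b)
        frontier = nxt
    return dist


def count_imhb(
    coordinates: np.ndarray,
    topology: MoleculeTopology,
    donor_acceptor_cutoff: float = 2.5,
    dha_angle_cutoff: float = 120.0,
    min_bond_separation: int = 3,
) -> int:
    """Count intramolecular hydrogen bonds by geometric criteria.

    Donors are hydrogens bonded to N or O; acceptors are N or O atoms other
    than the donor heavy atom. A D–H···A contact counts when the H···A
    distance is at most ``donor_acceptor_cutoff`` (Å) and the D–H···A angle
    at least ``dha_angle_cutoff`` (degrees). Pairs closer than
    ``min_bond_separation`` bonds are excluded, removing trivially adjacent
    contacts. Returns 0 with a warning when no hydrogens are present.
    """
    coords = np.asarray(coordinates, dtype=float)
    elements = topology.elements
    adj = topology.bond_adjacency()
    hydrogens = [i for i, e in enumerate(elements) if e == "H"]
    if not hydrogens:
        logger.warning("count_imhb: topology has no hydrogens; returning 0")
        return 0
    acceptors = [i for i, e in enumerate(elements) if e in ("N", "O")]
    count = 0
    for h in hydrogens:
        donors = [j for j in adj[h] if elements[j] in ("N", "O")]
        if not donors:
            continue
        donor = donors[0]
        sep = _bond_separation_within(topology, h, min_bond_separation - 1)
        for a in acceptors:
            if a == donor:
                continue
            if a in sep:  # fewer than min_bond_separation bonds away
                continue
            ha = np.linalg.norm(coords[a] - coords[h])
            if ha > donor_acceptor_cutoff:
                continue
            v1 = coords[donor] - coords[h]
            v2 = coords[a] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= dha_angle_cutoff:
                count += 1
    return count


def fold_class(r_gyr: float, thresholds: FoldThresholds = FoldThresholds()) -> str:
    """Discretize R_gyr into folded / semifolded / extended.

    Boundary values resolve toward the more compact class: R_gyr equal to
    ``folded_max`` is folded; equal to ``extended_min`` is extended (the
    extended boundary is inclusive so that the class map is exhaustive).
    """
    if r_gyr < 0:
        raise ValueError("R_gyr must be non-negative")
    if r_gyr <= thresholds.folded_max:
        return "folded"
    if r_gyr >= thresholds.extended_min:
        return "extended"
    return "semifolded"


def etr(epsa: float, tpsa: float) -> float:
    """EPSA/TPSA ratio — experimental over topological polar surface area.

    Both inputs are scalar 2D descriptors supplied externally (Å²); values
    below 1 indicate polarity shielding in the chromatographic (apolar)
    environment relative to the 2D expectation.
    """
    if tpsa <= 0:
        raise ValueError("TPSA must be positive")
    if epsa < 0:
        raise ValueError("EPSA must be non-negative")
    return epsa / tpsa


def conformer_properties(
    ensemble: Ensemble,
    scheme: PolarScheme = PolarScheme(),
    thresholds: FoldThresholds = FoldThresholds(),
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    r_gyr_mode: str = "mass_weighted",
    imhb: bool = True,
) -> pd.DataFrame:
    """Per-conformer property table for an ensemble.

    Columns: conformer_id, r_gyr, sasa_total, sa3d_psa, sa3d_npsa, imhb,
    fold_class, population (NaN when the ensemble carries none).
    """
    topo = ensemble.topology
    radii = topo.vdw_radii
    masses = topo.masses
    polar_mask = classify_polar_atoms(topo, scheme)
    has_h = any(e == "H" for e in topo.elements)
    rows = []
    for k, conf in enumerate(ensemble.conformers):
        rg = radius_of_gyration(conf.coordinates, masses, mode=r_gyr_mode)
        areas = shrake_rupley_sasa(conf.coordinates, radii, probe_radius, n_sphere_points)
        psa, npsa = partition_sasa(areas, polar_mask)
        n_hb = (
            count_imhb(conf.coordinates, topo) if (imhb and has_h and topo.bonds) else 0
        )
        rows.append(
            {
                "conformer_id": conf.conformer_id,
                "r_gyr": rg,
                "sasa_total": float(areas.sum()),
                "sa3d_psa": psa,
                "sa3d_npsa": npsa,
                "imhb": n_hb,
                "fold_class": fold_class(rg, thresholds),
                "population": (
                    float(ensemble.populations[k])
                    if ensemble.populations is not None
                    else np.nan
                ),
                "energy": conf.energy if conf.energy is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
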