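"""Synthetic degrader-mimic generator with known ground truth.

Real heterobifunctional degraders (PROTACs) consist of two rigid ligand
"warheads" joined by a flexible linker; the permeability-relevant contrast
studied here is between a fully nonpolar alkyl linker and a PEG-like linker
in which every third atom is an ether oxygen. This module builds toy
molecules with exactly that architecture and samples solvent-dependent
conformer ensembles from a deliberately physics-light pseudo-energy:

    E = E_clash + hydrophobic term + polar-exposure term

where the hydrophobic term rewards cross-region nonpolar contacts in a
polar solvent (driving hydrophobic collapse of the alkyl mimic in water)
and the polar-exposure term penalizes burying polar atoms in a polar
solvent (keeping the PEG mimic solvent-exposed, hence congruent across
solvents). No electrostatics or force field is attempted: the generator's
only job is to produce ensembles with the statistical structure that the
downstream analysis assumes — collapse vs extension for the alkyl mimic,
congruence for the PEG mimic — at a scale where tests run in seconds.

NOE datasets are generated from a chosen ground-truth population mixture by
r⁻⁶ ensemble averaging with Gaussian noise, discarding pairs beyond a
detectability ceiling, so population-deconvolution code can be validated
against a known answer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Conformer, Ensemble, MoleculeTopology, NOERestraint, Solvent

logger = logging.getLogger(__name__)

__all__ = [
    "MimicSpec",
    "SolventProfile",
    "WATER_PROFILE",
    "CHLOROFORM_PROFILE",
    "build_protac_mimic",
    "sample_conformers",
    "simulate_noes",
]


@dataclass(frozen=True)
class MimicSpec:
    """Blueprint of a degrader mimic.

    ``linker_type`` selects the alkyl (all-carbon) or PEG (every third atom
    oxygen) linker; ``n_linker_atoms`` its length; ``ligand_size`` the heavy
    atoms per rigid ligand body. ``seed`` controls the placement of polar
    atoms inside the ligand bodies, so an alkyl/PEG pair built with the same
    seed differs only in the linker-atom elements.
    """

    linker_type: str = "alkyl"
    n_linker_atoms: int = 12
    ligand_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linker_type not in ("alkyl", "peg"):
            raise ValueError(f"unknown linker type {self.linker_type!r}")
        if self.n_linker_atoms < 3:
            raise ValueError("linker needs at least 3 atoms")
        if self.ligand_size < 4:
            raise ValueError("ligand bodies need at least 4 heavy atoms")


@dataclass(frozen=True)
class SolventProfile:
    """Solvent term weights for the pseudo-energy (kcal/mol per unit score).

    A polar solvent carries a positive ``hydrophobic_weight`` (burial of
    nonpolar surface is rewarded — the hydrophobic effect) and a positive
    ``polar_exposure_weight`` (burying polar atoms costs energy). An apolar
    solvent inverts both signs: aliphatic surface is favorably solvated, so
    its burial costs energy and drives chain extension, while polar groups
    tolerate burial (e.g. via internal hydrogen bonds).
    """

    label: str
    dielectric: float
    hydrophobic_weight: float
    polar_exposure_weight: float

    def as_solvent(self) -> Solvent:
        return Solvent(self.label, self.dielectric)


#: Aqueous profile: strong hydrophobic effect, polar burial penalized.
WATER_PROFILE = SolventProfile(
    "water", dielectric=78.4, hydrophobic_weight=2.5, polar_exposure_weight=2.0
)
#: Chloroform (ε = 4.8, close to the ~3 of a membrane interior): a negative
#: hydrophobic weight encodes favorable solvation of aliphatic surface (so
#: burying nonpolar linker atoms costs energy and the chain extends), and a
#: negative polar weight lets polar atoms bury, as they do when internal
#: hydrogen bonds replace solvent contacts in apolar media.
CHLOROFORM_PROFILE = SolventProfile(
    "chloroform", dielectric=4.8, hydrophobic_weight=-1.0, polar_exposure_weight=-1.5
)

# geometry constants (Å / degrees): generic sp3-like values
_BOND = 1.54
_ANGLE = 112.0
_H_BOND = 1.09
_CONTACT_CUTOFF = 4.5
_CLASH_SIGMA = 3.0
_CLASH_K = 12.0


def _body_template(n_heavy: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Deterministic compact rigid-body geometry with a chain bond network.

    Atoms are grown one bond at a time along a fixed quasi-random direction
    sequence, rejecting placements that clash with earlier atoms; the result
    is a compact blob that depends only on ``n_heavy``. Atom 0 is the linker
    attachment point; the template is oriented so the body lies in the −x
    half space, leaving +x free for the linker.
    """
    rng = np.random.default_rng(20240917)  # fixed: template is part of the design
    coords = [np.zeros(3)]
    bonds: list[tuple[int, int]] = []
    for i in range(1, n_heavy):
        parent = max(0, i - 1 - (i % 3 == 0))  # occasional branching for compactness
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = coords[parent] + _BOND * direction
            d = np.linalg.norm(np.array(coords) - candidate, axis=1)
            d[parent] = np.inf
            if np.all(d > 2.2):
                break
        coords.append(candidate)
        bonds.append((parent, i))
    xyz = np.array(coords)
    # orient: centroid on the −x axis relative to the attachment atom
    centroid = xyz.mean(axis=0)
    axis = centroid - xyz[0]
    norm = np.linalg.norm(axis)
    if norm > 1e-9:
        target = np.array([-1.0, 0.0, 0.0])
        v = axis / norm
        rot = _rotation_between(v, target)
        xyz = (xyz - xyz[0]) @ rot.T
    return xyz, bonds


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180° flip about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def build_protac_mimic(spec: MimicSpec) -> MoleculeTopology:
    """Build the mimic topology: two rigid ligand bodies joined by a linker.

    Atom layout (contiguous blocks): ligand-A heavy atoms, ligand-A tagged
    hydrogens, linker atoms, ligand-B heavy atoms, ligand-B tagged
    hydrogens. Each body carries a few polar (O/N) heavy atoms at
    seed-dependent positions and ≥2 NOE-tagged protons; the linker is all
    carbon for ``alkyl`` and has an oxygen at every third position
    (3, 6, 9, …, 1-based) for ``peg``. An alkyl/PEG pair with identical
    seed and sizes differs only in those linker elements.
    """
    rng = np.random.default_rng(spec.seed)
    n_body = spec.ligand_size
    n_h = 3  # tagged protons per body

    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    region: list[str] = []
    proton_labels: dict[int, str] = {}

    def add_body(label: str, h_prefix: str) -> tuple[int, list[int]]:
        """Returns (attach_atom_index, tagged_h_indices)."""
        offset = len(elements)
        body_elements = ["C"] * n_body
        # two polar atoms per body, never at the attachment atom
        polar_pos = rng.choice(np.arange(1, n_body), size=min(2, n_body - 1), replace=False)
        for k, p in enumerate(sorted(polar_pos)):
            body_elements[p] = "O" if k % 2 == 0 else "N"
        _, body_bonds = _body_template(n_body)
        elements.extend(body_elements)
        region.extend([label] * n_body)
        bonds.extend((offset + i, offset + j) for i, j in body_bonds)
        # tagged protons on carbons spread across the body (never the attach atom)
        carbons = [i for i in range(1, n_body) if body_elements[i] == "C"]
        h_parents = [carbons[int(round(t))] for t in np.linspace(0, len(carbons) - 1, n_h)]
        h_idx = []
        for k, parent in enumerate(h_parents):
            hi = len(elements)
            elements.append("H")
            region.append(label)
            bonds.append((offset + parent, hi))
            proton_labels[hi] = f"{h_prefix}{k + 1}"
            h_idx.append(hi)
        return offset, h_idx

    attach_a, _ = add_body("ligand_a", "HA")

    linker_offset = len(elements)
    linker_heavy: list[int] = []
    for k in range(spec.n_linker_atoms):
        idx = len(elements)
        if spec.linker_type == "peg" and (k + 1) % 3 == 0:
            elements.append("O")
        else:
            elements.append("C")
        region.append("linker")
        linker_heavy.append(idx)
        if k == 0:
            bonds.append((attach_a, idx))
        else:
            bonds.append((linker_heavy[k - 1], idx))
    # tagged protons on the linker carbons: conformation-dependent NOE
    # reporters along the chain (these positions are carbon in both linker
    # types, so the alkyl/PEG pair stays element-matched there)
    n_hl = 0
    for k in range(spec.n_linker_atoms):
        if (k + 1) % 3 != 0:
            hi = len(elements)
            elements.append("H")
            region.append("linker")
            bonds.append((linker_heavy[k], hi))
            n_hl += 1
            proton_labels[hi] = f"HL{n_hl}"

    attach_b, _ = add_body("ligand_b", "HB")
    bonds.append((linker_heavy[-1], attach_b))

    return MoleculeTopology(
        elements=elements, bonds=bonds, proton_labels=proton_labels, region=region
    )


# --------------------------------------------------------------------------
# geometry assembly


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D after A-B-C."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    th = np.radians(theta)
    ph = np.radians(phi)
    d2 = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


class _MimicGeometry:
    """Rebuilds mimic coordinates from a dihedral vector.

    Derived purely from the topology's region/element layout, so any
    topology produced by :func:`build_protac_mimic` can be re-animated
    without carrying extra state. Degrees of freedom: one dihedral per
    linker atom, plus two placement dihedrals and one spin angle for the
    second ligand body.
    """

    def __init__(self, topology: MoleculeTopology):
        if topology.region is None:
            raise ValueError("topology lacks region labels; not a generator mimic")
        self.topology = topology
        reg = np.array(topology.region)
        heavy = np.array([e != "H" for e in topology.elements])
        self.idx_a = np.nonzero(reg == "ligand_a")[0]
        self.idx_linker = np.nonzero((reg == "linker") & heavy)[0]
        self.idx_linker_h = np.nonzero((reg == "linker") & ~heavy)[0]
        self.idx_b = np.nonzero(reg == "ligand_b")[0]
        if not (len(self.idx_a) and len(self.idx_linker) and len(self.idx_b)):
            raise ValueError("mimic topology must have ligand_a, linker and ligand_b regions")
        self.n_linker = len(self.idx_linker)
        adj = topology.bond_adjacency()
        self.attach_a = int(self.idx_a[0])
        self.attach_b = int(self.idx_b[0])
        self.linker_h_parent = {
            int(h): [p for p in adj[int(h)] if heavy[p]][0] for h in self.idx_linker_h
        }
        # rigid templates with hydrogens
        self.template_a = self._template_with_h(self.idx_a, adj)
        self.template_b = self._template_with_h(self.idx_b, adj)

    def _template_with_h(self, idx: np.ndarray, adj: dict[int, list[int]]) -> np.ndarray:
        heavy = [i for i in idx if self.topology.elements[i] != "H"]
        xyz_heavy, _ = _body_template(len(heavy))
        local = {atom: xyz_heavy[k] for k, atom in enumerate(heavy)}
        centroid = xyz_heavy.mean(axis=0)
        out = np.zeros((len(idx), 3))
        for k, atom in enumerate(idx):
            if self.topology.elements[atom] == "H":
                parent = [p for p in adj[atom] if p in local][0]
                away = local[parent] - centroid
                nrm = np.linalg.norm(away)
                away = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
                out[k] = local[parent] + _H_BOND * away
            else:
                out[k] = local[atom]
        return out

    @property
    def n_dihedrals(self) -> int:
        return self.n_linker + 3

    def coordinates(self, dihedrals: np.ndarray) -> np.ndarray:
        """Assemble full coordinates from the dihedral vector (degrees)."""
        if len(dihedrals) != self.n_dihedrals:
            raise ValueError(f"expected {self.n_dihedrals} dihedrals, got {len(dihedrals)}")
        n_atoms = self.topology.n_atoms
        coords = np.zeros((n_atoms, 3))
        # ligand A fixed at its template
        coords[self.idx_a] = self.template_a
        # frame seeds inside body A: attach atom plus two bonded predecessors
        a0 = self.template_a[0]
        a1 = self.template_a[1]
        a2 = self.template_a[min(2, len(self.idx_a) - 1)]
        prev3 = [a2, a1, a0]
        # linker chain (heavy atoms)
        for k in range(self.n_linker):
            pos = _nerf(prev3[-3], prev3[-2], prev3[-1], _BOND, _ANGLE, dihedrals[k])
            coords[self.idx_linker[k]] = pos
            prev3.append(pos)
        # ligand B anchor and orientation
        b0 = _nerf(prev3[-3], prev3[-2], prev3[-1], _BOND, _ANGLE, dihedrals[self.n_linker])
        b1 = _nerf(prev3[-2], prev3[-1], b0, _BOND, _ANGLE, dihedrals[self.n_linker + 1])
        spin = np.radians(dihedrals[self.n_linker + 2])
        t = self.template_b
        t0, t1 = t[0], t[1]
        v_t = t1 - t0
        v_t /= np.linalg.norm(v_t)
        v_b = b1 - b0
        v_b /= np.linalg.norm(v_b)
        rot = _rotation_between(v_t, v_b)
        # spin about the anchor axis
        ct, st = np.cos(spin), np.sin(spin)
        k_ax = v_b
        kx = np.array(
            [[0, -k_ax[2], k_ax[1]], [k_ax[2], 0, -k_ax[0]], [-k_ax[1], k_ax[0], 0]]
        )
        spin_rot = np.eye(3) * ct + st * kx + (1 - ct) * np.outer(k_ax, k_ax)
        coords[self.idx_b] = b0 + (t - t0) @ rot.T @ spin_rot.T
        # linker hydrogens: bisector offset from the parent, away from both
        # chain neighbors (deterministic, keeps H ~perpendicular to the chain)
        for h, parent in self.linker_h_parent.items():
            k = int(np.nonzero(self.idx_linker == parent)[0][0])
            before = coords[self.idx_linker[k - 1]] if k > 0 else coords[self.attach_a]
            after = (
                coords[self.idx_linker[k + 1]]
                if k + 1 < self.n_linker
                else coords[self.attach_b]
            )
            away = 2.0 * coords[parent] - before - after
            nrm = np.linalg.norm(away)
            if nrm < 1e-9:
                chain_dir = after - before
                away = np.cross(chain_dir, np.array([0.0, 0.0, 1.0]))
                nrm = np.linalg.norm(away)
                if nrm < 1e-9:
                    away = np.cross(chain_dir, np.array([0.0, 1.0, 0.0]))
                    nrm = np.linalg.norm(away)
            coords[h] = coords[parent] + _H_BOND * away / nrm
        return coords


class _EnergyModel:
    """Pseudo-energy: soft-sphere clash + solvent-dependent contact terms."""

    def __init__(self, topology: MoleculeTopology, solvent: SolventProfile):
        self.solvent = solvent
        elements = topology.elements
        reg = np.array(topology.region)
        heavy = np.array([e != "H" for e in elements])
        self.heavy_idx = np.nonzero(heavy)[0]
        self.region_code = np.array(
            [{"ligand_a": 0, "linker": 1, "ligand_b": 2}[r] for r in reg]
        )[self.heavy_idx]
        polar = np.array([e in ("N", "O") for e in elements])[self.heavy_idx]
        n = len(self.heavy_idx)
        iu, ju = np.triu_indices(n, k=1)
        cross = self.region_code[iu] != self.region_code[ju]
        self.pair_i = iu[cross]
        self.pair_j = ju[cross]
        # solvent terms score linker solvation/burial: only cross-region
        # contacts involving a linker atom enter the burial counts (the
        # ligand-ligand attraction is a common mode for both linker types
        # and carries no chameleonicity signal)
        linker_pair = (self.region_code[self.pair_i] == 1) | (
            self.region_code[self.pair_j] == 1
        )
        self.pair_nonpolar = (
            linker_pair & ~polar[self.pair_i] & ~polar[self.pair_j]
        )
        self.pair_polar = linker_pair & (polar[self.pair_i] | polar[self.pair_j])
        # normalization: contacts per heavy linker atom keeps weights
        # size-independent
        self.norm = float(((reg == "linker") & heavy).sum())

    def __call__(self, coords: np.ndarray) -> float:
        xyz = coords[self.heavy_idx]
        d = np.linalg.norm(xyz[self.pair_i] - xyz[self.pair_j], axis=1)
        clash = np.clip(_CLASH_SIGMA - d, 0.0, None)
        e_clash = _CLASH_K * float((clash**2).sum())
        contact = d < _CONTACT_CUTOFF
        burial_nonpolar = float((contact & self.pair_nonpolar).sum()) / self.norm
        burial_polar = float((contact & self.pair_polar).sum()) / self.norm
        return (
            e_clash
        # hydrophobic effect rewards nonpolar burial; polar burial is penalized
            - self.solvent.hydrophobic_weight * burial_nonpolar
            + self.solvent.polar_exposure_weight * burial_polar
        )


def sample_conformers(
    topology: MoleculeTopology,
    n: int,
    solvent: SolventProfile = WATER_PROFILE,
    seed: int = 0,
    temperature: float = 300.0,
    burn_in: int = 600,
    thinning: int = 15,
    step_deg: float = 55.0,
) -> Ensemble:
    """Metropolis sampling of linker dihedrals under the pseudo-energy.

    Starts from the all-trans (extended) chain, performs ``burn_in``
    single-dihedral Metropolis moves, then records a conformer every
    ``thinning`` accepted-or-rejected moves until ``n`` conformers are
    collected. Per-conformer pseudo-energies (kcal/mol) are stored, so the
    ensemble supports Boltzmann population analysis downstream.
    Deterministic for fixed (topology, solvent, seed).
    """
    if n < 1:
        raise ValueError("need at least one conformer")
    geom = _MimicGeometry(topology)
    energy = _EnergyModel(topology, solvent)
    rng = np.random.default_rng(seed)
    kt = 1.987204e-3 * temperature

    dihedrals = np.full(geom.n_dihedrals, 180.0)
    dihedrals[-1] = 0.0  # spin angle
    coords = geom.coordinates(dihedrals)
    e = energy(coords)

    conformers: list[Conformer] = []
    max_moves = burn_in + thinning * n + 10_000
    move = 0
    while len(conformers) < n and move < max_moves:
        move += 1
        k = rng.integers(geom.n_dihedrals)
        proposal = dihedrals.copy()
        if rng.random() < 0.3:
            proposal[k] = rng.uniform(-180.0, 180.0)
        else:
            proposal[k] = ((proposal[k] + rng.normal(0.0, step_deg) + 180.0) % 360.0) - 180.0
        new_coords = geom.coordinates(proposal)
        e_new = energy(new_coords)
        if e_new <= e or rng.random() < np.exp(-(e_new - e) / kt):
            dihedrals, coords, e = proposal, new_coords, e_new
        if move > burn_in and (move - burn_in) % thinning == 0:
            conformers.append(
                Conformer(coords.copy(), energy=e, conformer_id=str(len(conformers)))
            )
    if len(conformers) < n:
        raise RuntimeError(
            f"sampling exhausted the move budget ({max_moves} moves) with only "
            f"{len(conformers)}/{n} conformers recorded"
        )
    return Ensemble(topology=topology, conformers=conformers, solvent=solvent.as_solvent())


def simulate_noes(
    ensemble: Ensemble,
    true_populations: Sequence[float],
    n_restraints: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    observability_ceiling: float = 5.0,
    exponent: float = 6.0,
    tolerance_fraction: float = 0.10,
) -> tuple[list[NOERestraint], dict]:
    """Generate NOE restraints from a known population mixture.

    For every pair of tagged protons the population-averaged r⁻ᵉ distance is
    computed over the ensemble; pairs averaging beyond the observability
    ceiling (default 5 Å, the typical NOE detection limit) are discarded.
    Up to ``n_restraints`` observable pairs are drawn (covering intra- and
    inter-ligand pairs when available), Gaussian noise of ``noise_sd`` Å is
    added, and the ground truth (populations, exact averages, pair choices)
    is returned alongside for validation.
    """
    topo = ensemble.topology
    tags = sorted(topo.proton_labels.items())  # (atom, label)
    if len(tags) < 2:
        raise ValueError("ensemble topology has no tagged NOE protons")
    p = np.asarray(true_populations, dtype=float)
    if p.shape != (ensemble.n_conformers,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("true_populations must be a simplex vector over the ensemble")
    rng = np.random.default_rng(seed)
    coords = ensemble.coordinates
    region = topo.region or ["?"] * topo.n_atoms

    candidates = []
    for a in range(len(tags)):
        for b in range(a + 1, len(tags)):
            ia, la = tags[a]
            ib, lb = tags[b]
            d = np.linalg.norm(coords[:, ia, :] - coords[:, ib, :], axis=1)
            d_avg = float((p * d ** (-exponent)).sum() ** (-1.0 / exponent))
            if d_avg > observability_ceiling:
                continue
            if region[ia] == region[ib]:
                rc = "short" if d_avg < 3.5 else "medium"
            elif {region[ia], region[ib]} == {"ligand_a", "ligand_b"}:
                rc = "long"
            else:
                rc = "medium"
            candidates.append((la, lb, d_avg, rc))
    if not candidates:
        warnings.warn("no proton pair is NOE-observable for this mixture", stacklevel=2)
        return [], {"true_populations": p.tolist(), "pairs": [], "seed": seed}
    if len(candidates) < n_restraints:
        warnings.warn(
            f"only {len(candidates)} observable pairs (requested {n_restraints})",
            stacklevel=2,
        )
        chosen = list(range(len(candidates)))
    else:
        # deterministic stratified draw: long-range pairs first, then the rest
        order = rng.permutation(len(candidates))
        long_first = sorted(order, key=lambda i: candidates[i][3] != "long")
        chosen = sorted(long_first[:n_restraints])
    restraints = []
    truth_pairs = []
    for i in chosen:
        la, lb, d_avg, rc = candidates[i]
        d_exp = d_avg + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        d_exp = max(d_exp, 0.8)  # distances below van der Waals contact are unphysical
        restraints.append(
            NOERestraint(
                proton_i=la,
                proton_j=lb,
                d_exp=d_exp,
                tolerance=max(tolerance_fraction * d_exp, noise_sd),
                range_class=rc,
            )
        )
        truth_pairs.append({"pair": [la, lb], "d_avg": d_avg, "range_class": rc})
    truth = {
        "true_populations": p.tolist(),
        "pairs": truth_pairs,
        "noise_sd": noise_sd,
        "seed": seed,
        "observability_ceiling": observability_ceiling,
        "exponent": exponent,
    }
    return restraints, truth
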