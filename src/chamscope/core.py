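"""Shared domain objects for conformational-ensemble analysis.

The central containers are :class:`MoleculeTopology` (atoms, bonds,
NOE-active proton tags — shared by every conformer of a molecule),
:class:`Ensemble` (topology plus N coordinate sets with optional
per-conformer energies, solvent metadata and populations) and
:class:`NOERestraint` (an interproton distance restraint with tolerance).

Units are fixed package-wide: coordinates and distances in Å, energies in
kcal/mol, masses in Da. No unit autodetection is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BONDI_RADII",
    "ATOMIC_MASSES",
    "GAS_CONSTANT_KCAL",
    "MoleculeTopology",
    "Conformer",
    "Solvent",
    "Ensemble",
    "NOERestraint",
    "vdw_radius",
    "atomic_mass",
]

#: Gas constant in kcal mol^-1 K^-1, used for Boltzmann weighting.
GAS_CONSTANT_KCAL = 1.987204e-3

#: Bondi (1964) van der Waals radii in Å. Elements outside this table raise;
#: there is no silent default radius.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "Te": 2.06,
    "I": 1.98,
    "Xe": 2.16,
}

#: Standard atomic weights (Da) for the elements the package handles.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "As": 74.922,
    "Se": 78.971,
    "Br": 79.904,
    "Kr": 83.798,
    "Te": 127.60,
    "I": 126.90,
    "Xe": 131.29,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol has no tabulated radius or mass."""


def _normalize_symbol(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        raise UnknownElementError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius (Å) for ``element``.

    Raises :class:`UnknownElementError` for symbols outside the Bondi table —
    no silent default is substituted.
    """
    sym = _normalize_symbol(element)
    try:
        return BONDI_RADII[sym]
    except KeyError:
        raise UnknownElementError(
            f"no Bondi van der Waals radius tabulated for element {sym!r}"
        ) from None


def atomic_mass(element: str) -> float:
    """Standard atomic weight (Da) for ``element``."""
    sym = _normalize_symbol(element)
    try:
        return ATOMIC_MASSES[sym]
    except KeyError:
        raise UnknownElementError(
            f"no atomic mass tabulated for element {sym!r}"
        ) from None


@dataclass
class MoleculeTopology:
    """Atoms, bonds and proton tags shared by all conformers of a molecule.

    Parameters
    ----------
    elements
        Element symbol per atom; atom indices run contiguously from 0.
    bonds
        Unordered pairs of atom indices.
    proton_labels
        Optional text tags keyed by atom index, marking NOE-active hydrogens
        (e.g. ``{12: "HA1"}``).
    is_polar
        Optional boolean mask assigned by a polarity scheme; ``None`` until
        classified.
    region
        Optional per-atom structural region label (e.g. ``ligand_a``,
        ``linker``, ``ligand_b``) used by the synthetic generator and by
        NOE range classification.
    """

    elements: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    proton_labels: dict[int, str] = field(default_factory=dict)
    is_polar: Optional[np.ndarray] = None
    region: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.elements = [_normalize_symbol(e) for e in self.elements]
        n = len(self.elements)
        if n == 0:
            raise ValueError("topology must contain at least one atom")
        seen = set()
        norm_bonds: list[tuple[int, int]] = []
        for i, j in self.bonds:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a nonexistent atom")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                norm_bonds.append(key)
        self.bonds = norm_bonds
        for idx in self.proton_labels:
            if not (0 <= idx < n):
                raise ValueError(f"proton label on nonexistent atom {idx}")
            if self.elements[idx] != "H":
                raise ValueError(f"proton label on non-hydrogen atom {idx}")
        if self.region is not None and len(self.region) != n:
            raise ValueError("region labels must cover every atom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(e) for e in self.elements])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.elements])

    def neighbors(self, atom: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == atom:
                out.append(j)
            elif j == atom:
                out.append(i)
        return sorted(out)

    def bond_adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)


@dataclass
class Conformer:
    """One coordinate set of a molecule, with an optional pseudo/force-field
    energy in kcal/mol."""

    coordinates: np.ndarray  # (n_atoms, 3) Å
    energy: Optional[float] = None
    conformer_id: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates in conformer {self.conformer_id!r}")
        if self.energy is not None:
            self.energy = float(self.energy)


@dataclass(frozen=True)
class Solvent:
    """Solvent metadata attached to an ensemble.

    ``dielectric`` records the relative permittivity ε; chloroform (ε = 4.8)
    is the conventional surrogate for the membrane interior (ε ≈ 3.0), while
    water (ε ≈ 78.4) represents the aqueous compartment.
    """

    label: str = "unspecified"
    dielectric: Optional[float] = None


#: Common solvents for convenience; dielectric constants at ~25 °C.
WATER = Solvent("water", 78.4)
CHLOROFORM = Solvent("chloroform", 4.8)
MEMBRANE_INTERIOR = Solvent("membrane_interior", 3.0)


@dataclass
class Ensemble:
    """A multi-conformer ensemble: topology + coordinate sets (+ metadata).

    Invariants: every conformer has the topology's atom count; populations,
    when present, are non-negative and sum to 1 within 1e-9.
    """

    topology: MoleculeTopology
    conformers: list[Conformer]
    solvent: Solvent = field(default_factory=Solvent)
    populations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.conformers) == 0:
            raise ValueError("ensemble must contain at least one conformer")
        n = self.topology.n_atoms
        for k, conf in enumerate(self.conformers):
            if conf.coordinates.shape[0] != n:
                raise ValueError(
                    f"conformer {conf.conformer_id or k} has "
                    f"{conf.coordinates.shape[0]} atoms, topology has {n}"
                )
            if not conf.conformer_id:
                conf.conformer_id = str(k)
        if self.populations is not None:
            p = np.asarray(self.populations, dtype=float)
            if p.shape != (len(self.conformers),):
                raise ValueError("populations length must match conformer count")
            if np.any(p < 0):
                raise ValueError("populations must be non-negative")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"populations sum to {p.sum()!r}, expected 1")
            self.populations = p

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_conformers, n_atoms, 3)."""
        return np.stack([c.coordinates for c in self.conformers])

    @property
    def energies(self) -> Optional[np.ndarray]:
        """Per-conformer energies, or ``None`` if any conformer lacks one."""
        vals = [c.energy for c in self.conformers]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    @property
    def conformer_ids(self) -> list[str]:
        return [c.conformer_id for c in self.conformers]

    def with_populations(self, populations: Sequence[float]) -> "Ensemble":
        return Ensemble(
            topology=self.topology,
            conformers=self.conformers,
            solvent=self.solvent,
            populations=np.asarray(populations, dtype=float),
        )

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        idx = list(indices)
        if not idx:
            raise ValueError("cannot take an empty conformer subset")
        pops = None
        if self.populations is not None:
            p = self.populations[idx]
            pops = p / p.sum()
        return Ensemble(
            topology=self.topology,
            conformers=[self.conformers[i] for i in idx],
            solvent=self.solvent,
            populations=pops,
        )


@dataclass(frozen=True)
class NOERestraint:
    """An interproton NOE distance restraint.

    ``proton_i``/``proton_j`` are atom indices or group labels resolvable via
    the topology's proton tags; ``d_exp`` is the restraint distance (Å) and
    ``tolerance`` its uncertainty band (Å). ``range_class`` follows the NMR
    convention short / medium / long (long-range NOEs connect the two ligand
    ends of a degrader-like molecule).
    """

    proton_i: str
    proton_j: str
    d_exp: float
    tolerance: float
    range_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.d_exp <= 0:
            raise ValueError(f"restraint distance must be positive, got {self.d_exp}")
        if self.tolerance < 0:
            raise ValueError("restraint tolerance must be non-negative")
        if str(self.proton_i) == str(self.proton_j):
            raise ValueError("restraint endpoints must differ")
        if self.range_class is not None and self.range_class not in (
            "short",
            "medium",
            "long",
        ):
            raise ValueError(f"unknown range class {self.range_class!r}")


def replace_conformers(ensemble: Ensemble, conformers: list[Conformer]) -> Ensemble:
    """New ensemble sharing topology and solvent but with other conformers."""
    return Ensemble(topology=ensemble.topology, conformers=conformers, solvent=ensemble.solvent)
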