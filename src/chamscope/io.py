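"""Readers and writers for multi-conformer structures and restraint tables.

Three structure dialects are supported, chosen to cover the formats in which
conformer ensembles are commonly deposited:

* ``pdb_multimodel`` — MODEL/ENDMDL blocks with ATOM/HETATM records and the
  element column; occupancy and altloc fields are ignored (a warning is
  logged once per file). Bonds are carried in CONECT records.
* ``sdf`` — V2000 multi-record SDF, one record per conformer of the same
  molecule; per-conformer energies in a ``energy`` data field (kcal/mol).
  Parsing and writing go through RDKit.
* ``xyz`` — multi-frame XYZ; a ``energy=<value>`` token on the comment line
  carries the conformer energy.

NOE restraint tables are comma- or tab-separated text with a header row
(``atom_i, atom_j, distance, tolerance[, range_class]``). When the tolerance
column is absent a default of 10% of the restraint distance is applied,
reflecting typical NOE calibration uncertainty.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Conformer,
    Ensemble,
    MoleculeTopology,
    NOERestraint,
    Solvent,
    vdw_radius,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleFormatError",
    "read_ensemble",
    "write_ensemble",
    "read_noe_table",
    "write_noe_table",
    "write_property_table",
    "read_property_table",
]

FORMATS = ("pdb_multimodel", "sdf", "xyz")

_EXTENSION_FORMATS = {
    ".pdb": "pdb_multimodel",
    ".ent": "pdb_multimodel",
    ".sdf": "sdf",
    ".sd": "sdf",
    ".mol": "sdf",
    ".xyz": "xyz",
}


class EnsembleFormatError(ValueError):
    """A structure file violates the expected dialect."""


def _infer_format(path: Path) -> str:
    fmt = _EXTENSION_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise EnsembleFormatError(
            f"cannot infer structure format from extension {path.suffix!r}; "
            f"pass format explicitly (one of {FORMATS})"
        )
    return fmt


def read_ensemble(
    path: str | Path,
    format: Optional[str] = None,
    solvent: Optional[Solvent] = None,
) -> Ensemble:
    """Read a multi-conformer ensemble from ``path``.

    Parameters
    ----------
    path
        Structure file. Must exist and contain at least one conformer.
    format
        One of ``pdb_multimodel``, ``sdf``, ``xyz``; inferred from the file
        extension when omitted.
    solvent
        Optional solvent metadata to attach (formats do not carry it).

    Raises
    ------
    EnsembleFormatError
        Empty file, mismatched atom counts across models/frames (the error
        names the offending model), or an element outside the Bondi table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise EnsembleFormatError(f"unknown structure format {fmt!r}; expected one of {FORMATS}")
    if fmt == "pdb_multimodel":
        ens = _read_pdb(path)
    elif fmt == "sdf":
        ens = _read_sdf(path)
    else:
        ens = _read_xyz(path)
    # Validate every element against the Bondi table up front: unknown
    # elements must fail loudly at read time, not deep inside a SASA call.
    for el in set(ens.topology.elements):
        vdw_radius(el)
    if solvent is not None:
        ens.solvent = solvent
    return ens


def write_ensemble(ensemble: Ensemble, path: str | Path, format: Optional[str] = None) -> None:
    """Write ``ensemble`` to ``path`` in the named dialect.

    The output is re-readable by :func:`read_ensemble`; coordinates round-trip
    to the format's fixed-point precision (1e-3 Å) and SDF energies to 1e-6
    kcal/mol.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise EnsembleFormatError(f"unknown structure format {fmt!r}; expected one of {FORMATS}")
    if ensemble.n_conformers == 0:  # unreachable via the constructor; guards raw objects
        raise ValueError("refusing to write an empty ensemble")
    if fmt == "pdb_multimodel":
        _write_pdb(ensemble, path)
    elif fmt == "sdf":
        _write_sdf(ensemble, path)
    else:
        _write_xyz(ensemble, path)


# --------------------------------------------------------------------------
# PDB (multi-model)

_PDB_ATOM_RE = re.compile(r"^(ATOM|HETATM)")


def _read_pdb(path: Path) -> Ensemble:
    models: list[list[tuple[str, float, float, float]]] = []
    current: Optional[list] = None
    bonds: set[tuple[int, int]] = set()
    in_model_blocks = False
    warned_occupancy = False
    model_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model_blocks = True
                current = []
                name = line[6:].strip() or str(len(models) + 1)
                model_names.append(name)
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if in_model_blocks:
                        raise EnsembleFormatError(
                            f"{path}: ATOM record outside MODEL/ENDMDL block"
                        )
                    current = []
                    model_names.append("1")
                element = line[76:78].strip()
                if not element:
                    # fall back on the atom-name column
                    element = re.sub(r"[^A-Za-z]", "", line[12:16].strip())[:1]
                if not element:
                    raise EnsembleFormatError(
                        f"{path}: missing element symbol in record: {line.rstrip()!r}"
                    )
                altloc = line[16:17].strip()
                if altloc and not warned_occupancy:
                    logger.warning("%s: altloc/occupancy fields present; ignored", path)
                    warned_occupancy = True
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise EnsembleFormatError(
                        f"{path}: malformed coordinates in record: {line.rstrip()!r}"
                    ) from exc
                current.append((element, x, y, z))
            elif rec == "CONECT":
                fields = line.split()[1:]
                if len(fields) >= 2:
                    base = int(fields[0]) - 1
                    for other in fields[1:]:
                        j = int(other) - 1
                        if base != j:
                            bonds.add((min(base, j), max(base, j)))
    if current is not None:  # single implicit model without ENDMDL
        models.append(current)
    if not models or all(len(m) == 0 for m in models):
        raise EnsembleFormatError(f"{path}: no atoms found (empty file?)")
    models = [m for m in models if m]
    n0 = len(models[0])
    for k, m in enumerate(models):
        if len(m) != n0:
            raise EnsembleFormatError(
                f"{path}: model {model_names[k] if k < len(model_names) else k + 1} "
                f"has {len(m)} atoms but model {model_names[0]} has {n0}"
            )
    elements = [a[0] for a in models[0]]
    topo = MoleculeTopology(elements=elements, bonds=sorted(bonds))
    conformers = [
        Conformer(np.array([[a[1], a[2], a[3]] for a in m]), conformer_id=str(k))
        for k, m in enumerate(models)
    ]
    return Ensemble(topology=topo, conformers=conformers)


def _write_pdb(ensemble: Ensemble, path: Path) -> None:
    topo = ensemble.topology
    lines: list[str] = []
    for k, conf in enumerate(ensemble.conformers):
        lines.append(f"MODEL     {k + 1:4d}")
        for i, el in enumerate(topo.elements):
            x, y, z = conf.coordinates[i]
            name = f"{el}{i + 1}"[:4]
            lines.append(
                f"HETATM{i + 1:5d} {name:<4s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
            )
        lines.append("ENDMDL")
    for i, j in topo.bonds:
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# SDF (V2000, via RDKit)


def _topology_to_rdkit(topology: MoleculeTopology):
    from rdkit import Chem

    mol = Chem.RWMol()
    for el in topology.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j in topology.bonds:
        mol.AddBond(i, j, Chem.BondType.SINGLE)
    return mol


def _write_sdf(ensemble: Ensemble, path: Path) -> None:
    from rdkit import Chem
    from rdkit.Chem import SDWriter
    from rdkit.Geometry import Point3D

    mol = _topology_to_rdkit(ensemble.topology)
    writer = SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for conf in ensemble.conformers:
            m = Chem.RWMol(mol)
            c = Chem.Conformer(m.GetNumAtoms())
            for i, (x, y, z) in enumerate(conf.coordinates):
                c.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            m.AddConformer(c, assignId=True)
            m.SetProp("_Name", conf.conformer_id)
            if conf.energy is not None:
                m.SetProp("energy", f"{conf.energy:.6f}")
            writer.write(m)
    finally:
        writer.close()


def _read_sdf(path: Path) -> Ensemble:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    conformers: list[Conformer] = []
    topo: Optional[MoleculeTopology] = None
    for k, mol in enumerate(supplier):
        if mol is None:
            raise EnsembleFormatError(f"{path}: record {k + 1} failed to parse as SDF")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        if topo is None:
            topo = MoleculeTopology(elements=elements, bonds=bonds)
        else:
            if len(elements) != topo.n_atoms:
                raise EnsembleFormatError(
                    f"{path}: record {k + 1} has {len(elements)} atoms, "
                    f"record 1 has {topo.n_atoms}"
                )
            if elements != topo.elements:
                raise EnsembleFormatError(
                    f"{path}: record {k + 1} atom ordering differs from record 1"
                )
        coords = mol.GetConformer().GetPositions()
        energy = None
        if mol.HasProp("energy"):
            energy = float(mol.GetProp("energy"))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else str(k)
        conformers.append(Conformer(np.asarray(coords), energy=energy, conformer_id=name or str(k)))
    if topo is None or not conformers:
        raise EnsembleFormatError(f"{path}: no SDF records found (empty file?)")
    return Ensemble(topology=topo, conformers=conformers)


# --------------------------------------------------------------------------
# XYZ (multi-frame)

_ENERGY_TOKEN = re.compile(r"energy\s*=\s*([-+0-9.eE]+)")


def _read_xyz(path: Path) -> Ensemble:
    text = path.read_text().splitlines()
    frames: list[tuple[list[str], np.ndarray, Optional[float]]] = []
    pos = 0
    frame_no = 0
    while pos < len(text):
        if not text[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            n = int(text[pos].strip())
        except ValueError as exc:
            raise EnsembleFormatError(
                f"{path}: frame {frame_no}: expected atom count, got {text[pos]!r}"
            ) from exc
        if pos + 1 + n >= len(text) + 1 and pos + 2 + n > len(text) + 1:
            raise EnsembleFormatError(f"{path}: frame {frame_no} truncated")
        comment = text[pos + 1] if pos + 1 < len(text) else ""
        m = _ENERGY_TOKEN.search(comment)
        energy = float(m.group(1)) if m else None
        elements: list[str] = []
        coords = np.zeros((n, 3))
        for a in range(n):
            row = pos + 2 + a
            if row >= len(text):
                raise EnsembleFormatError(f"{path}: frame {frame_no} truncated")
            parts = text[row].split()
            if len(parts) < 4:
                raise EnsembleFormatError(
                    f"{path}: frame {frame_no}, atom line {a + 1} malformed: {text[row]!r}"
                )
            elements.append(parts[0])
            coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append((elements, coords, energy))
        pos += 2 + n
    if not frames:
        raise EnsembleFormatError(f"{path}: no frames found (empty file?)")
    el0 = frames[0][0]
    for k, (els, _, _) in enumerate(frames):
        if len(els) != len(el0):
            raise EnsembleFormatError(
                f"{path}: frame {k + 1} has {len(els)} atoms but frame 1 has {len(el0)}"
            )
        if els != el0:
            raise EnsembleFormatError(f"{path}: frame {k + 1} atom ordering differs from frame 1")
    topo = MoleculeTopology(elements=el0)
    conformers = [
        Conformer(coords, energy=energy, conformer_id=str(k))
        for k, (_, coords, energy) in enumerate(frames)
    ]
    return Ensemble(topology=topo, conformers=conformers)


def _write_xyz(ensemble: Ensemble, path: Path) -> None:
    lines: list[str] = []
    for conf in ensemble.conformers:
        lines.append(str(ensemble.topology.n_atoms))
        comment = f"conformer {conf.conformer_id}"
        if conf.energy is not None:
            comment += f" energy={conf.energy:.6f}"
        lines.append(comment)
        for el, (x, y, z) in zip(ensemble.topology.elements, conf.coordinates):
            lines.append(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# NOE restraint tables


def read_noe_table(
    path: str | Path,
    default_tolerance_fraction: float = 0.10,
    range_class_map: Optional[dict[str, str]] = None,
) -> list[NOERestraint]:
    """Parse an NOE restraint table.

    The file is comma- or tab-delimited with a header row containing at least
    ``atom_i``, ``atom_j`` and ``distance`` columns. A ``tolerance`` column is
    optional (default: ``default_tolerance_fraction`` × distance), as is
    ``range_class``. When ``range_class`` is absent and ``range_class_map``
    (proton label → structural region) is supplied, pairs bridging the two
    ligand regions are classified ``long``, pairs within one region
    ``short`` and all others ``medium``.

    Raises ``ValueError`` citing the offending row for non-positive
    distances. A duplicate unordered proton pair triggers a warning but is
    kept — repeated NOEs are legitimate in merged datasets.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NOE table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#", skip_blank_lines=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"atom_i", "atom_j", "distance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    restraints: list[NOERestraint] = []
    seen_pairs: set[frozenset[str]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = row._asdict()
        d = float(rec["distance"])
        if d <= 0:
            raise ValueError(f"{path}: row {row_no}: non-positive distance {d}")
        pi, pj = str(rec["atom_i"]).strip(), str(rec["atom_j"]).strip()
        tol = rec.get("tolerance")
        if tol is None or (isinstance(tol, float) and np.isnan(tol)):
            tol = default_tolerance_fraction * d
        rc = rec.get("range_class")
        if rc is not None and (not isinstance(rc, str) or not rc.strip()):
            rc = None
        if isinstance(rc, float) and np.isnan(rc):
            rc = None
        if rc is None and range_class_map is not None:
            rc = _infer_range_class(pi, pj, range_class_map)
        pair = frozenset((pi, pj))
        if pair in seen_pairs:
            warnings.warn(
                f"{path}: row {row_no}: duplicate proton pair ({pi}, {pj}); kept",
                stacklevel=2,
            )
        seen_pairs.add(pair)
        restraints.append(
            NOERestraint(
                proton_i=pi,
                proton_j=pj,
                d_exp=d,
                tolerance=float(tol),
                range_class=rc if isinstance(rc, str) else None,
            )
        )
    return restraints


def _infer_range_class(pi: str, pj: str, region_map: dict[str, str]) -> Optional[str]:
    ri, rj = region_map.get(pi), region_map.get(pj)
    if ri is None or rj is None:
        return None
    if ri == rj:
        return "short"
    if {ri, rj} == {"ligand_a", "ligand_b"}:
        return "long"
    return "medium"


def write_noe_table(restraints: Sequence[NOERestraint], path: str | Path, sep: str = "\t") -> None:
    """Serialize restraints as delimited text re-readable by
    :func:`read_noe_table`."""
    rows = [
        {
            "atom_i": r.proton_i,
            "atom_j": r.proton_j,
            "distance": round(r.d_exp, 6),
            "tolerance": round(r.tolerance, 6),
            "range_class": r.range_class or "",
        }
        for r in restraints
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Property tables (per-conformer descriptor output)

PROPERTY_COLUMNS = [
    "conformer_id",
    "r_gyr",
    "sasa_total",
    "sa3d_psa",
    "sa3d_npsa",
    "imhb",
    "fold_class",
    "population",
]


def write_property_table(
    table: pd.DataFrame,
    path: str | Path,
    metadata: Optional[dict] = None,
    sep: str = "\t",
) -> None:
    """Write a per-conformer property table plus an optional JSON sidecar
    echoing the descriptor scheme and thresholds used."""
    table.to_csv(path, sep=sep, index=False)
    if metadata is not None:
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def read_property_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
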