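"""Molecular structures, tabular inputs and active-site selection.

The shared data model is deliberately small: an :class:`Atom` carries an
element symbol, Cartesian coordinates in Angstrom and an optional partial
charge; a :class:`Molecule` is an ordered atom list plus a bond list.
Residues extracted from a PDB complex are themselves molecules (role
``"residue"``), collected in a :class:`ResidueSet`.

Energies (complex / ligand / residue systems) and the auxiliary activity,
orbital-energy and atomic-population tables are plain CSV/JSON files read
into pandas frames or :class:`EnergyTable` objects; no quantum-chemistry
engine is invoked here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "Atom",
    "Molecule",
    "ResidueSet",
    "EnergyTable",
    "ParseError",
    "perceive_bonds",
    "read_structure",
    "write_xyz",
    "select_active_site",
    "read_energy_table",
    "read_activity_table",
    "read_orbital_table",
    "read_population_table",
]

_PT = Chem.GetPeriodicTable()


class ParseError(ValueError):
    """Malformed structure or table input."""


def atomic_number(element: str) -> int:
    """Atomic number for an element symbol; raises for unknown symbols."""
    try:
        z = _PT.GetAtomicNumber(element.capitalize())
    except Exception as exc:  # RDKit raises RuntimeError on bad symbols
        raise ParseError(f"unknown element symbol: {element!r}") from exc
    if z <= 0:
        raise ParseError(f"unknown element symbol: {element!r}")
    return z


def covalent_radius(element: str) -> float:
    """Covalent radius in Angstrom (RDKit tabulation)."""
    return float(_PT.GetRcovalent(atomic_number(element)))


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Angstrom (RDKit tabulation)."""
    return float(_PT.GetRvdw(atomic_number(element)))


@dataclass
class Atom:
    element: str
    coords: np.ndarray
    partial_charge: float | None = None
    atom_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        atomic_number(self.element)  # validate symbol

    @property
    def atomic_number(self) -> int:
        return atomic_number(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.atomic_number == 1


@dataclass
class Molecule:
    """An ordered list of atoms with explicit bonds.

    ``role`` tags how the molecule enters the pipeline: ``ligand``,
    ``residue`` or ``complex`` member.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    role: str = "ligand"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.name!r} has no atoms")
        ids = {a.atom_id for a in self.atoms}
        if len(ids) != len(self.atoms):
            # assign sequential ids when the input did not provide unique ones
            for i, a in enumerate(self.atoms):
                a.atom_id = i
            ids = set(range(len(self.atoms)))
        norm = []
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i} in {self.name!r}")
            if i not in ids or j not in ids:
                raise ValueError(f"bond ({i},{j}) references missing atom in {self.name!r}")
            norm.append((min(i, j), max(i, j)))
        self.bonds = sorted(set(norm))

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array(
            [0.0 if a.partial_charge is None else a.partial_charge for a in self.atoms]
        )

    def atom_by_id(self, atom_id: int) -> Atom:
        for a in self.atoms:
            if a.atom_id == atom_id:
                return a
        raise KeyError(atom_id)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a rigidly moved copy; the original is never mutated."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_atoms = [
            Atom(a.element, R @ a.coords + t, a.partial_charge, a.atom_id)
            for a in self.atoms
        ]
        return Molecule(self.name, new_atoms, list(self.bonds), self.role)

    def total_electrons(self) -> int:
        return sum(a.atomic_number for a in self.atoms)


@dataclass
class ResidueSet:
    """Named residues (whole Molecules) extracted from one structure."""

    residues: list[Molecule]
    source: str = ""

    def __post_init__(self) -> None:
        names = [r.name for r in self.residues]
        if len(set(names)) != len(names):
            raise ValueError("residue names must be unique within a set")

    def __len__(self) -> int:
        return len(self.residues)

    def names(self) -> list[str]:
        return [r.name for r in self.residues]

    def __getitem__(self, name: str) -> Molecule:
        for r in self.residues:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass
class EnergyTable:
    """One energy per system id, with a uniform unit (default kcal/mol)."""

    energies: dict[str, float]
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        self.energies = {str(k): float(v) for k, v in self.energies.items()}

    def __len__(self) -> int:
        return len(self.energies)

    def __contains__(self, system_id: str) -> bool:
        return system_id in self.energies

    def __getitem__(self, system_id: str) -> float:
        try:
            return self.energies[system_id]
        except KeyError:
            raise KeyError(f"no energy for system {system_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"system_id": list(self.energies), "energy": list(self.energies.values())}
        )


# ---------------------------------------------------------------------------
# structure readers / writers
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected atom count") from None
    records = [ln for ln in lines[2 : 2 + n]]
    if len(records) < n:
        raise ParseError(
            f"{path}: header declares {n} atoms but only {len(records)} records follow"
        )
    atoms = []
    for k, ln in enumerate(records):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {k + 3}: expected 'element x y z'")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}, line {k + 3}: non-numeric coordinate") from None
        atoms.append(Atom(parts[0], np.array(xyz), atom_id=k))
    name = lines[1].strip() or path.stem
    return Molecule(name, atoms)


def write_xyz(mol: Molecule, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    lines = [str(len(mol)), comment if comment is not None else mol.name]
    for a in mol.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
    path.write_text("\n".join(lines) + "\n")


def _read_sdf(path: Path) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols: list[Molecule] = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"{path}: molecule record {idx + 1} failed to parse")
        conf = rdmol.GetConformer()
        atoms = []
        for a in rdmol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(Atom(a.GetSymbol(), np.array([p.x, p.y, p.z]), atom_id=a.GetIdx()))
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()]
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"{path.stem}_{idx}"
        mols.append(Molecule(name or f"{path.stem}_{idx}", atoms, bonds))
    if not mols:
        raise ParseError(f"{path}: no molecules in SDF")
    return mols


def _read_pdb(path: Path, ligand_resnames: set[str] | None = None):
    """Parse a PDB into (ResidueSet, ligand Molecule | None).

    HETATM records (excluding waters) form the ligand unless explicit ligand
    residue names are given.  altLoc 'A' (or blank) is kept; insertion codes
    are honoured as part of the residue key.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    residues: list[Molecule] = []
    ligand_atoms: list[Atom] = []
    aid = 0
    for model in structure:
        for chain in model:
            for res in chain:
                hetflag, resseq, icode = res.id
                resname = res.get_resname().strip()
                atoms = []
                for at in res:
                    if at.get_altloc() not in (" ", "A"):
                        continue
                    el = at.element.strip().capitalize() or at.get_name()[0]
                    atoms.append(Atom(el, np.array(at.get_coord(), float), atom_id=aid))
                    aid += 1
                if not atoms:
                    continue
                is_ligand = (
                    resname in ligand_resnames
                    if ligand_resnames
                    else (hetflag.startswith("H") and resname != "HOH")
                )
                if is_ligand:
                    ligand_atoms.extend(atoms)
                elif resname != "HOH":
                    label = f"{resname}{resseq}{icode.strip()}"
                    if chain.id.strip():
                        label = f"{label}_{chain.id}" if any(
                            r.name == label for r in residues
                        ) else label
                    residues.append(Molecule(label, atoms, role="residue"))
        break  # first model only
    rset = ResidueSet(residues, source=path.name)
    ligand = Molecule(path.stem + "_ligand", ligand_atoms, role="ligand") if ligand_atoms else None
    return rset, ligand


def read_structure(path: str | Path, fmt: str | None = None, **kwargs):
    """Read a structure file.

    Returns a :class:`Molecule` for XYZ, a list of molecules for SDF and a
    ``(ResidueSet, ligand)`` pair for PDB.  Atom order is preserved and
    coordinates are Angstrom throughout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "pdb":
        return _read_pdb(path, **kwargs)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def perceive_bonds(mol: Molecule, scale: float = 1.25) -> Molecule:
    """Distance-based bond perception for formats without a bond block.

    Two atoms are bonded when their separation is below ``scale`` times the
    sum of their covalent radii (0.4 A floor guards tiny radii).  Returns a
    new molecule; the input is untouched.
    """
    coords = mol.coords
    radii = np.array([covalent_radius(a.element) for a in mol.atoms])
    ids = [a.atom_id for a in mol.atoms]
    bonds = []
    for i in range(len(mol)):
        for j in range(i + 1, len(mol)):
            cutoff = max(scale * (radii[i] + radii[j]), 0.4)
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.append((ids[i], ids[j]))
    return Molecule(
        mol.name,
        [Atom(a.element, a.coords.copy(), a.partial_charge, a.atom_id) for a in mol.atoms],
        bonds,
        mol.role,
    )


# ---------------------------------------------------------------------------
# active-site selection
# ---------------------------------------------------------------------------

def select_active_site(
    residues: ResidueSet | Iterable[Molecule],
    ligand: Molecule,
    radius: float = 5.0,
) -> ResidueSet:
    """Residues with at least one atom within ``radius`` of any ligand atom.

    Whole residues are returned, never fragments (any-atom criterion on a
    sphere of the given radius centred on the ligand atoms).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(ligand) == 0:
        raise ValueError("ligand has no atoms")
    pool = residues.residues if isinstance(residues, ResidueSet) else list(residues)
    lig = ligand.coords
    selected = []
    for res in pool:
        d = np.linalg.norm(res.coords[:, None, :] - lig[None, :, :], axis=-1)
        if d.min() <= radius:
            selected.append(res)
    src = residues.source if isinstance(residues, ResidueSet) else ""
    return ResidueSet(selected, source=src)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def _normalise_decimal(v):
    # pasted literature values sometimes use decimal commas
    if isinstance(v, str):
        return v.replace(",", ".")
    return v


def read_energy_table(path: str | Path, unit: str = "kcal/mol") -> EnergyTable:
    """Read (system_id, energy) rows from CSV or a JSON list/dict."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            rows = [{"system_id": k, "energy": v} for k, v in data.items()]
        else:
            rows = data
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    for col in ("system_id", "energy"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    energies = pd.to_numeric(df["energy"].map(_normalise_decimal), errors="coerce")
    if energies.isna().any():
        bad = df.loc[energies.isna(), "system_id"].iloc[0]
        raise ParseError(f"{path}: non-numeric energy for system {bad!r}")
    ids = df["system_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate system_id {dup!r}")
    return EnergyTable(dict(zip(ids, energies.astype(float))), unit=unit)


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Activity table with columns (name, pIC50)."""
    df = pd.read_csv(path)
    for col in ("name", "pIC50"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["pIC50"] = pd.to_numeric(df["pIC50"].map(_normalise_decimal))
    return df


def read_orbital_table(path: str | Path) -> pd.DataFrame:
    """Frontier-orbital energies: columns (name, E_HOMO, E_LUMO), eV."""
    df = pd.read_csv(path)
    for col in ("name", "E_HOMO", "E_LUMO"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for col in ("E_HOMO", "E_LUMO"):
        df[col] = pd.to_numeric(df[col].map(_normalise_decimal))
    return df


def read_population_table(path: str | Path) -> pd.DataFrame:
    """Atomic electron populations for N−1, N, N+1 electron states."""
    df = pd.read_csv(path)
    for col in ("name", "atom_id", "q_Nminus1", "q_N", "q_Nplus1"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for col in ("q_Nminus1", "q_N", "q_Nplus1"):
        df[col] = pd.to_numeric(df[col].map(_normalise_decimal))
    return df
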