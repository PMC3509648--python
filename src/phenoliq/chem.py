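"""Molecular data model, structure I/O, and graph machinery.

The descriptor layer works on a deliberately small molecular representation:
an ordered list of atoms with 3D positions, a bond list, and the hydrogen-
suppressed graph derived from them.  Structure parsing and writing is
delegated to RDKit; molecules read from SMILES carry no coordinates and are
flagged so that 3D descriptors refuse to run until the structure has been
embedded.

Atomic property tables (mass, van der Waals volume, Sanderson
electronegativity, polarizability) ship as a plain-text data file and are
exposed as carbon-scaled weight schemes: every weight is divided by the
carbon value, so weight(C) = 1 for each property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Atom",
    "Molecule",
    "WeightScheme",
    "TopologicalDistanceMatrix",
    "SCHEME_CODES",
    "get_weight_scheme",
    "atomic_property_table",
    "read_structures",
    "write_sdf",
    "molecule_from_smiles",
    "molecule_from_rdkit",
    "embed_3d",
    "heavy_atom_graph",
    "weight_vector",
]

#: scheme code -> column of the property table (``u`` is unweighted)
SCHEME_CODES = {
    "u": None,
    "m": "mass",
    "v": "vdw_volume",
    "e": "sanderson_en",
    "p": "polarizability",
}


class UnsupportedElementError(ValueError):
    """Element outside the shipped property table."""


@dataclass(frozen=True)
class Atom:
    """A single atom: chemical symbol plus Cartesian position in Angstrom."""

    element: str
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.element not in atomic_property_table().index:
            raise UnsupportedElementError(
                f"element {self.element!r} is not in the atomic property table"
            )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.element}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Molecule:
    """Ordered atoms, bonds (index pairs with order), and a name.

    ``has_3d`` records whether the coordinates are meaningful; SMILES input
    produces ``has_3d=False`` and 3D descriptors reject such molecules until
    :func:`embed_3d` has been applied.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    name: str = ""
    has_3d: bool = True

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i}, {j}) has invalid atom indices")
        if not self.heavy_indices:
            raise ValueError(f"molecule {self.name!r} has no heavy atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions; error if not embedded."""
        self.require_3d()
        return np.array([a.position for a in self.atoms], dtype=float)

    def require_3d(self) -> None:
        if not self.has_3d:
            raise ValueError(
                f"molecule {self.name!r} has no 3D coordinates; "
                "embed it (embed_3d) before computing 3D descriptors"
            )


@dataclass(frozen=True)
class WeightScheme:
    """Per-element atomic weights scaled so that carbon equals 1."""

    code: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.code != "u":
            if abs(self.values.get("C", 0.0) - 1.0) > 1e-12:
                raise ValueError("carbon weight must be exactly 1")
            if any(v <= 0 for v in self.values.values()):
                raise ValueError("weights must be positive")

    def weight(self, element: str) -> float:
        if self.code == "u":
            return 1.0
        try:
            return self.values[element]
        except KeyError:
            raise UnsupportedElementError(
                f"element {element!r} missing from scheme {self.code!r}"
            ) from None


@dataclass(frozen=True)
class TopologicalDistanceMatrix:
    """Integer shortest-path distances between heavy atoms (unit bond length)."""

    entries: np.ndarray
    heavy_atom_count: int

    def __post_init__(self) -> None:
        d = self.entries
        if d.shape != (self.heavy_atom_count, self.heavy_atom_count):
            raise ValueError("distance matrix shape mismatch")
        if not np.array_equal(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


_PROPERTY_TABLE: pd.DataFrame | None = None


def atomic_property_table() -> pd.DataFrame:
    """Raw (unscaled) atomic property table indexed by element symbol."""
    global _PROPERTY_TABLE
    if _PROPERTY_TABLE is None:
        with resources.files("phenoliq.data").joinpath("atomic_properties.tsv").open() as fh:
            _PROPERTY_TABLE = pd.read_csv(fh, sep="\t", comment="#", index_col="element")
    return _PROPERTY_TABLE


def get_weight_scheme(code: str) -> WeightScheme:
    """Carbon-scaled weight scheme for ``code`` in {u, m, v, e, p}."""
    if code not in SCHEME_CODES:
        raise ValueError(f"unknown weight scheme {code!r}; choose from {sorted(SCHEME_CODES)}")
    if code == "u":
        return WeightScheme(code="u")
    column = SCHEME_CODES[code]
    table = atomic_property_table()[column]
    scaled = (table / table["C"]).to_dict()
    scaled["C"] = 1.0
    return WeightScheme(code=code, values=scaled)


# ---------------------------------------------------------------------------
# structure I/O (RDKit-backed)
# ---------------------------------------------------------------------------

def _rdkit():
    from rdkit import Chem  # local import keeps module import cheap

    return Chem


def molecule_from_rdkit(rdmol, name: str = "", has_3d: bool = True) -> Molecule:
    """Convert an RDKit Mol (with explicit hydrogens) to a :class:`Molecule`."""
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    atoms = []
    for atom in rdmol.GetAtoms():
        if conf is not None:
            p = conf.GetAtomPosition(atom.GetIdx())
            pos = (p.x, p.y, p.z)
        else:
            pos = (0.0, 0.0, 0.0)
        atoms.append(Atom(element=atom.GetSymbol(), position=pos))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    label = name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "")
    return Molecule(atoms=atoms, bonds=bonds, name=label, has_3d=has_3d and conf is not None)


def molecule_from_smiles(smiles: str, name: str = "") -> Molecule:
    """Parse SMILES; explicit hydrogens are added, no coordinates (``has_3d=False``)."""
    Chem = _rdkit()
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    return molecule_from_rdkit(rdmol, name=name, has_3d=False)


def embed_3d(mol: Molecule, seed: int = 2012) -> Molecule:
    """Generate 3D coordinates (ETKDG + force-field cleanup) for a molecule.

    Coordinates elsewhere in the package are taken as given; this helper is
    the single place where a geometry is created for structures that arrive
    without one (SMILES input).
    """
    Chem = _rdkit()
    from rdkit.Chem import AllChem

    rdmol = _to_rdkit(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {mol.name!r}")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol)
    except Exception:  # pragma: no cover - cleanup is best-effort
        pass
    return molecule_from_rdkit(rdmol, name=mol.name, has_3d=True)


def _to_rdkit(mol: Molecule):
    Chem = _rdkit()
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for atom in mol.atoms:
        rw.AddAtom(Chem.Atom(atom.element))
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    rdmol = rw.GetMol()
    if mol.has_3d:
        conf = Chem.Conformer(mol.n_atoms)
        for idx, atom in enumerate(mol.atoms):
            conf.SetAtomPosition(idx, Point3D(*atom.position))
        rdmol.AddConformer(conf)
    rdmol.SetProp("_Name", mol.name)
    try:
        Chem.SanitizeMol(rdmol)
    except Exception:
        Chem.SanitizeMol(
            rdmol,
            Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    return rdmol


def read_structures(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF/MOL V2000 file or a SMILES file.

    SDF/MOL input keeps the file's coordinates and adds explicit hydrogens if
    absent; SMILES input yields molecules flagged as not yet embedded.
    Malformed records raise with the record index.
    """
    Chem = _rdkit()
    path = Path(path)
    if format is None:
        format = {".sdf": "sdf", ".mol": "mol", ".smi": "smiles", ".smiles": "smiles"}.get(
            path.suffix.lower(), "sdf"
        )
    if not path.exists():
        raise FileNotFoundError(path)

    mols: list[Molecule] = []
    if format == "smiles":
        for idx, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            try:
                mols.append(molecule_from_smiles(parts[0], name=parts[1] if len(parts) > 1 else ""))
            except ValueError as exc:
                raise ValueError(f"record {idx}: {exc}") from exc
        return mols

    if format == "mol":
        rdmol = Chem.MolFromMolFile(str(path), removeHs=False)
        if rdmol is None:
            raise ValueError(f"record 0: malformed MOL file {path}")
        return [_finalize_read(rdmol)]

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"record {idx}: malformed SDF record in {path}")
        mols.append(_finalize_read(rdmol))
    if not mols:
        raise ValueError(f"no records found in {path}")
    return mols


def _finalize_read(rdmol) -> Molecule:
    Chem = _rdkit()
    if any(a.GetTotalNumHs() > 0 for a in rdmol.GetAtoms()):
        rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
    if any(a.GetFormalCharge() != 0 for a in rdmol.GetAtoms()):
        warnings.warn("formal charges present; descriptors treat atoms as neutral")
    return molecule_from_rdkit(rdmol)


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules to an SDF (V2000) file, preserving coordinates."""
    Chem = _rdkit()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in mols:
        writer.write(_to_rdkit(mol))
    writer.close()


# ---------------------------------------------------------------------------
# hydrogen-suppressed graph
# ---------------------------------------------------------------------------

def heavy_atom_graph(mol: Molecule) -> tuple[TopologicalDistanceMatrix, np.ndarray]:
    """Topological distance matrix and vertex degrees of the heavy-atom graph.

    Bond orders are ignored: every heavy-heavy bond contributes a unit edge.
    Raises if the hydrogen-suppressed graph is disconnected (graph
    descriptors are undefined there).
    """
    heavy = mol.heavy_indices
    index = {orig: k for k, orig in enumerate(heavy)}
    a = len(heavy)
    adj = np.zeros((a, a), dtype=int)
    for i, j, _ in mol.bonds:
        if i in index and j in index:
            adj[index[i], index[j]] = 1
            adj[index[j], index[i]] = 1
    dist = shortest_path(csr_matrix(adj), method="BF", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise ValueError(f"heavy-atom graph of {mol.name!r} is disconnected")
    degrees = adj.sum(axis=1)
    return TopologicalDistanceMatrix(entries=dist.astype(int), heavy_atom_count=a), degrees


def weight_vector(
    mol: Molecule, scheme: WeightScheme | str, include_h: bool = True
) -> np.ndarray:
    """Carbon-scaled atomic weights in atom order; hydrogens optional."""
    if isinstance(scheme, str):
        scheme = get_weight_scheme(scheme)
    atoms: Sequence[Atom] = (
        mol.atoms if include_h else [mol.atoms[i] for i in mol.heavy_indices]
    )
    return np.array([scheme.weight(a.element) for a in atoms], dtype=float)
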