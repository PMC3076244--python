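"""Molecule input/output on top of RDKit.

Molecules are held in a small immutable-ish graph model (heavy atoms only;
hydrogen counts are stored as atom attributes). Parsing, sanitization,
aromaticity perception and 2D coordinate generation are delegated to RDKit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: bond order vocabulary used throughout the package
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RD_TO_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_TO_RD = {v: k for k, v in _RD_TO_ORDER.items()}


class ChemIOError(Exception):
    """Base class for molecule I/O failures."""


class SmilesParseError(ChemIOError):
    pass


class EmptyInputError(ChemIOError):
    pass


@dataclass(frozen=True)
class Atom:
    """A heavy atom with the attributes that feed the atom invariant."""

    element: str
    formal_charge: int
    explicit_h_count: int
    aromatic: bool
    in_ring: bool
    degree: int


@dataclass(frozen=True)
class Bond:
    index: int
    atoms: tuple[int, int]
    order: str

    def other(self, atom_index: int) -> int:
        a, b = self.atoms
        return b if atom_index == a else a


@dataclass
class Molecule:
    """Annotated heavy-atom chemical graph with stable 0-based indices."""

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    coords2d: Optional[list[tuple[float, float]]] = None
    _adjacency: Optional[list[list[Bond]]] = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def incident_bonds(self, atom_index: int) -> list[Bond]:
        if self._adjacency is None:
            adj: list[list[Bond]] = [[] for _ in self.atoms]
            for bond in self.bonds:
                a, b = bond.atoms
                adj[a].append(bond)
                adj[b].append(bond)
            self._adjacency = adj
        return self._adjacency[atom_index]

    def neighbors(self, atom_index: int) -> list[int]:
        return [b.other(atom_index) for b in self.incident_bonds(atom_index)]

    def validate(self) -> None:
        seen_pairs = set()
        for i, bond in enumerate(self.bonds):
            a, b = bond.atoms
            if bond.index != i:
                raise ValueError(f"bond index {bond.index} != position {i}")
            if a == b:
                raise ValueError(f"bond {i} is a self-loop")
            if not (0 <= a < self.n_atoms and 0 <= b < self.n_atoms):
                raise ValueError(f"bond {i} references missing atoms {a},{b}")
            pair = frozenset((a, b))
            if pair in seen_pairs:
                raise ValueError(f"duplicate bond between atoms {a},{b}")
            seen_pairs.add(pair)
            if bond.order == "aromatic":
                if not (self.atoms[a].aromatic and self.atoms[b].aromatic):
                    raise ValueError(f"aromatic bond {i} joins non-aromatic atom")
        for idx, atom in enumerate(self.atoms):
            if atom.degree != len(self.incident_bonds(idx)):
                raise ValueError(f"atom {idx} degree mismatch")


def from_rdkit(rdmol: Chem.Mol, name: str = "") -> Molecule:
    """Convert a sanitized RDKit molecule into the internal graph model."""
    atoms = []
    for a in rdmol.GetAtoms():
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                explicit_h_count=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                in_ring=a.IsInRing(),
                degree=a.GetDegree(),
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        order = _RD_TO_ORDER.get(b.GetBondType())
        if order is None:
            raise ChemIOError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(
            Bond(
                index=b.GetIdx(),
                atoms=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                order=order,
            )
        )
    coords = None
    if rdmol.GetNumConformers() > 0:
        conf = rdmol.GetConformer()
        coords = [
            (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
            for i in range(rdmol.GetNumAtoms())
        ]
    if not name and rdmol.HasProp("_Name"):
        name = rdmol.GetProp("_Name")
    mol = Molecule(atoms=atoms, bonds=bonds, name=name, coords2d=coords)
    mol.validate()
    return mol


def to_rdkit(molecule: Molecule) -> Chem.Mol:
    """Rebuild an RDKit molecule (used for depiction and SDF export)."""
    rw = Chem.RWMol()
    for atom in molecule.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        a.SetNumExplicitHs(atom.explicit_h_count)
        a.SetIsAromatic(atom.aromatic)
        rw.AddAtom(a)
    for bond in molecule.bonds:
        a, b = bond.atoms
        rw.AddBond(a, b, _ORDER_TO_RD[bond.order])
        if bond.order == "aromatic":
            rw.GetBondBetweenAtoms(a, b).SetIsAromatic(True)
    rdmol = rw.GetMol()
    Chem.SanitizeMol(rdmol)
    if molecule.name:
        rdmol.SetProp("_Name", molecule.name)
    return rdmol


def parse_smiles(smiles: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Raises :class:`SmilesParseError` on syntax or valence problems,
    carrying the offending input in the message.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    return from_rdkit(rdmol, name=name)


def canonical_smiles(molecule: Molecule) -> str:
    return Chem.MolToSmiles(to_rdkit(molecule))


def read_sdf(path) -> list[Molecule]:
    """Read an SDF/MOL V2000 file, one Molecule per parsable record.

    Records that fail sanitization are skipped with a logged warning.
    """
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    except OSError as exc:
        raise ChemIOError(f"cannot open SDF file {path}: {exc}") from exc
    molecules = []
    skipped = 0
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            skipped += 1
            logger.warning("SDF record %d in %s failed sanitization; skipped", i, path)
            continue
        molecules.append(from_rdkit(rdmol))
    if not molecules:
        raise EmptyInputError(f"no parsable records in {path} ({skipped} skipped)")
    if skipped:
        logger.warning("%d of %d records skipped in %s", skipped, skipped + len(molecules), path)
    return molecules


def write_sdf(path, molecules: Iterable[Molecule]) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol in molecules:
            rdmol = to_rdkit(mol)
            if mol.coords2d is not None:
                conf = Chem.Conformer(rdmol.GetNumAtoms())
                for i, (x, y) in enumerate(mol.coords2d):
                    conf.SetAtomPosition(i, (x, y, 0.0))
                rdmol.AddConformer(conf)
            writer.write(rdmol)
    finally:
        writer.close()


def compute_coords2d(molecule: Molecule) -> list[tuple[float, float]]:
    """Generate 2D depiction coordinates (delegated to RDKit)."""
    rdmol = to_rdkit(molecule)
    AllChem.Compute2DCoords(rdmol)
    conf = rdmol.GetConformer()
    return [
        (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
        for i in range(rdmol.GetNumAtoms())
    ]


def renumber_atoms(
    molecule: Molecule,
    atom_perm: Sequence[int],
    bond_perm: Optional[Sequence[int]] = None,
) -> tuple[Molecule, dict[int, int]]:
    """Relabel atoms (and optionally reorder bonds) of a molecule.

    ``atom_perm[i]`` is the new index of old atom ``i``. Returns the
    renumbered molecule and a map from old bond index to new bond index.
    Used to check that fingerprints are input-order invariant.
    """
    n = molecule.n_atoms
    if sorted(atom_perm) != list(range(n)):
        raise ValueError("atom_perm is not a permutation")
    new_atoms: list[Optional[Atom]] = [None] * n
    for old, new in enumerate(atom_perm):
        new_atoms[new] = molecule.atoms[old]
    order = list(range(molecule.n_bonds)) if bond_perm is None else list(bond_perm)
    if sorted(order) != list(range(molecule.n_bonds)):
        raise ValueError("bond_perm is not a permutation")
    new_bonds = []
    bond_map = {}
    for new_idx, old_idx in enumerate(order):
        old_bond = molecule.bonds[old_idx]
        a, b = old_bond.atoms
        new_bonds.append(
            Bond(index=new_idx, atoms=(atom_perm[a], atom_perm[b]), order=old_bond.order)
        )
        bond_map[old_idx] = new_idx
    coords = None
    if molecule.coords2d is not None:
        coords = [molecule.coords2d[0]] * n
        for old, new in enumerate(atom_perm):
            coords[new] = molecule.coords2d[old]
    out = Molecule(atoms=new_atoms, bonds=new_bonds, name=molecule.name, coords2d=coords)
    out.validate()
    return out, bond_map
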