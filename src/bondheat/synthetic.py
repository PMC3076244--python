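"""Seeded generator of labeled molecule libraries with planted substructures.

Molecules are assembled by attaching fragments at open valences of randomly
built alkyl/aryl scaffolds. Actives receive "activating" fragments with a
configurable prevalence, inactives mostly lack them, and the bond indices of
every planted fragment are recorded as ground truth — so classifier quality
and coloring recovery can be measured without any external data.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from . import chem_io
from .chem_io import Molecule
from .coloring import BondColoring

MAX_ASSEMBLY_RETRIES = 20

_SCAFFOLD_UNITS = [
    "CCCC",
    "CCCCC",
    "CCC(C)C",
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "C1CCCC1",
    "CCOCC",
    "CCNCC",
]

_DECOY_FRAGMENTS = ["CC(C)C", "OC", "CCO", "CN", "CF", "C=CC"]


class SyntheticError(Exception):
    pass


class AssemblyError(SyntheticError):
    pass


class NoPlantedBondsError(SyntheticError):
    pass


@dataclass(frozen=True)
class PlantSpec:
    """A substructure planted into the library with class-dependent prevalence."""

    smiles: str
    effect: str  # "activating" | "deactivating"
    prevalence_active: float
    prevalence_inactive: float

    def __post_init__(self) -> None:
        if self.effect not in ("activating", "deactivating"):
            raise ValueError("effect must be 'activating' or 'deactivating'")
        for p in (self.prevalence_active, self.prevalence_inactive):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must be in [0, 1]")
        if Chem.MolFromSmiles(self.smiles) is None:
            raise ValueError(f"invalid fragment SMILES {self.smiles!r}")


@dataclass
class SyntheticLibrary:
    """Molecules, labels, and per-molecule planted-bond ground truth.

    ``ground_truth[i]`` maps plant index -> list of bond indices of that
    planted fragment in molecule i (internal fragment bonds).
    """

    molecules: list[Molecule]
    labels: np.ndarray  # observed labels (after optional noise)
    true_labels: np.ndarray  # labels before noise
    ground_truth: list[dict[int, list[int]]]
    plants: list[PlantSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.molecules)

    def planted_bonds(self, i: int, effect: Optional[str] = None) -> set[int]:
        bonds: set[int] = set()
        for p_idx, idxs in self.ground_truth[i].items():
            if effect is None or self.plants[p_idx].effect == effect:
                bonds.update(idxs)
        return bonds


def _attachable_atoms(rdmol: Chem.Mol, limit: Optional[int] = None) -> list[int]:
    n = rdmol.GetNumAtoms() if limit is None else limit
    return [
        i
        for i in range(n)
        if rdmol.GetAtomWithIdx(i).GetTotalNumHs() >= 1
    ]


def _attach_fragment(
    rdmol: Chem.Mol, frag_smiles: str, rng: random.Random
) -> tuple[Chem.Mol, list[int]]:
    """Attach a fragment by a single bond at a random open valence.

    Returns the new molecule and the bond indices of the fragment's internal
    bonds (CombineMols appends fragment bonds after the host's, and RDKit
    keeps bond order stable through sanitization).
    """
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        raise AssemblyError(f"invalid fragment SMILES {frag_smiles!r}")
    n_host_atoms = rdmol.GetNumAtoms()
    n_host_bonds = rdmol.GetNumBonds()
    hosts = _attachable_atoms(rdmol)
    frag_sites = _attachable_atoms(frag)
    if not hosts or not frag_sites:
        raise AssemblyError("no open valence for attachment")
    host_atom = rng.choice(hosts)
    frag_atom = rng.choice(frag_sites) + n_host_atoms
    combined = Chem.RWMol(Chem.CombineMols(rdmol, frag))
    combined.AddBond(host_atom, frag_atom, Chem.BondType.SINGLE)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    frag_bonds = list(range(n_host_bonds, n_host_bonds + frag.GetNumBonds()))
    return out, frag_bonds


def _build_scaffold(rng: random.Random) -> str:
    units = [rng.choice(_SCAFFOLD_UNITS) for _ in range(rng.randint(1, 2))]
    mol = Chem.MolFromSmiles(units[0])
    for extra in units[1:]:
        try:
            mol, _ = _attach_fragment(mol, extra, rng)
        except AssemblyError:
            continue
    return Chem.MolToSmiles(mol)


def _assemble_molecule(
    scaffold_smiles: str,
    plants_to_add: Sequence[tuple[int, PlantSpec]],
    rng: random.Random,
    decoy_rate: float,
) -> tuple[Chem.Mol, dict[int, list[int]]]:
    mol = Chem.MolFromSmiles(scaffold_smiles)
    annotations: dict[int, list[int]] = {}
    for decoy in _DECOY_FRAGMENTS:
        if rng.random() < decoy_rate:
            try:
                mol, _ = _attach_fragment(mol, decoy, rng)
            except AssemblyError:
                continue
    for p_idx, plant in plants_to_add:
        mol, frag_bonds = _attach_fragment(mol, plant.smiles, rng)
        annotations[p_idx] = frag_bonds
    return mol, annotations


def generate_library(
    n_active: int,
    n_inactive: int,
    plants: Sequence[PlantSpec],
    scaffold_pool_size: int = 20,
    seed: int = 0,
    label_noise: float = 0.0,
    decoy_rate: float = 0.25,
) -> SyntheticLibrary:
    """Build a labeled library; fully reproducible from ``seed``.

    Each molecule is a random scaffold from a seeded pool, decorated with
    decoy fragments, plus each plant with its class-conditional prevalence.
    Labels are flipped independently at rate ``label_noise``.
    """
    if n_active < 1 or n_inactive < 1:
        raise ValueError("need at least one molecule per class")
    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must be in [0, 1]")
    rng = random.Random(seed)
    pool = [_build_scaffold(rng) for _ in range(scaffold_pool_size)]
    plants = list(plants)
    molecules: list[Molecule] = []
    true_labels: list[int] = []
    observed: list[int] = []
    ground_truth: list[dict[int, list[int]]] = []
    specs = [1] * n_active + [-1] * n_inactive
    for i, label in enumerate(specs):
        to_add = []
        for p_idx, plant in enumerate(plants):
            prevalence = (
                plant.prevalence_active if label == 1 else plant.prevalence_inactive
            )
            if rng.random() < prevalence:
                to_add.append((p_idx, plant))
        rdmol = None
        annotations: dict[int, list[int]] = {}
        for _ in range(MAX_ASSEMBLY_RETRIES):
            try:
                rdmol, annotations = _assemble_molecule(
                    rng.choice(pool), to_add, rng, decoy_rate
                )
                break
            except AssemblyError:
                continue
        if rdmol is None:
            raise AssemblyError(f"could not assemble molecule {i} after retries")
        mol = chem_io.from_rdkit(rdmol, name=f"synth-{i:05d}")
        for p_idx, idxs in annotations.items():
            for b in idxs:
                if b >= mol.n_bonds:
                    raise AssemblyError("annotated bond outside molecule")
        molecules.append(mol)
        true_labels.append(label)
        observed.append(-label if rng.random() < label_noise else label)
        ground_truth.append(annotations)
    return SyntheticLibrary(
        molecules=molecules,
        labels=np.array(observed),
        true_labels=np.array(true_labels),
        ground_truth=ground_truth,
        plants=plants,
    )


def recovery_score(
    library: SyntheticLibrary,
    colorings: Sequence[BondColoring],
    effect: str = "activating",
) -> float:
    """Fraction of actives whose planted bonds separate from the rest.

    For "activating" plants: mean normalized score over planted bonds must
    exceed the mean over all other bonds; for "deactivating" plants the
    comparison is reversed. Only actives carrying the relevant plant count.
    """
    if len(colorings) != len(library):
        raise ValueError("colorings and library differ in length")
    hits = 0
    total = 0
    for i, coloring in enumerate(colorings):
        if library.labels[i] != 1:
            continue
        planted = library.planted_bonds(i, effect)
        if not planted:
            continue
        others = set(coloring.entries) - planted
        if not others:
            continue
        planted_nu = np.mean([coloring.entries[b].nu for b in planted])
        other_nu = np.mean([coloring.entries[b].nu for b in others])
        total += 1
        if effect == "activating" and planted_nu > other_nu:
            hits += 1
        elif effect == "deactivating" and planted_nu < other_nu:
            hits += 1
    if total == 0:
        raise NoPlantedBondsError(
            f"no active molecule carries a planted {effect} fragment"
        )
    return hits / total


def write_library(library: SyntheticLibrary, outdir) -> None:
    """Library as SDF + label CSV + ground-truth JSON (all plain text)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    chem_io.write_sdf(os.path.join(outdir, "molecules.sdf"), library.molecules)
    with open(os.path.join(outdir, "labels.csv"), "w") as fh:
        fh.write("name,label\n")
        for mol, label in zip(library.molecules, library.labels):
            fh.write(f"{mol.name},{label}\n")
    doc = {
        "plants": [
            {
                "smiles": p.smiles,
                "effect": p.effect,
                "prevalence_active": p.prevalence_active,
                "prevalence_inactive": p.prevalence_inactive,
            }
            for p in library.plants
        ],
        "ground_truth": [
            {str(p_idx): idxs for p_idx, idxs in gt.items()}
            for gt in library.ground_truth
        ],
        "true_labels": [int(x) for x in library.true_labels],
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(doc, fh, indent=1)


def default_plants() -> list[PlantSpec]:
    """One activating and one deactivating plant, noise-free defaults."""
    return [
        PlantSpec("C(=O)NO", "activating", prevalence_active=1.0, prevalence_inactive=0.0),
        PlantSpec("S(=O)(=O)N", "deactivating", prevalence_active=0.25, prevalence_inactive=0.9),
    ]
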