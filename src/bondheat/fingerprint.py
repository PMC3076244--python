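"""Explicit-growth circular-substructure fingerprint with bond provenance.

Every feature is a circular substructure grown iteration by iteration around
a center atom. Unlike folded fingerprints, the full mapping from each hashed
feature id back to the atoms and bonds of every occurrence is retained, so
model weights can later be attributed to individual bonds. Bonds from member
atoms to attachment points belong to a substructure's bond set at every
iteration, including iteration 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from .chem_io import Molecule

DEFAULT_DEPTH = 4
DEFAULT_HASH_BITS = 22

_PT = Chem.GetPeriodicTable()

#: edge labels used in canonical encodings
_ORDER_SYMBOL = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}

#: reserved node label for attachment points ("any atom" semantics)
WILDCARD = "*"


def atom_invariants(molecule: Molecule) -> list[tuple[int, int, int, int, int, int]]:
    """Per-atom initial identifiers, index-aligned with the molecule's atoms.

    The tuple is (atomic number, heavy-atom degree, total H count, formal
    charge, aromatic flag, in-ring flag) — intrinsic properties only, so
    equal atoms always map to equal invariants.
    """
    out = []
    for atom in molecule.atoms:
        out.append(
            (
                _PT.GetAtomicNumber(atom.element),
                atom.degree,
                atom.explicit_h_count,
                atom.formal_charge,
                int(atom.aromatic),
                int(atom.in_ring),
            )
        )
    return out


@dataclass(frozen=True)
class CircularSubstructure:
    """One circular substructure: the unit that becomes a feature."""

    center: int
    iteration: int
    member_atoms: frozenset[int]
    member_bonds: frozenset[int]
    attachment_points: frozenset[int]


def grow(molecule: Molecule, depth: int) -> list[CircularSubstructure]:
    """Grow circular substructures around every atom for iterations 0..depth.

    Iteration i+1 absorbs the attachment points of iteration i. Growth stops
    early for a center once its substructure covers the whole connected
    component; the fully-grown substructure is emitted exactly once.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    subs: list[CircularSubstructure] = []
    for center in range(molecule.n_atoms):
        members = {center}
        for iteration in range(depth + 1):
            member_bonds = set()
            attachment = set()
            for a in members:
                for bond in molecule.incident_bonds(a):
                    member_bonds.add(bond.index)
                    other = bond.other(a)
                    if other not in members:
                        attachment.add(other)
            subs.append(
                CircularSubstructure(
                    center=center,
                    iteration=iteration,
                    member_atoms=frozenset(members),
                    member_bonds=frozenset(member_bonds),
                    attachment_points=frozenset(attachment),
                )
            )
            if not attachment:
                break
            members |= attachment
    return subs


# ---------------------------------------------------------------------------
# Canonical encoding of a substructure (order-invariant serialization)
# ---------------------------------------------------------------------------


def _refine(colors: list[int], adj: list[list[tuple[int, str]]]) -> list[int]:
    """Iterative partition refinement on vertex colors."""
    n = len(colors)
    while True:
        sigs = []
        for v in range(n):
            nbr = tuple(sorted((el, colors[u]) for u, el in adj[v]))
            sigs.append((colors[v], nbr))
        ranking = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new_colors = [ranking[s] for s in sigs]
        if len(set(new_colors)) == len(set(colors)):
            return new_colors
        colors = new_colors


def _certificate_for_order(
    order: list[int], labels: list[str], adj: list[list[tuple[int, str]]]
) -> tuple:
    pos = {v: i for i, v in enumerate(order)}
    nodes = tuple(labels[v] for v in order)
    edges = []
    for v in order:
        for u, el in adj[v]:
            if pos[v] < pos[u]:
                edges.append((pos[v], pos[u], el))
    return (nodes, tuple(sorted(edges)))


def _canonical_certificate(
    labels: list[str], adj: list[list[tuple[int, str]]]
) -> tuple:
    """Canonical form of a small labeled graph.

    Partition refinement seeded by node labels; remaining ties (automorphic
    orbits) are resolved by individualize-and-refine branching, keeping the
    lexicographically smallest certificate.
    """
    n = len(labels)
    ranking = {s: i for i, s in enumerate(sorted(set(labels)))}
    init = [ranking[s] for s in labels]

    best: list[Optional[tuple]] = [None]

    def search(colors: list[int]) -> None:
        colors = _refine(colors, adj)
        cells: dict[int, list[int]] = {}
        for v, c in enumerate(colors):
            cells.setdefault(c, []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            order = sorted(range(n), key=lambda v: colors[v])
            cert = _certificate_for_order(order, labels, adj)
            if best[0] is None or cert < best[0]:
                best[0] = cert
            return
        for v in target:
            branched = [2 * c for c in colors]
            branched[v] -= 1
            search(branched)

    search(init)
    assert best[0] is not None
    return best[0]


def canonical_encoding(sub: CircularSubstructure, molecule: Molecule) -> str:
    """Serialize a substructure so that isomorphic substructures — regardless
    of atom input order — produce identical strings.

    Nodes are member atoms labeled by their invariants plus attachment points
    labeled by a wildcard; edges are the member bonds labeled by bond order.
    """
    invariants = atom_invariants(molecule)
    nodes = sorted(sub.member_atoms) + sorted(sub.attachment_points)
    index = {a: i for i, a in enumerate(nodes)}
    labels = []
    for a in nodes:
        if a in sub.member_atoms:
            labels.append("A" + ",".join(str(x) for x in invariants[a]))
        else:
            labels.append(WILDCARD)
    adj: list[list[tuple[int, str]]] = [[] for _ in nodes]
    for b in sorted(sub.member_bonds):
        bond = molecule.bonds[b]
        u, v = bond.atoms
        iu, iv = index[u], index[v]
        sym = _ORDER_SYMBOL[bond.order]
        adj[iu].append((iv, sym))
        adj[iv].append((iu, sym))
    nodes_part, edges_part = _canonical_certificate(labels, adj)
    node_str = "|".join(nodes_part)
    edge_str = ";".join(f"{i}{el}{j}" for i, j, el in edges_part)
    return f"{node_str}${edge_str}"


_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


def hash_feature(encoding: str, hash_bits: int = DEFAULT_HASH_BITS) -> int:
    """Stable FNV-1a 64-bit hash of the encoding, masked to ``hash_bits``.

    Never a per-process randomized hash: feature ids must be identical
    across runs and platforms so that saved models stay applicable.
    """
    if not 1 <= hash_bits <= 32:
        raise ValueError("hash_bits must be in [1, 32]")
    h = _FNV_OFFSET
    for byte in encoding.encode("utf-8"):
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h & ((1 << hash_bits) - 1)


@dataclass(frozen=True)
class FeatureOccurrence:
    """One concrete placement of a feature in a molecule."""

    center: int
    iteration: int
    member_atoms: frozenset[int]
    member_bonds: frozenset[int]
    encoding: str


@dataclass
class ProvenancedFingerprint:
    """Sparse binary fingerprint plus per-feature occurrence provenance.

    ``provenance`` maps each feature id to every occurrence whose encoding
    hashes to that id — including hash collisions, whose weight is by design
    attributed to all colliding bond sets. ``substructure_table`` exposes
    the distinct canonical encodings behind each id so collisions can be
    audited.
    """

    molecule: Molecule
    depth: int
    hash_bits: int
    present_features: frozenset[int] = field(default_factory=frozenset)
    provenance: dict[int, list[FeatureOccurrence]] = field(default_factory=dict)
    substructure_table: dict[int, set[str]] = field(default_factory=dict)

    def sorted_features(self) -> list[int]:
        return sorted(self.present_features)


def fingerprint(
    molecule: Molecule,
    depth: int = DEFAULT_DEPTH,
    hash_bits: int = DEFAULT_HASH_BITS,
) -> ProvenancedFingerprint:
    """Compute the provenanced fingerprint of a molecule.

    Binary semantics: a feature occurring at several centers is present once,
    but every occurrence is kept in the provenance.
    """
    provenance: dict[int, list[FeatureOccurrence]] = {}
    table: dict[int, set[str]] = {}
    for sub in grow(molecule, depth):
        enc = canonical_encoding(sub, molecule)
        fid = hash_feature(enc, hash_bits)
        provenance.setdefault(fid, []).append(
            FeatureOccurrence(
                center=sub.center,
                iteration=sub.iteration,
                member_atoms=sub.member_atoms,
                member_bonds=sub.member_bonds,
                encoding=enc,
            )
        )
        table.setdefault(fid, set()).add(enc)
    return ProvenancedFingerprint(
        molecule=molecule,
        depth=depth,
        hash_bits=hash_bits,
        present_features=frozenset(provenance),
        provenance=provenance,
        substructure_table=table,
    )


def collision_fraction(fps: Sequence[ProvenancedFingerprint]) -> float:
    """Fraction of feature ids that map to more than one distinct encoding
    across a set of fingerprints."""
    table: dict[int, set[str]] = {}
    for fp in fps:
        for fid, encs in fp.substructure_table.items():
            table.setdefault(fid, set()).update(encs)
    if not table:
        return 0.0
    colliding = sum(1 for encs in table.values() if len(encs) > 1)
    return colliding / len(table)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def to_sparse_line(fp: ProvenancedFingerprint, label: int) -> str:
    """One molecule as a sparse ``label id:1 id:1 ...`` line, ids ascending."""
    feats = " ".join(f"{fid}:1" for fid in fp.sorted_features())
    return f"{label:+d} {feats}".rstrip()


def write_sparse(path, fps: Sequence[ProvenancedFingerprint], labels: Sequence[int]) -> None:
    if len(fps) != len(labels):
        raise ValueError("fingerprints and labels differ in length")
    with open(path, "w") as fh:
        for fp, label in zip(fps, labels):
            fh.write(to_sparse_line(fp, label) + "\n")


def write_provenance(path, fps: Sequence[ProvenancedFingerprint]) -> None:
    """Sidecar provenance table: molecule, feature id, occurrence index,
    comma-separated bond indices."""
    with open(path, "w") as fh:
        fh.write("molecule\tfeature_id\toccurrence\tbond_indices\n")
        for fp in fps:
            name = fp.molecule.name
            for fid in fp.sorted_features():
                for k, occ in enumerate(fp.provenance[fid]):
                    bonds = ",".join(str(b) for b in sorted(occ.member_bonds))
                    fh.write(f"{name}\t{fid}\t{k}\t{bonds}\n")
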