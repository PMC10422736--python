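"""SMILES to directed molecular graphs with atom/bond feature matrices.

A molecule is encoded as a directed graph G(V, E): every chemical bond
contributes two opposed directed edges so that edge-wise hidden states can
flow in both directions during message passing. Atom and bond descriptors
follow the de-facto standard feature set of directed message-passing
encoders (element, degree, formal charge, chirality, attached hydrogens,
hybridization, aromaticity, scaled mass; bond type, conjugation, ring
membership, stereochemistry).

Hydrogens are implicit: they appear in the attached-H count, never as nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

# Feature vocabularies. Unknown values fall into the trailing "other" slot
# of each one-hot block, so featurization never raises on exotic atoms.
ELEMENTS = ["C", "N", "O", "F", "S", "Cl", "Br", "I", "P", "B", "Si"]
DEGREES = [0, 1, 2, 3, 4, 5]
FORMAL_CHARGES = [-2, -1, 0, 1, 2]
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
NUM_HS = [0, 1, 2, 3, 4]
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]

#: Atom feature width: one-hot blocks (each with an "other" slot) + aromatic
#: flag + scaled atomic mass.
ATOM_FDIM = (
    (len(ELEMENTS) + 1)
    + (len(DEGREES) + 1)
    + (len(FORMAL_CHARGES) + 1)
    + (len(CHIRAL_TAGS) + 1)
    + (len(NUM_HS) + 1)
    + (len(HYBRIDIZATIONS) + 1)
    + 2
)

#: Bond feature width: type/stereo one-hots (with "other") + conjugation +
#: ring flags.
BOND_FDIM = (len(BOND_TYPES) + 1) + (len(BOND_STEREO) + 1) + 2


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def _onehot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Fixed-width real vector describing one atom's local environment."""
    feats = (
        _onehot(atom.GetSymbol(), ELEMENTS)
        + _onehot(atom.GetDegree(), DEGREES)
        + _onehot(atom.GetFormalCharge(), FORMAL_CHARGES)
        + _onehot(atom.GetChiralTag(), CHIRAL_TAGS)
        + _onehot(atom.GetTotalNumHs(), NUM_HS)
        + _onehot(atom.GetHybridization(), HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )
    return np.array(feats, dtype=np.float64)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Fixed-width real vector for one bond; identical for both directions."""
    feats = (
        _onehot(bond.GetBondType(), BOND_TYPES)
        + _onehot(bond.GetStereo(), BOND_STEREO)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
    )
    return np.array(feats, dtype=np.float64)


@dataclass
class MolGraph:
    """Directed molecular graph with feature matrices.

    Attributes
    ----------
    n_atoms : number of heavy atoms.
    atom_features : (n_atoms, ATOM_FDIM) matrix X_v.
    directed_edges : (n_edges, 2) int array of (source, target) atom indices;
        each chemical bond contributes the pair (v, w) and (w, v).
    edge_features : (n_edges, BOND_FDIM) matrix X_e; an edge and its reverse
        share one row's values.
    reverse_index : (n_edges,) int array mapping an edge to its reverse.
    atom_order : canonical atom ranking used by the order-sensitive readout,
        so equivalent SMILES always present nodes in the same sequence.
    """

    n_atoms: int
    atom_features: np.ndarray
    directed_edges: np.ndarray
    edge_features: np.ndarray
    reverse_index: np.ndarray
    atom_order: np.ndarray
    smiles: str = field(default="")

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges)


def build_graph(smiles: str) -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph`.

    The molecule is renumbered into its canonical-SMILES atom order and the
    directed edge list sorted lexicographically, so every SMILES form of the
    same molecule produces a component-wise identical graph. Multi-fragment
    inputs (salts) keep the largest fragment with a warning. Raises
    :class:`SmilesParseError` on unparseable or empty input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"empty or invalid SMILES input: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        warnings.warn(
            f"multi-fragment SMILES {smiles!r}: keeping largest fragment",
            stacklevel=2,
        )
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"molecule has no atoms: {smiles!r}")

    # Round-trip through the canonical SMILES: the re-parsed molecule's atom
    # numbering is then a pure function of the molecule, not the input form.
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    n_atoms = mol.GetNumAtoms()

    atom_features = np.stack([featurize_atom(a) for a in mol.GetAtoms()])

    edges: list[tuple[int, int]] = []
    edge_feats: list[np.ndarray] = []
    for bond in mol.GetBonds():
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        edges.append((v, w))
        edge_feats.append(f)
        edges.append((w, v))
        edge_feats.append(f)

    if edges:
        order = sorted(range(len(edges)), key=lambda i: edges[i])
        edges = [edges[i] for i in order]
        edge_feats = [edge_feats[i] for i in order]
        position = {e: i for i, e in enumerate(edges)}
        reverse_index = np.array(
            [position[(w, v)] for (v, w) in edges], dtype=np.intp
        )
        directed_edges = np.asarray(edges, dtype=np.intp)
        edge_features = np.stack(edge_feats)
    else:
        reverse_index = np.zeros(0, dtype=np.intp)
        directed_edges = np.zeros((0, 2), dtype=np.intp)
        edge_features = np.zeros((0, BOND_FDIM), dtype=np.float64)

    return MolGraph(
        n_atoms=n_atoms,
        atom_features=atom_features,
        directed_edges=directed_edges,
        edge_features=edge_features,
        reverse_index=reverse_index,
        atom_order=np.arange(n_atoms, dtype=np.intp),
        smiles=canonical,
    )
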