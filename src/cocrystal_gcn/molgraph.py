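"""Molecular graphs and the paired covalent/noncovalent representation.

An API/coformer pair is modelled as one graph over the union of the two
molecules' heavy atoms.  Bonding information is split into two m x m
binary matrices:

* ``a_c`` — covalent adjacency: the bond graph of each molecule sits in
  its own diagonal block; the off-diagonal (intermolecular) blocks are
  zero.
* ``a_nc`` — noncovalent adjacency: every intermolecular atom pair is
  connected (the model has no prior knowledge of which contacts matter,
  so all of them are offered); the intramolecular blocks are zero.

Both matrices are symmetric with zero diagonal and have disjoint
supports.  Atom features are computed per heavy atom; hydrogens are
implicit and enter only through an H-count feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "MolGraph",
    "PairGraph",
    "canonicalize",
    "featurize_atoms",
    "build_pair_graph",
    "FEATURE_DIM",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + "other" bucket
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)  # + "other" bucket
_MAX_DEGREE = 5
_MAX_H = 4

#: element (10) + degree (6) + H-count (5) + charge (1) + aromatic (1)
#: + in-ring (1) + hybridization (4)
FEATURE_DIM = (len(_ELEMENTS) + 1) + (_MAX_DEGREE + 1) + (_MAX_H + 1) + 1 + 1 + 1 + (len(_HYBRIDIZATIONS) + 1)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of *smiles*.

    Idempotent; two notations of the same molecule map to the same
    string, which makes canonical SMILES usable as a dictionary key for
    deduplication.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def _one_hot(index: int, size: int) -> list[float]:
    row = [0.0] * size
    row[index] = 1.0
    return row


def featurize_atoms(mol: Chem.Mol) -> np.ndarray:
    """Per-heavy-atom feature matrix of shape (n_atoms, FEATURE_DIM).

    Feature groups: element one-hot over C/N/O/S/F/Cl/Br/I/P/other,
    heavy-atom degree one-hot 0-5, total hydrogen count one-hot 0-4
    (clipped), formal charge as a plain numeric column, aromaticity flag,
    ring-membership flag, hybridization one-hot sp/sp2/sp3/other.
    Elements outside the supported set fall into the "other" bucket
    rather than raising.
    """
    rows = []
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        elem_idx = _ELEMENTS.index(symbol) if symbol in _ELEMENTS else len(_ELEMENTS)
        hyb = atom.GetHybridization()
        hyb_idx = _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else len(_HYBRIDIZATIONS)
        row = (
            _one_hot(elem_idx, len(_ELEMENTS) + 1)
            + _one_hot(min(atom.GetDegree(), _MAX_DEGREE), _MAX_DEGREE + 1)
            + _one_hot(min(atom.GetTotalNumHs(), _MAX_H), _MAX_H + 1)
            + [float(atom.GetFormalCharge())]
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + [1.0 if atom.IsInRing() else 0.0]
            + _one_hot(hyb_idx, len(_HYBRIDIZATIONS) + 1)
        )
        rows.append(row)
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), FEATURE_DIM)


@dataclass(frozen=True)
class MolGraph:
    """A single molecule as a heavy-atom graph with per-atom features."""

    smiles: str
    atom_count: int
    elements: tuple[str, ...]
    bonds: frozenset[tuple[int, int]]  # unordered pairs stored as (lo, hi)
    features: np.ndarray = field(repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolGraph":
        mol = _mol_from_smiles(smiles)
        canonical = Chem.MolToSmiles(mol)
        # re-parse so atom order follows the canonical SMILES, giving a
        # deterministic serialization independent of the input notation
        mol = _mol_from_smiles(canonical)
        n = mol.GetNumAtoms()
        if n == 0:
            raise SmilesParseError(f"molecule has no heavy atoms: {smiles!r}")
        bonds = frozenset(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mol.GetBonds()
        )
        return cls(
            smiles=canonical,
            atom_count=n,
            elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
            bonds=bonds,
            features=featurize_atoms(mol),
        )

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 bond adjacency with zero diagonal."""
        a = np.zeros((self.atom_count, self.atom_count))
        for i, j in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass(frozen=True)
class PairGraph:
    """Combined API + coformer graph with block adjacency matrices.

    Atom order is API atoms first, then coformer atoms.  ``a_c`` holds
    the covalent bonds of each molecule in its diagonal block; ``a_nc``
    connects every API atom to every coformer atom and nothing else.
    """

    api: MolGraph
    coformer: MolGraph
    m: int
    x_in: np.ndarray = field(repr=False, compare=False)
    a_c: np.ndarray = field(repr=False, compare=False)
    a_nc: np.ndarray = field(repr=False, compare=False)

    def atom_roles(self) -> list[str]:
        """Per-atom role tag, ``"API"`` or ``"CF"``, in graph atom order."""
        return ["API"] * self.api.atom_count + ["CF"] * self.coformer.atom_count

    def to_debug_dump(self) -> str:
        """Plain-text dump of the pair (dense 0/1 matrices), for fixtures."""
        lines = [f"api {self.api.smiles}", f"coformer {self.coformer.smiles}", f"m {self.m}"]
        for name, mat in (("a_c", self.a_c), ("a_nc", self.a_nc)):
            lines.append(name)
            lines.extend(" ".join(str(int(v)) for v in row) for row in mat)
        return "\n".join(lines) + "\n"


def build_pair_graph(api: MolGraph | str, coformer: MolGraph | str) -> PairGraph:
    """Assemble the paired graph of an API and a coformer.

    Accepts :class:`MolGraph` objects or SMILES strings.  The stacked
    feature matrix puts API rows first; the covalent matrix is block
    diagonal, the noncovalent matrix fills exactly the two cross blocks.
    """
    if isinstance(api, str):
        api = MolGraph.from_smiles(api)
    if isinstance(coformer, str):
        coformer = MolGraph.from_smiles(coformer)
    na, nc = api.atom_count, coformer.atom_count
    if na == 0 or nc == 0:
        raise ValueError("both molecules must have at least one heavy atom")
    m = na + nc
    x_in = np.vstack([api.features, coformer.features])
    a_c = np.zeros((m, m))
    a_c[:na, :na] = api.adjacency()
    a_c[na:, na:] = coformer.adjacency()
    a_nc = np.zeros((m, m))
    a_nc[:na, na:] = 1.0
    a_nc[na:, :na] = 1.0
    return PairGraph(api=api, coformer=coformer, m=m, x_in=x_in, a_c=a_c, a_nc=a_nc)
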