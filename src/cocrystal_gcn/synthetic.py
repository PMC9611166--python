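"""Synthetic molecule libraries with a planted heterosynthon pairing rule.

Real cocrystal training data comes from licensed crystal-structure
databases and cannot ship with a package.  This module emulates its
statistical shape: a library of small organic molecules, a third of
which carry hydrogen-bond *donor* motifs (carboxylic acid, hydroxyl,
amide N-H), a third *acceptor* motifs (aromatic ring nitrogen, ester
carbonyl), and the rest neither.  The planted rule mirrors the
heterosynthon concept — hydrogen bonding between unlike functional
groups drives cocrystal formation — so a pair is labeled positive
exactly when one member is a donor molecule and the other an acceptor
molecule.  Labels can be flipped with a configurable noise probability
to emulate the false negatives that random pair generation introduces.

Molecules are assembled from a fragment grammar (scaffold x motif), so
every generated SMILES is valid by construction and motif membership is
controlled; each class is verified by substructure matching before use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem

from .data import LabeledPair, PairDataset
from .molgraph import canonicalize

__all__ = [
    "SyntheticSpec",
    "generate_library",
    "planted_label",
    "generate_dataset",
    "has_donor",
    "has_acceptor",
]

# donor motifs: O-H or amide N-H (hydrogen-bond donors)
_DONOR_SMARTS = [
    Chem.MolFromSmarts("[OX2H]"),            # hydroxyl (also matches the acid O-H)
    Chem.MolFromSmarts("[NX3;H1,H2][CX3]=O"),  # amide N-H
]
# acceptor motifs: aromatic ring nitrogen or ester carbonyl
_ACCEPTOR_SMARTS = [
    Chem.MolFromSmarts("[nX2]"),                    # pyridine/pyrazine-type N
    Chem.MolFromSmarts("[CX3](=O)[OX2H0][#6]"),     # ester
]

# alkyl/aryl substituents used as SMILES prefixes in the templates below
_CHAINS = ["", "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC",
           "CCCCCCCC", "CC(C)", "CC(C)C", "CCC(C)", "CC(C)(C)", "CCCC(C)"]

_DONOR_TEMPLATES = [
    "{r}C(=O)O",            # carboxylic acids
    "{r}CO",                # primary alcohols
    "{r}C(N)=O",            # primary amides
    "{r}c1ccc(O)cc1",       # phenols
    "{r}c1ccc(C(=O)O)cc1",  # aryl acids
    "{r}c1ccc(C(N)=O)cc1",  # aryl amides
]
_ACCEPTOR_TEMPLATES = [
    "{r}c1ccncc1",              # pyridines
    "{r}c1cnccn1",              # pyrazines
    "{r}C(=O)OC",               # methyl esters
    "{r}c1ccc(C(=O)OC)cc1",     # aryl methyl esters
]
_NEUTRAL_TEMPLATES = [
    "{r}C",               # alkanes
    "{r}C=C",             # terminal alkenes
    "{r}c1ccccc1",        # benzene / alkylbenzenes
    "{r}c1ccc(C)cc1",     # para-dialkylbenzenes
    "{r}C1CCCCC1",        # cyclohexanes
    "{r}c1ccc2ccccc2c1",  # naphthalenes
]


def _match_any(mol: Chem.Mol, patterns) -> bool:
    return any(mol.HasSubstructMatch(p) for p in patterns)


@lru_cache(maxsize=None)
def _motif_flags(smiles: str) -> tuple[bool, bool]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return _match_any(mol, _DONOR_SMARTS), _match_any(mol, _ACCEPTOR_SMARTS)


def has_donor(smiles: str) -> bool:
    """True if the molecule carries a hydrogen-bond donor motif."""
    return _motif_flags(smiles)[0]


def has_acceptor(smiles: str) -> bool:
    """True if the molecule carries a hydrogen-bond acceptor motif."""
    return _motif_flags(smiles)[1]


def motif_atom_indices(smiles: str) -> list[int]:
    """Atom indices (canonical order) belonging to donor or acceptor motifs.

    These are the atoms the planted rule keys on, so a faithful
    attribution method should concentrate positive relevance there for
    correctly predicted positive pairs.
    """
    mol = Chem.MolFromSmiles(canonicalize(smiles))
    atoms: set[int] = set()
    for pattern in _DONOR_SMARTS + _ACCEPTOR_SMARTS:
        for match in mol.GetSubstructMatches(pattern):
            atoms.update(match)
    return sorted(atoms)


def planted_label(a: str, b: str) -> int:
    """The planted pairing rule: 1 iff one molecule is a donor and the other an acceptor.

    Symmetric in its arguments; a deterministic function of the two
    molecules' substructure flags.
    """
    da, aa = _motif_flags(canonicalize(a))
    db, ab = _motif_flags(canonicalize(b))
    return int((da and ab) or (db and aa))


@lru_cache(maxsize=1)
def _class_pools() -> dict[str, list[str]]:
    """Enumerate the grammar, canonicalize, and keep motif-pure molecules per class."""
    pools: dict[str, list[str]] = {"donor": [], "acceptor": [], "neutral": []}
    specs = [("donor", _DONOR_TEMPLATES), ("acceptor", _ACCEPTOR_TEMPLATES),
             ("neutral", _NEUTRAL_TEMPLATES)]
    for cls, templates in specs:
        seen: set[str] = set()
        for template, r in itertools.product(templates, _CHAINS):
            smiles = template.format(r=r)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            d, a = _motif_flags(canon)
            if (cls == "donor" and (not d or a)) or \
               (cls == "acceptor" and (not a or d)) or \
               (cls == "neutral" and (d or a)):
                continue
            seen.add(canon)
            pools[cls].append(canon)
    # a molecule must belong to exactly one class pool
    for x, y in itertools.combinations(pools.values(), 2):
        assert not set(x) & set(y)
    return pools


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of a synthetic study.

    Defaults generate a balanced 2400-pair dataset (1200 positive, 1200
    negative) over a 150-molecule library with 5% label noise — a desk-
    scale analogue of a balanced database-derived training set with a
    small false-label rate.
    """

    n_molecules: int = 150
    donor_fraction: float = 0.35
    acceptor_fraction: float = 0.35
    n_pos: int = 1200
    n_neg: int = 1200
    label_noise: float = 0.05
    seed: int = 0
    #: >0 skews negative sampling toward reusing low-index molecules
    #: (Zipf-like weights), creating the over-represented compounds that
    #: rebalancing targets
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.donor_fraction <= 1 and 0 <= self.acceptor_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.donor_fraction + self.acceptor_fraction > 1 + 1e-9:
            raise ValueError("donor_fraction + acceptor_fraction must not exceed 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if min(self.n_molecules, self.n_pos, self.n_neg) <= 0:
            raise ValueError("counts must be positive")


def generate_library(spec: SyntheticSpec) -> list[str]:
    """Sample a library of unique canonical SMILES from the fragment grammar.

    Class sizes follow the spec fractions (donors, acceptors, remainder
    motif-free).  Deterministic given ``spec.seed``.
    """
    pools = _class_pools()
    n_donor = round(spec.n_molecules * spec.donor_fraction)
    n_acceptor = round(spec.n_molecules * spec.acceptor_fraction)
    n_neutral = spec.n_molecules - n_donor - n_acceptor
    wanted = {"donor": n_donor, "acceptor": n_acceptor, "neutral": n_neutral}
    rng = np.random.default_rng(spec.seed)
    library: list[str] = []
    for cls, n in wanted.items():
        pool = pools[cls]
        if n > len(pool):
            raise ValueError(
                f"requested {n} {cls} molecules but the grammar provides only {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        library.extend(pool[i] for i in idx)
    return library


def generate_dataset(spec: SyntheticSpec) -> PairDataset:
    """Build a labeled pair dataset under the planted rule.

    Exactly ``n_pos`` rule-positive and ``n_neg`` rule-negative unordered
    pairs are drawn without replacement from the library, then each label
    is independently flipped with probability ``label_noise``.
    """
    library = generate_library(spec)
    flags = [_motif_flags(s) for s in library]
    pos_candidates, neg_candidates = [], []
    for i, j in itertools.combinations(range(len(library)), 2):
        (di, ai), (dj, aj) = flags[i], flags[j]
        if (di and aj) or (dj and ai):
            pos_candidates.append((i, j))
        else:
            neg_candidates.append((i, j))
    if spec.n_pos > len(pos_candidates) or spec.n_neg > len(neg_candidates):
        raise ValueError(
            f"infeasible counts: at most {len(pos_candidates)} positive and "
            f"{len(neg_candidates)} negative pairs are available"
        )
    rng = np.random.default_rng(spec.seed)
    pos_idx = rng.choice(len(pos_candidates), size=spec.n_pos, replace=False)
    if spec.skew > 0:
        w = np.array(
            [(i + 1.0) ** -spec.skew * (j + 1.0) ** -spec.skew for i, j in neg_candidates]
        )
        neg_idx = rng.choice(
            len(neg_candidates), size=spec.n_neg, replace=False, p=w / w.sum()
        )
    else:
        neg_idx = rng.choice(len(neg_candidates), size=spec.n_neg, replace=False)
    pairs = []
    for k in pos_idx:
        i, j = pos_candidates[k]
        pairs.append((library[i], library[j], 1))
    for k in neg_idx:
        i, j = neg_candidates[k]
        pairs.append((library[i], library[j], 0))
    flips = rng.random(len(pairs)) < spec.label_noise
    return PairDataset(
        LabeledPair(a, b, (1 - y) if flip else y, "synthetic")
        for (a, b, y), flip in zip(pairs, flips)
    )
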