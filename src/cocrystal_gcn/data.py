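"""Labeled pair datasets: deduplication, rebalancing, splitting.

The training data for cocrystal prediction is a table of molecule pairs
with binary labels.  Positives come from curated crystal structures;
negatives are a mixture of experimentally verified non-formers and pairs
generated by randomly combining molecules.  Random combination
over-represents some compounds relative to the positive set, so a
rebalancing step removes the excess: compounds are ranked by how much
more often they occur among generated negatives than among positives,
and for each such compound only a diverse subset of its pairs (chosen by
greedy MaxMin selection on fingerprint distance) is kept.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .molgraph import canonicalize

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledPair",
    "PairDataset",
    "deduplicate",
    "generate_negative_pairs",
    "compound_frequency",
    "maxmin_select",
    "rebalance_negatives",
    "split_dataset",
    "kfold",
    "chemspace_embedding",
    "tanimoto_distance",
    "pair_fingerprint",
]

_SOURCES = {"csd_pos", "gen_neg", "exp_neg", "synthetic"}
_SOURCE_LABEL = {"csd_pos": 1, "gen_neg": 0, "exp_neg": 0}

_canon_cache: dict[str, str] = {}


def _canon(smiles: str) -> str:
    if smiles not in _canon_cache:
        _canon_cache[smiles] = canonicalize(smiles)
    return _canon_cache[smiles]


@dataclass(frozen=True)
class LabeledPair:
    """One labeled molecule pair.

    ``source`` records provenance: ``csd_pos`` (database positive),
    ``gen_neg`` (randomly combined negative), ``exp_neg`` (experimental
    negative), or ``synthetic``.  Pair identity is unordered: (a, b) and
    (b, a) denote the same pair.
    """

    api_smiles: str
    cf_smiles: str
    label: int
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        expected = _SOURCE_LABEL.get(self.source)
        if expected is not None and expected != self.label:
            raise ValueError(f"source {self.source!r} implies label {expected}, got {self.label}")
        if self.api_smiles == self.cf_smiles:
            raise ValueError(f"a pair must join two different molecules: {self.api_smiles!r}")

    def canonical(self) -> "LabeledPair":
        return replace(self, api_smiles=_canon(self.api_smiles), cf_smiles=_canon(self.cf_smiles))

    def key(self) -> tuple[str, str]:
        """Unordered canonical identity of the pair."""
        a, b = sorted((_canon(self.api_smiles), _canon(self.cf_smiles)))
        return (a, b)


class PairDataset:
    """An ordered collection of :class:`LabeledPair` with class bookkeeping."""

    def __init__(self, pairs: Iterable[LabeledPair]):
        self.pairs: list[LabeledPair] = list(pairs)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_pos, n_neg)."""
        n_pos = sum(p.label for p in self.pairs)
        return n_pos, len(self.pairs) - n_pos

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, PairDataset) and self.pairs == other.pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.api_smiles, p.cf_smiles, p.label, p.source) for p in self.pairs],
            columns=["api_smiles", "cf_smiles", "label", "source"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairDataset":
        df = pd.read_csv(path)
        return cls(
            LabeledPair(r.api_smiles, r.cf_smiles, int(r.label), r.source)
            for r in df.itertuples(index=False)
        )


def deduplicate(pairs: Iterable[LabeledPair]) -> PairDataset:
    """Drop duplicate unordered pairs (per label class); first occurrence wins."""
    seen: set[tuple[str, str, int]] = set()
    kept = []
    for p in pairs:
        k = (*p.key(), p.label)
        if k not in seen:
            seen.add(k)
            kept.append(p.canonical())
    return PairDataset(kept)


def generate_negative_pairs(
    pool: Sequence[str],
    n: int,
    forbidden: set[tuple[str, str]] | None = None,
    seed: int = 0,
) -> list[LabeledPair]:
    """Randomly combine molecules from *pool* into *n* negative pairs.

    No generated pair duplicates another or appears in *forbidden*
    (a set of unordered canonical SMILES 2-tuples, e.g. the known
    positives).  Deterministic for a given seed.
    """
    forbidden = {tuple(sorted(f)) for f in (forbidden or set())}
    unique_pool = sorted({_canon(s) for s in pool})
    candidates = [
        (a, b) for a, b in itertools.combinations(unique_pool, 2) if (a, b) not in forbidden
    ]
    if n > len(candidates):
        raise ValueError(
            f"cannot generate {n} distinct negative pairs; only {len(candidates)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [
        LabeledPair(candidates[i][0], candidates[i][1], 0, "gen_neg") for i in chosen
    ]


def compound_frequency(ds: PairDataset) -> dict[str, int]:
    """Occurrence count of each compound; every pair counts once per member."""
    counts: Counter[str] = Counter()
    for p in ds:
        counts[_canon(p.api_smiles)] += 1
        counts[_canon(p.cf_smiles)] += 1
    return dict(counts)


def maxmin_select(
    items: Sequence,
    k: int,
    distance: Callable[[object, object], float],
    seed: int | None = None,
) -> list[int]:
    """Greedy MaxMin diversity selection; returns selected *indices*.

    Starts from the first item in input order and repeatedly adds the
    item whose minimum distance to the already-selected set is largest,
    ties broken by lowest input index.  Fully deterministic; *seed* is
    accepted for interface uniformity but does not influence the
    selection.
    """
    n = len(items)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    selected = [0]
    min_dist = np.array([distance(items[0], items[i]) for i in range(n)], dtype=float)
    min_dist[0] = -np.inf
    while len(selected) < k:
        best = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(best)
        for i in range(n):
            if min_dist[i] > -np.inf:
                min_dist[i] = min(min_dist[i], distance(items[best], items[i]))
        min_dist[best] = -np.inf
    return selected


_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_fp_cache: dict[str, np.ndarray] = {}


def _mol_fp(smiles: str) -> np.ndarray:
    """1024-bit ECFP (Morgan radius 2) as a 0/1 numpy vector."""
    s = _canon(smiles)
    if s not in _fp_cache:
        _fp_cache[s] = _morgan.GetFingerprintAsNumPy(Chem.MolFromSmiles(s)).astype(np.uint8)
    return _fp_cache[s]


def pair_fingerprint(pair: LabeledPair) -> np.ndarray:
    """2048-bit fingerprint of a pair: member ECFPs concatenated in sorted canonical order."""
    a, b = pair.key()
    return np.concatenate([_mol_fp(a), _mol_fp(b)])


def tanimoto_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """1 - Tanimoto similarity of two binary fingerprints (0 for identical)."""
    inter = int(np.sum(fp_a & fp_b))
    union = int(np.sum(fp_a | fp_b))
    return 0.0 if union == 0 else 1.0 - inter / union


def _pair_distance(p: LabeledPair, q: LabeledPair) -> float:
    return tanimoto_distance(pair_fingerprint(p), pair_fingerprint(q))


def rebalance_negatives(
    gen_neg: PairDataset,
    csd_pos: PairDataset,
    exp_neg: PairDataset,
    remove_total: int,
    seed: int = 0,
) -> PairDataset:
    """Replace *remove_total* generated negatives with the experimental ones.

    Procedure: count each compound's frequency in the generated-negative
    and positive sets; rank compounds by the frequency difference
    (generated minus positive), largest first.  For each compound whose
    surviving generated frequency M exceeds its positive frequency N,
    keep only a MaxMin-diverse subset of its pairs and delete the rest,
    stopping once exactly *remove_total* pairs have been removed (the
    final compound is truncated to hit the total).  The experimental
    negatives are then appended unchanged.
    """
    if remove_total > len(gen_neg):
        raise ValueError("remove_total exceeds the generated-negative set size")
    gen_keys = {p.key() for p in gen_neg}
    overlap = [p for p in exp_neg if p.key() in gen_keys]
    if overlap:
        raise ValueError(
            f"exp_neg overlaps gen_neg after canonicalization ({len(overlap)} pairs)"
        )

    freq_neg = compound_frequency(gen_neg)
    freq_pos = compound_frequency(csd_pos)
    # largest frequency excess first; lexicographic tie-break for determinism
    ranking = sorted(
        freq_neg, key=lambda c: (-(freq_neg[c] - freq_pos.get(c, 0)), c)
    )

    alive = [True] * len(gen_neg)
    pair_members = [p.key() for p in gen_neg.pairs]
    removed = 0
    for compound in ranking:
        if removed >= remove_total:
            break
        idxs = [i for i, alive_i in enumerate(alive) if alive_i and compound in pair_members[i]]
        m_freq = len(idxs)
        n_freq = freq_pos.get(compound, 0)
        if m_freq <= n_freq:
            continue
        need = min(m_freq - n_freq, remove_total - removed)
        keep_count = m_freq - need
        if keep_count == 0:
            kept_local: list[int] = []
        else:
            members = [gen_neg.pairs[i] for i in idxs]
            kept_local = maxmin_select(members, keep_count, _pair_distance, seed=seed)
        kept_global = {idxs[j] for j in kept_local}
        for i in idxs:
            if i not in kept_global:
                alive[i] = False
        removed += need
    if removed < remove_total:
        raise ValueError(
            f"only {removed} pairs removable under the frequency rule, "
            f"requested {remove_total}"
        )
    survivors = [p for p, a in zip(gen_neg.pairs, alive) if a]
    return PairDataset(survivors + list(exp_neg.pairs))


def _largest_remainder(total: int, ratios: Sequence[float]) -> list[int]:
    shares = [total * r for r in ratios]
    base = [int(np.floor(s)) for s in shares]
    leftovers = total - sum(base)
    order = np.argsort([-(s - b) for s, b in zip(shares, base)], kind="stable")
    for i in range(leftovers):
        base[order[i]] += 1
    return base


def split_dataset(
    ds: PairDataset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[PairDataset, PairDataset, PairDataset]:
    """Random stratified train/validation/test split.

    Sizes follow largest-remainder rounding of the ratios applied
    within each label class, so every split's class balance matches the
    whole dataset to within one pair per class.  Deterministic given
    the seed.  Raises if any split would be empty.
    """
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-8:
        raise ValueError("ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    split_indices: list[list[int]] = [[], [], []]
    for label in (1, 0):
        idxs = np.array([i for i, p in enumerate(ds.pairs) if p.label == label])
        if idxs.size == 0:
            continue
        rng.shuffle(idxs)
        counts = _largest_remainder(len(idxs), ratios)
        start = 0
        for s, c in enumerate(counts):
            split_indices[s].extend(idxs[start : start + c].tolist())
            start += c
    if any(len(s) == 0 for s in split_indices):
        raise ValueError(f"empty split for ratios {ratios} on {len(ds)} pairs")
    return tuple(PairDataset([ds.pairs[i] for i in sorted(s)]) for s in split_indices)


def kfold(
    ds: PairDataset,
    k: int = 10,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> list[tuple[PairDataset, PairDataset, PairDataset]]:
    """*k* independent random train/val/test resplits.

    Each repetition re-randomizes the split from a seed derived
    deterministically from the master seed (this is repeated random
    subsampling, not a partitioned k-fold).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31 - 1)
    return [split_dataset(ds, ratios, seed=int(s)) for s in fold_seeds]


def chemspace_embedding(
    smiles_sets: dict[str, Sequence[str]],
    seed: int = 0,
    out_csv: str | Path | None = None,
    out_plot: str | Path | None = None,
) -> pd.DataFrame:
    """2-D chemical-space map of molecule sets via ECFP + t-SNE.

    Each molecule is fingerprinted (1024-bit ECFP, radius 2) and the
    fingerprints of all sets are embedded together with t-SNE.  Returns
    a table with columns ``set_label, smiles, x, y``; optionally writes
    it to CSV and renders a scatter plot colored by set.  Invalid
    SMILES are skipped with a warning.
    """
    from sklearn.manifold import TSNE

    labels, smiles, fps = [], [], []
    for set_label, mols in smiles_sets.items():
        for s in mols:
            if Chem.MolFromSmiles(s) is None:
                logger.warning("skipping invalid SMILES %r in set %r", s, set_label)
                warnings.warn(f"skipping invalid SMILES {s!r}")
                continue
            labels.append(set_label)
            smiles.append(_canon(s))
            fps.append(_mol_fp(s))
    fps = np.array(fps, dtype=float)
    perplexity = min(30.0, max(1.0, len(fps) - 1))
    coords = TSNE(
        n_components=2, random_state=seed, init="pca", perplexity=perplexity
    ).fit_transform(fps)
    df = pd.DataFrame({"set_label": labels, "smiles": smiles, "x": coords[:, 0], "y": coords[:, 1]})
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for set_label, grp in df.groupby("set_label"):
            ax.scatter(grp.x, grp.y, s=12, alpha=0.6, label=set_label)
        ax.legend()
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(out_plot, dpi=150)
        plt.close(fig)
    return df
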