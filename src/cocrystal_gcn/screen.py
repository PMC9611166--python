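"""Virtual coformer screening: score a candidate list against one API.

Every candidate is paired with the API, run through the trained
network, and ranked by predicted cocrystal probability; the top-k
candidates go on to experimental screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .model import ModelParams, batch_probabilities, _cached_mol
from .molgraph import build_pair_graph, canonicalize

logger = logging.getLogger(__name__)

__all__ = ["RankedCoformer", "screen"]


@dataclass(frozen=True)
class RankedCoformer:
    """One screened candidate with its score and 1-based rank."""

    coformer_id: str
    smiles: str
    score: float
    rank: int


def screen(
    api_smiles: str,
    candidates: Sequence[tuple[str, str]],
    params: ModelParams,
    top_k: int | None = None,
    out_csv: str | Path | None = None,
) -> list[RankedCoformer]:
    """Score (id, SMILES) candidates against the API and return the top-k.

    Candidates are sorted by descending probability, ties broken by
    input order.  Unparseable candidate SMILES are logged and excluded.
    The full ranked table (all parseable candidates) is written to
    *out_csv* when given; the return value is truncated to *top_k*.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    api = canonicalize(api_smiles)
    valid: list[tuple[str, str]] = []
    skipped: list[str] = []
    for cid, smiles in candidates:
        if Chem.MolFromSmiles(smiles) is None:
            logger.warning("skipping unparseable candidate %s: %r", cid, smiles)
            skipped.append(cid)
            continue
        valid.append((cid, canonicalize(smiles)))
    if not valid:
        raise ValueError("no parseable candidates")
    if top_k is None:
        top_k = len(valid)
    if top_k > len(valid):
        raise ValueError(f"top_k={top_k} exceeds the {len(valid)} parseable candidates")
    graphs = [build_pair_graph(_cached_mol(api), _cached_mol(s)) for _, s in valid]
    scores = batch_probabilities(params, graphs)
    order = np.argsort(-scores, kind="stable")  # stable: ties keep input order
    ranked = [
        RankedCoformer(coformer_id=valid[i][0], smiles=valid[i][1], score=float(scores[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]
    if out_csv is not None:
        df = pd.DataFrame([vars(r) for r in ranked])
        df["skipped_candidates"] = ";".join(skipped) if skipped else ""
        df.to_csv(out_csv, index=False)
    return ranked[:top_k]
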