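"""Layer-wise relevance propagation (LRP) for per-atom attribution.

The trained network's pre-sigmoid output (the cocrystal logit) is
redistributed backwards layer by layer: each neuron passes its
relevance to its inputs in proportion to their contribution to the
neuron's pre-activation (the epsilon-stabilized z-rule).  Adjacency
multiplications are treated as fixed-weight linear layers, so relevance
flows along graph edges; residual additions split relevance between the
skip branch and the convolution branch in proportion to the two
forward-pass contributions.  Bias terms are excluded from the
redistribution denominators, so with ``epsilon = 0`` the sum of input
relevances reproduces the logit exactly (conservation), which is the
main internal consistency check of the method.

The per-atom relevance is the sum of the relevances of the atom's input
features.  Red atoms (positive relevance) push the prediction towards
cocrystal formation, blue atoms against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .model import ModelParams, _relu, forward_logit
from .molgraph import PairGraph

__all__ = ["RelevanceMap", "lrp_atom_relevance", "render_heatmap", "lrp_linear"]


def _safe_share(z: np.ndarray, axis: int, epsilon: float) -> np.ndarray:
    """Contribution shares z / (sum z + eps*sign); zero where the sum is exactly 0."""
    denom = z.sum(axis=axis, keepdims=True)
    sign = np.where(denom >= 0, 1.0, -1.0)
    stabilized = denom + epsilon * sign
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(stabilized != 0, z / np.where(stabilized == 0, 1.0, stabilized), 0.0)
    return share


def lrp_linear(x: np.ndarray, w: np.ndarray, relevance_out: np.ndarray, epsilon: float) -> np.ndarray:
    """Redistribute relevance through ``y = x @ w (+ b)``.

    ``x`` has shape (..., I), ``w`` (I, O), ``relevance_out`` (..., O);
    returns (..., I).  The bias is not part of the denominator, so with
    ``epsilon = 0`` the redistribution is exactly conservative.  On a
    purely linear single-layer model this reduces to the analytic
    attribution ``R_i = x_i * w_i * R / y``.
    """
    z = x[..., :, None] * w  # (..., I, O)
    share = _safe_share(z, axis=-2, epsilon=epsilon)
    return np.einsum("...io,...o->...i", share, relevance_out)


@dataclass
class RelevanceMap:
    """Per-atom relevance aligned to PairGraph atom order (API atoms first)."""

    pair: PairGraph
    relevances: np.ndarray
    explained_value: float  # the pre-sigmoid logit being decomposed
    rule_epsilon: float
    feature_relevances: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        roles = self.pair.atom_roles()
        elements = list(self.pair.api.elements) + list(self.pair.coformer.elements)
        return pd.DataFrame({
            "atom_index": np.arange(self.pair.m),
            "molecule_role": roles,
            "element": elements,
            "relevance": self.relevances,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def lrp_atom_relevance(params: ModelParams, pair: PairGraph, epsilon: float = 1e-6) -> RelevanceMap:
    """Decompose the cocrystal logit of *pair* into per-atom relevances."""
    for name, w in params.weights().items():
        if not np.all(np.isfinite(w)):
            raise ValueError(f"parameter {name} contains non-finite values; train the model first")
    hp = params.hp

    # forward pass, keeping every intermediate
    x = pair.x_in
    z1 = x @ params.W1 + params.b1
    h1 = _relu(z1)
    z2 = h1 @ params.W2 + params.b2
    hne = _relu(z2)
    h = hne
    branches = []  # (residual_input, adjacency, weight, relu_output) per conv step
    for use, a, w in ((hp.use_covalent, pair.a_c, params.W_C), (hp.use_noncovalent, pair.a_nc, params.W_NC)):
        if not use:
            continue
        msg = a @ h
        r = _relu(msg @ w)
        branches.append((h, a, w, msg, r))
        h = h + r
    hnc = h
    g = hnc.sum(axis=0)
    if hp.mean_pool:
        g = g / pair.m
    hf = _relu(g @ params.W_FC1 + params.b_FC1)
    logit = float((hf @ params.W_FC2 + params.b_FC2)[0])

    # backward redistribution
    r_hf = lrp_linear(hf, params.W_FC2, np.array([logit]), epsilon)
    r_g = lrp_linear(g, params.W_FC1, r_hf, epsilon)
    # pooling: share proportional to each atom's (non-negative) activation;
    # a mean divides every contribution by m, leaving shares unchanged
    r_hnc = _safe_share(hnc, axis=0, epsilon=epsilon) * r_g[None, :]

    r_h = r_hnc
    for residual_in, a, w, msg, r_branch_out in reversed(branches):
        # split between skip connection and convolution branch per entry
        z_pair = np.stack([residual_in, r_branch_out])  # (2, m, d)
        shares = _safe_share(z_pair, axis=0, epsilon=epsilon)
        r_skip = shares[0] * r_h
        r_conv = shares[1] * r_h
        # through the weight: per node row, msg -> relu(msg @ w)
        r_msg = lrp_linear(msg, w, r_conv, epsilon)
        # through the adjacency: msg[i] = sum_k a[i, k] * h_in[k]
        z = a[:, :, None] * residual_in[None, :, :]  # (i, k, d)
        share = _safe_share(z, axis=1, epsilon=epsilon)
        r_h = r_skip + np.einsum("ikd,id->kd", share, r_msg)

    # node-embedding layers (relevance passes through ReLU unchanged)
    r_h1 = lrp_linear(h1, params.W2, r_h, epsilon)
    r_x = lrp_linear(x, params.W1, r_h1, epsilon)

    return RelevanceMap(
        pair=pair,
        relevances=r_x.sum(axis=1),
        explained_value=logit,
        rule_epsilon=epsilon,
        feature_relevances=r_x,
    )


def _atom_colors(relevances: np.ndarray) -> list[tuple[float, float, float]]:
    """Symmetric diverging scale centered at 0: white -> red (+), white -> blue (-)."""
    peak = np.max(np.abs(relevances))
    colors = []
    for r in relevances:
        v = 0.0 if peak == 0 else float(r) / peak
        if v >= 0:
            colors.append((1.0, 1.0 - v, 1.0 - v))
        else:
            colors.append((1.0 + v, 1.0 + v, 1.0))
    return colors


def render_heatmap(pair: PairGraph, rel: RelevanceMap, out_path: str | Path) -> Path:
    """Draw both molecules with atoms shaded by relevance; writes PNG or SVG.

    Color intensity is |relevance| normalized by the pair's maximum;
    the scale is symmetric so flipping every sign swaps red and blue.
    """
    if not np.all(np.isfinite(rel.relevances)):
        raise ValueError("relevances must be finite")
    out_path = Path(out_path)
    colors = _atom_colors(rel.relevances)
    na = pair.api.atom_count
    mols, highlights, highlight_colors = [], [], []
    for smiles, color_slice in ((pair.api.smiles, colors[:na]), (pair.coformer.smiles, colors[na:])):
        mol = Chem.MolFromSmiles(smiles)
        mols.append(mol)
        highlights.append(list(range(mol.GetNumAtoms())))
        highlight_colors.append({i: c for i, c in enumerate(color_slice)})
    if out_path.suffix.lower() == ".svg":
        drawer = rdMolDraw2D.MolDraw2DSVG(900, 450, 450, 450)
    else:
        drawer = rdMolDraw2D.MolDraw2DCairo(900, 450, 450, 450)
    drawer.DrawMolecules(
        mols,
        highlightAtoms=highlights,
        highlightAtomColors=highlight_colors,
        highlightBonds=[[] for _ in mols],
        legends=["API", "coformer"],
    )
    drawer.FinishDrawing()
    data = drawer.GetDrawingText()
    if isinstance(data, str):
        out_path.write_text(data)
    else:
        out_path.write_bytes(data)
    return out_path
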