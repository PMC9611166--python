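"""The pair-graph convolutional classifier.

Architecture (all activations ReLU unless noted):

1. node embedding: ``h_NE = relu(b2 + relu(b1 + X_in W1) W2)``
2. covalent graph convolution with residual: ``h_C = h_NE + relu(A_C h_NE W_C)``
3. noncovalent graph convolution with residual: ``h_NC = h_C + relu(A_NC h_C W_NC)``
4. global pooling: ``h_GP = 1^T h_NC`` (sum over atoms; mean optional)
5. fully connected head: ``p = sigmoid(b_FC2 + relu(b_FC1 + h_GP W_FC1) W_FC2)``

The covalent step propagates information along bonds inside each
molecule; the noncovalent step mixes information across the two
molecules through the dense intermolecular block, which is what lets
the model see donor/acceptor complementarity between partners.  Either
convolution can be disabled for ablation studies.

Training minimizes binary cross-entropy with Adam.  The implementation
is plain NumPy with hand-derived gradients (the architecture is fixed
and small, so a full autodiff framework buys nothing); gradients are
validated against finite differences in the test suite.  Batches are
zero-padded to the largest pair with an explicit node mask applied
after every layer so padded rows contribute exactly zero to pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import PairDataset, split_dataset, kfold as _kfold
from .molgraph import FEATURE_DIM, MolGraph, PairGraph, build_pair_graph

__all__ = [
    "Hyperparameters",
    "ModelParams",
    "Metrics",
    "node_embed",
    "gc_step",
    "global_pool",
    "predict",
    "forward_pair",
    "forward_logit",
    "bce_loss",
    "train",
    "evaluate",
    "roc_auc",
    "cross_validate",
    "pair_graphs",
    "save_params",
    "load_params",
]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable sigmoid


@dataclass(frozen=True)
class Hyperparameters:
    """Network and training configuration.

    ``embed_dim1/embed_dim2`` size the two node-embedding layers; the
    graph-convolution weights are ``embed_dim2 x embed_dim2`` because the
    residual additions require matching widths.  ``use_covalent`` /
    ``use_noncovalent`` toggle the two convolution steps (the ablation
    variants keep exactly one of them).  ``mean_pool`` switches the
    pooling from a plain sum over atoms to a mean.
    """

    feature_dim: int = FEATURE_DIM
    embed_dim1: int = 64
    embed_dim2: int = 64
    fc_hidden: int = 128
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    use_covalent: bool = True
    use_noncovalent: bool = True
    mean_pool: bool = False
    normalize_adjacency: bool = False
    clip_eps: float = 1e-7

    def __post_init__(self) -> None:
        if not (self.use_covalent or self.use_noncovalent):
            raise ValueError("at least one of use_covalent/use_noncovalent must be enabled")


_WEIGHT_FIELDS = ["W1", "b1", "W2", "b2", "W_C", "W_NC", "W_FC1", "b_FC1", "W_FC2", "b_FC2"]


@dataclass
class ModelParams:
    """All trainable weights plus the hyperparameters that shaped them."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W_C: np.ndarray
    W_NC: np.ndarray
    W_FC1: np.ndarray
    b_FC1: np.ndarray
    W_FC2: np.ndarray
    b_FC2: np.ndarray
    hp: Hyperparameters = field(default_factory=Hyperparameters)
    seed: int | None = None

    @classmethod
    def initialize(cls, hp: Hyperparameters, seed: int = 0) -> "ModelParams":
        """Seeded Glorot-uniform initialization (biases zero)."""
        rng = np.random.default_rng(seed)

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        d1, d2, h = hp.embed_dim1, hp.embed_dim2, hp.fc_hidden
        return cls(
            W1=glorot(hp.feature_dim, d1), b1=np.zeros(d1),
            W2=glorot(d1, d2), b2=np.zeros(d2),
            W_C=glorot(d2, d2), W_NC=glorot(d2, d2),
            W_FC1=glorot(d2, h), b_FC1=np.zeros(h),
            W_FC2=glorot(h, 1), b_FC2=np.zeros(1),
            hp=hp, seed=seed,
        )

    def weights(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in _WEIGHT_FIELDS}

    def copy(self) -> "ModelParams":
        return ModelParams(**{k: v.copy() for k, v in self.weights().items()}, hp=self.hp, seed=self.seed)

    def validate_shapes(self) -> None:
        hp = self.hp
        chain = [
            (self.W1, (hp.feature_dim, hp.embed_dim1)), (self.b1, (hp.embed_dim1,)),
            (self.W2, (hp.embed_dim1, hp.embed_dim2)), (self.b2, (hp.embed_dim2,)),
            (self.W_C, (hp.embed_dim2, hp.embed_dim2)), (self.W_NC, (hp.embed_dim2, hp.embed_dim2)),
            (self.W_FC1, (hp.embed_dim2, hp.fc_hidden)), (self.b_FC1, (hp.fc_hidden,)),
            (self.W_FC2, (hp.fc_hidden, 1)), (self.b_FC2, (1,)),
        ]
        for arr, shape in chain:
            if arr.shape != shape:
                raise ValueError(f"parameter shape {arr.shape} does not match expected {shape}")


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write weights to an .npz archive with a JSON hyperparameter sidecar."""
    path = Path(path)
    np.savez(path, **params.weights())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"hyperparameters": asdict(params.hp), "seed": params.seed}, indent=2))


def load_params(path: str | Path) -> ModelParams:
    path = Path(path)
    with np.load(path) as archive:
        weights = {k: archive[k] for k in _WEIGHT_FIELDS}
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return ModelParams(**weights, hp=Hyperparameters(**meta["hyperparameters"]), seed=meta["seed"])


# ---------------------------------------------------------------------------
# forward pass


def node_embed(x_in: np.ndarray, params: ModelParams) -> np.ndarray:
    """Two dense layers with ReLU applied per atom row."""
    if x_in.shape[-1] != params.hp.feature_dim:
        raise ValueError(f"expected feature dim {params.hp.feature_dim}, got {x_in.shape[-1]}")
    return _relu(params.b2 + _relu(params.b1 + x_in @ params.W1) @ params.W2)


def gc_step(h: np.ndarray, a: np.ndarray, w: np.ndarray, residual_source: np.ndarray) -> np.ndarray:
    """One residual graph convolution: ``residual_source + relu(a h w)``."""
    if a.shape[-1] != h.shape[-2] or h.shape[-1] != w.shape[0]:
        raise ValueError(f"incompatible shapes a={a.shape} h={h.shape} w={w.shape}")
    return residual_source + _relu(a @ h @ w)


def global_pool(h_nc: np.ndarray, mask: np.ndarray | None = None, mean: bool = False) -> np.ndarray:
    """Sum (or mean) over atom rows; permutation invariant."""
    if mask is not None:
        if not np.any(mask):
            raise ValueError("mask marks no valid atoms")
        h_nc = h_nc * np.asarray(mask, dtype=float)[..., None]
        count = np.sum(mask, axis=-1)
    else:
        count = h_nc.shape[-2]
    pooled = np.sum(h_nc, axis=-2)
    if mean:
        pooled = pooled / np.asarray(count)[..., None]
    return pooled


def predict(h_gp: np.ndarray, params: ModelParams) -> np.ndarray:
    """Fully connected head ending in a sigmoid probability."""
    return _sigmoid(predict_logit(h_gp, params))


def predict_logit(h_gp: np.ndarray, params: ModelParams) -> np.ndarray:
    if h_gp.shape[-1] != params.W_FC1.shape[0]:
        raise ValueError(f"expected pooled dim {params.W_FC1.shape[0]}, got {h_gp.shape[-1]}")
    hidden = _relu(params.b_FC1 + h_gp @ params.W_FC1)
    return (params.b_FC2 + hidden @ params.W_FC2)[..., 0]


def _maybe_normalize(a: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return a
    deg = a.sum(axis=-1)
    inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    return a * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]


def forward_logit(params: ModelParams, pair: PairGraph) -> float:
    """Pre-sigmoid network output for a single pair."""
    hp = params.hp
    h = node_embed(pair.x_in, params)
    if hp.use_covalent:
        h = gc_step(h, _maybe_normalize(pair.a_c, hp.normalize_adjacency), params.W_C, h)
    if hp.use_noncovalent:
        h = gc_step(h, _maybe_normalize(pair.a_nc, hp.normalize_adjacency), params.W_NC, h)
    g = global_pool(h, mean=hp.mean_pool)
    return float(predict_logit(g, params))


def forward_pair(params: ModelParams, pair: PairGraph) -> float:
    """Probability that the pair forms a cocrystal."""
    return float(_sigmoid(forward_logit(params, pair)))


# ---------------------------------------------------------------------------
# loss and metrics


def bce_loss(labels: Sequence[float], probs: Sequence[float], eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clipping."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    if y.size == 0:
        raise ValueError("bce_loss of an empty batch is undefined")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float | None:
    """Rank-based AUC (Mann-Whitney with ties counted 1/2); None if one class."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # average rank on ties
    u = np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class Metrics:
    """Confusion counts at a fixed cutoff plus threshold-free AUC.

    A metric whose denominator is zero (e.g. precision with no
    predicted positives) is reported as ``None`` rather than 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def acc(self) -> float | None:
        d = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "auc": self.auc, "acc": self.acc, "precision": self.precision, "recall": self.recall,
        }


# ---------------------------------------------------------------------------
# batching


_molgraph_cache: dict[str, MolGraph] = {}


def _cached_mol(smiles: str) -> MolGraph:
    if smiles not in _molgraph_cache:
        _molgraph_cache[smiles] = MolGraph.from_smiles(smiles)
    return _molgraph_cache[smiles]


def pair_graphs(ds: PairDataset) -> list[PairGraph]:
    """Build the PairGraph of every pair in the dataset (molecules cached)."""
    return [build_pair_graph(_cached_mol(p.api_smiles), _cached_mol(p.cf_smiles)) for p in ds]


def _pack_batch(graphs: Sequence[PairGraph], normalize: bool) -> tuple[np.ndarray, ...]:
    """Zero-pad a list of pairs to common atom count; returns (X, Ac, Anc, mask)."""
    b = len(graphs)
    m_max = max(g.m for g in graphs)
    f = graphs[0].x_in.shape[1]
    x = np.zeros((b, m_max, f))
    ac = np.zeros((b, m_max, m_max))
    anc = np.zeros((b, m_max, m_max))
    mask = np.zeros((b, m_max))
    for i, g in enumerate(graphs):
        x[i, : g.m] = g.x_in
        ac[i, : g.m, : g.m] = _maybe_normalize(g.a_c, normalize)
        anc[i, : g.m, : g.m] = _maybe_normalize(g.a_nc, normalize)
        mask[i, : g.m] = 1.0
    return x, ac, anc, mask


def _forward_batch(params: ModelParams, x, ac, anc, mask) -> dict:
    """Masked batched forward pass; returns every intermediate for backprop."""
    hp = params.hp
    m3 = mask[..., None]
    z1 = x @ params.W1 + params.b1
    h1 = _relu(z1) * m3
    z2 = h1 @ params.W2 + params.b2
    hne = _relu(z2) * m3
    cache = {"x": x, "ac": ac, "anc": anc, "mask": mask, "z1": z1, "h1": h1, "z2": z2, "hne": hne}
    h = hne
    if hp.use_covalent:
        zc = ac @ h @ params.W_C
        h = h + _relu(zc) * m3
        cache["zc"] = zc
        cache["hc"] = h
    if hp.use_noncovalent:
        znc = anc @ h @ params.W_NC
        cache["hc_in"] = cache.get("hc", hne)
        h = h + _relu(znc) * m3
        cache["znc"] = znc
    cache["hnc"] = h
    g = np.sum(h * m3, axis=1)
    counts = mask.sum(axis=1)
    if hp.mean_pool:
        g = g / counts[:, None]
    cache["g"] = g
    cache["counts"] = counts
    zf1 = g @ params.W_FC1 + params.b_FC1
    hf = _relu(zf1)
    logit = (hf @ params.W_FC2 + params.b_FC2)[:, 0]
    cache.update(zf1=zf1, hf=hf, logit=logit, prob=_sigmoid(logit))
    return cache


def _backward_batch(params: ModelParams, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
    """Gradient of the mean clipped BCE loss w.r.t. every weight."""
    hp = params.hp
    n = y.size
    m3 = cache["mask"][..., None]
    # analytic sigmoid+BCE gradient; clipping only guards the reported loss,
    # so saturated predictions still receive a full-strength training signal
    dlogit = (cache["prob"] - y) / n
    grads: dict[str, np.ndarray] = {}
    grads["W_FC2"] = cache["hf"].T @ dlogit[:, None]
    grads["b_FC2"] = np.array([dlogit.sum()])
    dhf = dlogit[:, None] @ params.W_FC2.T
    dzf1 = dhf * (cache["zf1"] > 0)
    grads["W_FC1"] = cache["g"].T @ dzf1
    grads["b_FC1"] = dzf1.sum(axis=0)
    dg = dzf1 @ params.W_FC1.T
    if hp.mean_pool:
        dg = dg / cache["counts"][:, None]
    dh = dg[:, None, :] * m3  # broadcast pooling gradient to valid atoms

    def _stacked_matmul(left: np.ndarray, right: np.ndarray) -> np.ndarray:
        # sum_b left[b].T @ right[b], flattened over the batch axis
        return left.reshape(-1, left.shape[-1]).T @ right.reshape(-1, right.shape[-1])

    if hp.use_noncovalent:
        dznc = dh * (cache["znc"] > 0) * m3
        mnc = cache["anc"] @ cache["hc_in"]
        grads["W_NC"] = _stacked_matmul(mnc, dznc)
        dh = dh + (np.swapaxes(cache["anc"], 1, 2) @ dznc) @ params.W_NC.T
    else:
        grads["W_NC"] = np.zeros_like(params.W_NC)
    if hp.use_covalent:
        dzc = dh * (cache["zc"] > 0) * m3
        mc = cache["ac"] @ cache["hne"]
        grads["W_C"] = _stacked_matmul(mc, dzc)
        dh = dh + (np.swapaxes(cache["ac"], 1, 2) @ dzc) @ params.W_C.T
    else:
        grads["W_C"] = np.zeros_like(params.W_C)

    dz2 = dh * (cache["z2"] > 0) * m3
    grads["W2"] = _stacked_matmul(cache["h1"], dz2)
    grads["b2"] = dz2.sum(axis=(0, 1))
    dh1 = dz2 @ params.W2.T
    dz1 = dh1 * (cache["z1"] > 0) * m3
    grads["W1"] = _stacked_matmul(cache["x"], dz1)
    grads["b1"] = dz1.sum(axis=(0, 1))
    return grads


def batch_probabilities(params: ModelParams, graphs: Sequence[PairGraph], batch_size: int = 256) -> np.ndarray:
    """Forward probabilities for many pairs, batched with padding."""
    out = np.empty(len(graphs))
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start : start + batch_size]
        x, ac, anc, mask = _pack_batch(chunk, params.hp.normalize_adjacency)
        out[start : start + len(chunk)] = _forward_batch(params, x, ac, anc, mask)["prob"]
    return out


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            getattr(params, k)[...] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    train_ds: PairDataset,
    val_ds: PairDataset,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> tuple[ModelParams, pd.DataFrame]:
    """Train by Adam on mini-batches; return the best-validation-AUC checkpoint.

    The log has one row per epoch with columns ``epoch, train_loss,
    val_auc``.  Fully deterministic given the seed (weight
    initialization and shuffling both derive from it).
    """
    hp = hp or Hyperparameters()
    for name, ds in (("training", train_ds), ("validation", val_ds)):
        n_pos, n_neg = ds.class_counts
        if len(ds) == 0 or (name == "training" and (n_pos == 0 or n_neg == 0)):
            raise ValueError(f"{name} set must be non-empty and contain both classes")
    params = ModelParams.initialize(hp, seed=seed)
    params.validate_shapes()
    optimizer = _Adam({k: v.shape for k, v in params.weights().items()}, lr=hp.learning_rate)
    rng = np.random.default_rng(seed)

    graphs = pair_graphs(train_ds)
    labels = np.array([p.label for p in train_ds], dtype=float)
    val_graphs = pair_graphs(val_ds)
    val_labels = [p.label for p in val_ds]

    best = params.copy()
    best_auc = -np.inf
    log_rows = []
    for epoch in range(hp.epochs):
        order = rng.permutation(len(graphs))
        losses = []
        for start in range(0, len(order), hp.batch_size):
            idx = order[start : start + hp.batch_size]
            chunk = [graphs[i] for i in idx]
            x, ac, anc, mask = _pack_batch(chunk, hp.normalize_adjacency)
            cache = _forward_batch(params, x, ac, anc, mask)
            y = labels[idx]
            losses.append(bce_loss(y, cache["prob"], eps=hp.clip_eps) * len(idx))
            if hp.learning_rate > 0:
                optimizer.step(params, _backward_batch(params, cache, y))
        val_auc = roc_auc(val_labels, batch_probabilities(params, val_graphs))
        log_rows.append(
            {"epoch": epoch, "train_loss": sum(losses) / len(graphs), "val_auc": val_auc}
        )
        if val_auc is not None and val_auc > best_auc:
            best_auc = val_auc
            best = params.copy()
    return best, pd.DataFrame(log_rows)


def evaluate(params: ModelParams, ds: PairDataset, threshold: float = 0.5) -> Metrics:
    """Confusion counts at the cutoff plus rank-based AUC."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    probs = batch_probabilities(params, pair_graphs(ds))
    y = np.array([p.label for p in ds])
    pred = probs >= threshold
    return Metrics(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        auc=roc_auc(y, probs),
    )


def cross_validate(
    ds: PairDataset,
    k: int = 10,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """k repetitions of random 8:1:1 resplit -> train -> evaluate.

    Returns a table with one row per fold (validation and test AUC,
    accuracy, precision, recall) plus a final ``mean`` row of arithmetic
    means.
    """
    rows = []
    folds = _kfold(ds, k=k, seed=seed)
    for i, (tr, va, te) in enumerate(folds):
        params, _ = train(tr, va, hp=hp, seed=seed + i)
        row: dict = {"fold": i}
        for split_name, split in (("val", va), ("test", te)):
            m = evaluate(params, split)
            row.update({
                f"{split_name}_auc": m.auc, f"{split_name}_acc": m.acc,
                f"{split_name}_precision": m.precision, f"{split_name}_recall": m.recall,
            })
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns=["fold"]).mean(numeric_only=True)
    mean_row["fold"] = "mean"
    return pd.concat([df, mean_row.to_frame().T], ignore_index=True)
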