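"""Graph auto-encoder for bin-specific embeddings of Hi-C contact graphs.

A contact matrix (raw counts or imputed binary) is taken as the adjacency
matrix A of a graph whose nodes are genomic bins.  The encoder is a
featureless graph convolution: one layer ``Z = (D^{-1/2} A D^{-1/2}) W0`` or
two layers ``Z = ReLU((D^{-1/2} A D^{-1/2}) W0) W1``.  The decoder is the
sigmoid inner product ``sigmoid(Z Z^T)``; training minimises binary
cross-entropy on adjacency reconstruction, optionally plus a contrastive
loss that pulls connected bins together in Euclidean space and pushes
unconnected bins beyond a margin — the configuration used when the 3-column
embedding is read out directly as a 3D structure.

The model is small enough that forward pass, analytic gradients and the
Adam optimizer are implemented directly on numpy arrays; training is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .hic_io import ContactMatrix, GenomeBins
from .impute import BinaryAdjacency

__all__ = [
    "Graph",
    "EdgeSplit",
    "ModelConfig",
    "TrainResult",
    "build_graph",
    "split_edges",
    "normalized_adjacency",
    "encoder_input",
    "init_weights",
    "encode",
    "decode",
    "loss_bce",
    "loss_contrastive",
    "ap_auc",
    "train",
]


@dataclass
class Graph:
    """Undirected, self-loop-free graph over genomic bins."""

    adjacency: np.ndarray
    bins: GenomeBins | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def positive_edges(self) -> np.ndarray:
        """Upper-triangular (i < j) node pairs with an edge, as an (m, 2) array."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([ii, jj])


@dataclass
class EdgeSplit:
    """7:2:1 partition of positive edges plus matched negative samples."""

    train_pos: np.ndarray
    val_pos: np.ndarray
    test_pos: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray


@dataclass
class ModelConfig:
    """Hyperparameters of the graph auto-encoder.

    ``layers=1`` learns an n x out_dim weight directly; ``layers=2`` goes
    through a hidden_dim-wide ReLU layer first (used with out_dim=3 for 3D
    reconstruction).  ``loss`` is "bce" or "bce_plus_contrastive"; the
    contrastive term is weighted by ``k_contrast`` and uses Euclidean
    distances with the given ``margin``.
    """

    layers: int = 1
    hidden_dim: int = 128
    out_dim: int = 128
    learning_rate: float = 0.01
    loss: str = "bce"
    k_contrast: float = 1.0
    margin: float = 1.0
    epochs: int = 200
    patience: int = 50
    seed: int = 0
    restarts: int = 1
    score_mode: str = "auto"  # "decoder", "distance" (-||zi - zj||) or "auto"
    self_loops: bool = True  # renormalization trick: encode D^-1/2 (A+I) D^-1/2

    def __post_init__(self) -> None:
        if self.layers not in (1, 2):
            raise ValueError("layers must be 1 or 2")
        if self.hidden_dim < 1 or self.out_dim < 1:
            raise ValueError("dimensions must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("bce", "bce_plus_contrastive"):
            raise ValueError("loss must be 'bce' or 'bce_plus_contrastive'")
        if self.score_mode not in ("auto", "decoder", "distance"):
            raise ValueError("score_mode must be 'auto', 'decoder' or 'distance'")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class TrainResult:
    """Outcome of training: embedding and metrics at the best-validation-AP epoch."""

    best_embedding: np.ndarray
    best_epoch: int
    val_ap: float
    val_auc: float
    test_ap: float
    test_auc: float
    reconstructed: np.ndarray
    score_mode: str = "decoder"
    best_weights: list[np.ndarray] = field(default_factory=list)
    final_weights: list[np.ndarray] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)


def build_graph(source) -> Graph:
    """Turn a contact matrix or binary adjacency into a graph.

    Any strictly positive entry is an edge; the diagonal is dropped (no
    self-loops); isolated nodes are retained.
    """
    if isinstance(source, (ContactMatrix, BinaryAdjacency)):
        values, bins = source.values, source.bins
    else:
        values, bins = np.asarray(source, dtype=float), None
    a = (values > 0).astype(float)
    np.fill_diagonal(a, 0.0)
    a = np.maximum(a, a.T)
    return Graph(adjacency=a, bins=bins)


def split_edges(
    g: Graph,
    ratios: tuple[float, float, float] = (7.0, 2.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> EdgeSplit:
    """Randomly split positive edges for training/validation/blind test.

    Positive edges are shuffled and split by the given ratios (default
    7:2:1); negatives (absent pairs) are sampled without replacement to
    match the validation and test positive counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = g.positive_edges()
    m = len(pos)
    if m < 10:
        raise ValueError(f"need at least 10 positive edges to split, got {m}")
    total = sum(ratios)
    n_val = int(m * ratios[1] / total)
    n_test = int(m * ratios[2] / total)
    if n_val == 0 or n_test == 0 or m - n_val - n_test == 0:
        raise ValueError(f"{m} edges cannot populate all three subsets at {ratios}")
    perm = rng.permutation(m)
    test_pos = pos[perm[:n_test]]
    val_pos = pos[perm[n_test : n_test + n_val]]
    train_pos = pos[perm[n_test + n_val :]]

    ii, jj = np.nonzero(np.triu(1.0 - g.adjacency, k=1))
    neg_pool = np.column_stack([ii, jj])
    n_need = n_val + n_test
    if len(neg_pool) < n_need:
        raise ValueError(
            f"only {len(neg_pool)} negative pairs available, need {n_need}"
        )
    pick = rng.choice(len(neg_pool), size=n_need, replace=False)
    test_neg = neg_pool[pick[:n_test]]
    val_neg = neg_pool[pick[n_test:]]
    return EdgeSplit(
        train_pos=train_pos,
        val_pos=val_pos,
        test_pos=test_pos,
        val_neg=val_neg,
        test_neg=test_neg,
    )


def normalized_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A D^{-1/2}; zero-degree rows stay zero."""
    a = np.asarray(a, dtype=float)
    deg = a.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


def encoder_input(a: np.ndarray, self_loops: bool = True) -> np.ndarray:
    """Normalized adjacency the encoder consumes.

    With ``self_loops`` (the default) the graph-convolution renormalization
    trick is applied: D^{-1/2} (A + I) D^{-1/2} with degrees of A + I.  The
    self-loop lets every bin's own identity flow into its embedding, which
    keeps bins with identical neighbourhoods at identical embeddings and
    markedly stabilizes the downstream clustering; without it the
    normalization is exactly ``normalized_adjacency``.
    """
    a = np.asarray(a, dtype=float)
    if self_loops:
        a = a + np.eye(a.shape[0])
    return normalized_adjacency(a)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_weights(n: int, config: ModelConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Glorot-uniform initial weights for the configured encoder."""
    if config.layers == 1:
        return [_glorot(rng, n, config.out_dim)]
    return [_glorot(rng, n, config.hidden_dim), _glorot(rng, config.hidden_dim, config.out_dim)]


def encode(s_norm: np.ndarray, weights: list[np.ndarray], config: ModelConfig) -> np.ndarray:
    """Encoder forward pass on a pre-normalized adjacency."""
    for w in weights:
        if not np.all(np.isfinite(w)):
            raise FloatingPointError("non-finite encoder weights")
    if config.layers == 1:
        return s_norm @ weights[0]
    h = s_norm @ weights[0]
    return np.maximum(h, 0.0) @ weights[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: reconstructed edge probabilities sigmoid(Z Z^T)."""
    z = np.asarray(z, dtype=float)
    return _sigmoid(z @ z.T)


def _pair_scores(z: np.ndarray, pairs: np.ndarray, mode: str) -> np.ndarray:
    if len(pairs) == 0:
        return np.empty(0)
    zi, zj = z[pairs[:, 0]], z[pairs[:, 1]]
    if mode == "distance":
        return -np.linalg.norm(zi - zj, axis=1)
    return _sigmoid(np.sum(zi * zj, axis=1))


def loss_bce(edges_pos: np.ndarray, edges_neg: np.ndarray, ahat: np.ndarray) -> float:
    """Mean binary cross-entropy of decoded probabilities on given pairs."""
    eps = 1e-12
    terms = []
    if len(edges_pos):
        p = ahat[edges_pos[:, 0], edges_pos[:, 1]]
        terms.append(-np.log(np.clip(p, eps, 1.0)))
    if len(edges_neg):
        p = ahat[edges_neg[:, 0], edges_neg[:, 1]]
        terms.append(-np.log(np.clip(1.0 - p, eps, 1.0)))
    if not terms:
        raise ValueError("no pairs supplied")
    return float(np.mean(np.concatenate(terms)))


def loss_contrastive(
    pairs: np.ndarray, labels: np.ndarray, z: np.ndarray, margin: float = 1.0
) -> float:
    """Mean contrastive loss 0.5 [a d^2 + (1-a) max(0, m-d)^2] over pairs.

    ``d`` is the Euclidean distance between the two embeddings; connected
    pairs (a=1) are pulled together, unconnected pairs pushed beyond ``m``.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    pairs = np.asarray(pairs)
    labels = np.asarray(labels, dtype=float)
    d = np.linalg.norm(z[pairs[:, 0]] - z[pairs[:, 1]], axis=1)
    vals = 0.5 * (labels * d**2 + (1.0 - labels) * np.maximum(0.0, margin - d) ** 2)
    return float(np.mean(vals))


def ap_auc(scores_pos, scores_neg) -> tuple[float, float]:
    """Average precision and ROC AUC for held-out positive vs negative pairs."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if len(scores_pos) == 0 or len(scores_neg) == 0:
        raise ValueError("both score lists must be nonempty")
    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([scores_pos, scores_neg])
    return float(average_precision_score(y, s)), float(roc_auc_score(y, s))


def _forward(s_norm, weights, config):
    if config.layers == 1:
        z = s_norm @ weights[0]
        return z, None
    h = s_norm @ weights[0]
    z = np.maximum(h, 0.0) @ weights[1]
    return z, h


def _backward(s_norm, weights, config, h, dz):
    if config.layers == 1:
        return [s_norm.T @ dz]
    hr = np.maximum(h, 0.0)
    dw1 = hr.T @ dz
    dh = (dz @ weights[1].T) * (h > 0)
    dw0 = s_norm.T @ dh
    return [dw0, dw1]


def _bce_full_grad(z, target, pos_weight):
    """Weighted full-matrix BCE on logits Z Z^T; returns (loss, dL/dZ)."""
    n = z.shape[0]
    x = z @ z.T
    sig = _sigmoid(x)
    eps = 1e-12
    per = -(
        pos_weight * target * np.log(np.clip(sig, eps, 1.0))
        + (1.0 - target) * np.log(np.clip(1.0 - sig, eps, 1.0))
    )
    loss = float(per.mean())
    g = (sig * (1.0 + (pos_weight - 1.0) * target) - pos_weight * target) / (n * n)
    dz = 2.0 * (g @ z)  # g symmetric since target and sigma(x) are
    return loss, dz


def _contrastive_grad(z, pairs, labels, margin):
    """Mean contrastive loss over pairs; returns (loss, dL/dZ)."""
    m = len(pairs)
    diff = z[pairs[:, 0]] - z[pairs[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    hinge = np.maximum(0.0, margin - d)
    vals = 0.5 * (labels * d**2 + (1.0 - labels) * hinge**2)
    loss = float(vals.mean())
    # d(0.5 d^2)/dzi = diff ; d(0.5 (m-d)^2)/dzi = -(m-d)/d * diff (0 at d=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_coef = np.where(d > 0, -hinge / d, 0.0)
    coef = (labels + (1.0 - labels) * neg_coef)[:, None] / m
    dz = np.zeros_like(z)
    np.add.at(dz, pairs[:, 0], coef * diff)
    np.add.at(dz, pairs[:, 1], -coef * diff)
    return loss, dz


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        for w, g, m, v in zip(weights, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(g: Graph, config: ModelConfig, split: EdgeSplit | None = None) -> TrainResult:
    """Train the auto-encoder with AP-based model selection.

    Validation and blind-test edges (and their sampled negatives) are masked
    out of the adjacency the encoder sees, so the reported test AP/AUC
    measure genuine link prediction.  The embedding snapshot from the epoch
    (and restart) with the highest validation AP is returned, together with
    validation and test metrics at that epoch and the decoded probability
    matrix.

    With ``score_mode="auto"`` held-out pairs are scored both by the decoder
    probability and by the negated embedding distance, and the scorer with
    the higher validation AP is kept — low-dimensional (3D) embeddings
    usually rank edges better by distance.  ``restarts`` reruns training
    from different weight initializations (same edge split) and keeps the
    restart with the best validation AP; one restart is enough for wide
    embeddings, while 3D models are hard to train and benefit from a few.
    """
    if split is None:
        split = split_edges(g, seed=np.random.default_rng(config.seed))

    # Mask held-out positive edges from the training adjacency.
    a_train = g.adjacency.copy()
    for pairs in (split.val_pos, split.test_pos):
        a_train[pairs[:, 0], pairs[:, 1]] = 0.0
        a_train[pairs[:, 1], pairs[:, 0]] = 0.0
    s_norm = encoder_input(a_train, self_loops=config.self_loops)
    target = (a_train > 0).astype(float)
    n = g.n
    n_pos = target.sum()
    pos_weight = (n * n - n_pos) / n_pos if n_pos > 0 else 1.0

    use_contrastive = config.loss == "bce_plus_contrastive"
    if use_contrastive:
        # Negative pool for contrastive sampling: pairs absent from the graph.
        ii, jj = np.nonzero(np.triu(1.0 - g.adjacency, k=1))
        neg_pool = np.column_stack([ii, jj])

    if config.score_mode == "auto":
        modes = ("decoder", "distance")
    else:
        modes = (config.score_mode,)

    chosen = None  # best-validation-AP snapshot across restarts

    for restart in range(config.restarts):
        rng = np.random.default_rng(config.seed + 7919 * restart)
        weights = init_weights(n, config, rng)
        opt = _Adam([w.shape for w in weights], config.learning_rate)
        train_losses: list[float] = []
        best = {"ap": -np.inf}

        def evaluate(z, epoch):
            ap_by_mode = {}
            for mode in modes:
                sp = _pair_scores(z, split.val_pos, mode)
                sn = _pair_scores(z, split.val_neg, mode)
                ap_by_mode[mode] = ap_auc(sp, sn)
            mode = max(ap_by_mode, key=lambda m: ap_by_mode[m][0])
            ap, auc = ap_by_mode[mode]
            if ap > best["ap"]:
                best.update(
                    ap=ap, auc=auc, epoch=epoch, mode=mode, z=z.copy(),
                    weights=[w.copy() for w in weights],
                    n_losses=len(train_losses),
                )
                return True
            return False

        z, _ = _forward(s_norm, weights, config)
        evaluate(z, 0)
        since_improve = 0
        for epoch in range(1, config.epochs + 1):
            z, h = _forward(s_norm, weights, config)
            loss, dz = _bce_full_grad(z, target, pos_weight)
            if use_contrastive:
                tp = split.train_pos
                k = min(len(tp), len(neg_pool))
                pick = rng.choice(len(neg_pool), size=k, replace=False)
                pairs = np.vstack([tp, neg_pool[pick]])
                labels = np.concatenate([np.ones(len(tp)), np.zeros(k)])
                closs, cdz = _contrastive_grad(z, pairs, labels, config.margin)
                loss += config.k_contrast * closs
                dz = dz + config.k_contrast * cdz
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            grads = _backward(s_norm, weights, config, h, dz)
            opt.step(weights, grads)
            train_losses.append(loss)

            z_eval, _ = _forward(s_norm, weights, config)
            if evaluate(z_eval, epoch):
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.patience:
                    break

        best["final_weights"] = [w.copy() for w in weights]
        best["losses"] = train_losses
        if chosen is None or best["ap"] > chosen["ap"]:
            chosen = best

    z_best = chosen["z"]
    sp = _pair_scores(z_best, split.test_pos, chosen["mode"])
    sn = _pair_scores(z_best, split.test_neg, chosen["mode"])
    test_ap, test_auc = ap_auc(sp, sn)
    return TrainResult(
        best_embedding=z_best,
        best_epoch=chosen["epoch"],
        val_ap=chosen["ap"],
        val_auc=chosen["auc"],
        test_ap=test_ap,
        test_auc=test_auc,
        reconstructed=decode(z_best),
        score_mode=chosen["mode"],
        best_weights=chosen["weights"],
        final_weights=chosen["final_weights"],
        train_losses=chosen["losses"],
    )
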