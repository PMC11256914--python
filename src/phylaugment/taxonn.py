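"""Phylum-stratified, correlation-ordered CNN ensemble for disease prediction.

The predictor exploits two structural properties of OTU tables.  First,
OTUs sharing a phylum are biologically related, so the feature vector is
partitioned into per-phylum clusters and each cluster gets its own small
1-D CNN.  Second, a CNN assumes neighbouring inputs are related, which
raw OTU order does not provide; within each cluster the OTUs are
therefore re-ordered by a cumulative correlation coefficient — the
geometric mean of the absolute Spearman correlations of an OTU with all
cluster members — sorted in decreasing order, so highly inter-correlated
OTUs become neighbours before convolution.

Per-cluster feature maps are flattened, concatenated, and passed through
a single fully connected layer with a 2-class softmax; training minimises
a class-weighted cross-entropy so imbalanced cohorts do not bias the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._nn import (
    MLP,
    act_backward,
    act_forward,
    conv1d_backward,
    conv1d_forward,
    conv1d_init,
    dense_backward,
    dense_forward,
    dense_init,
    maxpool1d_backward,
    maxpool1d_forward,
)
from .otu_io import OtuTable, TaxonomyMap
from .subspace_ae import LatentDataset

__all__ = [
    "PhylumPartition",
    "ClusterOrdering",
    "TaxonnConfig",
    "EnsembleModel",
    "assign_phylum_clusters",
    "spearman_matrix",
    "cumulative_correlation",
    "order_features",
    "weighted_cross_entropy",
    "default_class_weights",
    "prepare_blocks",
    "train_ensemble",
    "predict_proba",
    "integrated_gradients",
    "TaxonnClassifier",
]


# ---------------------------------------------------------------------------
# stratification


@dataclass
class PhylumPartition:
    """Disjoint assignment of OTU indices to named phylum clusters."""

    clusters: list[tuple[str, np.ndarray]]
    overflow: np.ndarray

    def all_indices(self) -> np.ndarray:
        parts = [idx for _, idx in self.clusters] + [self.overflow]
        return np.concatenate([np.asarray(p, dtype=int) for p in parts])


@dataclass
class ClusterOrdering:
    """Per-cluster permutation plus the coefficients that produced it."""

    permutations: list[np.ndarray]
    cumulative_coefficients: list[np.ndarray]


def assign_phylum_clusters(otu_ids: list[str], tax: TaxonomyMap,
                           top_k: int = 3, keep_other: bool = False
                           ) -> PhylumPartition:
    """Cluster OTU indices by phylum, keeping the ``top_k`` largest phyla.

    Remaining OTUs land in the overflow, which becomes an extra "Other"
    cluster when ``keep_other`` is set and is otherwise excluded from the
    model (with a warning).  Ties in phylum size break by phylum name.
    """
    missing = [o for o in otu_ids if o not in tax]
    if missing:
        raise ValueError(f"OTUs missing from taxonomy: {missing[:10]}")
    by_phylum: dict[str, list[int]] = {}
    for i, otu in enumerate(otu_ids):
        by_phylum.setdefault(tax.phylum(otu), []).append(i)
    ranked = sorted(by_phylum, key=lambda ph: (-len(by_phylum[ph]), ph))
    top = ranked[:top_k]
    clusters = [(ph, np.array(by_phylum[ph], dtype=int)) for ph in top]
    overflow = np.array(
        sorted(i for ph in ranked[top_k:] for i in by_phylum[ph]), dtype=int
    )
    if overflow.size and keep_other:
        clusters.append(("Other", overflow))
        overflow = np.array([], dtype=int)
    elif overflow.size:
        warnings.warn(
            f"{overflow.size} OTUs outside the top {top_k} phyla are excluded "
            "from the model (pass keep_other=True to keep them)",
            stacklevel=2,
        )
    return PhylumPartition(clusters=clusters, overflow=overflow)


def spearman_matrix(t: OtuTable | np.ndarray, cluster: np.ndarray) -> np.ndarray:
    """Spearman rank-correlation matrix of the OTUs in one cluster.

    Constant columns get correlation 0 with every other OTU by
    convention (their ranks carry no ordering information), keeping the
    downstream geometric-mean reduction well defined.
    """
    values = t.values if isinstance(t, OtuTable) else np.asarray(t, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    if cluster.size < 1:
        raise ValueError("empty cluster")
    if values.shape[0] < 3:
        raise ValueError("need >= 3 samples for rank correlations")
    sub = values[:, cluster]
    p = sub.shape[1]
    if p == 1:
        return np.ones((1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = stats.spearmanr(sub).statistic
    if p == 2:  # scipy returns a scalar for two columns
        r = float(rho) if np.isfinite(rho) else 0.0
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    constant = np.ptp(sub, axis=0) == 0
    if constant.any():
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def cumulative_correlation(rho: np.ndarray) -> np.ndarray:
    """Geometric mean of absolute correlations per row (self term included).

    Entry j is ``(prod_k |rho_jk|) ** (1/p)``; any exact-zero correlation
    in the row annihilates the product, so uninformative OTUs sort last.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        raise ValueError("empty correlation matrix")
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("correlation matrix must be square")
    a = np.abs(rho)
    p = a.shape[0]
    out = np.zeros(p)
    pos = (a > 0).all(axis=1)
    if pos.any():
        out[pos] = np.exp(np.log(a[pos]).mean(axis=1))
    return out


def order_features(coeffs: np.ndarray) -> np.ndarray:
    """Stable permutation sorting coefficients in non-increasing order."""
    coeffs = np.asarray(coeffs, dtype=float)
    if np.isnan(coeffs).any():
        raise ValueError("NaN cumulative coefficient")
    return np.argsort(-coeffs, kind="stable")


# ---------------------------------------------------------------------------
# losses


def default_class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Weights inversely proportional to class frequency, w0 + w1 = 2."""
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required to derive class weights")
    w0, w1 = 1.0 / n0, 1.0 / n1
    norm = 2.0 / (w0 + w1)
    return w0 * norm, w1 * norm


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           class_weights: tuple[float, float] = (1.0, 1.0)
                           ) -> float:
    """Class-weighted binary cross-entropy on class-1 probabilities."""
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if probs.size == 0:
        raise ValueError("empty batch")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels disagree in length")
    w0, w1 = class_weights
    if w0 <= 0 or w1 <= 0:
        raise ValueError("class weights must be positive")
    p = np.clip(probs, 1e-7, 1.0 - 1e-7)
    terms = w1 * labels * np.log(p) + w0 * (1 - labels) * np.log1p(-p)
    return float(-terms.mean())


# ---------------------------------------------------------------------------
# ensemble model


@dataclass
class TaxonnConfig:
    """CNN-ensemble hyperparameters (reference protocol defaults).

    ``standardize`` z-scores each input feature with training-set
    statistics before convolution.  On by default: raw relative
    abundances have tiny, heavy-tailed magnitudes that leave SGD nearly
    stalled; set it to False to feed abundances to the network directly
    as the reference recipe does.
    """

    epochs: int = 400
    batch_size: int = 5
    lr: float = 0.001
    n_filters: int = 32
    kernel: int = 5
    stride: int = 1
    pool_size: int = 2
    threshold: float = 0.5
    standardize: bool = True
    seed: int = 0


@dataclass
class EnsembleModel:
    """Per-cluster CNN bundles plus the shared merge head.

    ``cluster_indices``/``orderings`` record how a full feature matrix is
    sliced and permuted into blocks, so prediction re-applies the layout
    learned at training time.
    """

    blocks: list[dict]
    merge: dict
    class_weights: tuple[float, float]
    config: TaxonnConfig
    cluster_names: list[str]
    cluster_indices: list[np.ndarray] | None = None
    orderings: list[np.ndarray] | None = None
    block_stats: list[tuple[np.ndarray, np.ndarray]] | None = None
    training_log: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.blocks)


def _block_forward(spec: dict, x: np.ndarray, cfg: TaxonnConfig
                   ) -> tuple[np.ndarray, dict]:
    if spec["kind"] == "dense":
        z, xc = dense_forward(spec["params"], x)
        h, ac = act_forward("relu", z)
        return h, {"xc": xc, "ac": ac}
    conv, windows = conv1d_forward(spec["params"], x, stride=cfg.stride)
    h, rc = act_forward("relu", conv)
    pooled, pc = maxpool1d_forward(h, size=cfg.pool_size)
    flat = pooled.reshape(x.shape[0], -1)
    return flat, {"windows": windows, "rc": rc, "pc": pc,
                  "pooled_shape": pooled.shape, "x_len": x.shape[1]}


def _block_backward(spec: dict, cache: dict, dflat: np.ndarray,
                    cfg: TaxonnConfig) -> tuple[np.ndarray, dict]:
    if spec["kind"] == "dense":
        dz = act_backward("relu", cache["ac"], dflat)
        return dense_backward(spec["params"], cache["xc"], dz)
    dpooled = dflat.reshape(cache["pooled_shape"])
    dh = maxpool1d_backward(cache["pc"], dpooled, size=cfg.pool_size)
    dconv = act_backward("relu", cache["rc"], dh)
    return conv1d_backward(spec["params"], cache["windows"], cache["x_len"],
                           cfg.stride, dconv)


def _feat_width(spec: dict, cfg: TaxonnConfig) -> int:
    """Flattened output width of one block."""
    if spec["kind"] == "dense":
        return cfg.n_filters
    conv_len = (spec["width"] - cfg.kernel) // cfg.stride + 1
    pooled = conv_len // cfg.pool_size if conv_len >= cfg.pool_size else conv_len
    return cfg.n_filters * pooled


def _forward(model: EnsembleModel, blocks: list[np.ndarray]
             ) -> tuple[np.ndarray, list[dict], np.ndarray]:
    feats, caches = [], []
    for spec, x in zip(model.blocks, blocks):
        f, c = _block_forward(spec, x, model.config)
        feats.append(f)
        caches.append(c)
    concat = np.hstack(feats)
    logits, mc = dense_forward(model.merge, concat)
    probs, _ = act_forward("softmax", logits)
    return probs, caches, mc


def _init_model(widths: list[int], names: list[str], cfg: TaxonnConfig,
                class_weights: tuple[float, float],
                rng: np.random.Generator) -> EnsembleModel:
    blocks = []
    for w in widths:
        if w < cfg.kernel:
            warnings.warn(
                f"cluster of width {w} is narrower than the kernel "
                f"({cfg.kernel}); using a dense layer instead of convolution",
                stacklevel=3,
            )
            blocks.append({"kind": "dense", "width": w,
                           "params": dense_init(rng, w, cfg.n_filters)})
        else:
            blocks.append({"kind": "conv", "width": w,
                           "params": conv1d_init(rng, cfg.n_filters, cfg.kernel)})
    # merge-head input width: run a dummy forward
    total = sum(_feat_width(spec, cfg) for spec in blocks)
    merge = dense_init(rng, total, 2, scale=np.sqrt(1.0 / total))
    return EnsembleModel(blocks=blocks, merge=merge,
                         class_weights=class_weights, config=cfg,
                         cluster_names=names)


def train_ensemble(features: list[np.ndarray] | LatentDataset,
                   labels: np.ndarray | None = None,
                   cfg: TaxonnConfig | None = None,
                   class_weights: tuple[float, float] | None = None,
                   cluster_names: list[str] | None = None) -> EnsembleModel:
    """Train the CNN ensemble on per-cluster ordered matrices.

    ``features`` is either a list of (n x p_j) blocks (one per phylum
    cluster, columns already correlation-ordered) or a
    :class:`LatentDataset`, which is treated as a single block with its
    own labels.  Training is SGD on the weighted cross-entropy of the
    softmax output; deterministic for a fixed config seed.
    """
    cfg = cfg or TaxonnConfig()
    if isinstance(features, LatentDataset):
        labels = features.labels if labels is None else labels
        blocks = [features.features]
    else:
        blocks = [np.asarray(b, dtype=float) for b in features]
    if labels is None:
        raise ValueError("labels are required")
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("all blocks must have one row per sample")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need >= 2 samples of each class")
    if class_weights is None:
        class_weights = default_class_weights(labels)
    names = cluster_names or [f"cluster{i}" for i in range(len(blocks))]

    rng = np.random.default_rng(cfg.seed)
    model = _init_model([b.shape[1] for b in blocks], names, cfg,
                        class_weights, rng)
    if cfg.standardize:
        model.block_stats = [(b.mean(axis=0), b.std(axis=0) + 1e-8)
                             for b in blocks]
        blocks = [(b - mu) / sd
                  for b, (mu, sd) in zip(blocks, model.block_stats)]

    w_arr = np.asarray(class_weights)
    onehot = np.eye(2)[labels]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = [b[idx] for b in blocks]
            yb = labels[idx]
            probs, caches, mc = _forward(model, xb)
            losses.append(weighted_cross_entropy(probs[:, 1], yb, class_weights))
            # d loss / d logits for weighted CE on softmax outputs
            dlogits = w_arr[yb][:, None] * (probs - onehot[idx]) / len(idx)
            dconcat, merge_grads = dense_backward(model.merge, mc, dlogits)
            pos = 0
            for spec, cache in zip(model.blocks, caches):
                f_width = _feat_width(spec, cfg)
                _, grads = _block_backward(spec, cache,
                                           dconcat[:, pos:pos + f_width], cfg)
                spec["params"]["W"] -= cfg.lr * grads["W"]
                spec["params"]["b"] -= cfg.lr * grads["b"]
                pos += f_width
            model.merge["W"] -= cfg.lr * merge_grads["W"]
            model.merge["b"] -= cfg.lr * merge_grads["b"]
        model.training_log.append(float(np.mean(losses)))
    return model


def _as_blocks(model: EnsembleModel, features) -> list[np.ndarray]:
    if isinstance(features, LatentDataset):
        features = features.features
    if isinstance(features, list):
        blocks = [np.asarray(b, dtype=float) for b in features]
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if model.cluster_indices is not None:
            blocks = []
            for idx, perm in zip(model.cluster_indices, model.orderings):
                blocks.append(x[:, idx][:, perm])
        else:
            widths = [spec["width"] for spec in model.blocks]
            if x.shape[1] != sum(widths):
                raise ValueError(
                    f"feature width {x.shape[1]} != model layout {sum(widths)}"
                )
            blocks = list(np.split(x, np.cumsum(widths)[:-1], axis=1))
    for spec, b in zip(model.blocks, blocks):
        if b.shape[1] != spec["width"]:
            raise ValueError(
                f"block width {b.shape[1]} != trained width {spec['width']}"
            )
    if model.block_stats is not None:
        blocks = [(b - mu) / sd
                  for b, (mu, sd) in zip(blocks, model.block_stats)]
    return blocks


def predict_proba(model: EnsembleModel, features) -> np.ndarray:
    """Class-1 probability per sample (softmax pair sums to 1)."""
    blocks = _as_blocks(model, features)
    probs, _, _ = _forward(model, blocks)
    return probs[:, 1]


# ---------------------------------------------------------------------------
# attribution


def _input_gradient(model: EnsembleModel, blocks: list[np.ndarray]) -> np.ndarray:
    """d p(class 1) / d input, concatenated across blocks."""
    probs, caches, mc = _forward(model, blocks)
    # f = softmax(logits)[:, 1]; df/dlogits = p1 * (e1 - p)
    p1 = probs[:, 1:2]
    dlogits = p1 * (np.array([0.0, 1.0])[None, :] - probs)
    dconcat, _ = dense_backward(model.merge, mc, dlogits)
    parts, pos = [], 0
    for spec, cache in zip(model.blocks, caches):
        f_width = _feat_width(spec, model.config)
        dx, _ = _block_backward(spec, cache, dconcat[:, pos:pos + f_width],
                                model.config)
        parts.append(dx)
        pos += f_width
    return np.hstack(parts)


def integrated_gradients(model: EnsembleModel, sample: np.ndarray,
                         baseline: np.ndarray | None = None,
                         steps: int = 128) -> np.ndarray:
    """Integrated-gradients attribution of the class-1 probability.

    The path integral from ``baseline`` (default: all-zeros) to the
    sample is approximated with a midpoint Riemann sum over ``steps``
    points; by the completeness property the attributions sum to
    f(sample) - f(baseline) as ``steps`` grows.
    """
    if steps < 8:
        raise ValueError("steps must be >= 8")
    sample = np.asarray(sample, dtype=float).ravel()
    baseline = (np.zeros_like(sample) if baseline is None
                else np.asarray(baseline, dtype=float).ravel())
    if baseline.shape != sample.shape:
        raise ValueError("baseline and sample shapes differ")
    alphas = (np.arange(steps) + 0.5) / steps
    path = baseline[None, :] + alphas[:, None] * (sample - baseline)[None, :]
    blocks = _as_blocks(model, path)
    grads = _input_gradient(model, blocks)  # (steps, width) in block layout
    avg = grads.mean(axis=0)
    # IG is affine-invariant, so attribute in the standardised block
    # coordinates the network actually sees, then map back to input order
    s_blk = np.hstack(_as_blocks(model, sample[None, :]))[0]
    b_blk = np.hstack(_as_blocks(model, baseline[None, :]))[0]
    attr_block = avg * (s_blk - b_blk)
    if model.cluster_indices is not None:
        out = np.zeros_like(sample)
        pos = 0
        for idx, perm in zip(model.cluster_indices, model.orderings):
            w = len(idx)
            out[np.asarray(idx)[perm]] = attr_block[pos:pos + w]
            pos += w
        return out
    return attr_block


# ---------------------------------------------------------------------------
# ordering + sklearn-style wrapper


def prepare_blocks(values: np.ndarray, partition: PhylumPartition
                   ) -> tuple[list[np.ndarray], ClusterOrdering]:
    """Slice a feature matrix into clusters and correlation-order each.

    Returns the ordered blocks and the :class:`ClusterOrdering` (with
    coefficients) needed to re-apply the same layout to new data.
    """
    blocks, perms, coeffs = [], [], []
    for _, idx in partition.clusters:
        rho = spearman_matrix(values, idx)
        cc = cumulative_correlation(rho)
        perm = order_features(cc)
        blocks.append(values[:, idx][:, perm])
        perms.append(perm)
        coeffs.append(cc[perm])
    return blocks, ClusterOrdering(permutations=perms,
                                   cumulative_coefficients=coeffs)


class TaxonnClassifier:
    """Sklearn-style wrapper: stratify, order, train, predict.

    ``partition`` assigns full-matrix column indices to phylum clusters;
    when omitted the whole matrix is one cluster (used for latent
    features, where taxonomy no longer applies).  Ordering permutations
    are learned in :meth:`fit` from training data only.
    """

    def __init__(self, partition: PhylumPartition | None = None,
                 cfg: TaxonnConfig | None = None):
        self.partition = partition
        self.cfg = cfg or TaxonnConfig()
        self.model: EnsembleModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TaxonnClassifier":
        X = np.asarray(X, dtype=float)
        part = self.partition
        if part is None:
            part = PhylumPartition(
                clusters=[("all", np.arange(X.shape[1]))],
                overflow=np.array([], dtype=int),
            )
        blocks, ordering = prepare_blocks(X, part)
        self.model = train_ensemble(
            blocks, np.asarray(y, dtype=int), self.cfg,
            cluster_names=[name for name, _ in part.clusters],
        )
        self.model.cluster_indices = [idx for _, idx in part.clusters]
        self.model.orderings = ordering.permutations
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        p1 = predict_proba(self.model, np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p1, p1])
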