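"""Conditional GAN over relative-abundance vectors.

A generator maps (noise, class label) to a synthetic composition and a
discriminator scores (sample, class label) pairs as real vs generated;
the two are trained adversarially so that, per class, generated samples
become indistinguishable from real ones.  Both nets are small MLPs; the
class label is injected by concatenating its one-hot encoding to the
input of each net (the standard conditional-GAN construction).

The generator head is a softmax, so every generated row is a valid
composition by construction.  A softmax never emits exact zeros, while
real gut tables are ~75% exact zeros; ``sample_synthetic`` therefore
applies a thresholding step (entries below a cutoff are zeroed, the rest
renormalised) so generated tables carry the same kind of sparsity the
evaluation metrics measure.  By default the cutoff is calibrated: it is
the quantile of the generated values matching the sparsity observed in
the GAN's training data (recorded on the model at fit time), the same
analytic zero-calibration idea the synthetic-data simulator uses.  A
fixed numeric cutoff can be supplied instead.

Three numerical choices stabilise adversarial SGD at these data sizes:
the discriminator sees square-root-transformed abundances (a standard
variance stabiliser for proportions — without it most inputs are tiny
and the discriminator barely learns); the generator's output-layer
bias is initialised to the log of the mean training composition so the
generated marginal profile starts at the real mean profile; and
training keeps the checkpoint whose generated Shannon-diversity
distribution best matches the training data (a validation-metric
checkpoint rule, the tabular analogue of FID-based generator selection
— adversarial SGD oscillates, and the final epoch is often not the
best one).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, act_backward, act_forward
from .otu_io import OtuTable

__all__ = [
    "GanConfig",
    "GanModel",
    "generator_forward",
    "discriminator_forward",
    "cgan_loss",
    "train_cgan",
    "sample_synthetic",
]

_CLAMP = 1e-7  # probability clamp before logs


@dataclass
class GanConfig:
    """Conditional-GAN hyperparameters.

    Training defaults (400 epochs, batch 5, SGD at lr 1e-3) follow the
    reference protocol this framework implements; architecture widths are
    this package's declared defaults.
    """

    feature_dim: int
    noise_dim: int = 64
    hidden_dims_g: list[int] = field(default_factory=lambda: [128, 256])
    hidden_dims_d: list[int] = field(default_factory=lambda: [256, 128])
    n_classes: int = 2
    epochs: int = 400
    batch_size: int = 5
    lr: float = 0.001
    d_steps_per_g_step: int = 1
    saturating_g_loss: bool = False
    sparsify_tau: float | str = "auto"
    sparsify_mode: str = "quantile"  # "quantile" | "bernoulli"
    d_input_transform: str = "sqrt"  # "sqrt" | "identity"
    checkpoint_every: int = 2        # epochs between realism checkpoints; 0 = off
    checkpoint_eval_n: int = 400     # generated samples per checkpoint score
    checkpoint_class_weight: float = 0.5  # weight of the class-contrast term
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.n_classes != 2:
            raise ValueError("only binary conditioning (n_classes=2) is supported")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.d_input_transform not in ("sqrt", "identity"):
            raise ValueError("d_input_transform must be 'sqrt' or 'identity'")
        if isinstance(self.sparsify_tau, str) and self.sparsify_tau != "auto":
            raise ValueError("sparsify_tau must be a float or 'auto'")
        if self.sparsify_mode not in ("bernoulli", "quantile"):
            raise ValueError("sparsify_mode must be 'bernoulli' or 'quantile'")


@dataclass
class GanModel:
    """Trained (or freshly initialised) generator/discriminator pair.

    ``train_sparsity`` records the mean per-sample zero fraction of the
    training table; it calibrates the sampling-time sparsifier.
    """

    generator: MLP
    discriminator: MLP
    config: GanConfig
    otu_ids: list[str]
    training_log: list[tuple[float, float]] = field(default_factory=list)
    train_sparsity: float | None = None
    #: per-class additive logit bias (n_classes x feature_dim); initialised to
    #: the per-class log mean profiles so conditioning starts informative
    class_bias: np.ndarray | None = None

    @property
    def generator_params(self) -> dict[str, np.ndarray]:
        return self.generator.param_arrays()

    @property
    def discriminator_params(self) -> dict[str, np.ndarray]:
        return self.discriminator.param_arrays()


def _one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValueError("class labels must be a 1-D vector")
    if not np.isin(labels, np.arange(n_classes)).all():
        raise ValueError(f"class labels must be in {{0..{n_classes - 1}}}")
    return np.eye(n_classes)[labels]


def init_gan(cfg: GanConfig, otu_ids: list[str],
             rng: np.random.Generator) -> GanModel:
    g_dims = [cfg.noise_dim + cfg.n_classes, *cfg.hidden_dims_g, cfg.feature_dim]
    d_dims = [cfg.feature_dim + cfg.n_classes, *cfg.hidden_dims_d, 1]
    # generator head is linear; softmax (plus the class logit bias) is
    # applied in generator_forward
    gen = MLP(g_dims, hidden="leaky_relu", out="linear", rng=rng)
    dis = MLP(d_dims, hidden="leaky_relu", out="sigmoid", rng=rng)
    return GanModel(generator=gen, discriminator=dis, config=cfg,
                    otu_ids=list(otu_ids),
                    class_bias=np.zeros((cfg.n_classes, cfg.feature_dim)))


def generator_forward(model: GanModel, noise: np.ndarray,
                      class_labels: np.ndarray) -> np.ndarray:
    """Map a noise batch plus class labels to compositions (rows sum to 1)."""
    noise = np.atleast_2d(np.asarray(noise, dtype=float))
    if noise.shape[1] != model.config.noise_dim:
        raise ValueError(
            f"noise width {noise.shape[1]} != noise_dim {model.config.noise_dim}"
        )
    onehot = _one_hot(class_labels, model.config.n_classes)
    if onehot.shape[0] != noise.shape[0]:
        raise ValueError("noise batch and class labels disagree in length")
    logits = model.generator(np.hstack([noise, onehot]))
    if model.class_bias is not None:
        logits = logits + onehot @ model.class_bias
    return act_forward("softmax", logits)[0]


def _d_transform(cfg: GanConfig, x: np.ndarray) -> np.ndarray:
    return np.sqrt(x) if cfg.d_input_transform == "sqrt" else x


def discriminator_forward(model: GanModel, x: np.ndarray,
                          class_labels: np.ndarray) -> np.ndarray:
    """Probability that each (sample, label) pair is real."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    onehot = _one_hot(class_labels, model.config.n_classes)
    xt = _d_transform(model.config, x)
    return model.discriminator(np.hstack([xt, onehot]))[:, 0]


def cgan_loss(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """Adversarial objectives from discriminator probabilities.

    ``d_objective`` = mean log D(real) + mean log(1 - D(fake)), which the
    discriminator maximises; ``g_objective`` = mean log(1 - D(fake)),
    which the generator minimises.  Probabilities are clamped at 1e-7
    before the logs.
    """
    d_real = np.asarray(d_real, dtype=float).ravel()
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability batch")
    d_real = np.clip(d_real, _CLAMP, 1.0 - _CLAMP)
    d_fake = np.clip(d_fake, _CLAMP, 1.0 - _CLAMP)
    d_obj = float(np.mean(np.log(d_real)) + np.mean(np.log1p(-d_fake)))
    g_obj = float(np.mean(np.log1p(-d_fake)))
    return d_obj, g_obj


# ---------------------------------------------------------------------------
# training


def _shannon_rows(v: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(v > 0, v * np.log(v), 0.0)
    return -terms.sum(axis=1)


def _realism_score(model: "GanModel", eval_noise: np.ndarray,
                   eval_labels: np.ndarray, sh_real: np.ndarray,
                   train_sparsity: float,
                   class_diff_real: np.ndarray | None,
                   eval_uniforms: np.ndarray | None = None) -> float:
    """Checkpoint-selection score; lower is better.

    Two terms: |z| of the rank-sum statistic comparing generated vs
    training per-sample Shannon indices (marginal realism), plus the
    relative L2 mismatch between the generated and real case-minus-
    control mean sqrt-profiles (conditional fidelity — a conditional
    generator that loses the class contrast is useless for
    augmentation).  Generated samples are sparsified with the calibrated
    cutoff first, so the score evaluates exactly what
    ``sample_synthetic`` will emit.
    """
    x = generator_forward(model, eval_noise, eval_labels)
    if model.config.sparsify_mode == "bernoulli" and eval_uniforms is not None:
        xs = bernoulli_sparsify(x, train_sparsity, eval_uniforms)
    else:
        tau = float(np.quantile(x, train_sparsity))
        xs = sparsify_rows(x.copy(), tau) if tau > 0 else x
    sh_gen = _shannon_rows(xs)
    n1, n2 = sh_real.size, sh_gen.size
    ranks = np.argsort(np.argsort(np.concatenate([sh_real, sh_gen]))) + 1.0
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    score = abs((u - mu) / sd)
    w = model.config.checkpoint_class_weight
    if class_diff_real is not None and w > 0:
        sq = np.sqrt(xs)
        diff_gen = (sq[eval_labels == 1].mean(axis=0)
                    - sq[eval_labels == 0].mean(axis=0))
        denom = np.linalg.norm(class_diff_real) + 1e-12
        score += w * np.linalg.norm(diff_gen - class_diff_real) / denom
    return score


def _d_update(model: GanModel, x_real: np.ndarray, x_fake: np.ndarray,
              onehot: np.ndarray, lr: float) -> tuple[float, float]:
    dis = model.discriminator
    b = x_real.shape[0]
    cfg = model.config
    p_real, cache_r = dis.forward(np.hstack([_d_transform(cfg, x_real), onehot]))
    p_fake, cache_f = dis.forward(np.hstack([_d_transform(cfg, x_fake), onehot]))
    pr = np.clip(p_real, _CLAMP, 1.0 - _CLAMP)
    pf = np.clip(p_fake, _CLAMP, 1.0 - _CLAMP)
    # minimise -[log pr + log(1-pf)]
    _, grads_r = dis.backward(cache_r, -1.0 / (b * pr))
    _, grads_f = dis.backward(cache_f, 1.0 / (b * (1.0 - pf)))
    for p, gr, gf in zip(dis.params, grads_r, grads_f):
        p["W"] -= lr * (gr["W"] + gf["W"])
        p["b"] -= lr * (gr["b"] + gf["b"])
    return cgan_loss(p_real[:, 0], p_fake[:, 0])


def _g_update(model: GanModel, noise: np.ndarray, onehot: np.ndarray,
              lr: float, saturating: bool) -> None:
    gen, dis = model.generator, model.discriminator
    cfg = model.config
    b = noise.shape[0]
    logits, cache_g = gen.forward(np.hstack([noise, onehot]))
    if model.class_bias is not None:
        logits = logits + onehot @ model.class_bias
    x_fake, sm_cache = act_forward("softmax", logits)
    p_fake, cache_d = dis.forward(np.hstack([_d_transform(cfg, x_fake), onehot]))
    pf = np.clip(p_fake, _CLAMP, 1.0 - _CLAMP)
    if saturating:
        dy = -1.0 / (b * (1.0 - pf))   # minimise mean log(1 - D(G(z)))
    else:
        dy = -1.0 / (b * pf)           # minimise -mean log D(G(z))
    dx, _ = dis.backward(cache_d, dy)  # discriminator frozen
    dxf = dx[:, : cfg.feature_dim]
    if cfg.d_input_transform == "sqrt":
        dxf = dxf * 0.5 / np.sqrt(np.maximum(x_fake, 1e-8))
    dlogits = act_backward("softmax", sm_cache, dxf)
    _, grads_g = gen.backward(cache_g, dlogits)
    gen.step(grads_g, lr)
    if model.class_bias is not None:
        model.class_bias -= lr * (onehot.T @ dlogits)


def train_cgan(t: OtuTable, cfg: GanConfig) -> GanModel:
    """Train the conditional GAN on a labelled relative-abundance table.

    Each minibatch applies ``d_steps_per_g_step`` discriminator updates
    followed by one generator update, using plain SGD.  The training log
    records per-epoch means of the two adversarial objectives.
    Deterministic for a fixed config seed.
    """
    if t.mode != "relative":
        raise ValueError("GAN training expects a relative-abundance table")
    if t.labels is None:
        raise ValueError("GAN training requires labels")
    classes = np.unique(t.labels)
    if classes.size < 2:
        raise ValueError("both classes must be present (conditioning undefined)")
    if cfg.feature_dim != t.n_otus:
        raise ValueError(
            f"config feature_dim {cfg.feature_dim} != table n_otus {t.n_otus}"
        )

    rng = np.random.default_rng(cfg.seed)
    model = init_gan(cfg, t.otu_ids, rng)
    # class-bias init: softmax(class_bias[c]) equals the class-c mean
    # training composition, so conditioning starts at the right contrast
    for cls in range(cfg.n_classes):
        profile = t.values[t.labels == cls].mean(axis=0)
        model.class_bias[cls] = np.log(profile + 1e-8)

    x = t.values
    y = t.labels
    n = x.shape[0]
    train_sparsity = float((x == 0).mean())

    # fixed evaluation batch for realism checkpointing
    if cfg.checkpoint_every:
        eval_rng = np.random.default_rng(cfg.seed + 999)
        eval_noise = eval_rng.standard_normal((cfg.checkpoint_eval_n,
                                               cfg.noise_dim))
        eval_labels = np.arange(cfg.checkpoint_eval_n) % 2
        # fixed mask uniforms so checkpoint scores are comparable across epochs
        eval_uniforms = eval_rng.random((cfg.checkpoint_eval_n, cfg.feature_dim))
        sh_real = _shannon_rows(x)
        sq_real = np.sqrt(x)
        class_diff_real = (sq_real[y == 1].mean(axis=0)
                           - sq_real[y == 0].mean(axis=0))
    best_score, best_params = np.inf, None

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        d_objs, g_objs = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            onehot = _one_hot(yb, cfg.n_classes)
            for _ in range(cfg.d_steps_per_g_step):
                noise = rng.standard_normal((len(idx), cfg.noise_dim))
                x_fake = generator_forward(model, noise, yb)
                d_obj, g_obj = _d_update(model, xb, x_fake, onehot, cfg.lr)
            noise = rng.standard_normal((len(idx), cfg.noise_dim))
            _g_update(model, noise, onehot, cfg.lr, cfg.saturating_g_loss)
            d_objs.append(d_obj)
            g_objs.append(g_obj)
        model.training_log.append((float(np.mean(d_objs)), float(np.mean(g_objs))))
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            score = _realism_score(model, eval_noise, eval_labels, sh_real,
                                   train_sparsity, class_diff_real,
                                   eval_uniforms)
            if score < best_score:
                best_score = score
                best_params = (copy.deepcopy(model.generator.params),
                               copy.deepcopy(model.discriminator.params),
                               model.class_bias.copy())
    if best_params is not None:
        (model.generator.params, model.discriminator.params,
         model.class_bias) = best_params
    model.train_sparsity = train_sparsity
    return model


# ---------------------------------------------------------------------------
# sampling


def sparsify_rows(x: np.ndarray, tau: float) -> np.ndarray:
    """Zero entries below ``tau`` and renormalise; keeps >= 1 entry per row."""
    out = np.where(x < tau, 0.0, x)
    dead = ~out.any(axis=1)
    if dead.any():  # keep each dead row's largest entry
        out[dead, np.argmax(x[dead], axis=1)] = x[dead, np.argmax(x[dead], axis=1)]
    return out / out.sum(axis=1, keepdims=True)


def bernoulli_sparsify(x: np.ndarray, zero_fraction: float,
                       uniforms: np.ndarray) -> np.ndarray:
    """Zero entries via a value-independent Bernoulli mask; renormalise.

    ``uniforms`` is a U(0,1) matrix matching ``x``; entries where it falls
    below ``zero_fraction`` are zeroed.  Because the mask ignores entry
    magnitudes, the zero pattern carries no information about the
    underlying composition — matching zero mechanisms in which absence is
    driven by sampling depth rather than by true abundance, and avoiding
    a magnitude-linked presence/absence artifact a threshold rule would
    imprint on generated samples.
    """
    mask = uniforms < zero_fraction
    out = np.where(mask, 0.0, x)
    dead = ~out.any(axis=1)
    if dead.any():
        out[dead, np.argmax(x[dead], axis=1)] = x[dead, np.argmax(x[dead], axis=1)]
    return out / out.sum(axis=1, keepdims=True)


def sample_synthetic(model: GanModel, n_cases: int = 600, n_controls: int = 600,
                     seed: int = 0, sparsify: bool = True) -> OtuTable:
    """Draw labelled synthetic samples from a trained generator.

    Class balance is exact: the requested numbers of cases and controls
    are generated (controls first).  With ``sparsify`` the thresholding
    described in the module docstring is applied so outputs carry exact
    zeros like real tables.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("sample counts must be non-negative")
    n = n_cases + n_controls
    labels = np.concatenate(
        [np.zeros(n_controls, dtype=int), np.ones(n_cases, dtype=int)]
    )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, model.config.noise_dim))
    x = generator_forward(model, noise, labels) if n else np.zeros((0, model.config.feature_dim))
    if sparsify and n:
        target = model.train_sparsity if model.train_sparsity is not None else 0.0
        if model.config.sparsify_mode == "bernoulli":
            if target > 0:
                x = bernoulli_sparsify(x, target,
                                       rng.random((n, model.config.feature_dim)))
        else:
            tau = model.config.sparsify_tau
            if tau == "auto":
                # calibrated cutoff: zero the quantile of generated values
                # that reproduces the training table's zero fraction
                tau = float(np.quantile(x, target)) if target > 0 else 0.0
            if tau > 0:
                x = sparsify_rows(x, tau)
    width = max(4, len(str(max(n, 1))))
    sample_ids = [f"gen{str(i).zfill(width)}" for i in range(n)]
    return OtuTable(values=x, sample_ids=sample_ids, otu_ids=list(model.otu_ids),
                    labels=labels, mode="relative")
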