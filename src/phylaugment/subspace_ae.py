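"""Target-swapped autoencoder mapping real and GAN-generated samples onto
a common latent subspace.

A plain autoencoder reconstructs its input.  Here the reconstruction
target for each real sample is instead a *paired GAN-generated sample of
the same class*: the encoder/decoder are trained to minimise
``||decoder(encoder(real_i)) - generated_pair(i)||^2``.  Because the
decoder must produce generated-like outputs from encodings of real
inputs, the bottleneck representation stops carrying the features that
distinguish the two domains, and encodings of real and generated data
end up in a shared subspace — which is what makes augmenting a real
training set with generated samples effective downstream.

With ``generated = real`` and the identity pairing, the objective is
exactly the standard autoencoder reconstruction loss, a useful sanity
limit exercised in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP
from .otu_io import OtuTable

__all__ = [
    "SubspaceModel",
    "LatentDataset",
    "pair_targets",
    "reconstruction_loss",
    "train_subspace_ae",
    "encode",
    "build_augmented",
]


@dataclass
class SubspaceModel:
    encoder: MLP
    decoder: MLP
    latent_dim: int
    otu_ids: list[str]
    pairing: list[tuple[int, int]]
    #: fixed multiplier applied to encoder inputs; relative abundances
    #: average 1/n_otus, so scaling by n_otus puts them on an O(1) scale
    #: where tanh units actually receive gradient
    input_scale: float = 1.0
    training_log: list[float] = field(default_factory=list)

    @property
    def encoder_params(self) -> dict[str, np.ndarray]:
        return self.encoder.param_arrays()

    @property
    def decoder_params(self) -> dict[str, np.ndarray]:
        return self.decoder.param_arrays()


@dataclass
class LatentDataset:
    """Encoded samples: features (n x latent_dim), labels, per-row origin."""

    features: np.ndarray
    labels: np.ndarray
    origin: np.ndarray  # strings, "real" | "generated"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.origin = np.asarray(self.origin, dtype=object)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("latent features contain NaN/Inf")
        n = self.features.shape[0]
        if self.labels.shape != (n,) or self.origin.shape != (n,):
            raise ValueError("labels/origin length must match feature rows")

    @property
    def latent_dim(self) -> int:
        return self.features.shape[1]


def pair_targets(real: OtuTable, generated: OtuTable,
                 rule: str = "nearest_within_class", seed: int = 0
                 ) -> list[tuple[int, int]]:
    """Assign each real sample a generated target of the same class.

    ``nearest_within_class`` picks the generated sample minimising the
    Euclidean distance on relative abundances (ties broken by lower
    generated index); ``random_within_class`` draws uniformly, seeded.
    """
    if rule not in ("nearest_within_class", "random_within_class"):
        raise ValueError(f"unknown pairing rule {rule!r}")
    if real.otu_ids != generated.otu_ids:
        raise ValueError("real and generated tables must share OTU ids")
    if real.labels is None or generated.labels is None:
        raise ValueError("both tables need labels for class-aware pairing")
    rng = np.random.default_rng(seed)
    pairing: list[tuple[int, int]] = []
    for cls in np.unique(real.labels):
        gen_idx = np.flatnonzero(generated.labels == cls)
        if gen_idx.size == 0:
            raise ValueError(
                f"class {cls} present in real data but absent from generated data"
            )
        real_idx = np.flatnonzero(real.labels == cls)
        if rule == "nearest_within_class":
            # pairwise distances real(cls) x generated(cls)
            diff = real.values[real_idx][:, None, :] - generated.values[gen_idx][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            best = d2.argmin(axis=1)  # argmin takes the first (lowest) index on ties
            pairing.extend(
                (int(ri), int(gen_idx[b])) for ri, b in zip(real_idx, best)
            )
        else:
            picks = rng.choice(gen_idx, size=real_idx.size, replace=True)
            pairing.extend((int(ri), int(g)) for ri, g in zip(real_idx, picks))
    pairing.sort(key=lambda p: p[0])
    return pairing


def reconstruction_loss(reconstructed: np.ndarray,
                        target_generated: np.ndarray) -> float:
    """Squared Euclidean distance between reconstruction and its target."""
    a = np.asarray(reconstructed, dtype=float).ravel()
    b = np.asarray(target_generated, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(d @ d)


def train_subspace_ae(real: OtuTable, generated: OtuTable,
                      pairing: list[tuple[int, int]], latent_dim: int = 32,
                      epochs: int = 200, lr: float = 0.001,
                      batch_size: int = 5, seed: int = 0) -> SubspaceModel:
    """Train the target-swapped autoencoder with SGD.

    Encoder and decoder are symmetric single-hidden-layer MLPs (hidden
    width ``2 * latent_dim``, tanh); the decoder head is a softmax so
    reconstructions stay compositional.  Only real samples are encoder
    inputs during training; their paired generated samples are targets.
    """
    feature_dim = real.n_otus
    if latent_dim < 2:
        raise ValueError("latent_dim must be >= 2")
    if latent_dim >= feature_dim:
        raise ValueError(
            f"latent_dim {latent_dim} must be smaller than feature_dim {feature_dim}"
        )
    covered = sorted(i for i, _ in pairing)
    if covered != list(range(real.n_samples)):
        raise ValueError("pairing must cover every real sample exactly once")

    rng = np.random.default_rng(seed)
    enc = MLP([feature_dim, 2 * latent_dim, latent_dim],
              hidden="tanh", out="linear", rng=rng)
    dec = MLP([latent_dim, 2 * latent_dim, feature_dim],
              hidden="tanh", out="softmax", rng=rng)

    input_scale = float(feature_dim)
    x = real.values * input_scale
    targets = generated.values[[g for _, g in sorted(pairing)]]
    # decoder output-bias init: start at the mean target composition
    dec.params[-1]["b"][:] = np.log(targets.mean(axis=0) + 1e-8)
    n = x.shape[0]
    log: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, tb = x[idx], targets[idx]
            z, cache_e = enc.forward(xb)
            xhat, cache_d = dec.forward(z)
            diff = xhat - tb
            losses.append(float(np.einsum("ij,ij->", diff, diff) / len(idx)))
            dz, grads_d = dec.backward(cache_d, 2.0 * diff / len(idx))
            _, grads_e = enc.backward(cache_e, dz)
            dec.step(grads_d, lr)
            enc.step(grads_e, lr)
        log.append(float(np.mean(losses)))

    return SubspaceModel(encoder=enc, decoder=dec, latent_dim=latent_dim,
                         otu_ids=list(real.otu_ids), pairing=sorted(pairing),
                         input_scale=input_scale, training_log=log)


def encode(model: SubspaceModel, t: OtuTable, origin: str = "real"
           ) -> LatentDataset:
    """Map a table through the trained encoder into the latent subspace."""
    if t.otu_ids != model.otu_ids:
        missing = sorted(set(model.otu_ids) - set(t.otu_ids))
        extra = sorted(set(t.otu_ids) - set(model.otu_ids))
        raise ValueError(
            f"OTU mismatch with training data; missing={missing[:5]}, extra={extra[:5]}"
        )
    if origin not in ("real", "generated"):
        raise ValueError("origin must be 'real' or 'generated'")
    z = model.encoder(t.values * model.input_scale)
    labels = t.labels if t.labels is not None else np.zeros(t.n_samples, dtype=int)
    return LatentDataset(features=z, labels=labels,
                         origin=np.array([origin] * t.n_samples, dtype=object))


def build_augmented(real_latent: LatentDataset,
                    gen_latent: LatentDataset) -> LatentDataset:
    """Stack real and generated latent rows into one augmented dataset."""
    if gen_latent.features.shape[0] == 0:
        return real_latent
    if real_latent.latent_dim != gen_latent.latent_dim:
        raise ValueError(
            f"latent width mismatch: {real_latent.latent_dim} vs {gen_latent.latent_dim}"
        )
    return LatentDataset(
        features=np.vstack([real_latent.features, gen_latent.features]),
        labels=np.concatenate([real_latent.labels, gen_latent.labels]),
        origin=np.concatenate([real_latent.origin, gen_latent.origin]),
    )
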