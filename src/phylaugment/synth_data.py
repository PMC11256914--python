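"""Seeded simulator for case/control gut-microbiome OTU tables.

Real genus-level gut tables are highly sparse (roughly three quarters of
the entries are exact zeros), heavy-tailed (abundance variances are large
relative to means), and correlated in blocks that follow the taxonomy:
OTUs sharing a phylum co-vary more than OTUs in different phyla.  The
simulator reproduces those three features with a zero-inflated log-normal
model:

1. per-OTU log-mean abundances drawn from a normal with the configured
   dispersion (heavy-tailed mean profile);
2. per-sample latent vectors from a multivariate normal whose correlation
   matrix is block-diagonal by phylum (``block_correlation`` inside a
   block, zero across blocks; unit marginal variance);
3. exponentiation and row renormalisation onto the simplex;
4. a planted effect: in case samples the chosen differential OTUs are
   multiplied by ``2**effect_log2fc`` before renormalising;
5. Bernoulli zero-masking with probability ``target_sparsity`` per entry
   (so the expected zero fraction equals the target exactly), followed by
   renormalisation of the surviving entries.

The same seed yields bit-identical output.  Sub-streams for each stage are
spawned deterministically from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu_io import OtuTable, TaxonomyMap

__all__ = ["SimConfig", "simulate_dataset", "planted_effect_check"]

#: three dominant gut phyla used for default cluster structure
_DEFAULT_PHYLA = [("Firmicutes", 50), ("Proteobacteria", 40), ("Actinobacteria", 30)]


@dataclass
class SimConfig:
    """Parameters of the synthetic case/control benchmark.

    Defaults emulate a modest genus-level cohort: 120 OTUs across the
    three dominant phyla, 75% zeros, moderate within-phylum correlation
    and a planted one-log2-fold shift on 10 OTUs in the cases.
    """

    n_cases: int = 100
    n_controls: int = 100
    n_otus: int = 120
    phyla: list[tuple[str, int]] = field(default_factory=lambda: list(_DEFAULT_PHYLA))
    target_sparsity: float = 0.75
    block_correlation: float = 0.5
    n_differential: int = 10
    effect_log2fc: float = 1.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(c for _, c in self.phyla) != self.n_otus:
            raise ValueError(
                f"phyla OTU counts sum to {sum(c for _, c in self.phyla)}, "
                f"expected n_otus={self.n_otus}"
            )
        if not 0 < self.target_sparsity < 1:
            raise ValueError("target_sparsity must lie in (0, 1)")
        if self.target_sparsity >= 1.0 - 1.0 / self.n_otus:
            raise ValueError(
                f"target_sparsity={self.target_sparsity} infeasible for "
                f"{self.n_otus} OTUs (would leave <1 nonzero OTU per sample)"
            )
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.n_differential > self.n_otus:
            raise ValueError("n_differential exceeds n_otus")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _phylum_blocks(cfg: SimConfig) -> list[tuple[str, np.ndarray]]:
    blocks, start = [], 0
    for name, count in cfg.phyla:
        blocks.append((name, np.arange(start, start + count)))
        start += count
    return blocks


def _block_latents(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Correlated latent matrix via the one-factor-per-block construction.

    Inside a block, z = sqrt(r)*shared + sqrt(1-r)*own gives unit variance
    and pairwise correlation exactly r; across blocks correlation is 0.
    """
    z = np.empty((n, cfg.n_otus))
    r = cfg.block_correlation
    for _, idx in _phylum_blocks(cfg):
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, idx.size))
        z[:, idx] = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
    return z


def simulate_dataset(cfg: SimConfig) -> tuple[OtuTable, TaxonomyMap, list[str]]:
    """Simulate a labelled relative-abundance table plus taxonomy and truth.

    Returns the table (mode=relative, labels attached, controls first),
    a taxonomy map assigning each OTU its phylum block, and the ids of
    the planted differential OTUs.
    """
    root = np.random.default_rng(cfg.seed)
    rng_means, rng_latent, rng_truth, rng_mask = root.spawn(4)

    n = cfg.n_cases + cfg.n_controls
    labels = np.concatenate(
        [np.zeros(cfg.n_controls, dtype=int), np.ones(cfg.n_cases, dtype=int)]
    )

    log_mu = rng_means.normal(0.0, cfg.dispersion, size=cfg.n_otus)
    latent = _block_latents(cfg, n, rng_latent)
    log_abund = log_mu[None, :] + latent

    diff_idx = np.sort(
        rng_truth.choice(cfg.n_otus, size=cfg.n_differential, replace=False)
    )
    log_abund[np.ix_(labels == 1, diff_idx)] += cfg.effect_log2fc * np.log(2.0)

    abund = np.exp(log_abund)
    abund /= abund.sum(axis=1, keepdims=True)

    # Bernoulli zero-mask: each entry zeroed with p = target_sparsity
    mask = rng_mask.random(abund.shape) < cfg.target_sparsity
    # guard against all-zero rows: keep the largest entry of such rows
    dead = mask.all(axis=1)
    if dead.any():
        mask[dead, np.argmax(abund[dead], axis=1)] = False
    abund = np.where(mask, 0.0, abund)
    abund /= abund.sum(axis=1, keepdims=True)

    width = len(str(cfg.n_otus))
    otu_ids = [f"otu{str(i).zfill(width)}" for i in range(cfg.n_otus)]
    sample_ids = [f"s{str(i).zfill(len(str(n)))}" for i in range(n)]

    entries = {}
    for phylum, idx in _phylum_blocks(cfg):
        for i in idx:
            entries[otu_ids[i]] = {
                "kingdom": "Bacteria",
                "phylum": phylum,
                "genus": f"genus_{i}",
            }
    tax = TaxonomyMap(entries=entries)

    table = OtuTable(
        values=abund,
        sample_ids=sample_ids,
        otu_ids=otu_ids,
        labels=labels,
        mode="relative",
    )
    truth = [otu_ids[i] for i in diff_idx]
    return table, tax, truth


def planted_effect_check(t: OtuTable, truth: list[str]) -> pd.Series:
    """Per-OTU log ratio of mean case to mean control abundance.

    Returns ``log((mean_case + eps) / (mean_control + eps))`` per OTU
    (eps = 1e-8), indexed by OTU id — a quick oracle for whether planted
    differential OTUs actually shifted.
    """
    if t.labels is None:
        raise ValueError("table has no labels")
    missing = set(truth) - set(t.otu_ids)
    if missing:
        raise ValueError(f"truth OTUs absent from table: {sorted(missing)}")
    eps = 1e-8
    case_mean = t.values[t.labels == 1].mean(axis=0)
    ctrl_mean = t.values[t.labels == 0].mean(axis=0)
    ratio = np.log((case_mean + eps) / (ctrl_mean + eps))
    return pd.Series(ratio, index=t.otu_ids, name="log_case_control_ratio")
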