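"""End-to-end orchestration: simulate/read -> GAN -> harmonize -> predict.

The full run produces, under a run directory: the generated table, the
trained model files, a ``report.json`` with a realism block (sparsity +
diversity comparison of real vs generated) and a metrics block (CV AUC
distribution with percentile CI, held-out test metrics), and a manifest
recording the config hash and seed so a rerun with the same config is
bit-identical (modulo timestamps).

Model persistence is a single-file ``.npz`` per model with a JSON
metadata header carrying a format version, a model-type tag and a
checksum of the feature (OTU id) set; loading refuses version, type or
checksum mismatches.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import cgan, eval_metrics, otu_io, subspace_ae, taxonn
from .otu_io import OtuTable
from .synth_data import SimConfig, simulate_dataset

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "transfer_augment",
    "save_model",
    "load_model",
    "close_subcomposition",
]

_FORMAT_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# configuration


_DEFAULTS: dict = {
    "seed": 0,
    "feature_space": "latent",   # latent | otu
    "top_k_phyla": 3,
    "keep_other": False,
    "sim": {},                   # SimConfig overrides; ignored when paths given
    "gan": {"epochs": 400, "batch_size": 5, "lr": 0.001, "noise_dim": 64},
    "generate": {"n_cases": 600, "n_controls": 600},
    "ae": {"latent_dim": 16, "epochs": 200, "lr": 0.001, "batch_size": 5,
           "rule": "nearest_within_class"},
    "cnn": {"epochs": 400, "batch_size": 5, "lr": 0.001, "n_filters": 32,
            "kernel": 5, "stride": 1},
    "eval": {"test_fraction": 0.3, "n_repeats": 10, "n_folds": 10},
    "paths": {},                 # table / taxonomy / labels, optional
}


class PipelineConfig(dict):
    """Nested dict of stage configs with defaults merged in."""

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "PipelineConfig":
        def merge(base, over):
            out = dict(base)
            for k, v in (over or {}).items():
                out[k] = merge(base[k], v) if isinstance(base.get(k), dict) else v
            return out
        return cls(merge(_DEFAULTS, overrides or {}))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# serialization


def _otu_checksum(otu_ids: list[str]) -> str:
    return hashlib.sha256("\n".join(otu_ids).encode()).hexdigest()[:16]


def save_model(model, path: str) -> None:
    """Serialise a GAN, autoencoder or ensemble model to one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, cgan.GanModel):
        meta = {"type": "gan", "config": model.config.__dict__.copy(),
                "otu_ids": model.otu_ids,
                "g_dims": model.generator.dims, "d_dims": model.discriminator.dims,
                "checksum": _otu_checksum(model.otu_ids)}
        meta["train_sparsity"] = model.train_sparsity
        for k, v in model.generator.param_arrays().items():
            arrays[f"g_{k}"] = v
        for k, v in model.discriminator.param_arrays().items():
            arrays[f"d_{k}"] = v
        if model.class_bias is not None:
            arrays["class_bias"] = model.class_bias
        arrays["training_log"] = np.asarray(model.training_log, dtype=float)
    elif isinstance(model, subspace_ae.SubspaceModel):
        meta = {"type": "subspace_ae", "latent_dim": model.latent_dim,
                "input_scale": model.input_scale,
                "otu_ids": model.otu_ids, "pairing": model.pairing,
                "e_dims": model.encoder.dims, "d_dims": model.decoder.dims,
                "checksum": _otu_checksum(model.otu_ids)}
        for k, v in model.encoder.param_arrays().items():
            arrays[f"e_{k}"] = v
        for k, v in model.decoder.param_arrays().items():
            arrays[f"d_{k}"] = v
        arrays["training_log"] = np.asarray(model.training_log, dtype=float)
    elif isinstance(model, taxonn.EnsembleModel):
        meta = {"type": "ensemble", "config": model.config.__dict__.copy(),
                "class_weights": list(model.class_weights),
                "cluster_names": model.cluster_names,
                "kinds": [b["kind"] for b in model.blocks],
                "widths": [b["width"] for b in model.blocks],
                "has_layout": model.cluster_indices is not None,
                "checksum": "-"}
        for i, b in enumerate(model.blocks):
            arrays[f"blk{i}_W"] = b["params"]["W"]
            arrays[f"blk{i}_b"] = b["params"]["b"]
        arrays["merge_W"] = model.merge["W"]
        arrays["merge_b"] = model.merge["b"]
        if model.cluster_indices is not None:
            for i, (idx, perm) in enumerate(
                    zip(model.cluster_indices, model.orderings)):
                arrays[f"idx{i}"] = np.asarray(idx, dtype=int)
                arrays[f"perm{i}"] = np.asarray(perm, dtype=int)
        meta["has_stats"] = model.block_stats is not None
        if model.block_stats is not None:
            for i, (mu, sd) in enumerate(model.block_stats):
                arrays[f"stat{i}_mu"] = mu
                arrays[f"stat{i}_sd"] = sd
        arrays["training_log"] = np.asarray(model.training_log, dtype=float)
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    meta["format_version"] = _FORMAT_VERSION
    arrays["_meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ).copy()
    np.savez(path, **arrays)


def load_model(path: str, expect: str | None = None):
    """Load a serialised model; validates version, type tag and checksum."""
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["_meta"]).decode())
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')} "
            f"!= supported {_FORMAT_VERSION}"
        )
    kind = meta["type"]
    if expect is not None and kind != expect:
        raise ValueError(f"expected a {expect} model, file contains {kind}")
    if kind == "gan":
        if _otu_checksum(meta["otu_ids"]) != meta["checksum"]:
            raise ValueError("feature checksum mismatch: corrupt model file")
        cfg = cgan.GanConfig(**meta["config"])
        from ._nn import MLP
        gen = MLP.from_arrays(meta["g_dims"], "leaky_relu", "linear",
                              {k[2:]: data[k] for k in data if k.startswith("g_")})
        dis = MLP.from_arrays(meta["d_dims"], "leaky_relu", "sigmoid",
                              {k[2:]: data[k] for k in data if k.startswith("d_")})
        return cgan.GanModel(generator=gen, discriminator=dis, config=cfg,
                             otu_ids=list(meta["otu_ids"]),
                             training_log=[tuple(t) for t in
                                           data["training_log"].tolist()],
                             train_sparsity=meta.get("train_sparsity"),
                             class_bias=(data["class_bias"]
                                         if "class_bias" in data else None))
    if kind == "subspace_ae":
        if _otu_checksum(meta["otu_ids"]) != meta["checksum"]:
            raise ValueError("feature checksum mismatch: corrupt model file")
        from ._nn import MLP
        enc = MLP.from_arrays(meta["e_dims"], "tanh", "linear",
                              {k[2:]: data[k] for k in data if k.startswith("e_")})
        dec = MLP.from_arrays(meta["d_dims"], "tanh", "softmax",
                              {k[2:]: data[k] for k in data if k.startswith("d_")})
        return subspace_ae.SubspaceModel(
            encoder=enc, decoder=dec, latent_dim=meta["latent_dim"],
            otu_ids=list(meta["otu_ids"]),
            pairing=[tuple(p) for p in meta["pairing"]],
            input_scale=meta.get("input_scale", 1.0),
            training_log=data["training_log"].tolist())
    if kind == "ensemble":
        cfg = taxonn.TaxonnConfig(**meta["config"])
        blocks = [
            {"kind": k, "width": w,
             "params": {"W": data[f"blk{i}_W"], "b": data[f"blk{i}_b"]}}
            for i, (k, w) in enumerate(zip(meta["kinds"], meta["widths"]))
        ]
        model = taxonn.EnsembleModel(
            blocks=blocks,
            merge={"W": data["merge_W"], "b": data["merge_b"]},
            class_weights=tuple(meta["class_weights"]), config=cfg,
            cluster_names=list(meta["cluster_names"]),
            training_log=data["training_log"].tolist())
        if meta["has_layout"]:
            model.cluster_indices = [data[f"idx{i}"] for i in range(len(blocks))]
            model.orderings = [data[f"perm{i}"] for i in range(len(blocks))]
        if meta.get("has_stats"):
            model.block_stats = [
                (data[f"stat{i}_mu"], data[f"stat{i}_sd"])
                for i in range(len(blocks))
            ]
        return model
    raise ValueError(f"unknown model type tag {kind!r}")


# ---------------------------------------------------------------------------
# transfer learning


def transfer_augment(gan_model, new_table: OtuTable, n_cases: int,
                     n_controls: int, seed: int = 0) -> OtuTable:
    """Augment a new cohort with samples from a frozen, pre-trained GAN.

    The new cohort must share the GAN's OTU set exactly (order may
    differ; generated columns are re-aligned to the new table's order) —
    transferred generators are only meaningful when both cohorts were
    processed by the same upstream pipeline, and a feature-set mismatch
    is rejected with the symmetric difference listed.
    """
    if isinstance(gan_model, (str, Path)):
        gan_model = load_model(str(gan_model), expect="gan")
    model_set, table_set = set(gan_model.otu_ids), set(new_table.otu_ids)
    if model_set != table_set:
        missing = sorted(model_set - table_set)
        extra = sorted(table_set - model_set)
        raise ValueError(
            "OTU set mismatch between the trained GAN and the new cohort "
            f"(same-sequencing-pipeline requirement); missing from cohort: "
            f"{missing[:10]}, absent from model: {extra[:10]}"
        )
    gen = cgan.sample_synthetic(gan_model, n_cases=n_cases,
                                n_controls=n_controls, seed=seed)
    col = [gen.otu_ids.index(o) for o in new_table.otu_ids]
    return OtuTable(values=gen.values[:, col], sample_ids=list(gen.sample_ids),
                    otu_ids=list(new_table.otu_ids), labels=gen.labels,
                    mode="relative")


# ---------------------------------------------------------------------------
# latent harmonisation helpers


def close_subcomposition(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Renormalise the columns ``idx`` to a subcomposition summing to 1.

    All-zero rows fall back to the uniform composition so the closure is
    always defined.
    """
    sub = values[:, idx]
    sums = sub.sum(axis=1, keepdims=True)
    out = np.divide(sub, sums, out=np.full_like(sub, 1.0 / sub.shape[1]),
                    where=sums > 0)
    return out


def harmonize_per_cluster(real: OtuTable, generated: OtuTable,
                          partition: taxonn.PhylumPartition,
                          latent_dim: int = 16, epochs: int = 200,
                          lr: float = 0.001, batch_size: int = 5,
                          rule: str = "nearest_within_class", seed: int = 0
                          ) -> tuple[list, list[np.ndarray], list[np.ndarray]]:
    """Train one subspace autoencoder per phylum cluster.

    Each cluster's columns are closed to a subcomposition, an AE is
    trained with GAN-generated targets, and both tables are encoded.
    Returns the AE models plus the per-cluster latent blocks for the
    real and the generated table.
    """
    models, real_blocks, gen_blocks = [], [], []
    for k, (name, idx) in enumerate(partition.clusters):
        dim = min(latent_dim, max(2, idx.size - 1))
        sub_real = OtuTable(values=close_subcomposition(real.values, idx),
                            sample_ids=list(real.sample_ids),
                            otu_ids=[real.otu_ids[i] for i in idx],
                            labels=real.labels, mode="relative")
        sub_gen = OtuTable(values=close_subcomposition(generated.values, idx),
                           sample_ids=list(generated.sample_ids),
                           otu_ids=[generated.otu_ids[i] for i in idx],
                           labels=generated.labels, mode="relative")
        pairing = subspace_ae.pair_targets(sub_real, sub_gen, rule=rule,
                                           seed=seed + k)
        model = subspace_ae.train_subspace_ae(
            sub_real, sub_gen, pairing, latent_dim=dim, epochs=epochs,
            lr=lr, batch_size=batch_size, seed=seed + k)
        models.append(model)
        real_blocks.append(subspace_ae.encode(model, sub_real, "real").features)
        gen_blocks.append(subspace_ae.encode(model, sub_gen, "generated").features)
    return models, real_blocks, gen_blocks


# ---------------------------------------------------------------------------
# full pipeline


def _order_latent_blocks(blocks: list[np.ndarray]
                         ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Correlation-order latent blocks with the same machinery as OTUs."""
    perms = []
    ordered = []
    for b in blocks:
        rho = taxonn.spearman_matrix(b, np.arange(b.shape[1]))
        perm = taxonn.order_features(taxonn.cumulative_correlation(rho))
        perms.append(perm)
        ordered.append(b[:, perm])
    return ordered, perms


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict:
    """Execute simulate/read -> GAN -> generate -> harmonize -> classify -> evaluate.

    Writes every artifact plus ``report.json`` and ``manifest.json`` under
    ``out_dir`` and returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"stages": []}
    stage = "otu_io"
    try:
        # -- data -----------------------------------------------------
        paths = cfg["paths"]
        if paths.get("table"):
            table = otu_io.read_otu_table(paths["table"],
                                          label_column=paths.get("label_column"))
            if table.labels is None and paths.get("labels"):
                lab = otu_io.read_labels(paths["labels"])
                table = table.with_labels([lab[s] for s in table.sample_ids])
            if table.mode == "counts":
                table = otu_io.normalize_relative_abundance(table)
            tax = otu_io.read_taxonomy(paths["taxonomy"])
            truth: list[str] = []
        else:
            stage = "synth_data"
            table, tax, truth = simulate_dataset(
                SimConfig(**{"seed": seed, **cfg["sim"]}))
        table, removed = otu_io.filter_all_zero_otus(table)
        report["n_samples"], report["n_otus"] = table.n_samples, table.n_otus
        report["n_all_zero_otus_removed"] = len(removed)
        report["stages"].append(stage)

        # -- split ----------------------------------------------------
        stage = "split"
        idx = np.arange(table.n_samples)
        tr_idx, te_idx, _, _ = eval_metrics.train_test_split(
            idx, table.labels, test_fraction=cfg["eval"]["test_fraction"],
            seed=seed)
        train_t, test_t = table.select_samples(tr_idx), table.select_samples(te_idx)
        report["stages"].append(stage)

        # -- GAN ------------------------------------------------------
        stage = "cgan"
        gan_cfg = cgan.GanConfig(feature_dim=table.n_otus, seed=seed,
                                 **cfg["gan"])
        gan_model = cgan.train_cgan(train_t, gan_cfg)
        save_model(gan_model, str(out / "gan.npz"))
        gen_table = cgan.sample_synthetic(
            gan_model, n_cases=cfg["generate"]["n_cases"],
            n_controls=cfg["generate"]["n_controls"], seed=seed + 1)
        otu_io.write_otu_table(gen_table, str(out / "generated.tsv"),
                               label_column="label")
        report["stages"].append(stage)

        # -- realism block -------------------------------------------
        stage = "eval_metrics"
        sp_real, range_real = eval_metrics.sparsity(train_t)
        sp_gen, range_gen = eval_metrics.sparsity(gen_table)
        sh_real = [eval_metrics.shannon_index(r) for r in train_t.values]
        sh_gen = [eval_metrics.shannon_index(r) for r in gen_table.values]
        report["realism"] = {
            "sparsity_real": sp_real, "sparsity_real_range": range_real,
            "sparsity_generated": sp_gen, "sparsity_generated_range": range_gen,
            "shannon_wilcoxon_p": eval_metrics.compare_distributions(
                sh_real, sh_gen),
        }
        report["stages"].append(stage)

        # -- features -------------------------------------------------
        stage = "subspace_ae" if cfg["feature_space"] == "latent" else "taxonn"
        partition = taxonn.assign_phylum_clusters(
            table.otu_ids, tax, top_k=cfg["top_k_phyla"],
            keep_other=cfg["keep_other"])
        if cfg["feature_space"] == "latent":
            ae_cfg = cfg["ae"]
            models, real_blocks, gen_blocks = harmonize_per_cluster(
                train_t, gen_table, partition,
                latent_dim=ae_cfg["latent_dim"], epochs=ae_cfg["epochs"],
                lr=ae_cfg["lr"], batch_size=ae_cfg["batch_size"],
                rule=ae_cfg["rule"], seed=seed + 2)
            for k, m in enumerate(models):
                save_model(m, str(out / f"ae_cluster{k}.npz"))
            test_blocks = [
                subspace_ae.encode(m, OtuTable(
                    values=close_subcomposition(test_t.values, idx),
                    sample_ids=list(test_t.sample_ids),
                    otu_ids=[test_t.otu_ids[i] for i in idx],
                    labels=test_t.labels, mode="relative"), "real").features
                for m, (_, idx) in zip(models, partition.clusters)
            ]
            train_feats = [np.vstack([r, g])
                           for r, g in zip(real_blocks, gen_blocks)]
            y_train = np.concatenate([train_t.labels, gen_table.labels])
            ordered_train, perms = _order_latent_blocks(train_feats)
            ordered_test = [b[:, p] for b, p in zip(test_blocks, perms)]
        else:
            feats = np.vstack([train_t.values, gen_table.values])
            y_train = np.concatenate([train_t.labels, gen_table.labels])
            train_all, ordering = taxonn.prepare_blocks(feats, partition)
            ordered_train = train_all
            ordered_test = [
                test_t.values[:, idx][:, p]
                for (_, idx), p in zip(partition.clusters,
                                       ordering.permutations)
            ]
        report["stages"].append(stage)

        # -- classifier ----------------------------------------------
        stage = "taxonn"
        cnn_cfg = taxonn.TaxonnConfig(seed=seed + 3, **cfg["cnn"])
        clf = taxonn.train_ensemble(
            ordered_train, y_train, cnn_cfg,
            cluster_names=[n for n, _ in partition.clusters])
        save_model(clf, str(out / "classifier.npz"))
        probs = taxonn.predict_proba(clf, ordered_test)
        test_report = eval_metrics.binary_metrics(probs, test_t.labels,
                                                  threshold=cnn_cfg.threshold)
        report["metrics"] = {
            "test_auc": test_report.auc,
            "test_sensitivity": test_report.sensitivity,
            "test_specificity": test_report.specificity,
            "test_ppv": test_report.ppv,
            "test_npv": test_report.npv,
        }
        report["stages"].append(stage)
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.txt").write_text(f"stage={stage}\n{exc}\n")
        raise StageError(stage, str(exc)) from exc

    manifest = {"config_hash": cfg.content_hash(), "seed": seed,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
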