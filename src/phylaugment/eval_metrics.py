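"""Realism diagnostics for generated tables and CV-based performance metrics.

Two groups of tools live here.  Realism diagnostics compare generated
and real tables on sample-level summaries — sparsity (fraction of exact
zeros per sample), Shannon alpha diversity, Chao1 richness — with a
Wilcoxon rank-sum test on the per-sample distributions.  Performance
evaluation wraps repeated stratified k-fold cross-validation producing
one AUC per fold (10 x 10 folds = 100 AUC values by default), with the
95% CI taken as the empirical 2.5/97.5 percentiles of those values
(linear-interpolation definition).

The cross-validation harness enforces augmentation discipline: any
generative augmentation runs inside each training fold, so generated
samples never leak into a validation fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.model_selection import train_test_split as _sk_split

from .otu_io import OtuTable

__all__ = [
    "MetricsReport",
    "sparsity",
    "shannon_index",
    "chao1_index",
    "compare_distributions",
    "binary_metrics",
    "cross_validate",
    "train_test_split",
]


@dataclass
class MetricsReport:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    n_cv_values: int = 0


# ---------------------------------------------------------------------------
# realism diagnostics


def sparsity(t: OtuTable) -> tuple[float, tuple[float, float]]:
    """Mean per-sample zero fraction and its (min, max) range."""
    if t.n_samples == 0 or t.n_otus == 0:
        raise ValueError("empty table")
    frac = (t.values == 0).mean(axis=1)
    return float(frac.mean()), (float(frac.min()), float(frac.max()))


def shannon_index(sample: np.ndarray) -> float:
    """Shannon alpha diversity -sum(x ln x) over nonzero proportions."""
    x = np.asarray(sample, dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("negative abundance")
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {x.sum():.6f}")
    nz = x[x > 0]
    return float(-(nz * np.log(nz)).sum())


def chao1_index(sample: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    Requires integer counts (F1/F2 are singleton/doubleton counts).  For
    relative data, convert first by multiplying by a sequencing depth and
    rounding.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("negative count")
    if not np.allclose(x, np.round(x), atol=1e-9):
        raise ValueError(
            "Chao1 needs integer counts; convert relative abundances first "
            "(e.g. counts_from_relative with a chosen depth)"
        )
    x = np.round(x).astype(int)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def counts_from_relative(t: OtuTable, depth: int = 10000) -> OtuTable:
    """Scale a relative table to integer counts at a fixed depth (rounded)."""
    if t.mode != "relative":
        raise ValueError("expected a relative-mode table")
    counts = np.round(t.values * depth)
    return OtuTable(values=counts, sample_ids=list(t.sample_ids),
                    otu_ids=list(t.otu_ids),
                    labels=None if t.labels is None else t.labels.copy(),
                    mode="counts")


def compare_distributions(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# performance metrics


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks (tie-corrected)."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def binary_metrics(probs: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5) -> MetricsReport:
    """AUC plus threshold metrics (sensitivity/specificity/PPV/NPV)."""
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return MetricsReport(
        auc=_rank_auc(probs, labels),
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        ppv=_safe_ratio(tp, tp + fp, "PPV"),
        npv=_safe_ratio(tn, tn + fn, "NPV"),
    )


def percentile_ci(values: np.ndarray, level: float = 95.0
                  ) -> tuple[float, float]:
    """Empirical CI via linear-interpolation percentiles."""
    lo, hi = np.percentile(values, [(100 - level) / 2, 100 - (100 - level) / 2],
                           method="linear")
    return float(lo), float(hi)


def cross_validate(
    make_model: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    augment: Callable[[np.ndarray, np.ndarray, int], tuple[np.ndarray, np.ndarray]] | None = None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, MetricsReport]:
    """Repeated stratified k-fold CV producing one AUC per fold.

    ``make_model`` returns a fresh estimator with ``fit``/``predict_proba``
    per fold.  ``augment(X_train, y_train, fold_seed)``, when given, is
    applied to the training portion of each fold only — generated samples
    never reach validation data.  Defaults yield ``n_repeats * n_folds``
    = 100 AUC values; the report's CI is their empirical 95% percentile
    interval, and threshold metrics come from the pooled out-of-fold
    predictions of the first repeat.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} samples per class for {n_folds}-fold CV"
        )
    aucs = []
    first_repeat_probs = np.full(y.size, np.nan)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + rep)
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            X_tr, y_tr = X[tr], y[tr]
            if augment is not None:
                X_tr, y_tr = augment(X_tr, y_tr, seed + rep * n_folds + fold)
            model = make_model()
            model.fit(X_tr, y_tr)
            proba = np.asarray(model.predict_proba(X[va]))
            p1 = proba[:, 1] if proba.ndim == 2 else proba
            aucs.append(_rank_auc(p1, y[va]))
            if rep == 0:
                first_repeat_probs[va] = p1
    aucs = np.asarray(aucs)
    point = binary_metrics(first_repeat_probs, y, threshold=threshold)
    report = MetricsReport(
        auc=float(aucs.mean()),
        sensitivity=point.sensitivity,
        specificity=point.specificity,
        ppv=point.ppv,
        npv=point.npv,
        auc_ci=percentile_ci(aucs),
        n_cv_values=int(aucs.size),
    )
    return aucs, report


def train_test_split(X: np.ndarray, y: np.ndarray,
                     test_fraction: float = 0.3, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified 70/30-style split; returns X_train, X_test, y_train, y_test."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = np.asarray(y, dtype=int)
    X_tr, X_te, y_tr, y_te = _sk_split(
        np.asarray(X), y, test_size=test_fraction, stratify=y, random_state=seed
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        raise ValueError("split left a side with a single class")
    return X_tr, X_te, y_tr, y_te
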