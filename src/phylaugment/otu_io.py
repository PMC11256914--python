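"""Reading, writing and validating OTU abundance tables and taxonomy maps.

An OTU table is a samples x OTUs matrix of non-negative abundances, either
raw counts or relative abundances (rows on the probability simplex).  All
downstream generative and predictive stages in this package operate on
relative abundances; Chao1 richness alone needs counts.

Zeros are kept as exact zeros throughout — sparsity (the per-sample zero
fraction) is a first-class evaluation quantity, so no pseudocounts are ever
added on read or normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_labels",
    "normalize_relative_abundance",
    "filter_all_zero_otus",
    "read_taxonomy",
    "write_taxonomy",
]

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class OtuTableError(ValueError):
    """Raised for malformed tables, taxonomies or label files."""


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix with ids and optional binary labels.

    Parameters
    ----------
    values
        Non-negative float matrix, shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Unique string identifiers for rows and columns.
    labels
        Optional per-sample vector with entries in ``{0, 1}`` (1 = case).
    mode
        ``"counts"`` for raw counts, ``"relative"`` for simplex rows.
    """

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    labels: np.ndarray | None = None
    mode: str = "relative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise OtuTableError(f"values must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise OtuTableError("values contain NaN or Inf")
        if np.any(v < 0):
            raise OtuTableError("values contain negative entries")
        if len(self.sample_ids) != v.shape[0]:
            raise OtuTableError(
                f"{len(self.sample_ids)} sample ids for {v.shape[0]} rows"
            )
        if len(self.otu_ids) != v.shape[1]:
            raise OtuTableError(f"{len(self.otu_ids)} OTU ids for {v.shape[1]} columns")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise OtuTableError(f"duplicate {name} ids: {dupes}")
        if self.mode not in ("counts", "relative"):
            raise OtuTableError(f"unknown mode {self.mode!r}")
        if self.mode == "relative" and v.shape[1] > 0 and v.shape[0] > 0:
            sums = v.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
            if bad.size:
                raise OtuTableError(
                    "relative-mode rows must sum to 1 +/- 1e-6; offending samples: "
                    + ", ".join(self.sample_ids[i] for i in bad[:5])
                )
        if self.labels is not None:
            if self.labels.shape != (v.shape[0],):
                raise OtuTableError("labels length does not match n_samples")
            if not np.isin(self.labels, (0, 1)).all():
                raise OtuTableError("labels must be in {0, 1}")

    def with_labels(self, labels: np.ndarray) -> "OtuTable":
        return replace(self, labels=np.asarray(labels, dtype=int))

    def select_samples(self, idx: np.ndarray) -> "OtuTable":
        idx = np.asarray(idx)
        return OtuTable(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            otu_ids=list(self.otu_ids),
            labels=None if self.labels is None else self.labels[idx],
            mode=self.mode,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class TaxonomyMap:
    """Mapping OTU id -> ordered lineage ranks (kingdom ... genus/species)."""

    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    def phylum(self, otu_id: str) -> str:
        try:
            entry = self.entries[otu_id]
        except KeyError:
            raise OtuTableError(f"OTU {otu_id!r} absent from taxonomy map") from None
        return entry["phylum"]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.entries


# ---------------------------------------------------------------------------
# table reading / writing


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


_LABEL_STRINGS = {"0": 0, "1": 1, "control": 0, "case": 1}


def _coerce_label(raw, context: str) -> int:
    key = str(raw).strip().lower()
    if key not in _LABEL_STRINGS:
        raise OtuTableError(
            f"label {raw!r} in {context} not one of 0/1/control/case"
        )
    return _LABEL_STRINGS[key]


def read_otu_table(
    path: str,
    orientation: str = "samples_rows",
    label_column: str | None = None,
) -> OtuTable:
    """Read a delimited OTU table (comma or tab autodetected).

    The first column holds ids (samples or OTUs depending on
    ``orientation``); the header row holds the other axis's ids.  Mode is
    inferred: an all-integer body is treated as counts, otherwise as
    relative abundances whose rows must sum to 1 (+/- 1e-3; exact
    validation to 1e-6 happens after renormalising tiny drift).
    """
    if orientation not in ("samples_rows", "otus_rows"):
        raise ValueError(f"orientation must be samples_rows|otus_rows, got {orientation!r}")
    sep = _sniff_sep(path)
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header_ids = [h.strip() for h in fh.readline().rstrip("\n").split(sep)[1:]]
    if len(set(header_ids)) != len(header_ids):
        dupes = sorted({h for h in header_ids if header_ids.count(h) > 1})
        raise OtuTableError(f"duplicate ids in header: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)

    labels = None
    if label_column is not None:
        if orientation != "samples_rows":
            raise OtuTableError("label_column requires samples_rows orientation")
        if label_column not in df.columns:
            raise OtuTableError(f"label column {label_column!r} not in header")
        labels = np.array(
            [_coerce_label(v, f"column {label_column!r}") for v in df[label_column]]
        )
        df = df.drop(columns=[label_column])

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise OtuTableError(
                f"non-numeric cell at row {bad!r}, column {col!r}"
            ) from None

    if orientation == "otus_rows":
        values = values.T
        sample_ids, otu_ids = list(df.columns), list(df.index)
    else:
        sample_ids, otu_ids = list(df.index), list(df.columns)

    # counts vs relative: integer body => counts
    is_counts = np.allclose(values, np.round(values), atol=0) and values.max(initial=0) > 1
    if is_counts:
        mode = "counts"
    else:
        mode = "relative"
        sums = values.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-3)
        if bad.size:
            raise OtuTableError(
                "rows of a relative-abundance table must sum to 1 (+/- 1e-3); "
                f"sample {sample_ids[bad[0]]!r} sums to {sums[bad[0]]:.4f}. "
                "If these are counts, normalise with normalize_relative_abundance."
            )
        values = values / sums[:, None]  # absorb <=1e-3 drift

    return OtuTable(values=values, sample_ids=sample_ids, otu_ids=otu_ids,
                    labels=labels, mode=mode)


def write_otu_table(t: OtuTable, path: str, label_column: str | None = None) -> None:
    """Write a table as TSV, samples as rows; optionally append a label column."""
    df = t.to_dataframe()
    if t.mode == "counts":
        df = df.astype(int)
    if label_column is not None:
        if t.labels is None:
            raise OtuTableError("table has no labels to write")
        df[label_column] = t.labels
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_labels(path: str) -> dict[str, int]:
    """Read a two-column sample-id / label file ({0,1} or {control,case})."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise OtuTableError(f"label file must have 2 columns, found {df.shape[1]}")
    out: dict[str, int] = {}
    for sid, raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sid = str(sid).strip()
        if sid.lower() in ("sample_id", "sample"):  # tolerated header
            continue
        if sid in out:
            raise OtuTableError(f"duplicate sample id {sid!r} in label file")
        out[sid] = _coerce_label(raw, f"label file row {sid!r}")
    return out


# ---------------------------------------------------------------------------
# transforms


def normalize_relative_abundance(t: OtuTable) -> OtuTable:
    """Convert a count table to relative abundances (rows sum to 1)."""
    if t.mode != "counts":
        raise OtuTableError("table is already in relative mode")
    sums = t.values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise OtuTableError(
            "cannot normalise all-zero sample(s): "
            + ", ".join(t.sample_ids[i] for i in zero[:5])
        )
    return OtuTable(
        values=t.values / sums[:, None],
        sample_ids=list(t.sample_ids),
        otu_ids=list(t.otu_ids),
        labels=None if t.labels is None else t.labels.copy(),
        mode="relative",
    )


def filter_all_zero_otus(t: OtuTable) -> tuple[OtuTable, list[str]]:
    """Drop OTU columns that are zero in every sample.

    Returns the filtered table (column order preserved) and the removed
    OTU ids in their original order.
    """
    keep = t.values.any(axis=0)
    if not keep.any():
        raise OtuTableError("filtering would remove every OTU")
    removed = [o for o, k in zip(t.otu_ids, keep) if not k]
    if not removed:
        return t, []
    out = OtuTable(
        values=t.values[:, keep],
        sample_ids=list(t.sample_ids),
        otu_ids=[o for o, k in zip(t.otu_ids, keep) if k],
        labels=None if t.labels is None else t.labels.copy(),
        mode=t.mode,
    )
    return out, removed


# ---------------------------------------------------------------------------
# taxonomy


def _parse_lineage(otu_id: str, lineage: str) -> dict[str, str]:
    tokens = [tok.strip() for tok in lineage.split(";") if tok.strip()]
    entry: dict[str, str] = {}
    for i, tok in enumerate(tokens):
        matched = False
        for prefix, rank in zip(_RANK_PREFIXES, _RANK_NAMES):
            if tok.lower().startswith(prefix):
                entry[rank] = tok[len(prefix):].strip()
                matched = True
                break
        if not matched and i < len(_RANK_NAMES):
            # prefix-less lineage: assign by position
            entry.setdefault(_RANK_NAMES[i], tok)
    if not entry.get("phylum"):
        raise OtuTableError(f"lineage for OTU {otu_id!r} lacks a phylum rank: {lineage!r}")
    return entry


def read_taxonomy(path: str) -> TaxonomyMap:
    """Read a two-column OTU-id / lineage file (QIIME-style ranks accepted)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise OtuTableError("taxonomy file must have 2 columns (otu id, lineage)")
    entries: dict[str, dict[str, str]] = {}
    for otu_id, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        otu_id = str(otu_id).strip()
        if otu_id.lower() in ("otu_id", "otu"):  # tolerated header
            continue
        if otu_id in entries:
            raise OtuTableError(f"duplicate OTU id {otu_id!r} in taxonomy")
        entries[otu_id] = _parse_lineage(otu_id, str(lineage))
    return TaxonomyMap(entries=entries)


def write_taxonomy(tax: TaxonomyMap, path: str) -> None:
    with open(path, "w") as fh:
        for otu_id, entry in tax.entries.items():
            lineage = ";".join(
                f"{prefix}{entry[rank]}"
                for prefix, rank in zip(_RANK_PREFIXES, _RANK_NAMES)
                if rank in entry
            )
            fh.write(f"{otu_id}\t{lineage}\n")
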