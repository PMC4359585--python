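"""Reading, filtering and tokenizing OTU tables; model archive serialization.

The on-disk conventions: OTU tables are TSV with a header row of OTU
identifiers and a first column of sample identifiers (samples as rows);
label files are TSV keyed on sample identifier with one or more factor-label
columns. A minimal BIOM v1 (JSON) reader is provided behind the same entry
point. Trained models round-trip through a directory holding a JSON manifest
plus dense numeric arrays.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleLabels",
    "TokenizedDataset",
    "read_otu_table",
    "write_otu_table",
    "read_sample_labels",
    "filter_singleton_otus",
    "filter_high_abundance_otus",
    "tokenize",
    "align_test_table",
    "save_model",
    "load_model",
]

_ARCHIVE_VERSION = 1


@dataclass
class OtuTable:
    """A samples x OTUs table of non-negative integer counts.

    ``counts[n, t]`` is the number of sequences of OTU ``otu_ids[t]`` observed
    in sample ``sample_ids[n]``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match identifier lists")
        for kind, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {kind} identifier: {i!r}")
                seen.add(i)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers (relative abundances are rejected)")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass(frozen=True)
class SampleLabels:
    """The known (allowed) factor values of one sample.

    ``factor_values`` indexes into a shared factor vocabulary of size K; only
    these factors may contribute to the sample during training.
    """

    sample_id: str
    factor_values: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.factor_values) == 0:
            raise ValueError(f"sample {self.sample_id!r} has no factor values")


@dataclass
class TokenizedDataset:
    """Per-sample token lists: one token per count unit, in OTU-index order.

    The Gibbs sampler operates on tokens; abundance enters through token
    multiplicity. ``allowed_factors[n]`` is sample n's supervision set.
    """

    sample_ids: list[str]
    tokens: list[np.ndarray]
    allowed_factors: list[frozenset[int]]
    n_otus: int
    factor_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def tokens_per_sample(self) -> np.ndarray:
        return np.array([len(t) for t in self.tokens], dtype=np.int64)


def _parse_count_frame(df: pd.DataFrame, path, round_counts: bool) -> OtuTable:
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples (header-only table)")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no OTU columns")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(f"{path}: non-numeric count at sample {row!r}, OTU {col!r}")
        vals = numeric.to_numpy(dtype=np.float64)
        if round_counts:
            vals = np.round(vals)
        frac = vals != np.round(vals)
        if frac.any():
            row = df.index[np.flatnonzero(frac)[0]]
            raise ValueError(
                f"{path}: non-integer count {df[col][row]!r} at sample {row!r}, OTU {col!r}"
            )
        counts[:, j] = vals.astype(np.int64)
    return OtuTable(
        sample_ids=[str(s) for s in df.index],
        otu_ids=[str(c) for c in df.columns],
        counts=counts,
    )


def read_otu_table(path, dialect: str = "tsv", round_counts: bool = False) -> OtuTable:
    """Read an OTU count table from TSV (default) or BIOM v1 JSON.

    TSV layout: header row of OTU ids, first column of sample ids, samples as
    rows. Negative or fractional counts are rejected; set ``round_counts`` to
    round near-integer values instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        return _parse_count_frame(df, path, round_counts)
    if dialect == "biom":
        return _read_biom_v1(path, round_counts)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_biom_v1(path: Path, round_counts: bool) -> OtuTable:
    """Minimal BIOM v1 (JSON) reader: dense or sparse, observations x samples."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_url") and "biom" not in str(doc["format_url"]):
        raise ValueError(f"{path}: not a BIOM v1 document")
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    dense = np.zeros((n_obs, n_samp), dtype=np.float64)
    if doc["matrix_type"] == "dense":
        dense[:] = np.asarray(doc["data"], dtype=np.float64)
    else:
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = v
    # BIOM stores observations (OTUs) as rows; our convention is samples as rows.
    df = pd.DataFrame(dense.T, index=sample_ids, columns=otu_ids)
    return _parse_count_frame(df, path, round_counts)


def write_otu_table(table: OtuTable, path) -> None:
    """Write a table in the package's TSV convention (samples as rows)."""
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_sample_labels(
    path,
    label_columns: list[str],
    table: OtuTable | None = None,
) -> tuple[list[SampleLabels], list[str]]:
    """Read per-sample factor labels and build the factor vocabulary.

    Each factor value is column-qualified (``site=gut`` and ``host=gut`` stay
    distinct), and the vocabulary is the union over the named columns in
    first-appearance order; K is its size. Passing a single pre-combined
    column implements the combined-label convention. When ``table`` is given,
    labeled samples absent from it are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label file needs a sample column plus label columns")
    sample_col = df.columns[0]
    for col in label_columns:
        if col not in df.columns:
            raise ValueError(f"{path}: label column {col!r} not found")
    vocab: list[str] = []
    index: dict[str, int] = {}
    labels: list[SampleLabels] = []
    known = set(table.sample_ids) if table is not None else None
    for _, row in df.iterrows():
        sid = str(row[sample_col])
        if known is not None and sid not in known:
            warnings.warn(f"labeled sample {sid!r} absent from OTU table; skipped")
            continue
        values = set()
        for col in label_columns:
            raw = row[col]
            if pd.isna(raw) or str(raw) == "":
                continue
            name = f"{col}={raw}"
            if name not in index:
                index[name] = len(vocab)
                vocab.append(name)
            values.add(index[name])
        if not values:
            raise ValueError(f"{path}: sample {sid!r} has no usable label values")
        labels.append(SampleLabels(sample_id=sid, factor_values=frozenset(values)))
    return labels, vocab


def filter_singleton_otus(table: OtuTable) -> tuple[OtuTable, dict]:
    """Drop OTUs observed (nonzero) in exactly one sample.

    Returns the filtered table and a report with the removed OTU ids and the
    total count mass removed. Idempotent: a second application is a no-op.
    """
    presence = (table.counts > 0).sum(axis=0)
    keep = presence != 1
    removed_ids = [o for o, k in zip(table.otu_ids, keep) if not k]
    removed_counts = int(table.counts[:, ~keep].sum())
    filtered = OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
        counts=table.counts[:, keep],
    )
    return filtered, {"removed_otus": removed_ids, "removed_count": removed_counts}


def filter_high_abundance_otus(
    table: OtuTable,
    threshold: float,
    scope: list[str] | None = None,
) -> OtuTable:
    """Zero out OTUs whose mean relative abundance across scoped samples exceeds threshold.

    The mean is the average of per-sample fractions (not pooled counts), and
    columns are retained (set to zero) rather than dropped, so vocabularies
    stay aligned with a trained model. ``scope`` restricts the averaging to a
    sample subset; zeroing still applies to the whole column.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be a fraction in (0, 1)")
    if scope is None:
        rows = np.arange(table.n_samples)
    else:
        pos = {s: i for i, s in enumerate(table.sample_ids)}
        unknown = [s for s in scope if s not in pos]
        if unknown:
            raise ValueError(f"scope references unknown samples: {unknown}")
        rows = np.array([pos[s] for s in scope], dtype=np.int64)
    sub = table.counts[rows].astype(np.float64)
    totals = sub.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals > 0, sub / totals, 0.0)
    mean_abundance = fractions.mean(axis=0)
    new_counts = table.counts.copy()
    new_counts[:, mean_abundance > threshold] = 0
    return OtuTable(list(table.sample_ids), list(table.otu_ids), new_counts)


def tokenize(table: OtuTable, labels: list[SampleLabels], factor_names: list[str] | None = None) -> TokenizedDataset:
    """Expand counts into per-sample token lists (canonical OTU-index order).

    Sample n yields exactly row-sum(n) tokens, so the token histogram inverts
    to the count matrix. Every table sample must be labeled and have at least
    one nonzero count.
    """
    by_sample = {lab.sample_id: lab for lab in labels}
    tokens: list[np.ndarray] = []
    allowed: list[frozenset[int]] = []
    for n, sid in enumerate(table.sample_ids):
        if sid not in by_sample:
            raise ValueError(f"sample {sid!r} has no labels")
        row = table.counts[n]
        if row.sum() == 0:
            raise ValueError(f"sample {sid!r} has no counts (all-zero row)")
        tokens.append(np.repeat(np.arange(table.n_otus, dtype=np.int64), row))
        allowed.append(by_sample[sid].factor_values)
    return TokenizedDataset(
        sample_ids=list(table.sample_ids),
        tokens=tokens,
        allowed_factors=allowed,
        n_otus=table.n_otus,
        factor_names=list(factor_names) if factor_names is not None else [],
    )


def align_test_table(test: OtuTable, model_vocab: list[str]) -> tuple[OtuTable, dict]:
    """Project a test table onto the training OTU vocabulary.

    Test columns are reordered to the training order; test OTUs the model has
    never seen carry no information under the learned assemblages and are
    dropped (reported); training OTUs absent from the test table become zero
    columns.
    """
    if not model_vocab:
        raise ValueError("model OTU vocabulary is empty")
    test_pos = {o: j for j, o in enumerate(test.otu_ids)}
    shared = [o for o in model_vocab if o in test_pos]
    if not shared:
        raise ValueError("no overlap between test OTUs and the model vocabulary")
    new_counts = np.zeros((test.n_samples, len(model_vocab)), dtype=np.int64)
    for j, otu in enumerate(model_vocab):
        if otu in test_pos:
            new_counts[:, j] = test.counts[:, test_pos[otu]]
    dropped = [o for o in test.otu_ids if o not in set(model_vocab)]
    dropped_counts = int(
        test.counts[:, [test_pos[o] for o in dropped]].sum()
    ) if dropped else 0
    aligned = OtuTable(list(test.sample_ids), list(model_vocab), new_counts)
    return aligned, {"dropped_otus": dropped, "dropped_count": dropped_counts}


# --- model archive -----------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a TrainedModel to a directory (manifest.json + arrays.npz).

    The round-trip is lossless: counts, hyperparameter traces, snapshots and
    vocabularies are reproduced bit-for-bit by :func:`load_model`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    manifest = {
        "archive_version": _ARCHIVE_VERSION,
        "n_samples": model.dims.n_samples,
        "n_factors": model.dims.n_factors,
        "n_assemblages": model.dims.n_assemblages,
        "n_otus": model.dims.n_otus,
        "factor_names": model.factor_names,
        "otu_ids": model.otu_ids,
        "sample_ids": model.sample_ids,
        "allowed_factors": [sorted(a) for a in model.allowed_factors],
        "n_snapshots": len(model.snapshots),
        "config": dataclasses.asdict(cfg),
        "final_hyperparameters": list(model.final_hp.as_array()),
    }
    arrays = {
        "final_c_wl": model.final_counts.c_wl,
        "final_c_kl": model.final_counts.c_kl,
        "final_c_nk": model.final_counts.c_nk,
        "tokens_per_sample": model.dims.tokens_per_sample,
        "hp_trace": model.hp_trace,
        "log_prob_trace": model.log_prob_trace,
        "snap_c_wl": np.stack([s.counts.c_wl for s in model.snapshots]),
        "snap_c_kl": np.stack([s.counts.c_kl for s in model.snapshots]),
        "snap_c_nk": np.stack([s.counts.c_nk for s in model.snapshots]),
        "snap_hp": np.stack([s.hp.as_array() for s in model.snapshots]),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    np.savez(path / "arrays.npz", **arrays)


def load_model(path):
    """Load a TrainedModel archive written by :func:`save_model`."""
    from .model_core import CountTables, Dimensions, Hyperparameters
    from .trainer import McmcConfig, RetainedSample, TrainedModel

    path = Path(path)
    manifest_path = path / "manifest.json"
    arrays_path = path / "arrays.npz"
    if not manifest_path.exists() or not arrays_path.exists():
        raise FileNotFoundError(f"{path}: not a model archive (missing manifest or arrays)")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt manifest: {exc}") from exc
    version = manifest.get("archive_version")
    if version != _ARCHIVE_VERSION:
        raise ValueError(
            f"{path}: archive version {version} not supported (expected {_ARCHIVE_VERSION})"
        )
    try:
        arrays = np.load(arrays_path)
        _ = arrays["final_c_wl"]
    except (zipfile.BadZipFile, OSError, ValueError, KeyError) as exc:
        raise ValueError(f"{path}: corrupt array archive: {exc}") from exc

    dims = Dimensions(
        n_samples=manifest["n_samples"],
        n_factors=manifest["n_factors"],
        n_assemblages=manifest["n_assemblages"],
        n_otus=manifest["n_otus"],
        tokens_per_sample=arrays["tokens_per_sample"],
    )
    cfg = McmcConfig(**manifest["config"])
    hp_vals = manifest["final_hyperparameters"]
    final_hp = Hyperparameters(alpha_pi=hp_vals[0], alpha_theta=hp_vals[1], alpha_phi=hp_vals[2])
    snapshots = [
        RetainedSample(
            counts=CountTables(
                c_wl=arrays["snap_c_wl"][i],
                c_kl=arrays["snap_c_kl"][i],
                c_nk=arrays["snap_c_nk"][i],
            ),
            hp=Hyperparameters(
                alpha_pi=arrays["snap_hp"][i, 0],
                alpha_theta=arrays["snap_hp"][i, 1],
                alpha_phi=arrays["snap_hp"][i, 2],
            ),
        )
        for i in range(manifest["n_snapshots"])
    ]
    return TrainedModel(
        dims=dims,
        factor_names=manifest["factor_names"],
        otu_ids=manifest["otu_ids"],
        sample_ids=manifest["sample_ids"],
        allowed_factors=[frozenset(a) for a in manifest["allowed_factors"]],
        config=cfg,
        final_counts=CountTables(
            c_wl=arrays["final_c_wl"],
            c_kl=arrays["final_c_kl"],
            c_nk=arrays["final_c_nk"],
        ),
        final_hp=final_hp,
        snapshots=snapshots,
        hp_trace=arrays["hp_trace"],
        log_prob_trace=arrays["log_prob_trace"],
    )
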