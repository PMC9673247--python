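"""Core data containers: sample metadata and gene-by-sample count matrices.

Sample metadata is carried as a :class:`pandas.DataFrame` with the columns
``sample_id, species, fruit_type, stage_label, time, replicate``; the helpers
here validate its invariants.  Counts are an :class:`ExpressionMatrix`: an
integer genes-by-samples matrix aligned to that metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "METADATA_COLUMNS",
    "FRUIT_TYPES",
    "validate_metadata",
    "ExpressionMatrix",
    "read_counts_tsv",
    "read_metadata_tsv",
]

METADATA_COLUMNS = ("sample_id", "species", "fruit_type", "stage_label", "time", "replicate")
FRUIT_TYPES = ("dry", "fleshy")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata invariants and return a normalized copy.

    Checks: required columns present; sample_ids unique; times finite; each
    (species, stage_label) maps to exactly one time; fruit_type constant
    within a species and one of ``dry``/``fleshy``.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["time"] = meta["time"].astype(float)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids: {dups}")
    if not np.all(np.isfinite(meta["time"].to_numpy())):
        raise ValueError("non-finite time values in metadata")
    nt = meta.groupby(["species", "stage_label"])["time"].nunique()
    bad = nt[nt > 1]
    if len(bad):
        raise ValueError(f"(species, stage_label) pairs with >1 time value: {list(bad.index)}")
    nft = meta.groupby("species")["fruit_type"].nunique()
    bad = nft[nft > 1]
    if len(bad):
        raise ValueError(f"species with inconsistent fruit_type: {list(bad.index)}")
    unknown = set(meta["fruit_type"]) - set(FRUIT_TYPES)
    if unknown:
        raise ValueError(f"unknown fruit_type values: {sorted(unknown)}; expected {FRUIT_TYPES}")
    return meta


@dataclass
class ExpressionMatrix:
    """Integer gene-by-sample count matrix with aligned sample metadata."""

    gene_ids: pd.Index
    samples: pd.DataFrame  # validated metadata, one row per column of counts
    counts: np.ndarray  # (n_genes, n_samples) non-negative integers

    def __post_init__(self):
        self.gene_ids = pd.Index(self.gene_ids)
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if self.counts.min(initial=0) < 0:
            raise ValueError("negative counts")
        if self.gene_ids.has_duplicates:
            raise ValueError("duplicate gene_ids")
        self.samples = validate_metadata(self.samples).reset_index(drop=True)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.samples["sample_id"].to_numpy()
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(gene_ids)
        missing = [g for g, i in zip(gene_ids, idx) if i < 0]
        if missing:
            raise KeyError(f"gene ids not present: {missing[:10]}")
        return ExpressionMatrix(pd.Index(gene_ids), self.samples.copy(), self.counts[idx])

    def write_tsv(self, path, gene_column: str = "gene_id") -> None:
        df = self.to_frame()
        df.index.name = gene_column
        df.to_csv(path, sep="\t")


def read_counts_tsv(path, metadata: pd.DataFrame) -> ExpressionMatrix:
    """Read a counts TSV (first column gene ID, one column per sample).

    Samples are reordered to match ``metadata['sample_id']``; a sample listed
    in the metadata but absent from the counts is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = validate_metadata(metadata)
    missing = [s for s in meta["sample_id"] if s not in df.columns]
    if missing:
        raise ValueError(f"samples in metadata but not in counts file: {missing}")
    df = df[meta["sample_id"].tolist()]
    return ExpressionMatrix(df.index, meta, df.to_numpy())


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"stage_label": str, "species": str})
    return validate_metadata(meta)
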