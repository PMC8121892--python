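"""Data model and I/O for read-count tables, community matrices and metadata.

All tables travel as UTF-8 tab-separated text: a header row of taxon ids,
first column ``sample_id`` (or ``site_id`` for community matrices). Taxon
identifiers are opaque strings; no taxonomy is interpreted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BANK_POSITIONS = frozenset({"left", "centre", "right"})
PRIMERS = frozenset({"kelly", "mifish"})

#: metadata columns every sample record must carry
META_COLUMNS = ("sample_id", "site_id", "replicate_index", "bank", "primer", "is_negative")


class TableValidationError(ValueError):
    """A table violates a structural invariant (duplicates, negatives, ...)."""


@dataclass
class ReadCountTable:
    """Per-sample taxon read counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows indexed by ``sample_id``,
        columns are taxon ids.
    meta
        DataFrame indexed by ``sample_id`` with columns ``site_id``,
        ``replicate_index`` (1-based), ``bank`` (left/centre/right),
        ``primer`` (kelly/mifish) and ``is_negative``. Extra columns are
        preserved untouched.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample_id(s): {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate taxon id(s): {dups}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise TableValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise TableValidationError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"taxon {self.counts.columns[c]!r}"
            )
        missing = [c for c in META_COLUMNS[1:] if c not in self.meta.columns]
        if missing:
            raise TableValidationError(f"metadata missing column(s): {missing}")
        if not self.counts.index.equals(self.meta.index):
            raise TableValidationError("metadata rows do not match count-table samples")
        self.meta = self.meta.copy()
        self.meta["is_negative"] = self.meta["is_negative"].astype(bool)

    # -- convenience views ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def negatives(self) -> pd.DataFrame:
        """Count rows belonging to negative-control samples."""
        return self.counts.loc[self.meta["is_negative"].to_numpy()]

    @property
    def samples(self) -> pd.DataFrame:
        """Count rows belonging to real (non-control) samples."""
        return self.counts.loc[~self.meta["is_negative"].to_numpy()]

    def detected_taxa(self) -> set[str]:
        """Taxa with at least one read in a non-control sample."""
        pos = self.samples.sum(axis=0) > 0
        return set(pos.index[pos])

    def with_counts(self, counts: pd.DataFrame) -> "ReadCountTable":
        """New table with the same metadata, restricted to ``counts``' rows."""
        return ReadCountTable(counts=counts, meta=self.meta.loc[counts.index])

    def write(self, path: str | Path, meta_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep="\t", index=False)
        self.meta.reset_index(names="sample_id").to_csv(meta_path, sep="\t", index=False)


def read_count_table(path: str | Path, meta_path: str | Path) -> ReadCountTable:
    """Read a counts TSV and its metadata TSV into a validated table.

    The counts file has a ``sample_id`` first column and one column per
    taxon; the metadata file carries one row per sample. Raises
    :class:`TableValidationError` on malformed numbers (naming the cell),
    duplicate samples, or mismatched metadata.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "sample_id":
        raise TableValidationError(
            f"{path}: first column must be 'sample_id', got {raw.columns[0]!r}"
        )
    counts = raw.set_index("sample_id")
    parsed = {}
    for col in counts.columns:
        try:
            parsed[col] = pd.to_numeric(counts[col], errors="raise", downcast=None)
        except (ValueError, TypeError) as exc:
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableValidationError(
                f"{path}: malformed number in column {col!r}, row {row!r}"
            ) from exc
    counts = pd.DataFrame(parsed, index=counts.index)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "site_id": str})
    meta = meta.set_index("sample_id")
    try:
        meta = meta.loc[counts.index]
    except KeyError as exc:
        raise TableValidationError(f"{meta_path}: metadata rows do not match samples") from exc
    return ReadCountTable(counts=counts, meta=meta)


@dataclass
class CommunityMatrix:
    """Site x taxon matrix, either raw/merged counts or presence-absence."""

    values: pd.DataFrame  # rows = site_id, columns = taxon id
    mode: str  # "count" | "presence"

    def __post_init__(self) -> None:
        if self.mode not in ("count", "presence"):
            raise TableValidationError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            raise TableValidationError("duplicate site rows")
        vals = self.values.to_numpy()
        if (vals < 0).any():
            raise TableValidationError("community matrix has negative entries")
        if self.mode == "presence" and not np.isin(vals, (0, 1)).all():
            raise TableValidationError("presence matrix entries must be 0/1")

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "site_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, mode: str) -> "CommunityMatrix":
        raw = pd.read_csv(path, sep="\t", dtype={"site_id": str})
        return cls(values=raw.set_index("site_id"), mode=mode)


@dataclass(frozen=True)
class OverlapSummary:
    """Set-arithmetic bookkeeping for two taxon inventories.

    Percentages are of the union and stored at full precision;
    :meth:`rounded` gives the display form (nearest integer).
    """

    n_shared: int
    n_unique_a: int
    n_unique_b: int
    shared: frozenset = field(repr=False, default=frozenset())

    @property
    def n_total_a(self) -> int:
        return self.n_shared + self.n_unique_a

    @property
    def n_total_b(self) -> int:
        return self.n_shared + self.n_unique_b

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_unique_a + self.n_unique_b

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_union if self.n_union else 0.0

    @property
    def pct_unique_a(self) -> float:
        return 100.0 * self.n_unique_a / self.n_union if self.n_union else 0.0

    @property
    def pct_unique_b(self) -> float:
        return 100.0 * self.n_unique_b / self.n_union if self.n_union else 0.0

    def rounded(self) -> dict[str, int]:
        return {
            "pct_shared": round(self.pct_shared),
            "pct_unique_a": round(self.pct_unique_a),
            "pct_unique_b": round(self.pct_unique_b),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_shared": [self.n_shared],
                "n_unique_a": [self.n_unique_a],
                "n_unique_b": [self.n_unique_b],
                "n_total_a": [self.n_total_a],
                "n_total_b": [self.n_total_b],
                "n_union": [self.n_union],
                "pct_shared": [self.pct_shared],
                "pct_unique_a": [self.pct_unique_a],
                "pct_unique_b": [self.pct_unique_b],
            }
        )


def inventory_overlap(taxa_a: set[str], taxa_b: set[str]) -> OverlapSummary:
    """Decompose two taxon inventories into shared and assay-unique parts.

    Used to compare the inventories recovered by the two 12S assays: the
    summary records shared, per-assay-unique and union counts, and each
    category's percentage of the union.
    """
    a, b = set(taxa_a), set(taxa_b)
    shared = a & b
    return OverlapSummary(
        n_shared=len(shared),
        n_unique_a=len(a - b),
        n_unique_b=len(b - a),
        shared=frozenset(shared),
    )
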