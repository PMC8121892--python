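"""Contamination-minimisation filters and replicate/assay merging.

The cleaning pipeline for eDNA read tables, in the default order:

1. per-sample low-frequency filter (counts below 0.1% of the sample's own
   total are zeroed),
2. negative-control subtraction (the largest count of each taxon across
   all filtration blanks is subtracted from every sample),
3. replicate merge (the six water-sample replicates of a site are combined
   into one row),
4. assay merge (the two 12S primer tables are combined per site/taxon).

Every step is monotone: no count ever increases, and outputs stay
non-negative integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from riverdiv.tables_io import CommunityMatrix, ReadCountTable

DEFAULT_LOW_FREQUENCY_FRACTION = 0.001


def filter_low_frequency(
    table: ReadCountTable, fraction: float = DEFAULT_LOW_FREQUENCY_FRACTION
) -> ReadCountTable:
    """Zero counts strictly below ``fraction`` of their sample's total reads.

    The threshold is computed per sample on the pre-filter total and applied
    in a single pass; all-zero samples pass through unchanged. ``fraction=0``
    is the identity.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    counts = table.counts.to_numpy().copy()
    thresholds = fraction * counts.sum(axis=1, keepdims=True)
    counts[counts < thresholds] = 0
    return table.with_counts(
        pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns)
    )


def subtract_negative_controls(table: ReadCountTable) -> ReadCountTable:
    """Subtract each taxon's worst negative-control count from every sample.

    For each taxon, ``m`` is the maximum count observed across all
    negative-control rows (0 when there are none, or none are positive);
    every real sample's count becomes ``max(count - m, 0)``. The control
    rows are dropped from the output.
    """
    neg = table.negatives
    m = neg.max(axis=0).to_numpy() if len(neg) else np.zeros(len(table.taxon_ids))
    real = table.samples
    adjusted = np.maximum(real.to_numpy() - m[np.newaxis, :], 0)
    return table.with_counts(
        pd.DataFrame(adjusted, index=real.index, columns=real.columns)
    )


def merge_replicates(
    table: ReadCountTable,
    mode: str = "union_presence",
    expected_sites: list[str] | None = None,
) -> CommunityMatrix:
    """Combine each site's replicates into a single community row.

    ``union_presence``: a taxon is present at a site if any replicate has a
    positive count. ``max_count``: the per-taxon maximum count over the
    site's replicates. Negative controls must already be removed or are
    ignored; when ``expected_sites`` is given, any site left with no
    samples raises a ValueError naming it.
    """
    if mode not in ("union_presence", "max_count"):
        raise ValueError(f"unknown replicate-merge mode {mode!r}")
    real = ~table.meta["is_negative"].to_numpy()
    counts = table.counts.loc[real]
    sites = table.meta.loc[real, "site_id"]
    if sites.isna().any():
        bad = counts.index[sites.isna()].tolist()
        raise ValueError(f"samples without a site: {bad}")
    merged = counts.groupby(sites.to_numpy()).max()
    merged.index.name = "site_id"
    if expected_sites is not None:
        missing = [s for s in expected_sites if s not in merged.index]
        if missing:
            raise ValueError(f"site(s) with no samples after cleaning: {missing}")
    if mode == "union_presence":
        return CommunityMatrix(values=(merged > 0).astype(np.int64), mode="presence")
    return CommunityMatrix(values=merged, mode="count")


def _align_taxa(a: CommunityMatrix, b: CommunityMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two matrices on the union of their taxa, zero-filling gaps."""
    taxa = list(a.values.columns) + [t for t in b.values.columns if t not in a.values.columns]
    return (
        a.values.reindex(columns=taxa, fill_value=0),
        b.values.reindex(columns=taxa, fill_value=0),
    )


def merge_primers(a: CommunityMatrix, b: CommunityMatrix, mode: str = "max_count") -> CommunityMatrix:
    """Combine the two assay tables per site and taxon.

    Taxa present in only one assay's reference are treated as explicit zero
    columns in the other, so the merged matrix spans the union taxon
    universe. ``max_count`` takes the per-cell maximum (the per-assay
    detection-efficiency-robust default for count matrices);
    ``union_presence`` takes the logical OR of presences.
    """
    if mode not in ("max_count", "union_presence"):
        raise ValueError(f"unknown primer-merge mode {mode!r}")
    if set(a.site_ids) != set(b.site_ids):
        only_a = sorted(set(a.site_ids) - set(b.site_ids))
        only_b = sorted(set(b.site_ids) - set(a.site_ids))
        raise ValueError(f"site sets differ: only in a={only_a}, only in b={only_b}")
    va, vb = _align_taxa(a, b)
    vb = vb.loc[va.index]
    merged = pd.DataFrame(
        np.maximum(va.to_numpy(), vb.to_numpy()), index=va.index, columns=va.columns
    )
    if mode == "union_presence":
        return CommunityMatrix(values=(merged > 0).astype(np.int64), mode="presence")
    out_mode = "presence" if a.mode == b.mode == "presence" else "count"
    return CommunityMatrix(values=merged, mode=out_mode)


def to_presence_absence(m: CommunityMatrix) -> CommunityMatrix:
    """Convert counts to 0/1 presence; idempotent on presence input."""
    return CommunityMatrix(values=(m.values > 0).astype(np.int64), mode="presence")


def clean_pipeline(
    table: ReadCountTable,
    fraction: float = DEFAULT_LOW_FREQUENCY_FRACTION,
    replicate_mode: str = "max_count",
    negatives_first: bool = False,
) -> CommunityMatrix:
    """Run filter -> negative subtraction -> replicate merge for one assay.

    ``negatives_first`` swaps the first two steps (both orders are
    defensible; the default filters first).
    """
    if negatives_first:
        table = filter_low_frequency(subtract_negative_controls(table), fraction)
    else:
        table = subtract_negative_controls(filter_low_frequency(table, fraction))
    return merge_replicates(table, mode=replicate_mode)
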