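"""Filtering, partitioning and normalization ahead of network inference.

Mirrors the study workflow: a global low-abundance filter (drop OTUs
below a fraction of the grand total), a split of the count matrix into
per-lake / per-continent / per-diet datasets with a minimum sample size,
an occurrence filter with an optional "keep-sum" composite row so that
column totals survive filtering, and column normalization to relative
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import OTUTable, SampleMetadata

#: Label of the composite row aggregating occurrence-filtered OTUs.  It
#: takes part in normalization but is never eligible for edge inference.
KEEP_SUM_ID = "__filtered_sum__"


@dataclass(frozen=True)
class PartitionScheme:
    """How to split samples into datasets for network inference.

    mode
        ``lake`` (one dataset per lake with enough samples), ``continent``
        (one per continent) or ``diet`` (one per diet within one lake).
    min_samples
        Minimum sample size for a partition to stand on its own.
    fold_small_into_continent
        In lake mode, additionally emit a continent dataset for each
        continent that has lakes below ``min_samples``, so those samples
        still contribute to a (continental) network.
    lake
        Required in diet mode: which lake to split by diet.
    """

    mode: str = "lake"
    min_samples: int = 20
    fold_small_into_continent: bool = True
    lake: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("lake", "continent", "diet"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")
        if self.mode == "diet" and not self.lake:
            raise ValueError("diet mode requires a lake")


def filter_global_abundance(
    table: OTUTable, min_frac: float = 0.00005
) -> OTUTable:
    """Drop OTUs contributing less than ``min_frac`` of the grand total.

    The grand total is computed before filtering; an OTU is kept iff
    ``row_sum / grand_total >= min_frac``.  Row order is preserved.
    """
    if table.n_otus == 0:
        raise ValueError("empty table")
    row_sums = table.counts.sum(axis=1)
    grand = row_sums.sum()
    if grand == 0:
        raise ValueError("table has no counts")
    keep = row_sums / grand >= min_frac
    if not keep.any():
        raise ValueError("abundance filter removed every OTU")
    return table.select_otus(keep)


def drop_zero_otus(table: OTUTable) -> tuple[OTUTable, int]:
    """Remove OTUs with zero total count; returns (table, n_dropped)."""
    keep = table.counts.sum(axis=1) > 0
    return table.select_otus(keep), int((~keep).sum())


def partition_datasets(
    table: OTUTable,
    metadata: SampleMetadata,
    scheme: PartitionScheme,
) -> dict[str, tuple[OTUTable, SampleMetadata]]:
    """Split the table into named per-group datasets.

    Every partition drops its all-zero OTU rows (the per-partition OTU
    count downstream reports is taken after this step).  In lake mode,
    lakes with fewer than ``min_samples`` samples are absent from the
    output; with ``fold_small_into_continent`` their continent appears as
    an extra dataset holding *all* of that continent's samples.
    """
    meta = metadata.frame
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} missing from metadata")
    meta = meta.loc[table.sample_ids]

    groups: dict[str, list[str]] = {}
    if scheme.mode == "continent":
        for cont, sub in meta.groupby("continent", sort=True):
            groups[str(cont)] = list(sub.index)
    elif scheme.mode == "lake":
        small_continents: set[str] = set()
        for lake, sub in meta.groupby("lake", sort=True):
            if len(sub) >= scheme.min_samples:
                groups[str(lake)] = list(sub.index)
            else:
                small_continents.add(str(sub["continent"].iloc[0]))
        if scheme.fold_small_into_continent:
            for cont in sorted(small_continents):
                sel = meta.index[meta["continent"] == cont]
                groups[cont] = list(sel)
    else:  # diet
        sub = meta[meta["lake"] == scheme.lake]
        if sub.empty:
            raise ValueError(f"no samples for lake {scheme.lake!r}")
        for diet, dsub in sub.groupby("diet", sort=True):
            if diet == "":
                continue
            if len(dsub) >= scheme.min_samples:
                groups[str(diet)] = list(dsub.index)

    if not groups:
        raise ValueError(
            f"partitioning by {scheme.mode!r} produced no dataset with "
            f">= {scheme.min_samples} samples"
        )
    out: dict[str, tuple[OTUTable, SampleMetadata]] = {}
    for name, samples in groups.items():
        sub_table = table.select_samples(samples)
        sub_table, _ = drop_zero_otus(sub_table)
        out[name] = (sub_table, metadata.subset(samples))
    return out


def occurrence_filter(
    table: OTUTable,
    min_occurrence_frac: float = 0.31,
    keep_sum: bool = True,
) -> OTUTable:
    """Keep OTUs present in at least a fraction of samples.

    An OTU passes iff ``(nonzero samples) / n_samples >= threshold``.
    With ``keep_sum`` the filtered rows are summed into one composite
    row (:data:`KEEP_SUM_ID`), retained so column totals — hence the
    normalization denominators — are conserved exactly; the composite is
    never a node candidate.
    """
    if not (0.0 <= min_occurrence_frac <= 1.0):
        raise ValueError("min_occurrence_frac must lie in [0, 1]")
    occ = (table.counts > 0).sum(axis=1) / table.n_samples
    keep = occ >= min_occurrence_frac
    if not keep.any():
        raise ValueError("occurrence filter removed every OTU")
    kept = table.select_otus(keep)
    if not keep_sum or keep.all():
        return kept
    residual = table.counts[~keep].sum(axis=0)
    counts = np.vstack([kept.counts, residual])
    return OTUTable(
        counts,
        kept.otu_ids + [KEEP_SUM_ID],
        kept.sample_ids,
        kept.taxonomy + [""],
    )


def column_normalize(table: OTUTable) -> pd.DataFrame:
    """Relative abundances: each column divided by its sum.

    Returns a float DataFrame (OTUs x samples); the composite keep-sum
    row, if present, is part of the denominator.
    """
    sums = table.counts.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    norm = table.counts / sums
    return pd.DataFrame(norm, index=table.otu_ids, columns=table.sample_ids)
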