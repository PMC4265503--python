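"""Per-site recurrence counts: the quantity plotted on the overlay y-axis.

A *site* is one (gene, amino-acid position, source) triple.  Its count is the
number of table entries carrying a mutation at that position — a raw entry
count, not a proportion: reference compendia lack a definitive sample
denominator, so normalization is unsupported, and different amino-acid
changes at one position (V600E vs V600K) are pooled because the unit of
interest is the position.  Sources are never pooled — keeping the reference
and test counts separate is what makes the overlay work.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dataset import GENE_NAME, POSITION, SOURCE, MutationTable

__all__ = ["SiteCount", "count_sites", "apply_threshold", "top_sites",
           "counts_to_frame", "write_counts"]


@dataclass(frozen=True, order=True)
class SiteCount:
    """Recurrence count for one (gene, position, source) triple."""

    gene_name: str
    position: int
    source: str
    count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is a 1-based residue index")
        if self.count < 1:
            raise ValueError("an emitted site has at least one entry")


def count_sites(table: MutationTable) -> list[SiteCount]:
    """Tally entries per (gene, position, source).

    Records without a position are skipped (their number is available from
    the parse/validation reports); the counts of the emitted sites therefore
    sum exactly to the number of positioned records.  Output is sorted by
    (gene, source, position) for determinism.
    """
    df = table.df
    positioned = df[df[POSITION].notna()]
    if positioned.empty:
        return []
    grouped = (positioned.groupby([GENE_NAME, POSITION, SOURCE], sort=False)
               .size().reset_index(name="count"))
    sites = [
        SiteCount(gene_name=str(g), position=int(p), source=str(s), count=int(c))
        for g, p, s, c in grouped.itertuples(index=False)
    ]
    sites.sort(key=lambda s: (s.gene_name, s.source, s.position))
    return sites


def apply_threshold(counts: Sequence[SiteCount], min_count: int | Mapping[str, int],
                    ) -> list[SiteCount]:
    """Keep sites whose count meets a minimum recurrence.

    ``min_count`` may be a single integer applied to every source, or a
    mapping ``{source: min_count}`` so a large reference can be thresholded
    (e.g. at 10 entries) while a rare test set is kept in full; sources
    absent from the mapping default to 1 (no filtering).
    """
    if isinstance(min_count, Mapping):
        thresholds = dict(min_count)
        for v in thresholds.values():
            if v < 1:
                raise ValueError("min_count must be >= 1")
        return [s for s in counts if s.count >= thresholds.get(s.source, 1)]
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [s for s in counts if s.count >= min_count]


def top_sites(counts: Sequence[SiteCount], gene: str, source: str,
              n: int) -> list[SiteCount]:
    """The ``n`` most recurrent sites of one gene/source, ordered by
    descending count, ties broken by ascending position.  An unknown
    gene/source yields an empty list."""
    if n < 1:
        raise ValueError("n must be >= 1")
    relevant = [s for s in counts if s.gene_name == gene and s.source == source]
    relevant.sort(key=lambda s: (-s.count, s.position))
    return relevant[:n]


def counts_to_frame(counts: Iterable[SiteCount]) -> pd.DataFrame:
    """SiteCounts as a DataFrame (gene, position, source, count)."""
    rows = [(s.gene_name, s.position, s.source, s.count) for s in counts]
    return pd.DataFrame(rows, columns=[GENE_NAME, POSITION, SOURCE, "Count"])


def write_counts(counts: Iterable[SiteCount], path: str | Path) -> None:
    """Export site counts as TSV for downstream use."""
    counts_to_frame(counts).to_csv(path, sep="\t", index=False)
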