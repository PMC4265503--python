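"""Region drill-down: the row-level records behind a selected plot region.

Once a candidate hotspot site or region is spotted on the overlay, the
underlying mutation entries are what support further analysis — which
cancers they came from, what exact alterations they carry.  A region is a
closed interval of residues on one gene (e.g. residues 23–48); selection
returns every record whose position falls inside it, and export writes them
ranked first by source, then by position, ties preserving input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .dataset import GENE_NAME, POSITION, SOURCE, MutationTable, write_table

__all__ = ["RegionQuery", "select_region", "export_underlying"]


@dataclass(frozen=True)
class RegionQuery:
    """A gene plus a closed 1-based residue interval, optionally restricted
    to a subset of sources (default: all)."""

    gene_name: str
    start: int
    end: int
    sources: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start is a 1-based residue index")
        if self.start > self.end:
            raise ValueError(f"empty interval: start {self.start} > end {self.end}")
        if self.sources is not None:
            object.__setattr__(self, "sources", frozenset(self.sources))


def select_region(table: MutationTable, q: RegionQuery) -> MutationTable:
    """Records of ``q.gene_name`` with position in ``[q.start, q.end]``
    (both ends inclusive) and source in ``q.sources``.

    Records lacking a position are never returned — interval membership is
    undefined for them.  All extra columns are preserved; row order follows
    the input table.
    """
    df = table.df
    mask = (
        (df[GENE_NAME] == q.gene_name)
        & df[POSITION].notna()
        & (df[POSITION] >= q.start)
        & (df[POSITION] <= q.end)
    )
    if q.sources is not None:
        mask &= df[SOURCE].isin(q.sources)
    return MutationTable(df=df[mask].reset_index(drop=True),
                         provenance=list(table.provenance))


def export_underlying(table: MutationTable, path: str | Path,
                      format: str = "tsv") -> None:
    """Write the drill-down records ranked by (source, position).

    Source order is ascending lexicographic, positions ascending within a
    source, and the sort is stable so entries at one site keep their input
    order.  All columns, mandatory and extras, are included.
    """
    ranked = table.df.sort_values([SOURCE, POSITION], kind="stable",
                                  ascending=[True, True])
    out = MutationTable(df=ranked.reset_index(drop=True),
                        provenance=list(table.provenance))
    write_table(out, path, format=format)
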