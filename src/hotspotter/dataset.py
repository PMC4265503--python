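"""Mutation tables in the four-column overlay schema.

The overlay workflow operates on flat tables with one row per mutation entry
and four mandatory columns: ``Gene name``, ``Mutation AA``, ``Position`` and
``Source``.  ``Gene name`` and ``Mutation AA`` come straight from a COSMIC
export (or are mapped from MAF-style headers such as ``Hugo_Symbol`` /
``HGVSp_Short``); ``Position`` is derived by the parser; ``Source`` labels
which dataset a row belongs to so a small test cohort can be told apart from
the large reference compendium after the two are appended into one table.
Any further columns are carried through untouched, in their original order.

Tables are held as a :class:`MutationTable` — a pandas ``DataFrame`` plus a
provenance list of ``(path, source_label)`` pairs.  Row order is preserved by
every operation; duplicate rows are deliberately retained (reference
compendia contain redundant entries and no sample denominator, so
deduplication would silently change counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GENE_NAME",
    "MUTATION_AA",
    "POSITION",
    "SOURCE",
    "MANDATORY_COLUMNS",
    "SchemaError",
    "MutationTable",
    "ValidationReport",
    "read_table",
    "write_table",
    "set_source",
    "merge",
    "exclude_samples",
    "validate_schema",
]

GENE_NAME = "Gene name"
MUTATION_AA = "Mutation AA"
POSITION = "Position"
SOURCE = "Source"
MANDATORY_COLUMNS = (GENE_NAME, MUTATION_AA, POSITION, SOURCE)

_DELIMITERS = {"tsv": "\t", "csv": ","}


class SchemaError(ValueError):
    """A table does not satisfy the four-mandatory-column schema."""


@dataclass
class MutationTable:
    """One-row-per-mutation table plus provenance.

    ``df`` always contains the four mandatory columns (``Position`` may be
    null before annotation, ``Source`` empty before labelling); every other
    column is a pass-through extra.  ``provenance`` records where rows came
    from as ``(path or None, source_label)`` pairs.
    """

    df: pd.DataFrame
    provenance: list[tuple[str | None, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.df
        for col in (GENE_NAME, MUTATION_AA):
            if col not in df.columns:
                raise SchemaError(f"mandatory column {col!r} is missing")
        if POSITION not in df.columns:
            df = df.assign(**{POSITION: pd.Series([pd.NA] * len(df), dtype="Int64")})
        if SOURCE not in df.columns:
            df = df.assign(**{SOURCE: ""})
        df = df.copy()
        df[POSITION] = df[POSITION].astype("Int64")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def extras(self) -> list[str]:
        """Pass-through column names, in original order."""
        return [c for c in self.df.columns if c not in MANDATORY_COLUMNS]

    @property
    def sources(self) -> list[str]:
        """Distinct source labels in row order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.df[SOURCE]:
            if isinstance(s, str) and s and s not in seen:
                seen[s] = None
        return list(seen)

    @property
    def n_positioned(self) -> int:
        return int(self.df[POSITION].notna().sum())

    def canonical_columns(self) -> list[str]:
        return list(MANDATORY_COLUMNS) + self.extras

    def copy(self) -> "MutationTable":
        return MutationTable(df=self.df.copy(), provenance=list(self.provenance))

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, object]],
                     provenance: Sequence[tuple[str | None, str]] = ()
                     ) -> "MutationTable":
        rows = list(records)
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame({GENE_NAME: pd.Series(dtype=str),
                               MUTATION_AA: pd.Series(dtype=str)})
        return cls(df=df, provenance=list(provenance))


def read_table(path: str | Path, format: str = "tsv",
               column_map: Mapping[str, str] | None = None,
               source_label: str | None = None) -> MutationTable:
    """Read a mutation table from a delimited text file.

    ``column_map`` maps logical names to the file's actual headers, e.g.
    ``{"Gene name": "Hugo_Symbol", "Mutation AA": "HGVSp_Short"}`` for
    MAF-like exports.  ``Position`` and ``Source`` columns already present in
    the file are loaded as-is, not recomputed.
    """
    path = Path(path)
    if format not in _DELIMITERS:
        raise ValueError(f"format must be one of {sorted(_DELIMITERS)}, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(f"mutation table not found: {path}")
    df = pd.read_csv(path, sep=_DELIMITERS[format], dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if column_map:
        rename = {}
        for logical, actual in column_map.items():
            if actual not in df.columns:
                raise SchemaError(
                    f"column {actual!r} (mapped to {logical!r}) not in {path}")
            rename[actual] = logical
        df = df.rename(columns=rename)
    for col in (GENE_NAME, MUTATION_AA):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    if POSITION in df.columns:
        df[POSITION] = pd.to_numeric(df[POSITION].replace("", pd.NA),
                                     errors="coerce").astype("Int64")
    label = source_label
    if label is None:
        labels = [s for s in dict.fromkeys(df.get(SOURCE, [])) if s]
        label = labels[0] if len(labels) == 1 else ""
    table = MutationTable(df=df, provenance=[(str(path), label)])
    return table


def write_table(table: MutationTable, path: str | Path, format: str = "tsv") -> None:
    """Write a table with canonical header order: the four mandatory columns
    first, then extras in their original order."""
    if format not in _DELIMITERS:
        raise ValueError(f"format must be one of {sorted(_DELIMITERS)}, got {format!r}")
    path = Path(path)
    out = table.df.reindex(columns=table.canonical_columns())
    out.to_csv(path, sep=_DELIMITERS[format], index=False, encoding="utf-8")


def set_source(table: MutationTable, label: str) -> MutationTable:
    """Label every record with one source name (e.g. ``"COSMIC"``)."""
    if not label:
        raise ValueError("source label must be non-empty")
    df = table.df.copy()
    df[SOURCE] = label
    provenance = [(p, label) for p, _ in table.provenance] or [(None, label)]
    return MutationTable(df=df, provenance=provenance)


def merge(reference: MutationTable, test: MutationTable) -> MutationTable:
    """Append the test rows after the reference rows.

    The two tables must carry disjoint source labels — a shared label would
    make reference and test rows indistinguishable in the overlay.
    """
    ref_sources = set(reference.sources)
    test_sources = set(test.sources)
    shared = ref_sources & test_sources
    if shared:
        raise ValueError(
            f"reference and test tables share source label(s) {sorted(shared)}; "
            "distinct names in the 'Source' column are required to tell the "
            "datasets apart")
    columns = reference.canonical_columns()
    for extra in test.extras:
        if extra not in columns:
            columns.append(extra)
    df = pd.concat([reference.df.reindex(columns=columns),
                    test.df.reindex(columns=columns)], ignore_index=True)
    return MutationTable(df=df,
                         provenance=list(reference.provenance) + list(test.provenance))


def exclude_samples(reference: MutationTable, key_column: str,
                    keys: Iterable[str]) -> tuple[MutationTable, int]:
    """Drop reference rows whose ``key_column`` value is in ``keys``.

    Used for self-reference exclusion: when the test cohort's samples are
    already in the reference compendium, overlap at its own sites is an
    artifact unless those rows are removed first.  Returns the filtered
    table and the number of rows removed.
    """
    if key_column not in reference.df.columns:
        raise SchemaError(f"exclusion key column {key_column!r} not in table "
                          f"(columns: {list(reference.df.columns)})")
    keyset = set(keys)
    if not keyset:
        return reference.copy(), 0
    mask = ~reference.df[key_column].isin(keyset)
    df = reference.df[mask].reset_index(drop=True)
    return (MutationTable(df=df, provenance=list(reference.provenance)),
            int((~mask).sum()))


@dataclass
class ValidationReport:
    """Report-only schema check of a (possibly merged) table."""

    has_gene_name: bool
    has_mutation_aa: bool
    has_position: bool
    has_source: bool
    n_records: int
    n_unpositioned: int
    n_unlabelled: int
    sources: list[str]
    sources_distinct: bool

    @property
    def ok(self) -> bool:
        return (self.has_gene_name and self.has_mutation_aa and self.has_position
                and self.has_source and self.n_unpositioned == 0
                and self.n_unlabelled == 0 and self.sources_distinct)

    def as_dict(self) -> dict[str, object]:
        return {
            "has_gene_name": self.has_gene_name,
            "has_mutation_aa": self.has_mutation_aa,
            "has_position": self.has_position,
            "has_source": self.has_source,
            "n_records": self.n_records,
            "n_unpositioned": self.n_unpositioned,
            "n_unlabelled": self.n_unlabelled,
            "sources": self.sources,
            "sources_distinct": self.sources_distinct,
            "ok": self.ok,
        }


def validate_schema(table: MutationTable) -> ValidationReport:
    """Check the mandatory columns, unpositioned/unlabelled rows, and that
    provenance entries use distinct source labels."""
    df = table.df
    labels = [lab for _, lab in table.provenance]
    distinct = len(labels) == len(set(labels)) if labels else True
    n_unlabelled = int((df[SOURCE].fillna("") == "").sum()) if SOURCE in df else len(df)
    return ValidationReport(
        has_gene_name=GENE_NAME in df.columns,
        has_mutation_aa=MUTATION_AA in df.columns,
        has_position=POSITION in df.columns,
        has_source=SOURCE in df.columns,
        n_records=len(df),
        n_unpositioned=int(df[POSITION].isna().sum()) if POSITION in df else len(df),
        n_unlabelled=n_unlabelled,
        sources=table.sources,
        sources_distinct=distinct,
    )
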