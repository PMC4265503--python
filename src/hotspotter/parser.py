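"""Extract amino-acid positions from protein-level mutation annotations.

Mutation databases in the COSMIC style describe each somatic mutation at the
protein level with an HGVS-like string such as ``p.V600E`` (substitution),
``p.E746_A750del`` (in-frame deletion) or ``p.G12fs*2`` (frameshift).  For
recurrence plotting every mutation must be reduced to a single 1-based
amino-acid coordinate.  The rule applied here is: a substitution is plotted at
its substituted residue, and every non-substitution event is plotted at the
*first* residue at which the alteration occurs (the left endpoint of a range
such as ``E746_A750``).

Parsing is total: any string yields a :class:`ParseResult`, never an
exception.  Failures are typed — ``wildtype_or_unknown`` for annotations that
assert no interpretable site (``p.?``, ``p.=``, ``p.0``), ``no_position`` for
recognized event keywords lacking a residue number, and ``malformed`` for
everything else.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import MutationTable

__all__ = [
    "ParseStatus",
    "MutationClass",
    "ParseResult",
    "ParseReport",
    "parse_mutation_aa",
    "annotate_positions",
]


class ParseStatus(str, enum.Enum):
    OK = "ok"
    NO_POSITION = "no_position"
    WILDTYPE_OR_UNKNOWN = "wildtype_or_unknown"
    MALFORMED = "malformed"


class MutationClass(str, enum.Enum):
    SUBSTITUTION = "substitution"
    NONSENSE = "nonsense"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    FRAMESHIFT = "frameshift"
    START_LOST = "start_lost"
    COMPLEX = "complex"
    OTHER = "other"


@dataclass(frozen=True)
class ParseResult:
    """Outcome of parsing one annotation string.

    ``position`` and ``mutation_class`` are set iff ``status`` is ``OK``;
    ``raw`` always preserves the input byte-for-byte.
    """

    status: ParseStatus
    raw: str
    position: int | None = None
    mutation_class: MutationClass | None = None

    def __post_init__(self) -> None:
        if self.status is ParseStatus.OK:
            if self.position is None or self.position < 1:
                raise ValueError("status=ok requires a positive 1-based position")
            if self.mutation_class is None:
                raise ValueError("status=ok requires a mutation class")
        elif self.position is not None:
            raise ValueError("position must be absent unless status=ok")

    @property
    def ok(self) -> bool:
        return self.status is ParseStatus.OK


# Three-letter residue codes (HGVS long form), mapped to one-letter.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEC": "U", "PYL": "O", "TER": "*",
}

_THREE_RE = "|".join(_THREE_TO_ONE)
# A residue token: three-letter code, one-letter amino acid, stop (*) or
# unknown residue (X).  Matched case-insensitively, stored uppercase.
_RESIDUE_RE = rf"(?:{_THREE_RE}|[ACDEFGHIKLMNPQRSTUVWYX*])"

# First residue token followed by its 1-based coordinate.
_SITE_RE = re.compile(rf"({_RESIDUE_RE})\s*(\d+)", re.IGNORECASE)

# Event keywords, longest-match first so "delins" is not read as "del".
_KEYWORDS = (
    ("delins", MutationClass.COMPLEX),
    ("fs", MutationClass.FRAMESHIFT),
    ("dup", MutationClass.DUPLICATION),
    ("ins", MutationClass.INSERTION),
    ("del", MutationClass.DELETION),
)

# Annotations asserting wild type, no change, or an unknown consequence.
_WILDTYPE = {"?", "=", "0", "0?", "unknown", "wt", "wildtype", "(=)"}


def _normalize_residue(token: str) -> str:
    token = token.upper()
    return _THREE_TO_ONE.get(token, token)


def _strip_prefix(annotation: str) -> str:
    s = annotation.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    # HGVS predicted-consequence parentheses: p.(V600E)
    if len(s) >= 2 and s.startswith("(") and s.endswith(")") and s != "(=)":
        s = s[1:-1]
    return s.strip()


def _classify(body: str, first_residue: str, position: int) -> MutationClass:
    lowered = body.lower()
    for keyword, klass in _KEYWORDS:
        if keyword in lowered:
            return klass
    if first_residue == "*":
        # Stop-loss / extension: the altered residue is the stop codon itself.
        return MutationClass.OTHER
    after = _after_site(body)
    if first_residue == "M" and position == 1 and after == "?":
        return MutationClass.START_LOST
    alt = _leading_residue(after)
    if alt in {"*", "X"} or after.lower() in {"ter", "x", "*"}:
        return MutationClass.NONSENSE
    if alt is not None:
        return MutationClass.SUBSTITUTION
    return MutationClass.OTHER


def _after_site(body: str) -> str:
    m = _SITE_RE.search(body)
    return body[m.end():].strip() if m else ""


def _leading_residue(tail: str) -> str | None:
    """One-letter form of the residue token opening ``tail``, if any."""
    if not tail or tail.lower().startswith("ext"):
        # "ext" (stop/start extension keyword) is not a residue although it
        # begins with a letter that is one.
        return None
    m = re.match(rf"({_RESIDUE_RE})", tail, re.IGNORECASE)
    if m is None:
        return None
    return _normalize_residue(m.group(1))


def parse_mutation_aa(annotation: str) -> ParseResult:
    """Parse one protein-change annotation into a position and class.

    Accepts the COSMIC one-letter dialect (``p.V600E``), bare annotations
    without the ``p.`` prefix (``V600E``, common in MAF exports), and
    three-letter HGVS (``p.Val600Glu``).  Returns the first affected residue
    for every recognized event class.  Never raises.
    """
    if not isinstance(annotation, str):
        annotation = "" if annotation is None else str(annotation)
    body = _strip_prefix(annotation)
    if not body:
        return ParseResult(ParseStatus.MALFORMED, raw=annotation)
    if body.lower() in _WILDTYPE:
        return ParseResult(ParseStatus.WILDTYPE_OR_UNKNOWN, raw=annotation)

    site = _SITE_RE.search(body)
    if site is None:
        lowered = body.lower()
        if any(keyword in lowered for keyword, _ in _KEYWORDS):
            # A recognized event ("del", "fs", ...) with no residue number.
            return ParseResult(ParseStatus.NO_POSITION, raw=annotation)
        return ParseResult(ParseStatus.MALFORMED, raw=annotation)

    first_residue = _normalize_residue(site.group(1))
    position = int(site.group(2))
    if position < 1:
        return ParseResult(ParseStatus.MALFORMED, raw=annotation)
    klass = _classify(body, first_residue, position)
    return ParseResult(ParseStatus.OK, raw=annotation, position=position,
                       mutation_class=klass)


@dataclass
class ParseReport:
    """Per-status tallies from annotating a table of records."""

    counts: Counter = field(default_factory=Counter)

    def add(self, status: ParseStatus) -> None:
        self.counts[status.value] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_ok(self) -> int:
        return self.counts.get(ParseStatus.OK.value, 0)

    def as_dict(self) -> dict[str, int]:
        return {s.value: self.counts.get(s.value, 0) for s in ParseStatus}

    def __str__(self) -> str:
        parts = ", ".join(f"{k}={v}" for k, v in self.as_dict().items())
        return f"parsed {self.total} annotations: {parts}"


def annotate_positions(table: "MutationTable", recompute: bool = False
                       ) -> tuple["MutationTable", ParseReport]:
    """Fill the ``Position`` column from each record's ``Mutation AA``.

    Records whose annotation does not yield a position keep a null position;
    they are retained (never silently dropped) and surfaced in the report.
    Existing positions are trusted unless ``recompute`` is set, mirroring a
    prepare-once workflow.  Idempotent: re-annotating changes nothing.
    """
    from .dataset import MutationTable, POSITION, MUTATION_AA

    df = table.df.copy()
    report = ParseReport()
    positions: list[object] = []
    for aa, existing in zip(df[MUTATION_AA], df[POSITION]):
        result = parse_mutation_aa(aa if isinstance(aa, str) else "")
        report.add(result.status)
        if existing is not None and not _isna(existing) and not recompute:
            positions.append(int(existing))
        elif result.ok:
            positions.append(result.position)
        else:
            positions.append(None)
    df[POSITION] = positions
    df[POSITION] = df[POSITION].astype("Int64")
    return MutationTable(df=df, provenance=list(table.provenance)), report


def _isna(value: object) -> bool:
    import pandas as pd

    return value is None or (isinstance(value, float) and value != value) or value is pd.NA


def classify_many(annotations: Iterable[str]) -> list[ParseResult]:
    """Vector convenience: parse an iterable of annotation strings."""
    return [parse_mutation_aa(a) for a in annotations]
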