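"""Curated corpus of protein-change annotation dialect examples.

Each entry is ``(annotation, expected_status, expected_position,
expected_class)`` with ``None`` where the field does not apply.  The corpus
spans every mutation class the parser recognizes — substitutions in
one-letter, three-letter, bare and parenthesized spellings, nonsense,
deletions, insertions, duplications, frameshifts, start-loss, stop-loss,
complex events — plus the wild-type/unknown annotations and malformed
strings that must fail in a typed way.  It doubles as a regression suite
and as executable documentation of the dialect the parser accepts.
"""

from __future__ import annotations

from .parser import MutationClass as M
from .parser import ParseStatus as S

__all__ = ["DIALECT_SUITE"]

DIALECT_SUITE: list[tuple[str, S, int | None, M | None]] = [
    # substitutions — the dominant class in any compendium
    ("p.V600E", S.OK, 600, M.SUBSTITUTION),
    ("p.R132H", S.OK, 132, M.SUBSTITUTION),
    ("p.R132C", S.OK, 132, M.SUBSTITUTION),
    ("p.G12V", S.OK, 12, M.SUBSTITUTION),
    ("p.R175H", S.OK, 175, M.SUBSTITUTION),
    ("V600E", S.OK, 600, M.SUBSTITUTION),          # bare MAF-style
    ("p.Val600Glu", S.OK, 600, M.SUBSTITUTION),    # three-letter HGVS
    ("p.(V600E)", S.OK, 600, M.SUBSTITUTION),      # predicted consequence
    ("p.v600e", S.OK, 600, M.SUBSTITUTION),        # hand-edited case
    ("p.A1708E", S.OK, 1708, M.SUBSTITUTION),
    # nonsense — premature stop
    ("p.R213*", S.OK, 213, M.NONSENSE),
    ("p.Q61X", S.OK, 61, M.NONSENSE),
    ("p.Arg342Ter", S.OK, 342, M.NONSENSE),
    ("W288*", S.OK, 288, M.NONSENSE),
    # deletions — position is the first deleted residue
    ("p.E746_A750del", S.OK, 746, M.DELETION),
    ("p.L747_T751del", S.OK, 747, M.DELETION),
    ("p.K745del", S.OK, 745, M.DELETION),
    ("p.Met1del", S.OK, 1, M.DELETION),
    # insertions — position is the first flanking residue
    ("p.T73_I74insR", S.OK, 73, M.INSERTION),
    ("p.D770_N771insG", S.OK, 770, M.INSERTION),
    # duplications
    ("p.A767_V769dup", S.OK, 767, M.DUPLICATION),
    ("p.G12dup", S.OK, 12, M.DUPLICATION),
    # frameshifts — position is where the reading frame breaks
    ("p.G12fs*2", S.OK, 12, M.FRAMESHIFT),
    ("p.N239fs", S.OK, 239, M.FRAMESHIFT),
    ("p.Leu348fsTer7", S.OK, 348, M.FRAMESHIFT),
    ("p.K132Nfs*5", S.OK, 132, M.FRAMESHIFT),
    # complex (deletion-insertion)
    ("p.E746_A750delinsQ", S.OK, 746, M.COMPLEX),
    ("p.S752_I759delinsN", S.OK, 752, M.COMPLEX),
    # start-loss
    ("p.M1?", S.OK, 1, M.START_LOST),
    ("p.Met1?", S.OK, 1, M.START_LOST),
    # stop-loss / other events carrying a position
    ("p.*757L", S.OK, 757, M.OTHER),
    ("p.Ter494Ser", S.OK, 494, M.OTHER),
    ("p.X123_splice", S.OK, 123, M.OTHER),
    # wild-type / unknown consequence — no site asserted
    ("p.?", S.WILDTYPE_OR_UNKNOWN, None, None),
    ("?", S.WILDTYPE_OR_UNKNOWN, None, None),
    ("p.unknown", S.WILDTYPE_OR_UNKNOWN, None, None),
    ("p.=", S.WILDTYPE_OR_UNKNOWN, None, None),
    ("p.0", S.WILDTYPE_OR_UNKNOWN, None, None),
    ("p.0?", S.WILDTYPE_OR_UNKNOWN, None, None),
    # recognized event keyword, residue number missing
    ("p.del", S.NO_POSITION, None, None),
    ("p.fs", S.NO_POSITION, None, None),
    ("p.ins", S.NO_POSITION, None, None),
    # malformed
    ("", S.MALFORMED, None, None),
    ("p.", S.MALFORMED, None, None),
    ("xyz", S.MALFORMED, None, None),
    ("12345", S.MALFORMED, None, None),
    ("p.A", S.MALFORMED, None, None),
]
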