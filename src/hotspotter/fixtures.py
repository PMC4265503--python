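"""Synthetic reference/test mutation tables with planted hotspots.

Real reference compendia are large licensed downloads, so every capability
of the package is exercised against generated tables instead: a handful of
genes at realistic protein lengths, planted single-site hotspots (a chosen
count of entries at one residue), planted region hotspots (a total count
spread uniformly over a residue interval — each site individually rare, the
region collectively recurrent), and a homogeneous Poisson background of
scattered mutations per gene and source.

Annotation strings are emitted in a deterministic cycle of mutation classes
(substitution, deletion, frameshift, nonsense, insertion, duplication) so
the parser's first-affected-residue rule is exercised on every class; by
construction every generated annotation parses to its planted position.
Generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import SiteCount, apply_threshold
from .dataset import GENE_NAME, MUTATION_AA, SOURCE, MutationTable

__all__ = ["FixtureSpec", "RecoveryReport", "generate", "recover_planted",
           "default_fixture_spec"]

# Residue letter assigned to a position, deterministic and biologically legal.
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Mutation-class templates cycled deterministically while emitting records.
_CLASS_CYCLE = ("substitution", "deletion", "frameshift", "nonsense",
                "insertion", "duplication")


def _residue(pos: int) -> str:
    return _RESIDUES[pos % len(_RESIDUES)]


def _annotation(pos: int, length: int, cycle_index: int) -> str:
    """A well-formed annotation whose first affected residue is ``pos``."""
    klass = _CLASS_CYCLE[cycle_index % len(_CLASS_CYCLE)]
    aa = _residue(pos)
    alt = _residue(pos + 7)
    if klass == "substitution":
        return f"p.{aa}{pos}{alt}"
    if klass == "deletion":
        end = min(pos + 2, length)
        if end > pos:
            return f"p.{aa}{pos}_{_residue(end)}{end}del"
        return f"p.{aa}{pos}del"
    if klass == "frameshift":
        return f"p.{aa}{pos}fs*{(cycle_index % 9) + 2}"
    if klass == "nonsense":
        return f"p.{aa}{pos}*"
    if klass == "insertion":
        nxt = min(pos + 1, length)
        return f"p.{aa}{pos}_{_residue(nxt)}{nxt}ins{alt}"
    # duplication
    return f"p.{aa}{pos}dup"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic reference/test pair.

    ``planted_sites`` are (gene, position, source, count) single-site
    hotspots; ``region_hotspots`` are (gene, start, end, source, total)
    region hotspots whose total count is spread uniformly over the closed
    interval; ``background`` is the expected number of scattered background
    mutations per gene per source (Poisson, positions uniform over the
    protein).  Records whose source equals ``reference_source`` go to the
    reference table, ``test_source`` to the test table.
    """

    genes: tuple[tuple[str, int], ...]
    planted_sites: tuple[tuple[str, int, str, int], ...] = ()
    region_hotspots: tuple[tuple[str, int, int, str, int], ...] = ()
    background: float = 0.0
    seed: int = 0
    reference_source: str = "REF"
    test_source: str = "TEST"

    def gene_lengths(self) -> dict[str, int]:
        return {g: n for g, n in self.genes}

    def validate(self) -> None:
        lengths = self.gene_lengths()
        for gene, pos, source, count in self.planted_sites:
            if gene not in lengths:
                raise ValueError(f"planted site on unknown gene {gene!r}")
            if not 1 <= pos <= lengths[gene]:
                raise ValueError(
                    f"planted position {pos} beyond {gene} length {lengths[gene]}")
            if source not in (self.reference_source, self.test_source):
                raise ValueError(f"unknown source label {source!r}")
            if count < 1:
                raise ValueError("planted count must be >= 1")
        for gene, start, end, source, total in self.region_hotspots:
            if gene not in lengths:
                raise ValueError(f"region hotspot on unknown gene {gene!r}")
            if not 1 <= start <= end <= lengths[gene]:
                raise ValueError(
                    f"region [{start},{end}] invalid for {gene} "
                    f"(length {lengths[gene]})")
            if source not in (self.reference_source, self.test_source):
                raise ValueError(f"unknown source label {source!r}")
            if total < 1:
                raise ValueError("region total must be >= 1")
        if self.background < 0:
            raise ValueError("background rate must be >= 0")


def generate(spec: FixtureSpec) -> tuple[MutationTable, MutationTable]:
    """Generate (reference, test) tables from a fixture spec.

    Tables carry ``Gene name``, ``Mutation AA``, ``Source`` and a
    ``Sample name`` extra; positions are left for the parser to derive, so
    the tables enter the pipeline exactly as a freshly prepared export
    would.  With zero background, per-site tallies of the output equal the
    planted counts exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.gene_lengths()
    rows: dict[str, list[dict[str, object]]] = {
        spec.reference_source: [], spec.test_source: []}
    cycle = 0
    sample_counter: dict[str, int] = {}

    def emit(gene: str, pos: int, source: str) -> None:
        nonlocal cycle
        k = sample_counter.get(source, 0) + 1
        sample_counter[source] = k
        rows[source].append({
            GENE_NAME: gene,
            MUTATION_AA: _annotation(pos, lengths[gene], cycle),
            SOURCE: source,
            "Sample name": f"{source}_S{k:05d}",
        })
        cycle += 1

    for gene, pos, source, count in spec.planted_sites:
        for _ in range(count):
            emit(gene, pos, source)
    for gene, start, end, source, total in spec.region_hotspots:
        positions = rng.integers(start, end + 1, size=total)
        for pos in positions:
            emit(gene, int(pos), source)
    if spec.background > 0:
        for gene, length in spec.genes:
            for source in (spec.reference_source, spec.test_source):
                n = int(rng.poisson(spec.background))
                for pos in rng.integers(1, length + 1, size=n):
                    emit(gene, int(pos), source)

    def to_table(source: str) -> MutationTable:
        recs = rows[source]
        if recs:
            df = pd.DataFrame(recs)
        else:
            df = pd.DataFrame({GENE_NAME: pd.Series(dtype=str),
                               MUTATION_AA: pd.Series(dtype=str),
                               SOURCE: pd.Series(dtype=str),
                               "Sample name": pd.Series(dtype=str)})
        return MutationTable(df=df, provenance=[(None, source)])

    return to_table(spec.reference_source), to_table(spec.test_source)


@dataclass
class RecoveryReport:
    """End-to-end self-check: did the pipeline recover what was planted?"""

    min_count: int
    expected: list[tuple[str, int, str, int]]
    recovered: list[tuple[str, int, str, int]]
    missing: list[tuple[str, int, str, int]]
    region_survivors: list[SiteCount]
    background_survivors: list[SiteCount]

    @property
    def ok(self) -> bool:
        return not self.missing

    @property
    def n_false_survivors(self) -> int:
        return len(self.background_survivors)


def recover_planted(spec: FixtureSpec, counts: Sequence[SiteCount],
                    min_count: int) -> RecoveryReport:
    """Compare thresholded pipeline counts against the planted truth.

    Every planted site with count >= ``min_count`` must survive the
    threshold.  Surviving sites that were not planted are split into
    region-hotspot members (expected when a region's draws stack on one
    residue) and true background survivors, whose frequency is controlled
    by the background rate.
    """
    survivors = apply_threshold(counts, min_count)
    survivor_keys = {(s.gene_name, s.position, s.source): s.count
                     for s in survivors}
    planted_keys = {(g, p, s): c for g, p, s, c in spec.planted_sites}

    expected = [(g, p, s, c) for (g, p, s), c in planted_keys.items()
                if c >= min_count]
    recovered, missing = [], []
    for g, p, s, c in expected:
        if (g, p, s) in survivor_keys:
            recovered.append((g, p, s, c))
        else:
            missing.append((g, p, s, c))

    def in_region(site: SiteCount) -> bool:
        return any(site.gene_name == g and a <= site.position <= b
                   and site.source == src
                   for g, a, b, src, _ in spec.region_hotspots)

    region_survivors, background_survivors = [], []
    for s in survivors:
        if (s.gene_name, s.position, s.source) in planted_keys:
            continue
        (region_survivors if in_region(s) else background_survivors).append(s)
    return RecoveryReport(min_count=min_count, expected=expected,
                          recovered=recovered, missing=missing,
                          region_survivors=region_survivors,
                          background_survivors=background_survivors)


def default_fixture_spec(seed: int = 0, background: float = 3.0) -> FixtureSpec:
    """The bundled study conditions: 8 genes at real protein lengths, a large
    reference with site and region hotspots, and a small test cohort whose
    sites recur only one to four times each — the regime the overlay is for.
    """
    genes = (
        ("TP53", 393), ("PTEN", 403), ("CTNNB1", 781), ("NFE2L2", 605),
        ("BRAF", 766), ("IDH1", 414), ("KIT", 976), ("EGFR", 1210),
    )
    planted = (
        # reference hotspot sites (well above a threshold of 10)
        ("BRAF", 600, "REF", 120),
        ("IDH1", 132, "REF", 55),
        ("TP53", 273, "REF", 40),
        ("TP53", 248, "REF", 30),
        ("KIT", 816, "REF", 25),
        ("EGFR", 746, "REF", 18),
        ("CTNNB1", 41, "REF", 15),
        ("PTEN", 130, "REF", 12),
        # reference sites below threshold 10
        ("TP53", 175, "REF", 9),
        ("PTEN", 233, "REF", 6),
        # test cohort: every site rare (1-4 entries), overlapping reference
        # hotspot sites and regions
        ("BRAF", 600, "TEST", 4),
        ("TP53", 273, "TEST", 3),
        ("PTEN", 130, "TEST", 3),
        ("EGFR", 746, "TEST", 3),
        ("NFE2L2", 29, "TEST", 2),
        ("NFE2L2", 79, "TEST", 2),
        ("CTNNB1", 41, "TEST", 2),
        ("IDH1", 132, "TEST", 1),
    )
    regions = (
        ("NFE2L2", 23, 48, "REF", 26),
        ("NFE2L2", 71, 86, "REF", 16),
        ("CTNNB1", 32, 45, "REF", 20),
        ("KIT", 550, 590, "REF", 18),
    )
    return FixtureSpec(genes=genes, planted_sites=planted,
                       region_hotspots=regions, background=background,
                       seed=seed)
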