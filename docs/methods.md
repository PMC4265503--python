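# Methods

## The procedure

The package implements a visual recurrence-overlay method for nominating
candidate driver mutation hotspots. Its unit of analysis is the **site**: a
`(gene, amino-acid position, source)` triple, where *source* labels which
dataset a mutation entry came from (one large reference compendium vs. one
test cohort). The pipeline is:

1. **Position extraction.** Each protein-level annotation (`Mutation AA`,
   HGVS-like) is reduced to a single 1-based residue coordinate. A
   substitution is anchored at its substituted residue; every
   non-substitution event — deletion, insertion, duplication, frameshift,
   deletion-insertion — is anchored at the *first residue it affects*, i.e.
   the left endpoint of a range notation. Annotations that assert no site
   (`p.?`, `p.=`, `p.0`) or carry no residue number fail with a typed
   status; such records are retained and reported but never counted.
2. **Labelling and merging.** Both tables receive a `Source` label; labels
   must be distinct or the merged table could not be split back into its
   layers. Optionally, rows of the reference whose sample identifier belongs
   to the test cohort are removed first (*self-reference exclusion*), so a
   test mutation is never "confirmed" by its own entry in the reference.
3. **Counting.** Entries are tallied per site. The y-value is a raw entry
   count: reference compendia include cell lines, redundant samples and no
   reliable per-gene sample denominator, so proportions would suggest a
   precision the data cannot support. Different amino-acid changes at one
   position (V600E vs V600K) pool into one site, because the position is the
   unit of interest. Sources are never pooled.
4. **Thresholding.** Sites below a minimum count can be hidden. The default
   is 1 (no filtering) — the method's point is surfacing *low-frequency*
   test mutations — with `10` supported as the classic preset for taming a
   large reference, including per-source thresholds so the reference can be
   thresholded while the rare test set is shown in full.
5. **Overlay.** One facet per gene, x = position (linear), y = count.
   Reference sites are drawn as small blue markers below; test sites as
   strictly larger orange markers above. Marker geometry is a contract
   (test strictly larger, test on top), the exact sizes (4 pt vs 10 pt) and
   colors only defaults. Facets get independent y-scales because maximum
   counts differ by orders of magnitude across genes; y is linear by default
   with an opt-in log scale. No jitter is applied to coincident markers —
   placement stays faithful, occlusion within a series is accepted.
6. **Drill-down.** A region is a closed residue interval on one gene
   (`[23, 48]` contains both 23 and 48). Selection returns the underlying
   records; export ranks them by source (ascending lexicographic — the
   ranking direction is a documented convention), then position, stably, so
   ties keep input order. Both sources are included by default, filterable.

There is no hotspot-calling statistic anywhere: identification is by eye,
which is a stated scope decision, not an omission.

## Renderers

The static renderer uses matplotlib (SVG/PNG); each series is a distinct
SVG group whose markers are `<use>` elements, with reference groups
serialized before test groups so document order encodes layering. SVG output
pins the hash salt and drops the date so renders are byte-reproducible.

The interactive renderer writes a single self-contained HTML document
authored by this package: one inline SVG per facet, a `<title>` tooltip per
marker with the four fields (gene, position, source, count — in that default
order, configurable), machine-readable `data-*` attributes, the complete
point set embedded as a JSON payload, and a small vanilla-JS widget that
exports any (gene, interval) selection as TSV entirely client-side. No
server, no network assets, byte-reproducible.

## Tables and parsing choices

Canonical column names are `Gene name`, `Mutation AA`, `Position`, `Source`;
extras pass through in their original order and are written after the four
mandatory columns. Duplicate rows are retained (deduplicating a compendium
with known sample redundancy would silently change counts); gene symbols are
compared case-sensitively with no alias resolution; an existing `Position`
column is trusted unless recomputation is requested, mirroring a
prepare-once workflow.

The parser accepts one-letter and three-letter residue codes, optional `p.`
prefix and HGVS prediction parentheses, case-insensitively; `*`/`X`/`Ter`
are valid residue tokens. A stop-gain (`p.R213*`) is classed nonsense; a
stop-loss (`p.*757L`) anchors at the stop position and is classed *other*;
`delins` maps to *complex* with left-endpoint position (the natural
extension of the first-affected-residue rule; compendium encodings of
compound events vary). Full HGVS validation against reference sequences,
and c./g./intronic notation, are out of scope.

## Synthetic study conditions

Because realistic inputs are licensed multi-gigabyte downloads, the package
generates its own: `FixtureSpec` plants (a) site hotspots — an exact entry
count at one residue, (b) region hotspots — a total count spread uniformly
at random over a closed interval, emulating a region recurrently but
diffusely mutated, and (c) a homogeneous Poisson background per gene and
source with positions uniform over the protein. Annotation strings cycle
deterministically through six mutation-class templates so parser coverage
does not depend on chance; every generated annotation parses to its planted
position by construction, and generation is bit-reproducible per seed.

The default conditions use 8 well-known cancer genes at their real protein
lengths (TP53 393 aa … EGFR 1210 aa). The reference carries hotspot sites of
12–120 entries (BRAF 600 largest, echoing its real-world dominance), two
below-threshold sites, and region hotspots including NFE2L2 23–48 and 71–86
— intervals chosen to match the region semantics the drill-down is tested
on. The test cohort's sites recur only 1–4 times each and sit on reference
hotspot sites/regions: exactly the regime the overlay exists to expose. The
background rate is 3 expected mutations per gene per source — low enough
that the analytic Poisson tail bound puts the probability of any background
site reaching 10 entries far below 1% across a 20-seed sweep, which the
suite checks.

What the generator does **not** emulate: mutational signatures, codon usage,
per-cancer composition, sample redundancy, caller artifacts. Passing tests
therefore demonstrate the *mechanics* — parsing, conservation, thresholds,
rendering contracts, drill-down — not biological discovery performance on
real compendia.

Real-data headline counts (entry totals of specific COSMIC versions, counts
at specific IDH1/BRAF/TP53 sites) depend on licensed database versions and
are intentionally not reproduced.

## Numerical and degenerate-input choices

- Ties in `top_sites` break by ascending position; aggregation output is
  sorted by (gene, source, position) for determinism.
- Thresholds below 1, empty source labels, inverted intervals and planted
  positions beyond a protein's length raise `ValueError`/`SchemaError`;
  parsing itself never raises.
- Empty tables, empty facets and empty selections are valid values, not
  errors; an unknown gene in a plot request yields a warning and an empty
  facet.
- CLI exit statuses: 0 success, 2 usage/schema error, 1 I/O error.

## Problem sizes

The test suite and the acceptance script run the default conditions
(~470 records per seed) over up to 50 seeds for conservation checks and 20
seeds for the background false-survivor sweep — sizes chosen so the whole
suite completes in seconds while every check still exercises hundreds of
sites per run.

## Known limitations

- Entry counts conflate entries with samples when a source lists one sample
  repeatedly; this mirrors the underlying data model and is documented
  rather than corrected.
- The interactive HTML favors self-containment over features: no zooming or
  brushing, selection is by numeric interval rather than lasso.
- Overlapping markers within one series overplot exactly; only the
  two-series layering is guaranteed.
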