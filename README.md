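# hotspotter

Overlay visualization of somatic mutation recurrence: superimpose a (typically
small) test mutation set on a large reference compendium so candidate driver
hotspot **sites** and **regions** stand out — even when every test mutation is
individually rare.

## The problem

Driver mutations are usually nominated by recurrence: how often a gene is
mutated at one amino-acid position across tumors. But a driver can be
infrequent at any single site and still cluster within a region of the
protein, or be rare in one cancer type while recurrent across many. A
frequency cutoff inside one cohort misses both patterns.

The approach here is deliberately simple and visual. Every mutation entry is
reduced to one coordinate — its 1-based amino-acid position, taking the
*first affected residue* for non-substitutions (`p.E746_A750del` → 746) — and
tallied per `(gene, position, source)`, where *source* distinguishes the
reference compendium from the user's test cohort. The two series are then
drawn on one canvas per gene: x = position, y = count of position (the number
of entries at that site), reference sites as small blue points underneath,
test sites as intentionally large orange points on top. A test mutation seen
twice means little on its own; the same dot sitting on a heavily mutated
reference region is a lead. Hovering a marker reveals gene, position, source
and count; any gene region can be drilled into to export the underlying
records, ranked by source then position.

No statistics are computed — the method is an aid to the eye, agnostic to the
mutation callers and databases upstream. Tables are plain TSV/CSV with four
mandatory columns (`Gene name`, `Mutation AA`, `Position`, `Source`); any
other columns pass through untouched. MAF-style exports map on via a column
map (`Hugo_Symbol` → `Gene name`, `HGVSp_Short` → `Mutation AA`).

## Worked example

The repository bundles a synthetic reference/test pair
(`examples/data/`, generated by `examples/make_bundled_fixture.py`) with
planted hotspot sites (e.g. 120 entries at BRAF 600), planted region hotspots
(e.g. 26 entries spread over NFE2L2 residues 23–48) and a Poisson background.

```sh
python examples/overlay_workflow.py
```

prints

```
parsed 429 annotations: ok=429, no_position=0, wildtype_or_unknown=0, malformed=0
471 records -> 106 distinct (gene, position, source) sites; counts sum to 471
top BRAF reference site: position 600, 120 entries
38 sites shown after thresholding the reference at >=10
wrote example_output/overlay.svg and example_output/overlay.html — open the HTML
and hover any marker for gene, position, source and count
```

Reading the numbers: all 429 reference annotations yielded a position; the
merged 471 records collapse to 106 distinct sites whose counts conserve the
record total; the most recurrent BRAF reference site is position 600 with 120
entries (the planted hotspot); thresholding the reference at ≥ 10 entries
while keeping the rare test set in full leaves 38 sites on the plot. The HTML
file is fully self-contained — tooltips and region export work offline.

The same workflow is available from the shell:

```sh
hotspotter prepare --input examples/data/reference_mutations.tsv \
    --source COSMIC_SIM --output ref.tsv
hotspotter prepare --input examples/data/test_mutations.tsv \
    --source UCEC_SIM --output test.tsv
hotspotter merge --reference ref.tsv --test test.tsv --output combined.tsv
hotspotter plot --input combined.tsv --genes TP53,NFE2L2,BRAF \
    --reference-source COSMIC_SIM --test-source UCEC_SIM --svg overlay.svg \
    --html overlay.html
hotspotter query --input combined.tsv --gene NFE2L2 --start 23 --end 48 \
    --output nfe2l2_region.tsv
```

`merge` also supports self-reference exclusion (`--exclude-column`,
`--exclude-keys`) for when the test cohort's samples are already present in
the reference compendium. See `examples/` for narrative scripts covering
parsing, the overlay and region drill-down.

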