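"""Drill into the records behind a hotspot region.

After the overlay shows test mutations stacking over a mutated reference
region, the underlying row-level entries support the follow-up questions.
Here: the NFE2L2 region spanning residues 23-48 (a closed interval — both
endpoints are inside).  Run from the repository root:

    python examples/region_drilldown.py
"""

from pathlib import Path

from hotspotter import (RegionQuery, annotate_positions, export_underlying,
                        merge, read_table, select_region, set_source)

data = Path(__file__).parent / "data"
out = Path("example_output")
out.mkdir(exist_ok=True)

reference, _ = annotate_positions(read_table(data / "reference_mutations.tsv"),
                                  recompute=True)
test, _ = annotate_positions(read_table(data / "test_mutations.tsv"),
                             recompute=True)
combined = merge(set_source(reference, "COSMIC_SIM"),
                 set_source(test, "UCEC_SIM"))

query = RegionQuery(gene_name="NFE2L2", start=23, end=48)
selected = select_region(combined, query)
print(f"{len(selected)} entries in NFE2L2 residues [{query.start}, "
      f"{query.end}] across sources {selected.sources}")

export_underlying(selected, out / "nfe2l2_23_48.tsv")
print(f"wrote {out/'nfe2l2_23_48.tsv'} ranked by source, then position")

# first few drill-down rows, as exported
table = read_table(out / "nfe2l2_23_48.tsv")
for _, row in table.df.head(5).iterrows():
    print(f"  {row['Source']:12s} pos {int(row['Position']):4d}  "
          f"{row['Mutation AA']}")
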