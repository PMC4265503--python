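"""The full overlay workflow on the bundled tables.

Prepare both tables (derive positions, label sources), merge them, count
entries per (gene, position, source), and render the overlay: small blue
reference points under large orange test points, one facet per gene.  Run
from the repository root:

    python examples/overlay_workflow.py
"""

from pathlib import Path

from hotspotter import (annotate_positions, apply_threshold, build_overlay,
                        count_sites, merge, read_table, render_interactive,
                        render_static, set_source, top_sites)

data = Path(__file__).parent / "data"
out = Path("example_output")
out.mkdir(exist_ok=True)

# prepare: annotate positions, label each dataset distinctly
reference = read_table(data / "reference_mutations.tsv")
reference, report = annotate_positions(reference, recompute=True)
reference = set_source(reference, "COSMIC_SIM")
print(report)

test = read_table(data / "test_mutations.tsv")
test, _ = annotate_positions(test, recompute=True)
test = set_source(test, "UCEC_SIM")

# merge and count
combined = merge(reference, test)
counts = count_sites(combined)
print(f"{len(combined)} records -> {len(counts)} distinct "
      f"(gene, position, source) sites; counts sum to "
      f"{sum(c.count for c in counts)}")

# the most recurrent reference site of one gene
for site in top_sites(counts, "BRAF", "COSMIC_SIM", 1):
    print(f"top BRAF reference site: position {site.position}, "
          f"{site.count} entries")

# threshold the reference at 10 entries, keep the rare test set in full
shown = apply_threshold(counts, {"COSMIC_SIM": 10})
print(f"{len(shown)} sites shown after thresholding the reference at >=10")

genes = ["TP53", "PTEN", "CTNNB1", "NFE2L2", "BRAF", "IDH1", "KIT", "EGFR"]
spec = build_overlay(shown, genes, reference_source="COSMIC_SIM",
                     test_source="UCEC_SIM")
render_static(spec, out / "overlay.svg", format="svg")
render_interactive(spec, out / "overlay.html")
print(f"wrote {out/'overlay.svg'} and {out/'overlay.html'} — open the HTML "
      "and hover any marker for gene, position, source and count")
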