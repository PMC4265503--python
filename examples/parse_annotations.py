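"""Parse protein-change annotations into plottable amino-acid positions.

Every mutation entry is reduced to one 1-based residue coordinate: a
substitution sits at its substituted residue, and any other event (deletion,
insertion, frameshift, ...) at the first residue it affects.  Run:

    python examples/parse_annotations.py
"""

from hotspotter import parse_mutation_aa

annotations = [
    "p.V600E",            # the canonical BRAF hotspot substitution
    "p.R132H",            # the canonical IDH1 hotspot substitution
    "p.E746_A750del",     # in-frame deletion: plotted at its left endpoint
    "p.G12fs*2",          # frameshift: plotted where the frame breaks
    "p.R213*",            # nonsense
    "p.Val600Glu",        # three-letter spelling, same site
    "p.?",                # unknown consequence: no site to plot
    "not-an-annotation",  # malformed: typed failure, nothing raised
]

for annotation in annotations:
    r = parse_mutation_aa(annotation)
    if r.ok:
        print(f"{annotation:20s} -> position {r.position:5d}  "
              f"({r.mutation_class.value})")
    else:
        print(f"{annotation:20s} -> {r.status.value} (excluded from counting)")

# The position is what the overlay plots on x; entries whose annotation
# yields no position are retained in the table but never counted.
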