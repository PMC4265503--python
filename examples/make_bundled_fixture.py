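"""Regenerate the bundled synthetic mutation tables in examples/data/.

The bundled pair is the package's default study conditions (8 genes at real
protein lengths, planted site and region hotspots, Poisson background) under
a fixed seed, so every example and the README walkthrough run without any
external download.  Run from the repository root:

    python examples/make_bundled_fixture.py
"""

from pathlib import Path

from hotspotter import default_fixture_spec, generate, write_table

SEED = 20140101  # fixed: the bundled tables are part of the documentation

out = Path(__file__).parent / "data"
out.mkdir(exist_ok=True)
reference, test = generate(default_fixture_spec(seed=SEED))
write_table(reference, out / "reference_mutations.tsv")
write_table(test, out / "test_mutations.tsv")
print(f"wrote {len(reference)} reference and {len(test)} test records to {out}")
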