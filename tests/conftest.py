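import pandas as pd
import pytest

from hotspotter import (MutationTable, annotate_positions, count_sites,
                        default_fixture_spec, generate, merge)
from hotspotter.dataset import GENE_NAME, MUTATION_AA, POSITION, SOURCE


def make_table(rows, provenance=()):
    """Build a MutationTable from (gene, aa, position, source, *extras) dicts."""
    return MutationTable(df=pd.DataFrame(rows), provenance=list(provenance))


@pytest.fixture
def tiny_table():
    return make_table([
        {GENE_NAME: "BRAF", MUTATION_AA: "p.V600E", SOURCE: "REF"},
        {GENE_NAME: "BRAF", MUTATION_AA: "p.V600K", SOURCE: "REF"},
        {GENE_NAME: "IDH1", MUTATION_AA: "p.R132H", SOURCE: "REF"},
        {GENE_NAME: "EGFR", MUTATION_AA: "p.E746_A750del", SOURCE: "REF"},
        {GENE_NAME: "TP53", MUTATION_AA: "p.?", SOURCE: "REF"},
    ], provenance=[(None, "REF")])


@pytest.fixture(scope="session")
def study_conditions():
    """The bundled synthetic study conditions, run through the pipeline once."""
    spec = default_fixture_spec(seed=7)
    reference, test = generate(spec)
    reference, _ = annotate_positions(reference)
    test, _ = annotate_positions(test)
    combined = merge(reference, test)
    counts = count_sites(combined)
    return {"spec": spec, "reference": reference, "test": test,
            "combined": combined, "counts": counts}
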