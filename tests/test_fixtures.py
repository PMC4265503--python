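"""Synthetic-data generator: planted truth must be recoverable."""

import math
from dataclasses import replace

import pytest

from hotspotter import (FixtureSpec, annotate_positions, count_sites,
                        default_fixture_spec, generate, merge, parse_mutation_aa,
                        recover_planted)
from hotspotter.dataset import MUTATION_AA, POSITION, SOURCE


def pipeline_counts(spec):
    reference, test = generate(spec)
    reference, _ = annotate_positions(reference)
    test, _ = annotate_positions(test)
    return count_sites(merge(reference, test))


def test_planted_site_construction():
    spec = FixtureSpec(genes=(("G", 700),),
                       planted_sites=(("G", 600, "TEST", 3),))
    reference, test = generate(spec)
    assert len(reference) == 0
    assert len(test) == 3
    annotated, _ = annotate_positions(test)
    assert annotated.df[POSITION].tolist() == [600, 600, 600]


def test_region_hotspot_conservation():
    spec = FixtureSpec(genes=(("G", 100),),
                       region_hotspots=(("G", 23, 48, "REF", 26),), seed=5)
    reference, _ = generate(spec)
    annotated, _ = annotate_positions(reference)
    positions = annotated.df[POSITION].tolist()
    assert len(positions) == 26  # total distributed, none lost
    assert all(23 <= p <= 48 for p in positions)


def test_same_seed_is_bit_reproducible():
    spec = default_fixture_spec(seed=11)
    ref_a, test_a = generate(spec)
    ref_b, test_b = generate(spec)
    assert ref_a.df.equals(ref_b.df)
    assert test_a.df.equals(test_b.df)


def test_different_seeds_differ():
    ref_a, _ = generate(default_fixture_spec(seed=1))
    ref_b, _ = generate(default_fixture_spec(seed=2))
    assert not ref_a.df[MUTATION_AA].tolist() == ref_b.df[MUTATION_AA].tolist()


def test_every_generated_annotation_parses_at_its_position():
    """Generator and parser agree: all emitted annotations are well formed."""
    reference, test = generate(default_fixture_spec(seed=3))
    for table in (reference, test):
        for ann in table.df[MUTATION_AA]:
            assert parse_mutation_aa(ann).ok


def test_planted_position_beyond_length_rejected():
    spec = FixtureSpec(genes=(("G", 100),),
                       planted_sites=(("G", 101, "REF", 1),))
    with pytest.raises(ValueError, match="beyond"):
        generate(spec)
    bad_region = FixtureSpec(genes=(("G", 100),),
                             region_hotspots=(("G", 90, 120, "REF", 5),))
    with pytest.raises(ValueError, match="invalid"):
        generate(bad_region)


def test_zero_background_recovers_planted_counts_exactly():
    """With no background and no region hotspots, the pipeline tally IS the
    planted truth, for every seed."""
    for seed in range(5):
        base = default_fixture_spec(seed=seed, background=0.0)
        spec = replace(base, region_hotspots=())
        counts = pipeline_counts(spec)
        planted = {(g, p, s): c for g, p, s, c in spec.planted_sites}
        got = {(s.gene_name, s.position, s.source): s.count for s in counts}
        assert got == planted


def test_zero_background_region_draws_add_to_planted_sites():
    """A region hotspot overlapping a planted site adds its draws there:
    nothing is lost, and every non-planted site lies inside a region."""
    spec = default_fixture_spec(seed=2, background=0.0)
    counts = pipeline_counts(spec)
    planted = {(g, p, s): c for g, p, s, c in spec.planted_sites}
    region_total = sum(t for *_, t in spec.region_hotspots)
    assert sum(s.count for s in counts) == sum(planted.values()) + region_total
    for s in counts:
        key = (s.gene_name, s.position, s.source)
        if key in planted:
            assert s.count >= planted[key]
        else:
            assert any(s.gene_name == g and a <= s.position <= b
                       and s.source == src
                       for g, a, b, src, _ in spec.region_hotspots)


def test_recover_planted_threshold_semantics():
    spec = FixtureSpec(
        genes=(("G", 700),),
        planted_sites=(("G", 100, "REF", 12), ("G", 200, "REF", 3)))
    report = recover_planted(spec, pipeline_counts(spec), min_count=10)
    assert report.ok
    assert [(g, p) for g, p, s, c in report.expected] == [("G", 100)]
    assert report.n_false_survivors == 0


def test_recover_planted_empty_spec():
    spec = FixtureSpec(genes=(("G", 100),))
    report = recover_planted(spec, pipeline_counts(spec), min_count=10)
    assert report.expected == [] and report.ok


def test_background_false_survivor_rate_within_analytic_bound():
    """With the background rate low enough that the analytic tail bound puts
    P(any background site >= min_count) well under 1%, a 20-seed sweep should
    show (essentially) no false survivors."""
    min_count = 10
    background = 3.0
    spec0 = default_fixture_spec(seed=0, background=background)
    # Bound: a background site's count is at most Binomial(N, 1/L) thinned
    # from N ~ Poisson(rate); P(site count >= 10) is astronomically small for
    # rate 3 spread over hundreds of residues.  Union bound over all sites:
    n_genes = len(spec0.genes)
    min_len = min(n for _, n in spec0.genes)
    lam = background / min_len
    per_site = sum(math.exp(-lam) * lam ** k / math.factorial(k)
                   for k in range(min_count, 30))
    assert per_site * n_genes * 2 * min_len * 20 < 0.01  # oracle bound
    false_runs = 0
    for seed in range(20):
        spec = default_fixture_spec(seed=seed, background=background)
        report = recover_planted(spec, pipeline_counts(spec), min_count)
        assert report.ok  # planted sites always recovered
        if report.n_false_survivors:
            false_runs += 1
    assert false_runs == 0
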