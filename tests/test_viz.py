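"""Overlay construction and rendering contracts."""

import json
import re
import xml.etree.ElementTree as ET

import pytest

from hotspotter import SiteCount, build_overlay, render_interactive, render_static
from hotspotter.viz import ConfigError

SVG_NS = "{http://www.w3.org/2000/svg}"


@pytest.fixture
def two_source_counts():
    return [
        SiteCount("G1", 100, "REF", 3), SiteCount("G1", 200, "REF", 7),
        SiteCount("G1", 150, "TEST", 2), SiteCount("G2", 50, "REF", 4),
        SiteCount("G2", 50, "TEST", 1),
    ]


@pytest.fixture
def overlay(two_source_counts):
    return build_overlay(two_source_counts, ["G1", "G2"],
                         reference_source="REF", test_source="TEST")


def test_build_overlay_roles_and_layering(overlay):
    ref = overlay.series_by_role("reference")
    test = overlay.series_by_role("test")
    assert ref.source == "REF" and test.source == "TEST"
    assert test.zorder > ref.zorder
    assert test.size > ref.size


def test_single_source_defaults_to_reference():
    counts = [SiteCount("G", 10, "COSMIC", 5)]
    spec = build_overlay(counts, ["G"])
    assert [s.role for s in spec.series] == ["reference"]
    assert spec.series[0].source == "COSMIC"


def test_two_sources_require_explicit_roles(two_source_counts):
    with pytest.raises(ConfigError, match="name reference_source"):
        build_overlay(two_source_counts, ["G1"])


def test_more_than_two_sources_rejected():
    counts = [SiteCount("G", i, src, 1) for i, src in
              enumerate(["A", "B", "C"], start=1)]
    with pytest.raises(ConfigError, match="at most two"):
        build_overlay(counts, ["G"], reference_source="A", test_source="B")


def test_unknown_role_source_rejected(two_source_counts):
    with pytest.raises(ConfigError, match="not present"):
        build_overlay(two_source_counts, ["G1"],
                      reference_source="NOPE", test_source="TEST")


def test_style_override_keeps_invariants(two_source_counts):
    spec = build_overlay(two_source_counts, ["G1"], reference_source="REF",
                         test_source="TEST",
                         style={"reference_color": "#ff7f0e",
                                "test_color": "#1f77b4"})
    assert spec.series_by_role("reference").color == "#ff7f0e"
    assert spec.series_by_role("test").color == "#1f77b4"
    assert spec.series_by_role("test").size > spec.series_by_role("reference").size
    with pytest.raises(ConfigError, match="strictly larger"):
        build_overlay(two_source_counts, ["G1"], reference_source="REF",
                      test_source="TEST",
                      style={"reference_size": 10, "test_size": 4})


def _marker_groups(svg_path):
    root = ET.parse(svg_path).getroot()
    groups = {}
    for g in root.iter(f"{SVG_NS}g"):
        gid = g.get("id", "")
        if gid.startswith("hotspotter-"):
            groups[gid] = len(g.findall(f".//{SVG_NS}use"))
    return groups


def test_static_svg_marker_count_bijection(overlay, two_source_counts, tmp_path):
    """Each site count appears as exactly one marker in its facet/series."""
    path = tmp_path / "overlay.svg"
    render_static(overlay, path, format="svg")
    groups = _marker_groups(path)
    assert sum(groups.values()) == len(two_source_counts)
    assert groups["hotspotter-reference-facet0"] == 2
    assert groups["hotspotter-test-facet0"] == 1
    assert groups["hotspotter-reference-facet1"] == 1
    assert groups["hotspotter-test-facet1"] == 1


def test_static_svg_test_markers_after_reference(overlay, tmp_path):
    """Document order encodes layering: within each facet the test group is
    serialized after the reference group, so test markers sit on top."""
    path = tmp_path / "overlay.svg"
    render_static(overlay, path, format="svg")
    ids = re.findall(r'id="(hotspotter-[a-z]+-facet\d+)"', path.read_text())
    for i in (0, 1):
        assert ids.index(f"hotspotter-test-facet{i}") > \
            ids.index(f"hotspotter-reference-facet{i}")


def test_static_rendering_is_deterministic(overlay, tmp_path):
    a, b = tmp_path / "a.svg", tmp_path / "b.svg"
    render_static(overlay, a, format="svg")
    render_static(overlay, b, format="svg")
    assert a.read_bytes() == b.read_bytes()


def test_static_png_renders(overlay, tmp_path):
    path = tmp_path / "overlay.png"
    render_static(overlay, path, format="png")
    assert path.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"


def test_empty_spec_renders_labelled_empty_facets(tmp_path):
    spec = build_overlay([], ["EMPTY1", "EMPTY2"])
    path = tmp_path / "empty.svg"
    render_static(spec, path, format="svg")
    assert sum(_marker_groups(path).values()) == 0
    assert "EMPTY1" in path.read_text()


def _embedded_payload(html_path):
    html = html_path.read_text()
    m = re.search(r'<script type="application/json" id="hotspotter-data">(.*?)'
                  r'</script>', html, re.S)
    return json.loads(m.group(1)), html


def test_interactive_payload_matches_counts(overlay, two_source_counts, tmp_path):
    """Every marker's embedded hover payload carries the four tooltip fields
    of its site count."""
    path = tmp_path / "overlay.html"
    render_interactive(overlay, path)
    payload, html = _embedded_payload(path)
    got = {(p["gene_name"], p["position"], p["source"], p["count"])
           for p in payload["points"]}
    want = {(c.gene_name, c.position, c.source, c.count)
            for c in two_source_counts}
    assert got == want
    assert payload["tooltip_fields"] == ["gene_name", "position", "source", "count"]
    # one <circle> marker per site, each with a populated tooltip
    circles = re.findall(r'<circle class="marker[^"]*"', html)
    assert len(circles) == len(two_source_counts)
    assert html.count("<title>Gene name:") == len(two_source_counts)
    assert "Count of position: 7" in html


def test_interactive_test_markers_after_reference(overlay, tmp_path):
    path = tmp_path / "overlay.html"
    render_interactive(overlay, path)
    html = path.read_text()
    for facet in re.findall(r'<svg class="facet".*?</svg>', html, re.S):
        roles = re.findall(r'<circle class="marker (\w+)"', facet)
        if "test" in roles and "reference" in roles:
            # all reference circles precede all test circles
            assert roles == sorted(roles, key=lambda r: r == "test")


def test_interactive_rendering_is_deterministic(overlay, tmp_path):
    a, b = tmp_path / "a.html", tmp_path / "b.html"
    render_interactive(overlay, a)
    render_interactive(overlay, b)
    assert a.read_bytes() == b.read_bytes()


def test_interactive_empty_spec(tmp_path):
    spec = build_overlay([], ["G"])
    path = tmp_path / "empty.html"
    render_interactive(spec, path)
    payload, html = _embedded_payload(path)
    assert payload["points"] == []
    assert "<circle" not in html
    assert html.startswith("<!DOCTYPE html>")
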