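"""Overlay rendering: test-set recurrence superimposed on a reference set.

The figure is a stack of gene facets sharing the idiom of a lollipop plot:
x = amino-acid position (1-based, linear), y = entry count at that position.
Two layered point series are drawn per facet — the reference compendium as
small muted (blue) points underneath, the test cohort as intentionally large
salient (orange) points on top — so a low-frequency test mutation sitting on
a reference hotspot site or region is visible at a glance.

Two renderers consume the same :class:`OverlaySpec`:

* :func:`render_static` — SVG or PNG via matplotlib; every site is one
  marker, test markers are serialized after (above) reference markers.
* :func:`render_interactive` — a single self-contained HTML file with an
  inline SVG per facet, native hover tooltips showing (gene, position,
  source, count) for every marker, and a region-selection widget that
  exports the selected points as TSV.  No server, no external assets.

Rendering is deterministic: the same spec yields byte-identical output.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .aggregate import SiteCount

__all__ = ["ConfigError", "SeriesSpec", "OverlaySpec", "DEFAULT_STYLE",
           "build_overlay", "render_static", "render_interactive"]


class ConfigError(ValueError):
    """Invalid overlay configuration (sources, roles or style)."""


#: Default style: the reference series is small and blue, the test series is
#: intentionally large and orange.  Sizes are marker diameters in points for
#: the static renderer and pixel radii are derived from them for the HTML
#: renderer; the ordering (test strictly larger, test on top) is a contract,
#: the magnitudes are only defaults.
DEFAULT_STYLE: dict[str, object] = {
    "reference_color": "#1f77b4",
    "test_color": "#ff7f0e",
    "reference_size": 4.0,
    "test_size": 10.0,
    "facet_height": 1.6,
    "facet_width": 9.0,
    "y_scale": "linear",
}

_TOOLTIP_FIELDS = ("gene_name", "position", "source", "count")
_TOOLTIP_LABELS = {
    "gene_name": "Gene name",
    "position": "Position",
    "source": "Source",
    "count": "Count of position",
}


@dataclass(frozen=True)
class SeriesSpec:
    """One layered point series (role = 'reference' or 'test')."""

    role: str
    source: str
    color: str
    size: float
    zorder: int


@dataclass
class OverlaySpec:
    """A renderable description of one overlay figure."""

    facets: list[str]
    series: list[SeriesSpec]
    counts: list[SiteCount]
    tooltip_fields: tuple[str, ...] = _TOOLTIP_FIELDS
    y_scale: str = "linear"
    facet_height: float = 1.6
    facet_width: float = 9.0

    def series_by_role(self, role: str) -> SeriesSpec | None:
        for s in self.series:
            if s.role == role:
                return s
        return None

    def facet_counts(self, gene: str, source: str) -> list[SiteCount]:
        return [c for c in self.counts
                if c.gene_name == gene and c.source == source]


def build_overlay(counts: Sequence[SiteCount], genes: Sequence[str],
                  reference_source: str | None = None,
                  test_source: str | None = None,
                  style: Mapping[str, object] | None = None) -> OverlaySpec:
    """Assemble an overlay spec from site counts and a facet (gene) list.

    Role assignment is explicit: with two sources present, name which is the
    reference and which the test set.  A single source defaults to the
    reference role (reference-only browsing).  Styles may be overridden per
    key of :data:`DEFAULT_STYLE`, but the layering contract — test markers
    strictly larger than and above reference markers — always holds.
    """
    if not genes:
        raise ConfigError("at least one gene facet is required")
    merged = dict(DEFAULT_STYLE)
    if style:
        unknown = set(style) - set(DEFAULT_STYLE)
        if unknown:
            raise ConfigError(f"unknown style keys: {sorted(unknown)}")
        merged.update(style)

    present: list[str] = []
    for c in counts:
        if c.source not in present:
            present.append(c.source)
    if len(present) > 2:
        raise ConfigError(
            f"counts carry {len(present)} source labels {present}; an overlay "
            "superimposes at most two (reference and test)")
    for named in (reference_source, test_source):
        if named is not None and present and named not in present:
            raise ConfigError(f"source {named!r} not present in counts "
                              f"(have {present})")
    if reference_source is None and test_source is None:
        if len(present) == 1:
            reference_source = present[0]
        elif len(present) == 2:
            raise ConfigError(
                f"two sources present {present}: name reference_source and "
                "test_source explicitly")
    elif reference_source is None or test_source is None:
        # One role named; the other source (if any) takes the remaining role.
        remaining = [s for s in present if s not in (reference_source, test_source)]
        if len(remaining) > 1:
            raise ConfigError("ambiguous role assignment")
        if remaining:
            if reference_source is None:
                reference_source = remaining[0]
            else:
                test_source = remaining[0]

    ref_size = float(merged["reference_size"])
    test_size = float(merged["test_size"])
    if test_size <= ref_size:
        raise ConfigError("test markers must be strictly larger than "
                          f"reference markers (got {test_size} <= {ref_size})")

    series: list[SeriesSpec] = []
    if reference_source is not None:
        series.append(SeriesSpec("reference", reference_source,
                                 str(merged["reference_color"]), ref_size, 1))
    if test_source is not None:
        series.append(SeriesSpec("test", test_source,
                                 str(merged["test_color"]), test_size, 2))
    if not series and counts:
        raise ConfigError("no role assignment for the sources present")

    assigned = {s.source for s in series}
    stray = [s for s in present if s not in assigned]
    if stray:
        raise ConfigError(f"sources {stray} have no reference/test role")

    return OverlaySpec(
        facets=list(genes), series=series, counts=list(counts),
        y_scale=str(merged["y_scale"]),
        facet_height=float(merged["facet_height"]),
        facet_width=float(merged["facet_width"]),
    )


def render_static(spec: OverlaySpec, path: str | Path, format: str = "svg") -> None:
    """Render the overlay to SVG or PNG.

    One marker per site count, one horizontal facet row per gene (empty
    facets are drawn empty but labelled), independent y scaling per facet.
    Output is byte-stable for a fixed spec.
    """
    if format not in ("svg", "png"):
        raise ValueError(f"format must be 'svg' or 'png', got {format!r}")
    path = Path(path)
    n = len(spec.facets)
    with plt.rc_context({"svg.hashsalt": "hotspotter"}):
        fig, axes = plt.subplots(
            n, 1, figsize=(spec.facet_width, spec.facet_height * n),
            sharex=True, squeeze=False)
        xmax = max((c.position for c in spec.counts), default=100)
        for i, gene in enumerate(spec.facets):
            ax = axes[i, 0]
            # Reference first, test second: document order encodes layering.
            for series in sorted(spec.series, key=lambda s: s.zorder):
                sites = spec.facet_counts(gene, series.source)
                xs = [c.position for c in sites]
                ys = [c.count for c in sites]
                ax.plot(xs, ys, linestyle="", marker="o",
                        markersize=series.size, color=series.color,
                        markeredgecolor="none", zorder=series.zorder,
                        gid=f"hotspotter-{series.role}-facet{i}",
                        label=series.source if i == 0 else None)
            ax.set_ylabel(gene, rotation=0, ha="right", va="center", fontsize=9)
            ax.set_xlim(0, xmax * 1.02 + 1)
            if spec.y_scale == "log":
                ax.set_yscale("log")
            else:
                ax.set_ylim(bottom=0)
            ax.margins(y=0.15)
            ax.tick_params(labelsize=7)
        axes[-1, 0].set_xlabel("Amino acid position")
        if spec.series:
            fig.legend(loc="upper right", fontsize=8, frameon=False)
        fig.suptitle("Mutation recurrence overlay", fontsize=10)
        metadata = {"Date": None} if format == "svg" else {}
        fig.savefig(path, format=format, metadata=metadata)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Interactive HTML


def _tooltip_text(spec: OverlaySpec, c: SiteCount) -> str:
    values = {"gene_name": c.gene_name, "position": c.position,
              "source": c.source, "count": c.count}
    return "\n".join(f"{_TOOLTIP_LABELS[f]}: {values[f]}"
                     for f in spec.tooltip_fields)


def _facet_svg(spec: OverlaySpec, gene: str, width: int = 880,
               height: int = 130) -> str:
    pad_l, pad_r, pad_t, pad_b = 55, 15, 12, 24
    inner_w = width - pad_l - pad_r
    inner_h = height - pad_t - pad_b
    xmax = max((c.position for c in spec.counts), default=100)
    ymax = max((c.count for c in spec.counts
                if c.gene_name == gene), default=1)

    def sx(pos: int) -> float:
        return pad_l + inner_w * pos / max(xmax, 1)

    def sy(count: int) -> float:
        return pad_t + inner_h * (1 - count / max(ymax, 1))

    parts = [
        f'<svg class="facet" width="{width}" height="{height}" '
        f'data-gene="{html.escape(gene, quote=True)}" role="img">',
        f'<rect x="{pad_l}" y="{pad_t}" width="{inner_w}" height="{inner_h}" '
        'fill="#fafafa" stroke="#cccccc"/>',
        f'<text x="8" y="{pad_t + inner_h / 2:.1f}" class="gene-label">'
        f'{html.escape(gene)}</text>',
        f'<text x="{pad_l}" y="{height - 6}" class="tick">1</text>',
        f'<text x="{width - pad_r}" y="{height - 6}" class="tick" '
        f'text-anchor="end">{xmax}</text>',
        f'<text x="{pad_l - 4}" y="{pad_t + 8}" class="tick" '
        f'text-anchor="end">{ymax}</text>',
    ]
    # Reference circles first, test circles last: SVG paints in document
    # order, so test markers are never occluded.
    for series in sorted(spec.series, key=lambda s: s.zorder):
        radius = max(series.size / 2.0, 1.5)
        for c in spec.facet_counts(gene, series.source):
            title = html.escape(_tooltip_text(spec, c))
            parts.append(
                f'<circle class="marker {series.role}" cx="{sx(c.position):.2f}" '
                f'cy="{sy(c.count):.2f}" r="{radius:.1f}" fill="{series.color}" '
                f'fill-opacity="0.85" data-gene="{html.escape(c.gene_name, quote=True)}" '
                f'data-position="{c.position}" data-source="{html.escape(c.source, quote=True)}" '
                f'data-count="{c.count}"><title>{title}</title></circle>')
    parts.append("</svg>")
    return "\n".join(parts)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Mutation recurrence overlay</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; color: #222; }}
.gene-label {{ font-size: 11px; font-weight: bold; }}
.tick {{ font-size: 9px; fill: #666; }}
.marker:hover {{ stroke: #000; stroke-width: 1.5; }}
.controls {{ margin: 1em 0; padding: 0.6em; background: #f0f0f0; }}
.controls label {{ margin-right: 0.8em; }}
.legend span {{ margin-right: 1.2em; }}
.dot {{ display: inline-block; border-radius: 50%; vertical-align: middle; }}
</style>
</head>
<body>
<h2>Mutation recurrence overlay</h2>
<p>x: amino-acid position (1-based) &mdash; y: count of position (entries at
that site). Hover a marker for gene, position, source and count.</p>
<div class="legend">{legend}</div>
<div class="controls">
<strong>Region drill-down:</strong>
<label>gene <select id="region-gene">{gene_options}</select></label>
<label>start <input id="region-start" type="number" min="1" value="1" size="6"></label>
<label>end <input id="region-end" type="number" min="1" value="100" size="6"></label>
<button id="region-export">Export region TSV</button>
</div>
{facets}
<script type="application/json" id="hotspotter-data">{payload}</script>
<script>
(function () {{
  var data = JSON.parse(document.getElementById("hotspotter-data").textContent);
  document.getElementById("region-export").addEventListener("click", function () {{
    var gene = document.getElementById("region-gene").value;
    var start = parseInt(document.getElementById("region-start").value, 10);
    var end = parseInt(document.getElementById("region-end").value, 10);
    if (!(start >= 1) || !(end >= start)) {{
      alert("Need 1 <= start <= end."); return;
    }}
    var rows = data.points.filter(function (p) {{
      return p.gene_name === gene && p.position >= start && p.position <= end;
    }});
    rows.sort(function (a, b) {{
      return a.source < b.source ? -1 : a.source > b.source ? 1
           : a.position - b.position;
    }});
    var tsv = "Gene name\\tPosition\\tSource\\tCount\\n" + rows.map(function (p) {{
      return [p.gene_name, p.position, p.source, p.count].join("\\t");
    }}).join("\\n") + "\\n";
    var blob = new Blob([tsv], {{type: "text/tab-separated-values"}});
    var a = document.createElement("a");
    a.href = URL.createObjectURL(blob);
    a.download = gene + "_" + start + "-" + end + ".tsv";
    a.click();
    URL.revokeObjectURL(a.href);
  }});
}})();
</script>
</body>
</html>
"""


def render_interactive(spec: OverlaySpec, path: str | Path) -> None:
    """Write a self-contained interactive HTML overlay.

    Every marker carries a native tooltip with the gene name, amino-acid
    position, source and count of position, plus machine-readable ``data-*``
    attributes; the full point set is embedded as a JSON payload consumed by
    the region-selection widget, which exports any (gene, interval) slice as
    TSV sorted by source then position.
    """
    path = Path(path)
    payload = {
        "facets": spec.facets,
        "series": [{"role": s.role, "source": s.source, "color": s.color,
                    "size": s.size} for s in spec.series],
        "tooltip_fields": list(spec.tooltip_fields),
        "points": [
            {"gene_name": c.gene_name, "position": c.position,
             "source": c.source, "count": c.count,
             "role": next((s.role for s in spec.series if s.source == c.source),
                          "reference")}
            for c in spec.counts
        ],
    }
    legend = "".join(
        f'<span><span class="dot" style="background:{s.color};'
        f'width:{int(s.size)}px;height:{int(s.size)}px"></span> '
        f'{html.escape(s.source)} ({s.role})</span>'
        for s in spec.series)
    gene_options = "".join(
        f'<option value="{html.escape(g, quote=True)}">{html.escape(g)}</option>'
        for g in spec.facets)
    facets = "\n".join(_facet_svg(spec, gene) for gene in spec.facets)
    document = _HTML_TEMPLATE.format(
        legend=legend, gene_options=gene_options, facets=facets,
        payload=json.dumps(payload, separators=(",", ":"), sort_keys=True))
    path.write_text(document, encoding="utf-8")
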