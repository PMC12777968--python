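"""Declarative visualization spec: tracks, marks, scales, encodings.

The spec targets the Vega-Lite JSON grammar (v5, ``$schema`` pinned below).
Its structure is constant-size: read data enters as *one* compressed
``§``-joined payload string, and in-spec transform expressions split it
into records/fields/elements at render time — so only the payload grows
with read count, never the marks or transforms.

Colors follow the Wong colorblind-safe palette throughout.  Read borders
encode mapping quality: near-certain placements (MAPQ ≥ 60) are grey,
uncertain ones fade through yellow down to vermillion at MAPQ 0, making
problematic mappings visible at a glance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .core import PlotDataset

VEGA_LITE_SCHEMA = "https://vega.github.io/schema/vega-lite/v5.json"

# Wong's 8-color colorblind-safe palette, plus the customary grey.
PALETTE: Dict[str, str] = {
    "black": "#000000",
    "orange": "#E69F00",
    "skyblue": "#56B4E9",
    "green": "#009E73",
    "yellow": "#F0E442",
    "blue": "#0072B2",
    "vermillion": "#D55E00",
    "purple": "#CC79A7",
    "grey": "#999999",
}

_BASE_COLORS = {
    "A": PALETTE["green"],
    "C": PALETTE["blue"],
    "G": PALETTE["orange"],
    "T": PALETTE["vermillion"],
    "N": PALETTE["grey"],
}

MATCH_FILL = PALETTE["grey"]
DELETION_COLOR = PALETTE["black"]
INSERTION_COLOR = PALETTE["purple"]
LINKER_COLOR = PALETTE["grey"]
HIGHLIGHT_FILL = PALETTE["yellow"]

# MAPQ border scale breakpoints: vermillion at 0 fading through yellow at 30
# (≈1/1000 placement-error, a conventional "moderate" confidence) to grey at
# the near-certain threshold of 60; clamped to grey above.
_MAPQ_STOPS: Tuple[Tuple[int, str], ...] = (
    (0, PALETTE["vermillion"]),
    (30, PALETTE["yellow"]),
    (60, PALETTE["grey"]),
)


def base_color(base: str) -> str:
    """Nucleotide color (Wong palette); total and injective on A/C/G/T."""
    try:
        return _BASE_COLORS[base.upper()]
    except KeyError:
        raise ValueError(f"unknown base symbol {base!r}") from None


def _hex_to_rgb(color: str) -> Tuple[int, int, int]:
    return tuple(int(color[i : i + 2], 16) for i in (1, 3, 5))


def mapq_border_color(mapq: int) -> str:
    """Border color for a read's mapping quality.

    Piecewise-linear RGB interpolation along vermillion → yellow → grey,
    anchored at MAPQ 0/30/60; values above 60 clamp to grey.
    """
    if not 0 <= mapq <= 255:
        raise ValueError(f"MAPQ out of range: {mapq}")
    if mapq >= _MAPQ_STOPS[-1][0]:
        return _MAPQ_STOPS[-1][1]
    for (q0, c0), (q1, c1) in zip(_MAPQ_STOPS, _MAPQ_STOPS[1:]):
        if q0 <= mapq <= q1:
            t = (mapq - q0) / (q1 - q0)
            rgb0, rgb1 = _hex_to_rgb(c0), _hex_to_rgb(c1)
            rgb = tuple(round(a + t * (b - a)) for a, b in zip(rgb0, rgb1))
            return "#{:02X}{:02X}{:02X}".format(*rgb)
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class PlotOptions:
    """Rendering/subsampling options shared by all exporters."""

    max_read_depth: int = 500
    plot_all: bool = False
    aux_tags: Tuple[str, ...] = ()
    embed_js: bool = True
    width: int = 800
    seed: int = 42
    show_arrows: bool = True  # pointed end on reverse-strand reads

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.max_read_depth < 1:
            raise ValueError(f"max_read_depth must be >= 1, got {self.max_read_depth}")


# window width above which per-base reference letters stop being legible
REFERENCE_LETTER_LIMIT = 2000


def build_plot_spec(dataset: PlotDataset, options: PlotOptions) -> dict:
    """Assemble the full declarative spec for one region.

    Vertically concatenated tracks: reference letters + coverage bars on
    top, then the read track with highlight rectangles behind it.  Read
    data is the single compressed payload; the transform pipeline (constant
    size, independent of read count) splits it on ``§`` and spaces and
    parses the edit grammar client-side.  Interactive parameters: a
    read-name search box and hover tooltips (name, MAPQ, position, plus any
    requested aux tags).
    """
    region = dataset.region
    n = len(region)
    if len(dataset.reference) != n or len(dataset.coverage) != n:
        raise ValueError("dataset reference/coverage length does not match region")

    aux_table = {
        read.name: dict(read.aux)
        for read in dataset.reads
        if read.aux
    }
    row_table = {f.name: f.row for f in dataset.fragments}

    tooltip = [
        {"field": "name", "type": "nominal", "title": "read"},
        {"field": "mapq", "type": "quantitative", "title": "MAPQ"},
        {"field": "pos", "type": "quantitative", "title": "position"},
    ] + [
        {"field": f"aux.{tag}", "type": "nominal", "title": tag}
        for tag in options.aux_tags
    ]

    coverage_track = {
        "name": "coverage",
        "height": 60,
        "data": {"name": "coverage"},
        "mark": {"type": "bar", "color": PALETTE["blue"]},
        "encoding": {
            "x": {
                "field": "pos",
                "type": "quantitative",
                "scale": {"domain": [region.start, region.end + 1]},
                "axis": None,
            },
            "y": {"field": "depth", "type": "quantitative", "title": "coverage"},
        },
    }

    reference_track = {
        "name": "reference",
        "height": 16,
        "data": {"name": "reference"},
        "mark": {
            "type": "text",
            "fontSize": 10,
            "font": "monospace",
            "opacity": 1 if n <= REFERENCE_LETTER_LIMIT else 0,
        },
        "encoding": {
            "x": {
                "field": "pos",
                "type": "quantitative",
                "scale": {"domain": [region.start, region.end + 1]},
                "axis": None,
            },
            "text": {"field": "base", "type": "nominal"},
            "color": {
                "field": "base",
                "type": "nominal",
                "scale": {
                    "domain": list(_BASE_COLORS),
                    "range": list(_BASE_COLORS.values()),
                },
                "legend": None,
            },
        },
    }

    # Constant-size transform pipeline: payload → records → fields → elements.
    read_transforms = [
        {"calculate": f"split(datum.packed, '{chr(0xA7)}')", "as": "records"},
        {"flatten": ["records"]},
        {"calculate": "split(datum.records, ' ')", "as": "fields"},
        {"calculate": "datum.fields[0]", "as": "name"},
        {"calculate": "toNumber(datum.fields[1])", "as": "pos"},
        {"calculate": "toNumber(datum.fields[2])", "as": "mapq"},
        {"calculate": "datum.fields[3]", "as": "strand"},
        {"calculate": "split(datum.fields[4], '|')", "as": "edit_tokens"},
        {"flatten": ["edit_tokens"]},
    ]

    read_track = {
        "name": "reads",
        "data": {"name": "reads"},
        "transform": read_transforms,
        "layer": [
            {
                "name": "highlight_background",
                "data": {"name": "highlights"},
                "mark": {"type": "rect", "fill": HIGHLIGHT_FILL, "opacity": 0.25},
                "encoding": {
                    "x": {"field": "start", "type": "quantitative"},
                    "x2": {"field": "end2"},
                },
            },
            {
                "name": "fragment_rects",
                "mark": {"type": "rect", "fill": MATCH_FILL, "strokeWidth": 1},
                "encoding": {
                    "x": {
                        "field": "pos",
                        "type": "quantitative",
                        "scale": {"domain": [region.start, region.end + 1]},
                        "title": str(region.chrom),
                    },
                    "y": {"field": "row", "type": "ordinal", "axis": None},
                    "stroke": {
                        "field": "mapq",
                        "type": "quantitative",
                        "scale": {
                            "domain": [q for q, _ in _MAPQ_STOPS],
                            "range": [c for _, c in _MAPQ_STOPS],
                            "clamp": True,
                        },
                        "legend": {"title": "MAPQ"},
                    },
                    "opacity": {
                        "condition": {
                            "test": "read_search == '' || test(regexp(read_search), datum.name)",
                            "value": 1,
                        },
                        "value": 0.15,
                    },
                    "tooltip": tooltip,
                },
            },
        ],
    }

    spec = {
        "$schema": VEGA_LITE_SCHEMA,
        "usermeta": {
            "region": {"chrom": region.chrom, "start": region.start, "end": region.end},
            "n_rows": dataset.n_rows,
            "n_reads": len(dataset.reads),
            "palette": PALETTE,
            "mapq_stops": [[q, c] for q, c in _MAPQ_STOPS],
            "base_colors": _BASE_COLORS,
            "aux": aux_table,
            "rows": row_table,
            "show_arrows": options.show_arrows,
        },
        "params": [
            {
                "name": "read_search",
                "value": "",
                "bind": {"input": "text", "name": "Read name: "},
            }
        ],
        "width": options.width,
        "vconcat": [coverage_track, reference_track, read_track],
        "datasets": {
            "reads": [{"packed": dataset.packed_values}],
            "reference": [
                {"pos": region.start + i, "base": b}
                for i, b in enumerate(dataset.reference)
            ],
            "coverage": [
                {"pos": region.start + i, "depth": int(d)}
                for i, d in enumerate(dataset.coverage)
            ],
            "highlights": [
                {
                    "start": h.region.start,
                    "end2": h.region.end + 1,
                    "label": h.label,
                    "source": h.source,
                }
                for h in dataset.highlights
            ],
        },
    }
    return spec


def spec_to_json(spec: dict) -> str:
    """Canonical (sorted-keys, compact) JSON serialization of the spec."""
    return json.dumps(spec, sort_keys=True, separators=(",", ":"), ensure_ascii=False)
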