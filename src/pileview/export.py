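"""Exporters: self-contained HTML, static images, and raw data files.

Every exporter is a pure function of (dataset, options): no timestamps,
hostnames, or other environment state are written, so repeated runs emit
byte-identical files.
"""

from __future__ import annotations

import io
import json
import os
import re
from pathlib import Path
from typing import List, Optional, Sequence, TextIO, Union

from ._client import (
    CDN_URLS,
    HTML_TEMPLATE,
    LZ_DECOMPRESS_JS,
    NO_EMBED_SHIM_JS,
    RENDERER_JS,
)
from .core import Highlight, GenomicRegion, PlotDataset
from .lzstr import compress_utf16, decompress_utf16
from .plotspec import PlotOptions, spec_to_json
from .render import render_svg, render_with_matplotlib

STATIC_FORMATS = ("svg", "png", "pdf")
DATA_FORMATS = ("json", "tsv")

_PAYLOAD_RE = re.compile(r"var PAYLOAD=(\"(?:[^\"\\]|\\.)*\");")


def write_html(spec: dict, out_path: os.PathLike, embed_js: bool = True) -> None:
    """Write a single self-contained HTML report.

    The spec is serialized, lz-string-compressed, and embedded as one
    escaped string literal next to a small decompressor.  With ``embed_js``
    the full rendering runtime is inlined too and the file references no
    external URL; without it, the runtime comes from pinned CDN script
    tags, which makes the file smaller but requires network access when
    opened.
    """
    payload = compress_utf16(spec_to_json(spec))
    # \uXXXX-escape everything non-ASCII: safe in any <script> context
    literal = json.dumps(payload, ensure_ascii=True)
    region = spec.get("usermeta", {}).get("region", {})
    if region:
        title = f"pileup {region['chrom']}:{region['start']}-{region['end']}"
    else:
        title = "pileup"
    if embed_js:
        runtime_scripts = ""
        inline_js = LZ_DECOMPRESS_JS + RENDERER_JS
    else:
        runtime_scripts = "".join(f'<script src="{url}"></script>\n' for url in CDN_URLS)
        inline_js = LZ_DECOMPRESS_JS + NO_EMBED_SHIM_JS
    html = HTML_TEMPLATE.format(
        title=title,
        runtime_scripts=runtime_scripts,
        payload_literal=literal,
        inline_js=inline_js,
    )
    Path(out_path).write_text(html, encoding="utf-8", newline="\n")


def read_embedded_spec(html_path: os.PathLike) -> dict:
    """Recover the plot spec from a written report (decompress + parse)."""
    text = Path(html_path).read_text(encoding="utf-8")
    m = _PAYLOAD_RE.search(text)
    if not m:
        raise ValueError(f"no embedded payload found in {html_path}")
    compressed = json.loads(m.group(1))
    return json.loads(decompress_utf16(compressed))


def external_urls(html_path: os.PathLike) -> List[str]:
    """All http(s) URLs appearing in src/href attributes of the report."""
    text = Path(html_path).read_text(encoding="utf-8")
    return re.findall(r"(?:src|href)\s*=\s*[\"'](https?://[^\"']+)[\"']", text)


def write_static(
    dataset: PlotDataset,
    out_path: os.PathLike,
    fmt: str,
    options: Optional[PlotOptions] = None,
) -> None:
    """Render the dataset to SVG (direct drawing) or PNG/PDF (matplotlib)."""
    options = options or PlotOptions()
    if fmt == "svg":
        Path(out_path).write_text(render_svg(dataset, options), encoding="utf-8", newline="\n")
    elif fmt in ("png", "pdf"):
        render_with_matplotlib(dataset, options, out_path, fmt)
    else:
        raise ValueError(f"unsupported static format {fmt!r}; expected one of {STATIC_FORMATS}")


# --------------------------------------------------------------------------
# Data export
# --------------------------------------------------------------------------


def _read_rows(dataset: PlotDataset) -> List[dict]:
    rows = []
    for frag in dataset.fragments:
        for read in frag.reads:
            rows.append(
                {
                    "name": read.name,
                    "pos": read.pos,
                    "mapq": read.mapq,
                    "strand": read.strand,
                    "row": frag.row,
                    "edits": read.edits.text,
                }
            )
    return rows


def _reference_rows(dataset: PlotDataset) -> List[dict]:
    start = dataset.region.start
    return [{"pos": start + i, "base": b} for i, b in enumerate(dataset.reference)]


def _highlight_rows(dataset: PlotDataset) -> List[dict]:
    return [
        {"start": h.region.start, "end": h.region.end, "label": h.label}
        for h in dataset.highlights
    ]


def write_data(
    dataset: PlotDataset,
    out: Union[os.PathLike, TextIO],
    fmt: str,
    spec: Optional[dict] = None,
) -> None:
    """Export the underlying data as JSON or TSV.

    JSON is one document with four sections: the full plot ``spec`` plus
    ``reads``/``reference``/``highlights`` tables.  TSV writes the three
    tables; given a path, they land in sibling files
    (``<stem>.reads.tsv`` etc.), while a stream gets all three separated by
    ``#`` section markers (for shell pipelines).
    """
    if fmt == "json":
        doc = {
            "spec": spec or {},
            "reads": _read_rows(dataset),
            "reference": _reference_rows(dataset),
            "highlights": _highlight_rows(dataset),
        }
        text = json.dumps(doc, sort_keys=True, indent=1, ensure_ascii=False) + "\n"
        if hasattr(out, "write"):
            out.write(text)
        else:
            Path(out).write_text(text, encoding="utf-8", newline="\n")
    elif fmt == "tsv":
        tables = {
            "reads": (["name", "pos", "mapq", "strand", "row", "edits"], _read_rows(dataset)),
            "reference": (["pos", "base"], _reference_rows(dataset)),
            "highlights": (["start", "end", "label"], _highlight_rows(dataset)),
        }
        if hasattr(out, "write"):
            for name, (cols, rows) in tables.items():
                out.write(f"#{name}\n")
                out.write(_tsv_text(cols, rows))
        else:
            base = Path(out)
            stem = base.with_suffix("") if base.suffix == ".tsv" else base
            for name, (cols, rows) in tables.items():
                Path(f"{stem}.{name}.tsv").write_text(
                    _tsv_text(cols, rows), encoding="utf-8", newline="\n"
                )
    else:
        raise ValueError(f"unsupported data format {fmt!r}; expected one of {DATA_FORMATS}")


def _tsv_text(cols: Sequence[str], rows: Sequence[dict]) -> str:
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"


def read_data_tsv(path: os.PathLike) -> List[dict]:
    """Parse one exported TSV table back into dicts (numbers restored)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    cols = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        fields = line.split("\t")
        row = {}
        for c, v in zip(cols, fields):
            row[c] = int(v) if c in ("pos", "mapq", "row", "start", "end") else v
        out.append(row)
    return out
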