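"""Server-side static rendering: marks, SVG, and raster backends.

Static output draws the expanded marks directly — the packed payload is
decoded server-side, so no browser or JavaScript runtime is involved and
the tool stays usable on headless clusters.  One mark list feeds all
formats: the SVG writer emits deterministic text (byte-identical across
runs for identical inputs), and PNG/PDF paint the same marks with
matplotlib.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

from .core import Fragment, PlotDataset
from .encoding import decode_edits
from .plotspec import (
    DELETION_COLOR,
    HIGHLIGHT_FILL,
    INSERTION_COLOR,
    LINKER_COLOR,
    MATCH_FILL,
    PALETTE,
    REFERENCE_LETTER_LIMIT,
    PlotOptions,
    base_color,
    mapq_border_color,
)

_MARGIN = 10.0
_COVERAGE_H = 60.0
_REF_H = 14.0
_ROW_PITCH = 12.0
_READ_H = 9.0


@dataclasses.dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str
    stroke: str = ""
    stroke_width: float = 0.0
    opacity: float = 1.0
    cls: str = ""
    title: str = ""


@dataclasses.dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    color: str
    width: float = 1.0
    cls: str = ""


@dataclasses.dataclass(frozen=True)
class Text:
    x: float
    y: float
    s: str
    color: str
    size: float = 10.0


@dataclasses.dataclass(frozen=True)
class Polygon:
    points: Tuple[Tuple[float, float], ...]
    fill: str
    cls: str = ""


@dataclasses.dataclass
class FragmentGroup:
    """All marks belonging to one fragment (one ``<g>`` in the SVG)."""

    name: str
    marks: List[object] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class MarkSet:
    width: float
    height: float
    background: List[Rect] = dataclasses.field(default_factory=list)
    coverage: List[Rect] = dataclasses.field(default_factory=list)
    reference: List[Text] = dataclasses.field(default_factory=list)
    fragments: List[FragmentGroup] = dataclasses.field(default_factory=list)
    labels: List[Text] = dataclasses.field(default_factory=list)


def compute_marks(dataset: PlotDataset, options: PlotOptions) -> MarkSet:
    """Expand the dataset into positioned, colored drawing primitives."""
    region = dataset.region
    n = len(region)
    plot_w = float(options.width) - 2 * _MARGIN
    bw = plot_w / n  # pixels per base

    def x(pos: int) -> float:
        # left pixel edge of a 1-based reference position, clamped to the plot
        return _MARGIN + max(0.0, min(float(n), pos - region.start)) * bw

    def x_end(pos: int) -> float:
        return _MARGIN + max(0.0, min(float(n), pos - region.start + 1)) * bw

    show_letters = n <= REFERENCE_LETTER_LIMIT and bw >= 4.0
    y_cov = _MARGIN
    y_ref = y_cov + _COVERAGE_H + 4
    y_reads = y_ref + (_REF_H if show_letters else 0) + 4
    n_rows = dataset.n_rows or max((f.row for f in dataset.fragments), default=0)
    height = y_reads + n_rows * _ROW_PITCH + _MARGIN

    marks = MarkSet(width=float(options.width), height=height)

    # highlights as full-height background bands
    for h in dataset.highlights:
        x0, x1 = x(h.region.start), x_end(h.region.end)
        if x1 <= x0:
            continue
        marks.background.append(
            Rect(x0, y_cov, x1 - x0, height - y_cov - _MARGIN, HIGHLIGHT_FILL,
                 opacity=0.25, cls="highlight", title=h.label)
        )

    # coverage bars, merged into runs of equal depth
    max_depth = max((int(d) for d in dataset.coverage), default=0) or 1
    run_start = 0
    cov = list(int(d) for d in dataset.coverage)
    for i in range(1, n + 1):
        if i == n or cov[i] != cov[run_start]:
            depth = cov[run_start]
            if depth > 0:
                bar_h = _COVERAGE_H * depth / max_depth
                marks.coverage.append(
                    Rect(x(region.start + run_start), y_cov + _COVERAGE_H - bar_h,
                         x_end(region.start + i - 1) - x(region.start + run_start),
                         bar_h, PALETTE["blue"], cls="coverage",
                         title=f"depth {depth}")
                )
            run_start = i
    marks.labels.append(
        Text(_MARGIN, y_cov + 8, f"coverage (max {max_depth})", PALETTE["black"], 8.0)
    )

    if show_letters:
        for i, b in enumerate(dataset.reference):
            color = base_color(b) if b in "ACGTN" else PALETTE["black"]
            marks.reference.append(
                Text(x(region.start + i) + bw / 2, y_ref + _REF_H - 4, b, color, 9.0)
            )

    for frag in dataset.fragments:
        marks.fragments.append(_fragment_marks(frag, dataset, options, x, x_end, y_reads, bw))

    marks.labels.append(
        Text(float(options.width) / 2, height - 1, str(region), PALETTE["black"], 9.0)
    )
    return marks


def _fragment_marks(frag: Fragment, dataset: PlotDataset, options: PlotOptions,
                    x, x_end, y_reads: float, bw: float) -> FragmentGroup:
    region = dataset.region
    group = FragmentGroup(name=frag.name)
    y = y_reads + (frag.row - 1) * _ROW_PITCH
    # mate linker behind the reads
    if len(frag.reads) == 2:
        left, right = frag.reads
        if right.pos > left.end + 1:
            group.marks.append(
                Line(x_end(left.end), y + _READ_H / 2, x(right.pos), y + _READ_H / 2,
                     LINKER_COLOR, 1.0, cls="linker")
            )
    for read in frag.reads:
        if read.end < region.start or read.pos > region.end:
            continue  # mate entirely outside the window
        border = mapq_border_color(read.mapq)
        x0, x1 = x(read.pos), x_end(read.end)
        group.marks.append(
            Rect(x0, y, x1 - x0, _READ_H, MATCH_FILL, stroke=border,
                 stroke_width=1.0, cls="read",
                 title=f"{read.name} pos={read.pos} MAPQ={read.mapq} {read.strand}")
        )
        if options.show_arrows and read.strand == "-" and read.pos >= region.start:
            tip = max(_MARGIN, x0 - min(4.0, bw))
            group.marks.append(
                Polygon(((x0, y), (tip, y + _READ_H / 2), (x0, y + _READ_H)),
                        border, cls="arrow")
            )
        for el in decode_edits(read.edits.text, read.pos):
            if el.end < region.start or el.start > region.end:
                continue
            ex0, ex1 = x(el.start), x_end(el.end)
            if el.kind == "mismatch":
                group.marks.append(
                    Rect(ex0, y, max(ex1 - ex0, 0.5), _READ_H, base_color(el.base),
                         cls="mismatch", title=f"{el.base}@{el.start}")
                )
            elif el.kind == "deletion":
                group.marks.append(
                    Rect(ex0, y, ex1 - ex0, _READ_H, "#FFFFFF", cls="deletion-gap")
                )
                group.marks.append(
                    Line(ex0, y + _READ_H / 2, ex1, y + _READ_H / 2,
                         DELETION_COLOR, 1.5, cls="deletion")
                )
            elif el.kind == "skip":
                group.marks.append(
                    Rect(ex0, y, ex1 - ex0, _READ_H, "#FFFFFF", cls="skip-gap")
                )
                group.marks.append(
                    Line(ex0, y + _READ_H / 2, ex1, y + _READ_H / 2,
                         LINKER_COLOR, 0.75, cls="skip")
                )
            elif el.kind == "insertion":
                # caret on the boundary after el.start
                cx = x_end(el.start)
                group.marks.append(
                    Polygon(((cx - 3, y), (cx + 3, y), (cx, y + 4)),
                            INSERTION_COLOR, cls="insertion")
                )
    return group


# --------------------------------------------------------------------------
# SVG backend
# --------------------------------------------------------------------------


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def _esc(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _svg_mark(m: object) -> str:
    if isinstance(m, Rect):
        attrs = (
            f'x="{_fmt(m.x)}" y="{_fmt(m.y)}" width="{_fmt(m.w)}" height="{_fmt(m.h)}" '
            f'fill="{m.fill}"'
        )
        if m.stroke:
            attrs += f' stroke="{m.stroke}" stroke-width="{_fmt(m.stroke_width)}"'
        if m.opacity != 1.0:
            attrs += f' opacity="{_fmt(m.opacity)}"'
        if m.cls:
            attrs += f' class="{m.cls}"'
        title = f"<title>{_esc(m.title)}</title>" if m.title else ""
        return f"<rect {attrs}>{title}</rect>" if title else f"<rect {attrs}/>"
    if isinstance(m, Line):
        cls = f' class="{m.cls}"' if m.cls else ""
        return (
            f'<line x1="{_fmt(m.x1)}" y1="{_fmt(m.y1)}" x2="{_fmt(m.x2)}" '
            f'y2="{_fmt(m.y2)}" stroke="{m.color}" stroke-width="{_fmt(m.width)}"{cls}/>'
        )
    if isinstance(m, Text):
        return (
            f'<text x="{_fmt(m.x)}" y="{_fmt(m.y)}" font-size="{_fmt(m.size)}" '
            f'font-family="monospace" text-anchor="middle" fill="{m.color}">'
            f"{_esc(m.s)}</text>"
        )
    if isinstance(m, Polygon):
        pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in m.points)
        cls = f' class="{m.cls}"' if m.cls else ""
        return f'<polygon points="{pts}" fill="{m.fill}"{cls}/>'
    raise TypeError(f"unknown mark {m!r}")


def render_svg(dataset: PlotDataset, options: PlotOptions) -> str:
    """Deterministic standalone SVG 1.1 document for the dataset."""
    marks = compute_marks(dataset, options)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(marks.width)}" height="{_fmt(marks.height)}" '
        f'viewBox="0 0 {_fmt(marks.width)} {_fmt(marks.height)}">',
        f'<rect x="0" y="0" width="{_fmt(marks.width)}" height="{_fmt(marks.height)}" fill="#FFFFFF"/>',
    ]
    for section, items in (
        ("background", marks.background),
        ("coverage", marks.coverage),
        ("reference", marks.reference),
    ):
        parts.append(f'<g class="{section}">')
        parts.extend(_svg_mark(m) for m in items)
        parts.append("</g>")
    parts.append('<g class="reads">')
    for group in marks.fragments:
        parts.append(f'<g class="fragment" data-name="{_esc(group.name)}">')
        parts.extend(_svg_mark(m) for m in group.marks)
        parts.append("</g>")
    parts.append("</g>")
    parts.extend(_svg_mark(m) for m in marks.labels)
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


# --------------------------------------------------------------------------
# Raster/vector backends via matplotlib
# --------------------------------------------------------------------------


def render_with_matplotlib(dataset: PlotDataset, options: PlotOptions, out_path, fmt: str) -> None:
    """Paint the same marks with matplotlib and save as PNG or PDF."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon, Rectangle as MplRect

    marks = compute_marks(dataset, options)
    dpi = 100.0
    fig, ax = plt.subplots(figsize=(marks.width / dpi, marks.height / dpi), dpi=dpi)
    ax.set_xlim(0, marks.width)
    ax.set_ylim(marks.height, 0)  # y grows downward, like SVG
    ax.axis("off")

    def paint(m: object) -> None:
        if isinstance(m, Rect):
            ax.add_patch(
                MplRect((m.x, m.y), m.w, m.h, facecolor=m.fill,
                        edgecolor=m.stroke or "none",
                        linewidth=m.stroke_width, alpha=m.opacity)
            )
        elif isinstance(m, Line):
            ax.plot([m.x1, m.x2], [m.y1, m.y2], color=m.color, linewidth=m.width)
        elif isinstance(m, Text):
            ax.text(m.x, m.y, m.s, color=m.color, fontsize=m.size * 0.75,
                    ha="center", family="monospace")
        elif isinstance(m, Polygon):
            ax.add_patch(MplPolygon(list(m.points), closed=True, facecolor=m.fill))

    for items in (marks.background, marks.coverage, marks.reference):
        for m in items:
            paint(m)
    for group in marks.fragments:
        for m in group.marks:
            paint(m)
    for m in marks.labels:
        paint(m)
    fig.savefig(str(out_path), format=fmt, metadata=_no_metadata(fmt))
    plt.close(fig)


def _no_metadata(fmt: str) -> Optional[dict]:
    # suppress timestamps so repeated runs produce identical bytes
    if fmt == "png":
        return {"Software": None}
    if fmt == "pdf":
        return {"CreationDate": None, "Producer": None, "Creator": None}
    return None
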