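"""Deterministic color mapping and SVG emission for pathway overlays.

Methylation betas map onto a dark-blue -> white -> dark-red gradient
(white at beta 0.5); expression log2 folds map the *opposite* way round —
over-expression is blue, under-expression red — so that a silencing
methylation event and its expression echo share a color across panels.
Gray marks genes whose sites were all filtered out, light green marks genes
with no data at all, and a green border flags genes averaging several sites.

All SVG output is built by plain string assembly with fixed float
formatting: the same plan always yields byte-identical documents, which
makes renders diffable and playback frames cacheable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .analysis import DEFAULT_FOLD_SCALE, GeneOverlay
from .io import OmicsMatrix, SampleGrouping
from .kgml import EntryNode, PathwayGraph

__all__ = [
    "ColorSpec",
    "RenderPlan",
    "beta_to_color",
    "fold_to_color",
    "render_pathway",
    "render_grid",
    "plot_gene",
    "render_playback",
    "summary_report",
    "gene_urls",
]

RGB = tuple[int, int, int]


def _hex(color: RGB) -> str:
    return "#{:02X}{:02X}{:02X}".format(*color)


def _parse_hex(s: str) -> RGB:
    s = s.lstrip("#")
    return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))


@dataclass(frozen=True)
class ColorSpec:
    """Endpoint colors for the gradients plus the status palette."""

    meth_low: RGB = (0x00, 0x00, 0x8B)      # dark blue, beta 0
    meth_mid: RGB = (0xFF, 0xFF, 0xFF)      # white, beta 0.5
    meth_high: RGB = (0x8B, 0x00, 0x00)     # dark red, beta 1
    expr_over: RGB = (0x00, 0x00, 0x8B)     # blue, fold +s (deliberate inversion)
    expr_mid: RGB = (0xFF, 0xFF, 0xFF)
    expr_under: RGB = (0x8B, 0x00, 0x00)    # red, fold -s
    no_data: RGB = (0xCC, 0xFF, 0xCC)       # light green
    no_passing_sites: RGB = (0xBE, 0xBE, 0xBE)  # gray
    multi_site_border: RGB = (0x00, 0x80, 0x00)  # green


def _lerp(a: RGB, b: RGB, t: float) -> RGB:
    return tuple(int(round(a[i] + (b[i] - a[i]) * t)) for i in range(3))  # type: ignore[return-value]


def beta_to_color(beta: float, spec: ColorSpec = ColorSpec()) -> RGB:
    """Piecewise-linear gradient low->mid on [0, 0.5], mid->high on [0.5, 1].

    Hits the endpoint colors exactly at 0, 0.5 and 1; each RGB channel is
    monotone along each segment.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta {beta} outside [0, 1]")
    if beta <= 0.5:
        return _lerp(spec.meth_low, spec.meth_mid, beta / 0.5)
    return _lerp(spec.meth_mid, spec.meth_high, (beta - 0.5) / 0.5)


def fold_to_color(
    fold: float, spec: ColorSpec = ColorSpec(), scale: float = DEFAULT_FOLD_SCALE
) -> RGB:
    """Map a clipped log2 fold onto red (-s) -> white (0) -> blue (+s).

    Over-expressed genes are blue and under-expressed red — inverted from
    expression-centric conventions so shared methylation/expression patterns
    line up visually.  The caller clips; out-of-range folds are an error.
    """
    if not (-scale <= fold <= scale):
        raise ValueError(f"fold {fold} outside [-{scale}, {scale}]")
    if fold >= 0:
        return _lerp(spec.expr_mid, spec.expr_over, fold / scale)
    return _lerp(spec.expr_mid, spec.expr_under, -fold / scale)


def overlay_fill(
    overlay: GeneOverlay,
    value: float | None,
    kind: str,
    spec: ColorSpec,
    scale: float = DEFAULT_FOLD_SCALE,
) -> RGB:
    """Resolve a gene box fill from status + display value."""
    if overlay.status == "no_data":
        return spec.no_data
    if overlay.status == "no_passing_sites":
        return spec.no_passing_sites
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return spec.no_passing_sites
    if kind == "methylation":
        return beta_to_color(float(value), spec)
    return fold_to_color(float(np.clip(value, -scale, scale)), spec, scale)


# stroke styles per relation subtype: (color, dasharray or None, arrowhead)
EDGE_STYLES: dict[str, tuple[str, str | None, str]] = {
    "activation": ("#000000", None, "arrow"),
    "expression": ("#006400", None, "arrow"),
    "inhibition": ("#B22222", None, "bar"),
    "repression": ("#B22222", "6,3", "bar"),
    "methylation": ("#6A0DAD", "2,4", "none"),
    "phosphorylation": ("#FF8C00", None, "arrow"),
    "binding": ("#444444", None, "none"),
    "indirect": ("#000000", "8,4", "arrow"),
    "unknown": ("#808080", "1,3", "none"),
}


@dataclass
class RenderPlan:
    """Everything a pathway render needs, resolved ahead of drawing."""

    view_mode: str  # single_sample | multi_sample | group_wise
    graph: PathwayGraph
    overlays: Mapping[str, GeneOverlay]
    kind: str = "methylation"
    grouping: SampleGrouping | None = None
    sample: str | None = None
    samples: Sequence[str] | None = None
    color_spec: ColorSpec = field(default_factory=ColorSpec)
    fold_scale: float = DEFAULT_FOLD_SCALE
    margin: float = 40.0
    legend_height: float = 28.0

    def __post_init__(self) -> None:
        if self.view_mode not in ("single_sample", "multi_sample", "group_wise"):
            raise ValueError(f"unknown view mode {self.view_mode!r}")
        if self.view_mode == "group_wise" and self.grouping is None:
            raise ValueError("group_wise view requires a grouping")
        if self.view_mode == "single_sample" and self.sample is None:
            raise ValueError("single_sample view requires sample=")

    def boxes_per_gene(self) -> int:
        if self.view_mode == "group_wise":
            assert self.grouping is not None
            return len(self.grouping.group_order)
        if self.view_mode == "multi_sample":
            return len(self.samples or ())
        return 1


def _fmt(x: float) -> str:
    # fixed two-decimal formatting keeps output byte-stable across platforms
    return f"{x:.2f}".rstrip("0").rstrip(".")


class _Svg:
    """Minimal deterministic SVG document builder."""

    def __init__(self, width: float, height: float) -> None:
        self.parts: list[str] = [
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
            f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        ]

    def rect(self, x, y, w, h, fill: str, stroke: str = "#000000",
             stroke_width: float = 1.0, extra: str = "") -> None:
        self.parts.append(
            f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" height="{_fmt(h)}" '
            f'fill="{fill}" stroke="{stroke}" stroke-width="{_fmt(stroke_width)}"{extra}/>\n'
        )

    def line(self, x1, y1, x2, y2, stroke: str, width: float = 1.2,
             dash: str | None = None) -> None:
        d = f' stroke-dasharray="{dash}"' if dash else ""
        self.parts.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="{stroke}" stroke-width="{_fmt(width)}"{d}/>\n'
        )

    def polygon(self, points: Sequence[tuple[float, float]], fill: str) -> None:
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)
        self.parts.append(f'<polygon points="{pts}" fill="{fill}"/>\n')

    def text(self, x, y, content: str, size: float = 9.0, anchor: str = "middle",
             fill: str = "#000000") -> None:
        safe = (
            content.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        )
        self.parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="Helvetica" '
            f'font-size="{_fmt(size)}" text-anchor="{anchor}" fill="{fill}">{safe}</text>\n'
        )

    def tobytes(self) -> bytes:
        return ("".join(self.parts) + "</svg>\n").encode("utf-8")


def _entry_boxes(plan: RenderPlan, entry: EntryNode) -> list[tuple[str, float]]:
    """(label, display value) per sub-box for one gene entry."""
    ov = plan.overlays.get(entry.label)
    if ov is None:
        ov = GeneOverlay(gene=entry.label, status="no_data")
    if plan.view_mode == "group_wise":
        assert plan.grouping is not None
        return [(g, ov.per_group_value.get(g, float("nan"))) for g in plan.grouping.group_order]
    if plan.view_mode == "multi_sample":
        return [(s, ov.per_sample_value.get(s, float("nan"))) for s in (plan.samples or ())]
    return [(plan.sample or "", ov.per_sample_value.get(plan.sample or "", float("nan")))]


def _draw_edge(svg: _Svg, plan: RenderPlan, x1, y1, x2, y2, subtype: str) -> None:
    color, dash, head = EDGE_STYLES.get(subtype, EDGE_STYLES["unknown"])
    svg.line(x1, y1, x2, y2, color, dash=dash)
    if head == "none":
        return
    ang = math.atan2(y2 - y1, x2 - x1)
    if head == "arrow":
        size = 7.0
        left = (x2 - size * math.cos(ang - 0.45), y2 - size * math.sin(ang - 0.45))
        right = (x2 - size * math.cos(ang + 0.45), y2 - size * math.sin(ang + 0.45))
        svg.polygon([(x2, y2), left, right], color)
    elif head == "bar":
        size = 5.0
        px, py = math.cos(ang + math.pi / 2), math.sin(ang + math.pi / 2)
        svg.line(x2 - size * px, y2 - size * py, x2 + size * px, y2 + size * py, color, width=2.0)


def render_pathway(plan: RenderPlan) -> bytes:
    """Render a pathway view as a deterministic standalone SVG document.

    One rectangle per gene entry at its KGML coordinates, split into one
    sub-box per group (group-wise) or per selected sample (multi-sample);
    relation edges get per-subtype stroke styles; the legend names the view
    and, group-wise, each group with its sample count in parentheses.
    """
    graph = plan.graph
    boxes = [e.graphics for e in graph.entries if e.graphics is not None]
    if boxes:
        max_x = max(b.x_center + b.width / 2 for b in boxes)
        max_y = max(b.y_center + b.height / 2 for b in boxes)
    else:
        max_x = max_y = 100.0
    width = max_x + plan.margin
    height = max_y + plan.margin + plan.legend_height
    svg = _Svg(width, height)

    # legend row
    y_leg = max_y + plan.margin / 2 + 10
    title = graph.title or graph.pathway_id
    if plan.view_mode == "group_wise":
        assert plan.grouping is not None
        sizes = plan.grouping.sizes(_plan_sample_ids(plan))
        groups = ", ".join(f"{g} ({sizes.get(g, 0)})" for g in plan.grouping.group_order)
        svg.text(10, y_leg, f"{title} | {plan.kind} | groups: {groups}", anchor="start")
    elif plan.view_mode == "single_sample":
        svg.text(10, y_leg, f"{title} | {plan.kind} | sample: {plan.sample}", anchor="start")
    else:
        svg.text(10, y_leg, f"{title} | {plan.kind} | {len(plan.samples or ())} samples",
                 anchor="start")

    # edges first so boxes draw over them
    centers = {
        e.entry_id: (e.graphics.x_center, e.graphics.y_center)
        for e in graph.entries
        if e.graphics is not None
    }
    for rel in graph.relations:
        if rel.source_entry not in centers or rel.target_entry not in centers:
            continue
        (x1, y1), (x2, y2) = centers[rel.source_entry], centers[rel.target_entry]
        for subtype in sorted(rel.effective_subtypes):
            _draw_edge(svg, plan, x1, y1, x2, y2, subtype)

    for entry in graph.entries:
        g = entry.graphics
        if g is None:
            continue
        if entry.entry_type != "gene":
            # neutral rendering for maps/compounds/groups — no overlay color
            svg.rect(g.x_left, g.y_top, g.width, g.height, "#F5F5F5", "#999999")
            if entry.label:
                svg.text(g.x_center, g.y_center + 3, entry.label, size=8.0)
            continue
        ov = plan.overlays.get(entry.label) or GeneOverlay(gene=entry.label, status="no_data")
        sub = _entry_boxes(plan, entry)
        n = max(len(sub), 1)
        bw = g.width / n
        for i, (_name, val) in enumerate(sub):
            fill = overlay_fill(ov, val, plan.kind, plan.color_spec, plan.fold_scale)
            svg.rect(g.x_left + i * bw, g.y_top, bw, g.height, _hex(fill),
                     stroke="#000000", stroke_width=0.5)
        border = (
            _hex(plan.color_spec.multi_site_border) if ov.multi_site else "#000000"
        )
        svg.rect(g.x_left, g.y_top, g.width, g.height, "none", border,
                 stroke_width=1.6 if ov.multi_site else 1.0)
        svg.text(g.x_center, g.y_center + 3, entry.label)
    return svg.tobytes()


def _plan_sample_ids(plan: RenderPlan) -> list[str]:
    if plan.samples:
        return list(plan.samples)
    # group sizes fall back to every sample any overlay knows about
    ids: list[str] = []
    for ov in plan.overlays.values():
        for s in ov.per_sample_value:
            if s not in ids:
                ids.append(s)
    return ids


def render_grid(
    overlays: Mapping[str, GeneOverlay] | Sequence[tuple[str, GeneOverlay]],
    *,
    kind: str = "methylation",
    view_mode: str = "group_wise",
    grouping: SampleGrouping | None = None,
    sample: str | None = None,
    samples: Sequence[str] | None = None,
    columns: int | None = None,
    cell_width: float = 110.0,
    cell_height: float = 48.0,
    color_spec: ColorSpec | None = None,
    fold_scale: float = DEFAULT_FOLD_SCALE,
) -> bytes:
    """Render genes in a pathway-independent grid (gene-grid view).

    Cells are laid out row-major in the given order — feeding ranked
    similarity hits preserves their reading order.  Coloring and status
    rules are identical to :func:`render_pathway`; default column count is
    ``ceil(sqrt(N))``.
    """
    items = list(overlays.items()) if isinstance(overlays, Mapping) else list(overlays)
    if not items:
        raise ValueError("grid needs at least one gene")
    n = len(items)
    ncol = columns or math.ceil(math.sqrt(n))
    nrow = math.ceil(n / ncol)
    pad = 8.0
    width = ncol * (cell_width + pad) + pad
    height = nrow * (cell_height + pad) + pad + 20
    spec = color_spec or ColorSpec()

    # reuse the pathway renderer via a synthetic grid-layout graph
    from .kgml import GraphicsBox, EntryNode as _E, PathwayGraph as _G

    entries = []
    for i, (label, _ov) in enumerate(items):
        r, c = divmod(i, ncol)
        entries.append(
            _E(
                entry_id=str(i + 1),
                entry_type="gene",
                kegg_ids=(),
                label=label,
                aliases=(label,),
                graphics=GraphicsBox(
                    x_center=pad + c * (cell_width + pad) + cell_width / 2,
                    y_center=pad + r * (cell_height + pad) + cell_height / 2,
                    width=cell_width,
                    height=cell_height,
                ),
            )
        )
    grid_graph = _G("grid", "n/a", "gene grid", entries, [])
    plan = RenderPlan(
        view_mode=view_mode,
        graph=grid_graph,
        overlays=dict(items),
        kind=kind,
        grouping=grouping,
        sample=sample,
        samples=samples,
        color_spec=spec,
        fold_scale=fold_scale,
        margin=pad * 2,
    )
    return render_pathway(plan)


def plot_gene(
    overlay: GeneOverlay,
    matrix: OmicsMatrix,
    grouping: SampleGrouping | None = None,
    *,
    kind: str = "barplot",
    bins: int = 20,
    out_svg: str | Path | None = None,
    out_tsv: str | Path | None = None,
):
    """Bar plot or histogram of a gene's per-sample values, plus its numbers.

    Bar plots show one bar per sample, grouped contiguously by group order
    with separators between blocks; histograms use fixed bins over [0, 1]
    for betas.  Returns a DataFrame of the plotted numbers; ``out_tsv``
    writes it alongside the image so every figure has its data on disk.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    plt.rcParams["svg.hashsalt"] = "methpath"

    samples = list(matrix.sample_ids)
    if grouping is not None:
        ordered = []
        for g in grouping.group_order:
            ordered.extend(grouping.members(g, samples))
        ordered.extend(s for s in samples if s not in ordered)
        samples = ordered
    values = [overlay.per_sample_value.get(s, float("nan")) for s in samples]
    groups = [grouping.group_of(s) if grouping else "" for s in samples]
    table = pd.DataFrame({"sample": samples, "group": groups, "value": values})

    fig, ax = plt.subplots(figsize=(max(4, len(samples) * 0.22), 3.2))
    if kind == "barplot":
        ax.bar(range(len(samples)), values, color="#4472C4", width=0.8)
        if grouping is not None and len(grouping.group_order) > 1:
            # separator after each group block
            idx = 0
            for g in grouping.group_order[:-1]:
                idx += len(grouping.members(g, samples))
                ax.axvline(idx - 0.5, color="black", linewidth=0.8)
        ax.set_xticks([])
        ax.set_ylabel("beta" if matrix.kind == "methylation" else "log2 fold")
    elif kind == "histogram":
        finite = [v for v in values if not math.isnan(v)]
        rng = (0.0, 1.0) if matrix.kind == "methylation" else None
        ax.hist(finite, bins=bins, range=rng, color="#4472C4", edgecolor="black")
        ax.set_xlabel("beta" if matrix.kind == "methylation" else "log2 fold")
        ax.set_ylabel("samples")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    ax.set_title(overlay.gene)
    fig.tight_layout()
    if out_svg is not None:
        fig.savefig(out_svg, format="svg", metadata={"Date": None})
    plt.close(fig)
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    return table


def render_playback(
    graph: PathwayGraph,
    meth_overlays: Mapping[str, GeneOverlay],
    order: Sequence[str],
    out_dir: str | Path,
    *,
    expr_overlays: Mapping[str, GeneOverlay] | None = None,
    color_spec: ColorSpec | None = None,
    fold_scale: float = DEFAULT_FOLD_SCALE,
) -> list[Path]:
    """Write one single-sample SVG frame per sample in *order*.

    Frames are numbered ``frame_000.svg`` onward.  When expression overlays
    are supplied each gene shows its methylation box and expression box side
    by side (the original tool stacks them; side-by-side keeps both visible
    in a static frame).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = color_spec or ColorSpec()
    paths: list[Path] = []
    for i, sample in enumerate(order):
        if expr_overlays is None:
            plan = RenderPlan(
                view_mode="single_sample",
                graph=graph,
                overlays=meth_overlays,
                kind="methylation",
                sample=sample,
                color_spec=spec,
                fold_scale=fold_scale,
            )
            data = render_pathway(plan)
        else:
            data = _render_dual_frame(
                graph, meth_overlays, expr_overlays, sample, spec, fold_scale
            )
        p = out_dir / f"frame_{i:03d}.svg"
        p.write_bytes(data)
        paths.append(p)
    return paths


def _render_dual_frame(
    graph: PathwayGraph,
    meth_overlays: Mapping[str, GeneOverlay],
    expr_overlays: Mapping[str, GeneOverlay],
    sample: str,
    spec: ColorSpec,
    fold_scale: float,
) -> bytes:
    boxes = [e.graphics for e in graph.entries if e.graphics is not None]
    max_x = max((b.x_center + b.width / 2 for b in boxes), default=100.0)
    max_y = max((b.y_center + b.height / 2 for b in boxes), default=100.0)
    svg = _Svg(max_x + 40, max_y + 68)
    svg.text(10, max_y + 50, f"sample: {sample} | left box methylation, right box expression",
             anchor="start")
    for entry in graph.entries:
        g = entry.graphics
        if g is None:
            continue
        if entry.entry_type != "gene":
            svg.rect(g.x_left, g.y_top, g.width, g.height, "#F5F5F5", "#999999")
            continue
        mo = meth_overlays.get(entry.label) or GeneOverlay(entry.label, status="no_data")
        eo = expr_overlays.get(entry.label) or GeneOverlay(entry.label, status="no_data")
        half = g.width / 2
        mfill = overlay_fill(mo, mo.per_sample_value.get(sample), "methylation", spec)
        efill = overlay_fill(eo, eo.per_sample_value.get(sample), "expression", spec, fold_scale)
        svg.rect(g.x_left, g.y_top, half, g.height, _hex(mfill), stroke_width=0.5)
        svg.rect(g.x_left + half, g.y_top, half, g.height, _hex(efill), stroke_width=0.5)
        border = _hex(spec.multi_site_border) if mo.multi_site else "#000000"
        svg.rect(g.x_left, g.y_top, g.width, g.height, "none", border,
                 stroke_width=1.6 if mo.multi_site else 1.0)
        svg.text(g.x_center, g.y_center + 3, entry.label)
    return svg.tobytes()


def summary_report(
    checked: Sequence[tuple[str, str, Iterable[str]]]
) -> str:
    """Multi-file summary: one block per (metadata file, pathway) pair.

    Matched gene symbols are deduplicated and listed alphabetically with a
    count, so summaries are diffable across runs.
    """
    blocks = []
    for fname, pathway, genes in checked:
        uniq = sorted({g for g in genes}, key=str.lower)
        lines = [f"file: {fname}", f"pathway: {pathway}", f"matched genes ({len(uniq)}):"]
        lines.extend(f"  {g}" for g in uniq)
        blocks.append("\n".join(lines))
    return ("\n\n".join(blocks) + "\n") if blocks else ""


def gene_urls(symbol: str) -> dict[str, str]:
    """Lookup URLs for a gene symbol (GeneCards, Pubmed, Ensembl).

    Pure URL construction — no browser is launched.
    """
    s = symbol.strip()
    return {
        "genecards": f"https://www.genecards.org/cgi-bin/carddisp.pl?gene={s}",
        "pubmed": f"https://pubmed.ncbi.nlm.nih.gov/?term={s}",
        "ensembl": f"https://www.ensembl.org/Human/Search/Results?q={s}",
    }
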