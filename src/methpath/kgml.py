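"""KGML pathway graphs: parsing, serialization, fetching and caching.

KGML (KEGG Markup Language) encodes a pathway as ``entry`` elements (genes,
compounds, maps, groups) carrying ``graphics`` layout boxes, plus typed
``relation`` edges between entries.  This module parses KGML into a small
typed graph, writes it back out, and talks to the KEGG REST API through an
injectable transport so everything is testable offline.

Conventions adopted here:

* KGML ``graphics`` x/y are box *centers* (the KGML convention); renderers
  convert to top-left corners at draw time.
* The display label of a gene entry is the first comma-separated token of
  the graphics ``name`` attribute with any trailing ``...`` stripped; the
  full token set is kept as ``aliases`` for case-insensitive matching.
* Relations with an unrecognized subtype are kept with subtype ``unknown``
  rather than dropped, so they can be rendered explicitly.
"""

from __future__ import annotations

import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from lxml import etree

__all__ = [
    "GraphicsBox",
    "EntryNode",
    "RelationEdge",
    "PathwayGraph",
    "KgmlError",
    "FetchError",
    "parse_kgml",
    "serialize_graph",
    "fetch_pathway",
    "list_pathways",
    "list_organisms",
]

ENTRY_TYPES = {"gene", "ortholog", "compound", "map", "group", "enzyme", "other"}
RELATION_CLASSES = {"PPrel", "GErel", "ECrel", "PCrel", "maplink"}
RELATION_SUBTYPES = {
    "activation",
    "inhibition",
    "repression",
    "expression",
    "methylation",
    "phosphorylation",
    "indirect",
    "binding",
    "unknown",
}
GRAPHICS_SHAPES = {"rectangle", "circle", "roundrectangle", "line"}

KEGG_BASE_URL = "https://rest.kegg.jp"
_PATHWAY_ID_RE = re.compile(r"^[a-z]{2,4}\d{5}$")


class KgmlError(ValueError):
    """Malformed or schema-violating KGML input."""


class FetchError(RuntimeError):
    """Network failure, HTTP error, or offline cache miss."""


@dataclass(frozen=True)
class GraphicsBox:
    """Layout box of a KGML entry; ``x_center``/``y_center`` are box centers."""

    x_center: float
    y_center: float
    width: float
    height: float
    shape: str = "rectangle"

    def __post_init__(self) -> None:
        if self.shape not in GRAPHICS_SHAPES:
            raise KgmlError(f"unknown graphics shape {self.shape!r}")
        if self.shape == "rectangle" and (self.width <= 0 or self.height <= 0):
            raise KgmlError("rectangle graphics must have positive width and height")

    @property
    def x_left(self) -> float:
        return self.x_center - self.width / 2

    @property
    def y_top(self) -> float:
        return self.y_center - self.height / 2


@dataclass(frozen=True)
class EntryNode:
    entry_id: str
    entry_type: str
    kegg_ids: tuple[str, ...]
    label: str
    aliases: tuple[str, ...]
    graphics: GraphicsBox | None = None
    components: tuple[str, ...] = ()  # child entry ids of a "group" entry

    def __post_init__(self) -> None:
        if self.entry_type not in ENTRY_TYPES:
            raise KgmlError(f"unknown entry type {self.entry_type!r}")
        if self.entry_type == "gene" and not self.label:
            raise KgmlError(f"gene entry {self.entry_id} has an empty label")
        if self.label and self.label not in self.aliases:
            raise KgmlError("aliases must contain the display label")

    def matches_symbol(self, symbol: str) -> bool:
        """Case-insensitive match of *symbol* against any alias."""
        s = symbol.strip().lower()
        return any(a.lower() == s for a in self.aliases)


@dataclass(frozen=True)
class RelationEdge:
    source_entry: str
    target_entry: str
    relation_class: str
    subtypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.relation_class not in RELATION_CLASSES:
            raise KgmlError(f"unknown relation class {self.relation_class!r}")
        bad = set(self.subtypes) - RELATION_SUBTYPES
        if bad:
            raise KgmlError(f"unknown relation subtypes {sorted(bad)}")

    @property
    def effective_subtypes(self) -> frozenset[str]:
        """Subtype set with empty collapsed to {'unknown'}."""
        return self.subtypes if self.subtypes else frozenset({"unknown"})


@dataclass
class PathwayGraph:
    """A parsed KGML pathway: ordered entries plus typed relations."""

    pathway_id: str
    organism: str
    title: str
    entries: list[EntryNode] = field(default_factory=list)
    relations: list[RelationEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise KgmlError(f"duplicate entry ids {dup}")
        known = set(ids)
        for rel in self.relations:
            for end in (rel.source_entry, rel.target_entry):
                if end not in known:
                    raise KgmlError(f"relation endpoint {end!r} is not an entry id")

    def entry_by_id(self, entry_id: str) -> EntryNode:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    def gene_entries(self) -> list[EntryNode]:
        return [e for e in self.entries if e.entry_type == "gene"]

    def entries_for_symbol(self, symbol: str) -> list[EntryNode]:
        return [e for e in self.gene_entries() if e.matches_symbol(symbol)]

    def structurally_equal(self, other: "PathwayGraph") -> bool:
        return (
            self.pathway_id == other.pathway_id
            and self.organism == other.organism
            and self.title == other.title
            and self.entries == other.entries
            and self.relations == other.relations
        )


def _split_label(graphics_name: str) -> tuple[str, tuple[str, ...]]:
    tokens = [t.strip() for t in graphics_name.split(",")]
    tokens = [t for t in tokens if t and t != "..."]
    tokens = [t[:-3].strip() if t.endswith("...") else t for t in tokens]
    if not tokens:
        return "", ()
    return tokens[0], tuple(dict.fromkeys(tokens))


def parse_kgml(source: bytes | str) -> PathwayGraph:
    """Parse a KGML byte stream into a :class:`PathwayGraph`.

    Document order of entries and relations is preserved.  Unknown relation
    subtype names map to ``unknown``; group entries retain the ids of their
    component entries.

    Raises
    ------
    KgmlError
        On malformed XML (the message names the byte offset) or on a missing
        ``pathway`` root / entry ids.
    """
    data = source.encode() if isinstance(source, str) else source
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise KgmlError(f"malformed XML at byte offset ~{exc.position}: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlError(f"root element is {root.tag!r}, expected 'pathway'")

    pathway_id = root.get("name", "").removeprefix("path:")
    organism = root.get("org", "")
    title = root.get("title", "")

    entries: list[EntryNode] = []
    relations: list[RelationEdge] = []
    for el in root:
        if el.tag == "entry":
            entry_id = el.get("id")
            if not entry_id:
                raise KgmlError("entry element without an id attribute")
            entry_type = el.get("type", "other")
            if entry_type not in ENTRY_TYPES:
                entry_type = "other"
            kegg_ids = tuple(el.get("name", "").split())
            gfx_el = el.find("graphics")
            graphics = None
            label, aliases = "", ()
            if gfx_el is not None:
                label, aliases = _split_label(gfx_el.get("name", ""))
                shape = gfx_el.get("type", "rectangle")
                if shape not in GRAPHICS_SHAPES:
                    shape = "rectangle"
                graphics = GraphicsBox(
                    x_center=float(gfx_el.get("x", 0)),
                    y_center=float(gfx_el.get("y", 0)),
                    width=float(gfx_el.get("width", 46)),
                    height=float(gfx_el.get("height", 17)),
                    shape=shape,
                )
            if entry_type == "gene" and not label:
                # fall back on the KEGG id so the invariant holds
                label = kegg_ids[0] if kegg_ids else entry_id
                aliases = (label,)
            components = tuple(
                c.get("id") for c in el.findall("component") if c.get("id")
            )
            entries.append(
                EntryNode(
                    entry_id=entry_id,
                    entry_type=entry_type,
                    kegg_ids=kegg_ids,
                    label=label,
                    aliases=aliases,
                    graphics=graphics,
                    components=components,
                )
            )
        elif el.tag == "relation":
            src, tgt = el.get("entry1"), el.get("entry2")
            if not src or not tgt:
                raise KgmlError("relation element missing entry1/entry2")
            rel_class = el.get("type", "PPrel")
            if rel_class not in RELATION_CLASSES:
                rel_class = "PPrel"
            subtypes = frozenset(
                s.get("name") if s.get("name") in RELATION_SUBTYPES else "unknown"
                for s in el.findall("subtype")
            )
            relations.append(RelationEdge(src, tgt, rel_class, subtypes))

    return PathwayGraph(pathway_id, organism, title, entries, relations)


def serialize_graph(graph: PathwayGraph) -> bytes:
    """Render *graph* back to KGML bytes; ``parse_kgml`` round-trips it."""
    graph.validate()
    root = etree.Element(
        "pathway",
        name=f"path:{graph.pathway_id}",
        org=graph.organism,
        title=graph.title,
    )
    for e in graph.entries:
        el = etree.SubElement(
            root, "entry", id=e.entry_id, name=" ".join(e.kegg_ids), type=e.entry_type
        )
        if e.graphics is not None:
            g = e.graphics
            # re-join aliases so _split_label recovers them verbatim
            etree.SubElement(
                el,
                "graphics",
                name=", ".join(e.aliases),
                type=g.shape,
                x=_num(g.x_center),
                y=_num(g.y_center),
                width=_num(g.width),
                height=_num(g.height),
            )
        for cid in e.components:
            etree.SubElement(el, "component", id=cid)
    for r in graph.relations:
        el = etree.SubElement(
            root, "relation", entry1=r.source_entry, entry2=r.target_entry, type=r.relation_class
        )
        for name in sorted(r.subtypes):
            etree.SubElement(el, "subtype", name=name, value="")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# --------------------------------------------------------------------------
# KEGG REST access.  `transport` is any callable url -> bytes; the default
# uses urllib.  Tests inject a fake transport so they never touch the network.

Transport = Callable[[str], bytes]


def _urllib_transport(url: str) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            if resp.status >= 400:
                raise FetchError(f"HTTP {resp.status} for {url}")
            return resp.read()
    except FetchError:
        raise
    except Exception as exc:  # URLError, timeout, ...
        raise FetchError(f"failed to fetch {url}: {exc}") from exc


def fetch_pathway(
    pathway_id: str,
    cache_dir: str | Path,
    *,
    offline: bool = False,
    transport: Transport = _urllib_transport,
) -> PathwayGraph:
    """Fetch (or load from cache) the KGML for *pathway_id* and parse it.

    The cache stores one file per pathway id, byte-identical to the server
    response, so a warm cache implies zero network activity and reproducible
    parses.  ``offline=True`` with a cold cache raises :class:`FetchError`.
    """
    if not _PATHWAY_ID_RE.match(pathway_id):
        raise ValueError(
            f"invalid pathway id {pathway_id!r}: expected e.g. 'hsa04668'"
        )
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_file = cache_dir / f"{pathway_id}.kgml"
    if cache_file.exists():
        return parse_kgml(cache_file.read_bytes())
    if offline:
        raise FetchError(f"offline and no cached copy of {pathway_id}")
    data = transport(f"{KEGG_BASE_URL}/get/{pathway_id}/kgml")
    cache_file.write_bytes(data)
    return parse_kgml(data)


def _parse_list_response(text: str) -> list[tuple[str, str]]:
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        key, _, title = line.partition("\t")
        key = key.strip().removeprefix("path:")
        out.append((key, title.strip()))
    return out


def list_pathways(
    organism: str,
    cache_dir: str | Path,
    *,
    offline: bool = False,
    transport: Transport = _urllib_transport,
) -> list[tuple[str, str]]:
    """List ``(pathway_id, title)`` pairs for a KEGG organism code, cached."""
    if not re.match(r"^[a-z]{2,4}$", organism):
        raise ValueError(f"invalid organism code {organism!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_file = cache_dir / f"pathways_{organism}.tsv"
    if cache_file.exists():
        return _parse_list_response(cache_file.read_text())
    if offline:
        raise FetchError(f"offline and no cached pathway list for {organism}")
    data = transport(f"{KEGG_BASE_URL}/list/pathway/{organism}")
    cache_file.write_bytes(data)
    return _parse_list_response(data.decode())


def list_organisms(
    cache_dir: str | Path,
    *,
    offline: bool = False,
    transport: Transport = _urllib_transport,
) -> list[tuple[str, str]]:
    """List ``(org_code, description)`` from the KEGG organism endpoint."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_file = cache_dir / "organisms.tsv"
    if cache_file.exists():
        text = cache_file.read_text()
    elif offline:
        raise FetchError("offline and no cached organism list")
    else:
        data = transport(f"{KEGG_BASE_URL}/list/organism")
        cache_file.write_bytes(data)
        text = data.decode()
    out = []
    for line in text.splitlines():
        cols = line.split("\t")
        if len(cols) >= 3:
            out.append((cols[1], cols[2]))
    return out
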