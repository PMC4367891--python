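"""KGML pathway parsing from a local cache.

KGML (KEGG Markup Language) describes a pathway map as *entries* (enzyme,
compound, map boxes with pixel graphics, origin top-left) and *reactions*
(substrates/products, reversible or not).  This module parses the
reference-pathway dialect (``ec``/``ko``/``map`` files): enzyme entries carry
one or more ``ec:x.x.x.x`` names; gene-type entries from organism-specific
files are ignored, because presence is decided from user annotations, not
KEGG's organism layer.

Pathways load offline from a cache directory laid out as
``<cache>/kgml/<pathway_id>.xml``.  A fetcher interface exists for callers
that want to populate the cache; the default fetcher only reports a miss.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .ec import ECNumber, ECParseError, normalize_ec

__all__ = [
    "Graphics",
    "PathwayEntry",
    "Reaction",
    "PathwayModel",
    "KGMLError",
    "CacheMiss",
    "PathwayCache",
    "NullFetcher",
    "parse_kgml",
    "parse_kgml_string",
    "pathway_ec_set",
]

log = logging.getLogger(__name__)


class KGMLError(ValueError):
    """Raised for malformed KGML input."""


class CacheMiss(KeyError):
    """Requested pathway is not in the local KGML cache."""


@dataclass(frozen=True)
class Graphics:
    x: float
    y: float  # box centre, KGML pixel space
    width: float
    height: float
    label: str = ""


@dataclass
class PathwayEntry:
    entry_id: str
    entry_type: str
    ec_links: list[ECNumber] = field(default_factory=list)
    reaction_id: str = ""
    graphics: Graphics | None = None
    flagged: bool = False  # enzyme entry with zero parseable ECs


@dataclass
class Reaction:
    reaction_id: str
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    reversible: bool = False


@dataclass
class PathwayModel:
    pathway_id: str
    title: str = ""
    entries: list[PathwayEntry] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    dangling_reaction_ids: list[str] = field(default_factory=list)

    def enzyme_entries(self) -> list[PathwayEntry]:
        return [e for e in self.entries if e.entry_type == "enzyme"]


def _parse_entry(elem) -> PathwayEntry:
    etype = elem.get("type", "")
    ecs: list[ECNumber] = []
    if etype == "enzyme":
        for token in elem.get("name", "").split():
            if token.lower().startswith("ec:"):
                token = token[3:]
            try:
                ecs.append(normalize_ec(token))
            except ECParseError:
                log.warning("unparseable EC token %r in KGML entry %s", token, elem.get("id"))
    g = elem.find("graphics")
    graphics = None
    if g is not None:
        graphics = Graphics(
            x=float(g.get("x", 0)),
            y=float(g.get("y", 0)),
            width=float(g.get("width", 0)),
            height=float(g.get("height", 0)),
            label=g.get("name", ""),
        )
        if etype == "enzyme" and (graphics.width <= 0 or graphics.height <= 0):
            raise KGMLError(f"non-positive graphics box on entry {elem.get('id')}")
    entry = PathwayEntry(
        entry_id=elem.get("id", ""),
        entry_type=etype,
        ec_links=ecs,
        reaction_id=elem.get("reaction", ""),
        graphics=graphics,
    )
    if etype == "enzyme" and not ecs:
        entry.flagged = True
        log.warning("enzyme entry %s has no parseable EC links", entry.entry_id)
    return entry


def parse_kgml_string(text: str, source: str = "<string>") -> PathwayModel:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise KGMLError(f"malformed KGML XML in {source}: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLError(f"root element is <{root.tag}>, expected <pathway> in {source}")
    pathway_id = root.get("number") or root.get("name", "").split(":")[-1].lstrip("eckomap")
    model = PathwayModel(pathway_id=pathway_id or "", title=root.get("title", ""))
    seen_ids: set[str] = set()
    for elem in root.findall("entry"):
        entry = _parse_entry(elem)
        if entry.entry_id in seen_ids:
            raise KGMLError(f"duplicate entry id {entry.entry_id} in {source}")
        seen_ids.add(entry.entry_id)
        model.entries.append(entry)
    for relem in root.findall("reaction"):
        rid = relem.get("name") or relem.get("id", "")
        model.reactions.append(
            Reaction(
                reaction_id=rid,
                substrates=[s.get("name", "") for s in relem.findall("substrate")],
                products=[p.get("name", "") for p in relem.findall("product")],
                reversible=relem.get("type") == "reversible",
            )
        )
    known = {r.reaction_id for r in model.reactions}
    for entry in model.entries:
        if entry.reaction_id and entry.reaction_id not in known:
            model.dangling_reaction_ids.append(entry.reaction_id)
    if model.dangling_reaction_ids:
        log.warning(
            "%d entry reaction reference(s) without a <reaction> element in %s",
            len(model.dangling_reaction_ids), source,
        )
    return model


def parse_kgml(path: str | Path) -> PathwayModel:
    """Parse one KGML file into a :class:`PathwayModel`."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise KGMLError(f"cannot read KGML file {path}: {exc}") from exc
    return parse_kgml_string(text, source=str(path))


def pathway_ec_set(model: PathwayModel) -> set[ECNumber]:
    """Union of EC links over enzyme entries; wildcards included as-is
    (no expansion policy)."""
    return {ec for entry in model.enzyme_entries() for ec in entry.ec_links}


class NullFetcher:
    """Offline fetcher: always reports a cache miss.

    Stands where a network KEGG client would plug in; deliberately inert so
    the tool is hermetic.
    """

    def fetch(self, pathway_id: str) -> str:
        raise CacheMiss(f"pathway {pathway_id} not in local cache and no fetcher configured")


class PathwayCache:
    """Local KGML cache: ``<root>/kgml/<pathway_id>.xml``."""

    def __init__(self, root: str | Path, fetcher: NullFetcher | None = None) -> None:
        self.root = Path(root)
        self.fetcher = fetcher or NullFetcher()

    def path_for(self, pathway_id: str) -> Path:
        return self.root / "kgml" / f"{pathway_id}.xml"

    def load(self, pathway_id: str) -> PathwayModel:
        path = self.path_for(pathway_id)
        if path.exists():
            return parse_kgml(path)
        text = self.fetcher.fetch(pathway_id)  # raises CacheMiss by default
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text, encoding="utf-8")
        return parse_kgml(path)
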