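"""BRENDA-style literature index.

BRENDA's flatfile links each EC entry to organisms (``PR`` protein lines)
and numbered literature references (``RF`` lines); a ``PR`` line cites its
references by number in angle brackets, e.g. ``<1,2>``.  This module
consumes only those three fields — the tool uses BRENDA purely as an
(EC, organism) -> publications index.

Commentary matching the configurable pattern "no activity in" marks a
publication as *negative* evidence: literature suggesting the function is
absent from that organism.  Organisms are matched case-insensitively on
genus + species (strain suffixes ignored), since BRENDA rarely records
strains.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .ec import ECNumber, ECParseError, normalize_ec

__all__ = [
    "Publication",
    "LiteratureIndex",
    "BrendaFormatError",
    "parse_brenda_flatfile",
    "write_brenda_flatfile",
    "references_for",
    "organism_key",
    "NEGATIVE_PATTERN",
]

log = logging.getLogger(__name__)

NEGATIVE_PATTERN = re.compile(r"no activity in", re.IGNORECASE)

_PUBMED_RE = re.compile(r"\{Pubmed:(\d+)\}", re.IGNORECASE)
_XREF_RE = re.compile(r"<([\d,\s]+)>")
_PROTNUM_RE = re.compile(r"^#\d+#\s*")


class BrendaFormatError(ValueError):
    """Raised for unreadable BRENDA flatfile input."""


@dataclass(frozen=True)
class Publication:
    citation_text: str
    pubmed_id: str = ""
    polarity: str = "positive"  # "positive" | "negative"

    def __post_init__(self) -> None:
        if not self.citation_text:
            raise ValueError("citation_text must be non-empty")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive or negative, got {self.polarity!r}")


def organism_key(name: str) -> str:
    """Normalise an organism name to its genus+species key, lowercased;
    strain designations beyond the first two tokens are dropped."""
    tokens = name.strip().lower().split()
    return " ".join(tokens[:2])


@dataclass
class LiteratureIndex:
    """(EC, genus+species key) -> deduplicated publication list."""

    entries: dict[tuple[ECNumber, str], list[Publication]] = field(default_factory=dict)

    def add(self, ec: ECNumber, organism: str, publication: Publication) -> None:
        key = (ec, organism_key(organism))
        bucket = self.entries.setdefault(key, [])
        if not any(
            p.pubmed_id == publication.pubmed_id
            and p.citation_text == publication.citation_text
            and p.polarity == publication.polarity
            for p in bucket
        ):
            bucket.append(publication)

    def ec_numbers(self) -> list[ECNumber]:
        return sorted({ec for ec, _ in self.entries})


def _parse_pr_line(text: str, negative_pattern: re.Pattern = NEGATIVE_PATTERN):
    """Split a PR line into (organism, reference numbers, polarity)."""
    body = _PROTNUM_RE.sub("", text.strip())
    refs: list[int] = []
    m = _XREF_RE.search(body)
    if m:
        refs = [int(t) for t in m.group(1).replace(" ", "").split(",") if t]
        body = _XREF_RE.sub("", body).strip()
    polarity = "positive"
    if negative_pattern.search(body):
        polarity = "negative"
        body = negative_pattern.sub("", body).strip()
    # drop parenthesised commentary; organism is what remains
    body = re.sub(r"\([^)]*\)", "", body).strip().strip(",")
    return body, refs, polarity


def parse_brenda_flatfile(
    path: str | Path, negative_pattern: re.Pattern = NEGATIVE_PATTERN
) -> LiteratureIndex:
    """Parse ID/PR/RF fields of a BRENDA-style flatfile into a
    :class:`LiteratureIndex`.

    Continuation lines (leading whitespace) extend the previous field line.
    A PR cross-reference number with no matching RF line is skipped with a
    warning.
    """
    path = Path(path)
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise BrendaFormatError(f"cannot read BRENDA flatfile {path}: {exc}") from exc

    index = LiteratureIndex()
    current_ec: ECNumber | None = None
    pr_lines: list[str] = []
    rf_lines: list[str] = []
    logical: list[tuple[str, str]] = []

    for line in raw.splitlines():
        if not line.strip():
            continue
        if line[0] in (" ", "\t") and logical and line.strip():
            tag, text = logical[-1]
            logical[-1] = (tag, text + " " + line.strip())
        else:
            parts = line.split("\t", 1)
            if len(parts) == 1:
                parts = line.split(None, 1)
            tag = parts[0].strip()
            text = parts[1].strip() if len(parts) > 1 else ""
            logical.append((tag, text))

    def flush() -> None:
        nonlocal pr_lines, rf_lines
        if current_ec is None:
            pr_lines, rf_lines = [], []
            return
        references: dict[int, Publication] = {}
        for text in rf_lines:
            m = re.match(r"^<(\d+)>\s*(.*)$", text)
            if not m:
                log.warning("unnumbered RF line ignored under EC %s: %r", current_ec, text)
                continue
            num = int(m.group(1))
            citation = m.group(2).strip()
            pm = _PUBMED_RE.search(citation)
            references[num] = Publication(
                citation_text=_PUBMED_RE.sub("", citation).strip(),
                pubmed_id=pm.group(1) if pm else "",
            )
        for text in pr_lines:
            organism, ref_nums, polarity = _parse_pr_line(text, negative_pattern)
            if not organism:
                continue
            for num in ref_nums:
                ref = references.get(num)
                if ref is None:
                    log.warning(
                        "PR cross-reference <%d> has no RF line under EC %s", num, current_ec
                    )
                    continue
                index.add(
                    current_ec,
                    organism,
                    Publication(
                        citation_text=ref.citation_text,
                        pubmed_id=ref.pubmed_id,
                        polarity=polarity,
                    ),
                )
        pr_lines, rf_lines = [], []

    for tag, text in logical:
        if tag == "ID":
            flush()
            try:
                current_ec = normalize_ec(text.split()[0])
            except (ECParseError, IndexError):
                log.warning("unparseable ID line %r; entry skipped", text)
                current_ec = None
        elif tag == "///":
            flush()
            current_ec = None
        elif tag == "PR" and current_ec is not None:
            pr_lines.append(text)
        elif tag == "RF" and current_ec is not None:
            rf_lines.append(text)
    flush()
    return index


def write_brenda_flatfile(index: LiteratureIndex, path: str | Path) -> None:
    """Serialise an index back to the flatfile dialect read by
    :func:`parse_brenda_flatfile` (round-trips to an identical index).

    Negative-evidence publications are written with the "no activity in"
    commentary that the parser recognises.
    """
    by_ec: dict[ECNumber, list[tuple[str, Publication]]] = {}
    for (ec, org), pubs in index.entries.items():
        for pub in pubs:
            by_ec.setdefault(ec, []).append((org, pub))
    with open(path, "w", encoding="utf-8") as fh:
        for ec in sorted(by_ec):
            fh.write(f"ID\t{ec}\n")
            items = sorted(
                by_ec[ec], key=lambda t: (t[0], t[1].polarity, t[1].pubmed_id, t[1].citation_text)
            )
            refs: list[Publication] = []
            for _, pub in items:
                key = (pub.pubmed_id, pub.citation_text)
                if key not in [(r.pubmed_id, r.citation_text) for r in refs]:
                    refs.append(pub)
            ref_num = {(r.pubmed_id, r.citation_text): i + 1 for i, r in enumerate(refs)}
            for i, (org, pub) in enumerate(items, start=1):
                num = ref_num[(pub.pubmed_id, pub.citation_text)]
                prefix = "no activity in " if pub.polarity == "negative" else ""
                fh.write(f"PR\t#{i}# {prefix}{org.capitalize()} <{num}>\n")
            for r in refs:
                pm = f" {{Pubmed:{r.pubmed_id}}}" if r.pubmed_id else ""
                fh.write(f"RF\t<{ref_num[(r.pubmed_id, r.citation_text)]}> {r.citation_text}{pm}\n")
            fh.write("///\n")


def references_for(
    index: LiteratureIndex, ec: ECNumber, organism: str
) -> tuple[list[Publication], list[Publication]]:
    """Publications for (EC, organism), split into (positive, negative).

    The organism is matched case-insensitively on its genus+species prefix,
    so "Bacillus subtilis 168" finds entries recorded as "Bacillus subtilis".
    """
    pubs = index.entries.get((ec, organism_key(organism)), [])
    positive = [p for p in pubs if p.polarity == "positive"]
    negative = [p for p in pubs if p.polarity == "negative"]
    return positive, negative
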