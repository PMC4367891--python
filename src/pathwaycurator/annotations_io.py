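"""Genome annotation ingestion.

Builds a uniform, source-tagged gene -> EC model from three inputs:

* GenBank flat files (CDS features with ``EC_number`` qualifiers),
* protein FASTA (sequences only, plus an optional ``EC=x.x.x.x`` header token),
* user-supplied tab-separated annotation tables.

Every assignment is tagged with the label of the source that asserted it,
so downstream reports can show which evidence stream claimed which function.
EC numbers are never inferred from free-text product descriptions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .ec import ECNumber, ECParseError, normalize_ec

__all__ = [
    "GeneAnnotation",
    "OrganismAnnotation",
    "AnnotationFormatError",
    "parse_genbank_annotations",
    "parse_fasta_annotations",
    "parse_annotation_table",
    "write_annotation_table",
    "merge_sources",
]

log = logging.getLogger(__name__)

_FASTA_EC_TOKEN = re.compile(r"\bEC=([0-9.\-]+)", re.IGNORECASE)


class AnnotationFormatError(ValueError):
    """Raised for malformed annotation input files."""


@dataclass
class GeneAnnotation:
    """One gene's functional assignment(s) from a single source.

    A gene may legitimately carry more than one EC number (bifunctional
    enzymes, or ambiguous assignments awaiting curation).
    """

    gene_id: str
    ec_numbers: list[ECNumber] = field(default_factory=list)
    product: str = ""
    source: str = ""
    sequence: str = ""  # protein translation, used by the homology module

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        # deduplicate while preserving order
        seen: set[ECNumber] = set()
        unique = []
        for ec in self.ec_numbers:
            if ec not in seen:
                seen.add(ec)
                unique.append(ec)
        self.ec_numbers = unique


@dataclass
class OrganismAnnotation:
    """All gene annotations for one organism, possibly from several sources."""

    organism_id: str
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.organism_id:
            raise ValueError("organism_id must be non-empty")
        seen: set[tuple[str, str]] = set()
        for g in self.genes:
            key = (g.gene_id, g.source)
            if key in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r} for source {g.source!r}")
            seen.add(key)

    @property
    def sources(self) -> set[str]:
        return {g.source for g in self.genes}

    def ec_set(self) -> set[ECNumber]:
        return {ec for g in self.genes for ec in g.ec_numbers}

    def genes_with_ec(self, ec: ECNumber, prefix_wildcards: bool = False) -> list[GeneAnnotation]:
        return [
            g
            for g in self.genes
            if any(ec.matches(e, prefix_wildcards) or e.matches(ec, prefix_wildcards)
                   for e in g.ec_numbers)
        ]

    def ec_provenance(self) -> dict[ECNumber, list[tuple[str, str]]]:
        """Map each EC to the sorted (gene_id, source) pairs asserting it."""
        prov: dict[ECNumber, set[tuple[str, str]]] = {}
        for g in self.genes:
            for ec in g.ec_numbers:
                prov.setdefault(ec, set()).add((g.gene_id, g.source))
        return {ec: sorted(pairs) for ec, pairs in prov.items()}

    def sequences(self) -> dict[str, str]:
        """gene_id -> protein sequence, for genes that carry one."""
        return {g.gene_id: g.sequence for g in self.genes if g.sequence}


def _gene_id_from_cds(feature) -> str | None:
    # precedence: locus_tag > protein_id > gene
    for key in ("locus_tag", "protein_id", "gene"):
        vals = feature.qualifiers.get(key)
        if vals and vals[0].strip():
            return vals[0].strip()
    return None


def parse_genbank_annotations(
    path: str | Path, source_label: str, organism_id: str | None = None
) -> OrganismAnnotation:
    """Parse CDS features of a GenBank flat file into an :class:`OrganismAnnotation`.

    EC numbers come from ``EC_number`` qualifiers; gene ids from locus_tag,
    falling back to protein_id then gene; protein translations are retained
    when present.  CDS features with no usable id are skipped with a warning.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    skipped = 0
    org = organism_id
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise AnnotationFormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise AnnotationFormatError(f"no GenBank records found in {path}")
    for record in records:
        if org is None:
            org = record.annotations.get("organism") or record.annotations.get("source")
        for feat in record.features:
            if feat.type != "CDS":
                continue
            gene_id = _gene_id_from_cds(feat)
            if gene_id is None:
                skipped += 1
                log.warning("CDS without locus_tag/protein_id/gene in %s: skipped", path)
                continue
            ecs = []
            for raw in feat.qualifiers.get("EC_number", []):
                try:
                    ecs.append(normalize_ec(raw))
                except ECParseError:
                    log.warning("unparseable EC_number %r on %s in %s", raw, gene_id, path)
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    ec_numbers=ecs,
                    product=feat.qualifiers.get("product", [""])[0],
                    source=source_label,
                    sequence=feat.qualifiers.get("translation", [""])[0],
                )
            )
    if skipped:
        log.warning("%d CDS feature(s) skipped in %s for lack of an id", skipped, path)
    if org is None:
        org = path.stem
    return OrganismAnnotation(organism_id=org, genes=genes)


def parse_fasta_annotations(
    path: str | Path, source_label: str, organism_id: str | None = None
) -> OrganismAnnotation:
    """Read a protein FASTA.  Sequences are the payload; an optional
    ``EC=x.x.x.x`` token in the description is honoured (FASTA has no
    annotation standard, so nothing else is interpreted)."""
    path = Path(path)
    genes = []
    for record in SeqIO.parse(str(path), "fasta"):
        ecs = []
        for m in _FASTA_EC_TOKEN.finditer(record.description):
            try:
                ecs.append(normalize_ec(m.group(1)))
            except ECParseError:
                log.warning("unparseable EC= token %r in %s", m.group(1), path)
        desc = record.description
        if desc.startswith(record.id):
            desc = desc[len(record.id):].strip()
        genes.append(
            GeneAnnotation(
                gene_id=record.id,
                ec_numbers=ecs,
                product=_FASTA_EC_TOKEN.sub("", desc).strip(),
                source=source_label,
                sequence=str(record.seq),
            )
        )
    return OrganismAnnotation(organism_id=organism_id or path.stem, genes=genes)


def parse_annotation_table(
    path: str | Path, source_label: str, organism_id: str | None = None
) -> OrganismAnnotation:
    """Parse a user annotation table.

    Format: UTF-8 TSV with columns ``gene_id``, ``ec_list``
    (semicolon-separated, may be empty) and optional ``product``; lines
    starting with ``#`` are comments.
    """
    path = Path(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(cols)}"
                )
            gene_id, ec_list = cols[0].strip(), cols[1].strip()
            product = cols[2].strip() if len(cols) == 3 else ""
            ecs = []
            for token in filter(None, (t.strip() for t in ec_list.split(";"))):
                try:
                    ecs.append(normalize_ec(token))
                except ECParseError as exc:
                    raise AnnotationFormatError(f"{path}:{lineno}: {exc}") from None
            genes.append(
                GeneAnnotation(gene_id=gene_id, ec_numbers=ecs, product=product,
                               source=source_label)
            )
    return OrganismAnnotation(organism_id=organism_id or path.stem, genes=genes)


def write_annotation_table(annotation: OrganismAnnotation, path: str | Path) -> None:
    """Serialise to the table format read by :func:`parse_annotation_table`.

    Round trip preserves the (gene_id, EC, source) triples of a single-source
    annotation; the source label itself lives in the file name / caller.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tec_list\tproduct\n")
        for g in annotation.genes:
            ecs = ";".join(str(ec) for ec in g.ec_numbers)
            fh.write(f"{g.gene_id}\t{ecs}\t{g.product}\n")


def merge_sources(annotations: Iterable[OrganismAnnotation]) -> OrganismAnnotation:
    """Union several annotation sources for one organism.

    Genes are keyed by (gene_id, source); identical duplicates collapse.  ECs
    keep their per-source provenance so reports can show which source
    asserted which function.  Idempotent and order-independent at the level
    of (gene_id, EC, source) triples.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("merge_sources needs at least one OrganismAnnotation")
    org_ids = {a.organism_id for a in annotations}
    if len(org_ids) != 1:
        raise ValueError(f"cannot merge annotations for different organisms: {sorted(org_ids)}")
    merged: dict[tuple[str, str], GeneAnnotation] = {}
    for ann in annotations:
        for g in ann.genes:
            key = (g.gene_id, g.source)
            if key in merged:
                existing = merged[key]
                existing.ec_numbers = list(
                    dict.fromkeys(existing.ec_numbers + g.ec_numbers)
                )
                if not existing.product:
                    existing.product = g.product
                if not existing.sequence:
                    existing.sequence = g.sequence
            else:
                merged[key] = GeneAnnotation(
                    gene_id=g.gene_id,
                    ec_numbers=list(g.ec_numbers),
                    product=g.product,
                    source=g.source,
                    sequence=g.sequence,
                )
    genes = [merged[k] for k in sorted(merged)]
    return OrganismAnnotation(organism_id=annotations[0].organism_id, genes=genes)
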