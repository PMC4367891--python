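"""Cross-organism pathway comparison.

The unit of comparison is the EC number.  For one KEGG pathway and a set of
organisms (the query listed first) we build a binary presence/absence
matrix over the pathway's EC set, derive pairwise Hamming distances (the
number of enzymatic functions present in exactly one of two organisms),
and call two kinds of curation candidates:

* **pathway holes** — ECs absent from the query but present in at least a
  configurable fraction of the reference organisms (default half,
  operationalising "most of the references").  Candidate filler genes are
  ranked from reciprocal-best-hit partners (preferred) and top-k hits
  against reference genes carrying the function.
* **misannotations** — ECs present *only* in the query, with no positive
  literature for the query organism (positive literature vetoes the call).
  Alternative functions are other, reference-supported ECs co-annotated on
  the same genes.

Callers never edit annotations; they emit ranked suggestions for a curator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations_io import OrganismAnnotation
from .brenda_lit import LiteratureIndex, references_for
from .ec import ECNumber
from .homology import HitRecord, RBHPair
from .kegg_pathway import PathwayModel, pathway_ec_set

__all__ = [
    "PresenceMatrix",
    "CandidateGene",
    "HoleCall",
    "MisannotationCall",
    "build_presence_matrix",
    "hamming_distance",
    "distance_matrix",
    "call_pathway_holes",
    "call_misannotations",
    "write_presence_tsv",
    "write_distance_tsv",
    "write_hole_calls_tsv",
    "write_misannotation_calls_tsv",
    "DEFAULT_MIN_REF_FRACTION",
]

DEFAULT_MIN_REF_FRACTION = 0.5


@dataclass
class PresenceMatrix:
    """Organisms x pathway-ECs binary matrix with per-cell support.

    ``presence`` is an int DataFrame (index: organisms, query first;
    columns: canonical EC strings in EC sort order).  ``support`` records,
    for each cell equal to 1, the (gene_id, source) pairs behind it.
    """

    pathway_id: str
    organisms: list[str]
    ecs: list[ECNumber]
    presence: pd.DataFrame
    support: dict[tuple[str, str], list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def query(self) -> str:
        return self.organisms[0]

    @property
    def references(self) -> list[str]:
        return self.organisms[1:]

    def row(self, organism: str) -> pd.Series:
        if organism not in self.presence.index:
            raise KeyError(f"unknown organism {organism!r}")
        return self.presence.loc[organism]

    def supporting_genes(self, organism: str, ec: ECNumber) -> list[tuple[str, str]]:
        return self.support.get((organism, str(ec)), [])


def build_presence_matrix(
    pathway: PathwayModel,
    annotations: Sequence[OrganismAnnotation],
    prefix_wildcards: bool = False,
) -> PresenceMatrix:
    """Score each (organism, pathway EC) cell as present iff some gene of
    the organism carries that EC.

    Wildcard ECs in the pathway match only identical wildcard annotations
    unless ``prefix_wildcards`` enables prefix matching.  Row order follows
    the input annotation order (query first by convention); column order is
    canonical EC order, stable across runs.
    """
    if not annotations:
        raise ValueError("need at least one organism annotation")
    ecs = sorted(pathway_ec_set(pathway))
    if not ecs:
        raise ValueError(f"pathway {pathway.pathway_id} has an empty EC set")
    organisms = [a.organism_id for a in annotations]
    if len(set(organisms)) != len(organisms):
        raise ValueError("duplicate organism ids in annotation list")
    data = []
    support: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for ann in annotations:
        row = []
        for ec in ecs:
            genes = ann.genes_with_ec(ec, prefix_wildcards=prefix_wildcards)
            row.append(1 if genes else 0)
            if genes:
                support[(ann.organism_id, str(ec))] = sorted(
                    {(g.gene_id, g.source) for g in genes}
                )
        data.append(row)
    presence = pd.DataFrame(
        data, index=organisms, columns=[str(ec) for ec in ecs], dtype=int
    )
    return PresenceMatrix(
        pathway_id=pathway.pathway_id,
        organisms=organisms,
        ecs=ecs,
        presence=presence,
        support=support,
    )


def hamming_distance(matrix: PresenceMatrix, org_a: str, org_b: str) -> int:
    """Number of pathway ECs present in exactly one of the two organisms."""
    a = matrix.row(org_a)
    b = matrix.row(org_b)
    return int((a != b).sum())


def distance_matrix(matrix: PresenceMatrix) -> pd.DataFrame:
    """Symmetric, zero-diagonal integer matrix of pairwise Hamming distances."""
    if len(matrix.organisms) < 2:
        raise ValueError("distance matrix needs at least two organisms")
    orgs = matrix.organisms
    out = pd.DataFrame(0, index=orgs, columns=orgs, dtype=int)
    for i, a in enumerate(orgs):
        for b in orgs[i + 1:]:
            d = hamming_distance(matrix, a, b)
            out.loc[a, b] = d
            out.loc[b, a] = d
    return out


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str  # candidate in the query genome
    evidence: str  # "RBH" | "top-k"
    ref_organism: str
    ref_gene: str
    bit_score: float
    percent_identity: float
    z_score: float | None = None


@dataclass
class HoleCall:
    """An EC absent from the query but supported by the references."""

    ec: ECNumber
    reference_support: float  # fraction of references with presence
    supporting_organisms: list[str]
    candidate_genes: list[CandidateGene] = field(default_factory=list)


@dataclass
class MisannotationCall:
    """A query-only EC with no positive literature for the query organism."""

    ec: ECNumber
    genes: list[str]
    literature_support: int  # positive publications found for the query (0 by definition)
    alternative_ecs: list[ECNumber] = field(default_factory=list)


def _hole_candidates(
    matrix: PresenceMatrix,
    ec: ECNumber,
    rbh: Mapping[str, Sequence[RBHPair]] | None,
    top_k: Mapping[str, Mapping[str, Sequence[HitRecord]]] | None,
) -> list[CandidateGene]:
    candidates: dict[str, CandidateGene] = {}

    def consider(c: CandidateGene) -> None:
        old = candidates.get(c.gene_id)
        if old is None:
            candidates[c.gene_id] = c
            return
        # RBH evidence outranks top-k; within a class keep the better score
        rank_new = (c.evidence == "RBH", c.bit_score)
        rank_old = (old.evidence == "RBH", old.bit_score)
        if rank_new > rank_old:
            candidates[c.gene_id] = c

    for ref_org in matrix.references:
        ref_genes = {g for g, _src in matrix.supporting_genes(ref_org, ec)}
        if not ref_genes:
            continue
        for pair in (rbh or {}).get(ref_org, []):
            if pair.gene_b in ref_genes:
                consider(
                    CandidateGene(
                        gene_id=pair.gene_a,
                        evidence="RBH",
                        ref_organism=ref_org,
                        ref_gene=pair.gene_b,
                        bit_score=pair.forward.bit_score,
                        percent_identity=pair.forward.percent_identity,
                        z_score=pair.forward.z_score,
                    )
                )
        ref_top = (top_k or {}).get(ref_org, {})
        for ref_gene in sorted(ref_genes):
            for hit in ref_top.get(ref_gene, []):
                consider(
                    CandidateGene(
                        gene_id=hit.subject_id,
                        evidence="top-k",
                        ref_organism=ref_org,
                        ref_gene=ref_gene,
                        bit_score=hit.bit_score,
                        percent_identity=hit.percent_identity,
                        z_score=hit.z_score,
                    )
                )
    return sorted(
        candidates.values(),
        key=lambda c: (c.evidence != "RBH", -c.bit_score, c.gene_id),
    )


def call_pathway_holes(
    matrix: PresenceMatrix,
    rbh: Mapping[str, Sequence[RBHPair]] | None = None,
    top_k: Mapping[str, Mapping[str, Sequence[HitRecord]]] | None = None,
    min_ref_fraction: float = DEFAULT_MIN_REF_FRACTION,
) -> list[HoleCall]:
    """Call candidate pathway holes for the matrix's query organism.

    ``rbh`` maps each reference organism to its query<->reference RBH pairs
    (gene_a in the query); ``top_k`` maps each reference organism to
    reference-gene -> hits *into the query genome*.  Both are optional —
    without them, holes are still called, just without candidate genes.
    """
    if not matrix.references:
        raise ValueError("hole calling needs at least one reference organism")
    calls = []
    qrow = matrix.row(matrix.query)
    for ec in matrix.ecs:
        col = str(ec)
        if qrow[col] != 0:
            continue
        supporters = [r for r in matrix.references if matrix.presence.loc[r, col] == 1]
        support = len(supporters) / len(matrix.references)
        if support < min_ref_fraction or not supporters:
            continue
        calls.append(
            HoleCall(
                ec=ec,
                reference_support=support,
                supporting_organisms=supporters,
                candidate_genes=_hole_candidates(matrix, ec, rbh, top_k),
            )
        )
    return calls


def call_misannotations(
    matrix: PresenceMatrix,
    annotations: OrganismAnnotation,
    literature: LiteratureIndex | None = None,
    organism_name: str | None = None,
    min_ref_fraction: float = DEFAULT_MIN_REF_FRACTION,
) -> list[MisannotationCall]:
    """Call candidate misannotations for the query organism.

    ``annotations`` is the query's merged annotation (for co-annotated
    alternative functions); ``organism_name`` is the name used for
    literature lookup (defaults to the query organism id).  An EC is called
    iff it is present in the query, absent from *all* references, and has
    zero positive publications for the query organism.
    """
    if not matrix.references:
        raise ValueError("misannotation calling needs at least one reference organism")
    name = organism_name or matrix.query
    n_refs = len(matrix.references)
    calls = []
    qrow = matrix.row(matrix.query)
    for ec in matrix.ecs:
        col = str(ec)
        if qrow[col] != 1:
            continue
        if int(matrix.presence.loc[matrix.references, col].sum()) != 0:
            continue
        lit_support = 0
        if literature is not None:
            positive, _negative = references_for(literature, ec, name)
            lit_support = len(positive)
        if lit_support > 0:
            continue  # literature asserts the function: not flagged
        gene_ids = sorted({g for g, _src in matrix.supporting_genes(matrix.query, ec)})
        alternatives: set[ECNumber] = set()
        for g in annotations.genes:
            if g.gene_id not in gene_ids:
                continue
            for other in g.ec_numbers:
                if other == ec or other not in matrix.ecs:
                    continue
                ref_frac = (
                    float(matrix.presence.loc[matrix.references, str(other)].sum()) / n_refs
                )
                if ref_frac >= min_ref_fraction:
                    alternatives.add(other)
        calls.append(
            MisannotationCall(
                ec=ec,
                genes=gene_ids,
                literature_support=lit_support,
                alternative_ecs=sorted(alternatives),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# TSV exports (stable column order)

def write_presence_tsv(matrix: PresenceMatrix, path: str | Path) -> None:
    matrix.presence.to_csv(path, sep="\t", index_label="organism")


def write_distance_tsv(distances: pd.DataFrame, path: str | Path) -> None:
    distances.to_csv(path, sep="\t", index_label="organism")


def write_hole_calls_tsv(calls: Sequence[HoleCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ec\treference_support\tsupporting_organisms\tcandidate_genes\n")
        for c in calls:
            cands = ";".join(
                f"{g.gene_id}({g.evidence},{g.ref_organism}:{g.ref_gene},{g.bit_score:g})"
                for g in c.candidate_genes
            )
            fh.write(
                f"{c.ec}\t{c.reference_support:.3f}\t"
                f"{','.join(c.supporting_organisms)}\t{cands}\n"
            )


def write_misannotation_calls_tsv(calls: Sequence[MisannotationCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ec\tgenes\tpositive_publications\talternative_ecs\n")
        for c in calls:
            fh.write(
                f"{c.ec}\t{','.join(c.genes)}\t{c.literature_support}\t"
                f"{','.join(str(e) for e in c.alternative_ecs)}\n"
            )
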