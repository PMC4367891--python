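"""End-to-end orchestration: inputs -> comparison -> report.

`run_pipeline` is the library entry point working on parsed objects;
`run_synthetic_case` re-reads a generated fixture case from disk through
the ordinary parsers (so the full format surface is exercised) and runs
the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations_io import (
    OrganismAnnotation,
    merge_sources,
    parse_annotation_table,
    parse_fasta_annotations,
    parse_genbank_annotations,
)
from .brenda_lit import LiteratureIndex, parse_brenda_flatfile
from .comparison import (
    DEFAULT_MIN_REF_FRACTION,
    HoleCall,
    MisannotationCall,
    PresenceMatrix,
    build_presence_matrix,
    call_misannotations,
    call_pathway_holes,
    distance_matrix,
)
from .fixtures import SyntheticCase
from .homology import (
    DEFAULT_MAX_EVALUE,
    HitRecord,
    HitTable,
    RBHPair,
    parse_blast_tabular,
    reciprocal_best_hits,
    top_k_hits,
)
from .kegg_pathway import PathwayModel, parse_kgml
from .report import Palette, build_html_report, default_palette

__all__ = ["PipelineResult", "run_pipeline", "run_synthetic_case"]


@dataclass
class PipelineResult:
    matrix: PresenceMatrix
    distances: pd.DataFrame
    rbh: dict[str, list[RBHPair]] = field(default_factory=dict)
    top_k: dict[str, dict[str, list[HitRecord]]] = field(default_factory=dict)
    hole_calls: list[HoleCall] = field(default_factory=list)
    misannotation_calls: list[MisannotationCall] = field(default_factory=list)
    report_dir: Path | None = None


def run_pipeline(
    pathway: PathwayModel,
    annotations: Sequence[OrganismAnnotation],
    hit_tables: Mapping[str, tuple[HitTable, HitTable]] | None = None,
    literature: LiteratureIndex | None = None,
    output_dir: str | Path | None = None,
    palette: Palette | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_ref_fraction: float = DEFAULT_MIN_REF_FRACTION,
    k: int = 3,
    prefix_wildcards: bool = False,
    heatmap_png: bool = True,
) -> PipelineResult:
    """Run comparison and (optionally) report rendering.

    ``annotations`` lists one merged annotation per organism, query first.
    ``hit_tables`` maps each reference organism to its
    (query->reference, reference->query) hit-table pair.
    """
    matrix = build_presence_matrix(pathway, annotations, prefix_wildcards=prefix_wildcards)
    distances = distance_matrix(matrix)

    rbh: dict[str, list[RBHPair]] = {}
    top_k: dict[str, dict[str, list[HitRecord]]] = {}
    for ref_org, (fwd, rev) in (hit_tables or {}).items():
        rbh[ref_org] = reciprocal_best_hits(fwd, rev, max_evalue=max_evalue)
        top_k[ref_org] = top_k_hits(rev, k=k, max_evalue=max_evalue)

    hole_calls = call_pathway_holes(
        matrix, rbh=rbh, top_k=top_k, min_ref_fraction=min_ref_fraction
    )
    misannotation_calls = call_misannotations(
        matrix,
        annotations=annotations[0],
        literature=literature,
        min_ref_fraction=min_ref_fraction,
    )

    report_dir = None
    if output_dir is not None:
        report_dir = build_html_report(
            output_dir,
            pathway=pathway,
            matrix=matrix,
            palette=palette or default_palette(matrix.organisms),
            annotations=list(annotations),
            distances=distances,
            rbh=rbh,
            top_k=top_k,
            literature=literature,
            hole_calls=hole_calls,
            misannotation_calls=misannotation_calls,
            heatmap_png=heatmap_png,
        )
    return PipelineResult(
        matrix=matrix,
        distances=distances,
        rbh=rbh,
        top_k=top_k,
        hole_calls=hole_calls,
        misannotation_calls=misannotation_calls,
        report_dir=report_dir,
    )


def load_case_annotations(case: SyntheticCase) -> list[OrganismAnnotation]:
    """Parse a synthetic case's GenBank + table files and merge the two
    sources per organism (query first)."""
    merged = []
    for org in case.organisms:
        gbk = parse_genbank_annotations(
            case.path(f"genbank:{org}"), source_label="genbank", organism_id=org
        )
        table = parse_annotation_table(
            case.path(f"table:{org}"), source_label="table", organism_id=org
        )
        fasta = parse_fasta_annotations(
            case.path(f"fasta:{org}"), source_label="fasta", organism_id=org
        )
        # FASTA contributes sequences only; fold them into the merge so any
        # gene known only from FASTA still has its protein available.
        merged.append(merge_sources([gbk, table, fasta]))
    return merged


def run_synthetic_case(
    case: SyntheticCase,
    output_dir: str | Path | None = None,
    heatmap_png: bool = True,
    **pipeline_kwargs,
) -> PipelineResult:
    """Re-read every artefact of a generated case from disk and run the
    full pipeline on it."""
    pathway = parse_kgml(case.path("kgml"))
    annotations = load_case_annotations(case)
    hit_tables = {}
    for ref in case.reference_organisms:
        fwd = parse_blast_tabular(
            case.path(f"hits:{case.query_organism}->{ref}"),
            direction=(case.query_organism, ref),
        )
        rev = parse_blast_tabular(
            case.path(f"hits:{ref}->{case.query_organism}"),
            direction=(ref, case.query_organism),
        )
        hit_tables[ref] = (fwd, rev)
    literature = parse_brenda_flatfile(case.path("brenda"))
    return run_pipeline(
        pathway,
        annotations,
        hit_tables=hit_tables,
        literature=literature,
        output_dir=output_dir,
        heatmap_png=heatmap_png,
        **pipeline_kwargs,
    )
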