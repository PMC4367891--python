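"""Browsable report rendering.

Produces the static, relocatable output a curator browses: a colour-coded
SVG pathway diagram (each enzyme box at its KGML coordinates, one
horizontal colour band per organism in which the function is present), a
Hamming-distance heatmap (TSV is the authoritative artefact; PNG optional),
and hyperlinked HTML evidence tables.  KEGG and PubMed links are URL
templates only — nothing is fetched, and the report contains no absolute
local paths.  All SVG/HTML/TSV output is byte-deterministic for fixed
inputs.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations_io import OrganismAnnotation
from .brenda_lit import LiteratureIndex, references_for
from .comparison import (
    HoleCall,
    MisannotationCall,
    PresenceMatrix,
    write_distance_tsv,
    write_hole_calls_tsv,
    write_misannotation_calls_tsv,
    write_presence_tsv,
)
from .homology import HitRecord, RBHPair
from .kegg_pathway import PathwayModel

__all__ = ["Palette", "default_palette", "render_pathway_svg", "render_heatmap",
           "build_html_report", "KEGG_ENTRY_URL", "PUBMED_URL"]

KEGG_ENTRY_URL = "https://www.kegg.jp/entry/{id}"
PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"

# query drawn first in red, references in the order supplied (cf. the usual
# convention of highlighting the query organism)
_DEFAULT_COLOURS = [
    "#e41a1c", "#a65628", "#ffd92f", "#4daf4a", "#377eb8", "#984ea3",
    "#ff7f00", "#66c2a5", "#f781bf", "#999999", "#1b9e77", "#d95f02",
]


@dataclass
class Palette:
    """Ordered organism -> hex colour map; order equals matrix organism order."""

    colours: dict[str, str]

    def __post_init__(self) -> None:
        vals = list(self.colours.values())
        if len(set(vals)) != len(vals):
            raise ValueError("palette colours must be unique")

    def __getitem__(self, organism: str) -> str:
        if organism not in self.colours:
            raise KeyError(f"palette has no colour for organism {organism!r}")
        return self.colours[organism]

    @property
    def organisms(self) -> list[str]:
        return list(self.colours)


def default_palette(organisms: Sequence[str]) -> Palette:
    if len(organisms) > len(_DEFAULT_COLOURS):
        raise ValueError(f"default palette supports up to {len(_DEFAULT_COLOURS)} organisms")
    return Palette({org: _DEFAULT_COLOURS[i] for i, org in enumerate(organisms)})


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def render_pathway_svg(
    model: PathwayModel, matrix: PresenceMatrix, palette: Palette
) -> str:
    """Draw the pathway at KGML coordinates with per-organism presence bands.

    Each enzyme box is split into equal horizontal bands, one per organism
    (in palette order) for which any EC of that box is present; organisms
    with no evidence contribute no band, so an unannotated function is an
    outline-only box.
    """
    for org in matrix.organisms:
        palette[org]  # raises KeyError if missing
    boxes = [e for e in model.enzyme_entries() if e.graphics is not None]
    width = max((e.graphics.x + e.graphics.width for e in boxes), default=400) + 40
    legend_h = 18 * len(matrix.organisms) + 30
    height = max((e.graphics.y + e.graphics.height for e in boxes), default=300) + legend_h + 40

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}">',
        f'<title>{html.escape(model.title or model.pathway_id)}</title>',
        '<rect x="0" y="0" width="100%" height="100%" fill="#ffffff"/>',
    ]
    # legend
    parts.append(f'<text x="20" y="20" font-size="13" font-family="sans-serif">'
                 f'{html.escape(model.title or ("pathway " + model.pathway_id))}</text>')
    for i, org in enumerate(matrix.organisms):
        y = 34 + 18 * i
        parts.append(
            f'<rect x="20" y="{y}" width="12" height="12" fill="{palette[org]}" '
            f'stroke="#000000" stroke-width="0.5"/>'
        )
        label = org + (" (query)" if org == matrix.query else "")
        parts.append(
            f'<text x="38" y="{y + 10}" font-size="11" font-family="sans-serif">'
            f'{html.escape(label)}</text>'
        )
    y_offset = legend_h

    for entry in boxes:
        g = entry.graphics
        x0 = g.x - g.width / 2
        y0 = g.y - g.height / 2 + y_offset
        present = [
            org
            for org in matrix.organisms
            if any(matrix.presence.loc[org, str(ec)] == 1
                   for ec in entry.ec_links if str(ec) in matrix.presence.columns)
        ]
        if present:
            band_h = g.height / len(present)
            for i, org in enumerate(present):
                parts.append(
                    f'<rect x="{_fmt(x0)}" y="{_fmt(y0 + i * band_h)}" '
                    f'width="{_fmt(g.width)}" height="{_fmt(band_h)}" '
                    f'fill="{palette[org]}"/>'
                )
        parts.append(
            f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(g.width)}" '
            f'height="{_fmt(g.height)}" fill="none" stroke="#000000" stroke-width="1"/>'
        )
        label = g.label or " ".join(str(ec) for ec in entry.ec_links)
        parts.append(
            f'<text x="{_fmt(g.x)}" y="{_fmt(g.y + y_offset + 3)}" font-size="8" '
            f'font-family="sans-serif" text-anchor="middle">{html.escape(label)}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_heatmap(
    distances: pd.DataFrame,
    out_tsv: str | Path,
    out_png: str | Path | None = None,
) -> None:
    """Write the Hamming-distance heatmap.

    The TSV is always produced and is the authoritative artefact; the PNG
    (linear colour scale from 0 to the maximum distance) is optional.
    """
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix must have identical row and column labels")
    if not (distances.values == distances.values.T).all():
        raise ValueError("distance matrix must be symmetric")
    write_distance_tsv(distances, out_tsv)
    if out_png is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = max(1, int(distances.values.max()))  # degenerate all-zero scale still renders
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(distances), 1.0 + 0.6 * len(distances)))
    im = ax.imshow(distances.values, cmap="viridis", vmin=0, vmax=vmax)
    ax.set_xticks(range(len(distances)), labels=list(distances.columns),
                  rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(distances)), labels=list(distances.index), fontsize=7)
    for i in range(len(distances)):
        for j in range(len(distances)):
            ax.text(j, i, str(int(distances.values[i, j])), ha="center", va="center",
                    fontsize=7, color="white")
    fig.colorbar(im, ax=ax, label="Hamming distance")
    fig.tight_layout()
    fig.savefig(out_png, dpi=100, metadata={"Software": "pathwaycurator"})
    plt.close(fig)


# ---------------------------------------------------------------------------
# HTML

def _page(title: str, body: str, home: bool = True) -> str:
    nav = '<p><a href="index.html">&larr; report index</a></p>\n' if home else ""
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n"
        '<meta charset="utf-8"/>\n'
        f"<title>{html.escape(title)}</title>\n"
        "<style>body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:3px 8px;font-size:90%}"
        "th{background:#eee}</style>\n"
        "</head>\n<body>\n"
        f"<h1>{html.escape(title)}</h1>\n{nav}{body}\n</body>\n</html>\n"
    )


def _table(headers: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    head = "".join(f"<th>{h}</th>" for h in headers)
    body = "\n".join("<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in rows)
    return f"<table>\n<tr>{head}</tr>\n{body}\n</table>\n"


def _kegg_link(identifier: str) -> str:
    url = KEGG_ENTRY_URL.format(id=identifier)
    return f'<a href="{url}">{html.escape(identifier)}</a>'


def _pubmed_link(pmid: str, text: str) -> str:
    esc = html.escape(text)
    if not pmid:
        return esc
    url = PUBMED_URL.format(pmid=pmid)
    return f'{esc} <a href="{url}">[PubMed {pmid}]</a>'


def build_html_report(
    output_dir: str | Path,
    pathway: PathwayModel,
    matrix: PresenceMatrix,
    palette: Palette,
    annotations: Sequence[OrganismAnnotation],
    distances: pd.DataFrame,
    rbh: Mapping[str, Sequence[RBHPair]] | None = None,
    top_k: Mapping[str, Mapping[str, Sequence[HitRecord]]] | None = None,
    literature: LiteratureIndex | None = None,
    hole_calls: Sequence[HoleCall] = (),
    misannotation_calls: Sequence[MisannotationCall] = (),
    heatmap_png: bool = True,
) -> Path:
    """Write the full browsable report directory and return its path.

    Sections: pathway diagram (SVG), per-EC annotations table, RBH table,
    top-hits table, literature table (with a distinct possible-absence
    section), heatmap, hole calls and misannotation calls; plus the TSV
    exports.  Static HTML with relative links only.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"report directory {out} is not writable: {exc}") from exc

    title = pathway.title or f"pathway {pathway.pathway_id}"

    # diagram
    (out / "pathway.svg").write_text(render_pathway_svg(pathway, matrix, palette),
                                     encoding="utf-8")

    # TSV artefacts + heatmap
    write_presence_tsv(matrix, out / "presence.tsv")
    render_heatmap(distances, out / "heatmap.tsv",
                   out / "heatmap.png" if heatmap_png else None)
    write_hole_calls_tsv(hole_calls, out / "hole_calls.tsv")
    write_misannotation_calls_tsv(misannotation_calls, out / "misannotation_calls.tsv")

    ann_by_org = {a.organism_id: a for a in annotations}

    # annotations page: per EC, per organism, genes with their source labels
    rows = []
    for ec in matrix.ecs:
        for org in matrix.organisms:
            for gene_id, source in matrix.supporting_genes(org, ec):
                product = ""
                ann = ann_by_org.get(org)
                if ann:
                    for g in ann.genes:
                        if g.gene_id == gene_id and g.product:
                            product = g.product
                            break
                rows.append([_kegg_link(str(ec)), html.escape(org), _kegg_link(gene_id),
                             html.escape(source), html.escape(product)])
    annotations_html = _table(["EC number", "organism", "gene", "source", "product"], rows)
    (out / "annotations.html").write_text(
        _page(f"Annotations — {title}", annotations_html), encoding="utf-8")

    # RBH page
    rows = []
    for ref_org in matrix.references:
        for pair in (rbh or {}).get(ref_org, []):
            z = "" if pair.forward.z_score is None else f"{pair.forward.z_score:.2f}"
            rows.append([
                html.escape(matrix.query), _kegg_link(pair.gene_a),
                html.escape(ref_org), _kegg_link(pair.gene_b),
                f"{pair.forward.percent_identity:.1f}",
                f"{pair.forward.e_value:.2g}", f"{pair.forward.bit_score:g}", z,
            ])
    rbh_html = _table(
        ["query organism", "query gene", "reference organism", "reference gene",
         "% identity", "E-value", "bit score", "Z-score"], rows)
    (out / "rbh.html").write_text(
        _page(f"Reciprocal best hits — {title}", rbh_html), encoding="utf-8")

    # top-k hits page
    rows = []
    for ref_org in matrix.references:
        for ref_gene in sorted((top_k or {}).get(ref_org, {})):
            for rank, hit in enumerate((top_k or {})[ref_org][ref_gene], start=1):
                z = "" if hit.z_score is None else f"{hit.z_score:.2f}"
                rows.append([
                    html.escape(ref_org), _kegg_link(ref_gene), str(rank),
                    _kegg_link(hit.subject_id), f"{hit.percent_identity:.1f}",
                    f"{hit.e_value:.2g}", f"{hit.bit_score:g}", z,
                ])
    top_html = _table(
        ["reference organism", "reference gene", "rank", "query candidate",
         "% identity", "E-value", "bit score", "Z-score"], rows)
    (out / "top_hits.html").write_text(
        _page(f"Top BLAST-style hits — {title}", top_html), encoding="utf-8")

    # literature page
    pos_rows, neg_rows = [], []
    if literature is not None:
        for ec in matrix.ecs:
            for org in matrix.organisms:
                positive, negative = references_for(literature, ec, org)
                for pub in positive:
                    pos_rows.append([_kegg_link(str(ec)), html.escape(org),
                                     _pubmed_link(pub.pubmed_id, pub.citation_text)])
                for pub in negative:
                    neg_rows.append([_kegg_link(str(ec)), html.escape(org),
                                     _pubmed_link(pub.pubmed_id, pub.citation_text)])
    lit_html = (
        "<h2>Supporting publications</h2>\n"
        + _table(["EC number", "organism", "publication"], pos_rows)
        + "<h2>Possible absence (negative evidence)</h2>\n"
        + _table(["EC number", "organism", "publication"], neg_rows)
    )
    (out / "literature.html").write_text(
        _page(f"Literature — {title}", lit_html), encoding="utf-8")

    # heatmap page
    dist_rows = [
        [html.escape(a)] + [str(int(distances.loc[a, b])) for b in distances.columns]
        for a in distances.index
    ]
    heat_html = (
        ('<p><img src="heatmap.png" alt="Hamming distance heatmap"/></p>\n'
         if heatmap_png else "")
        + _table(["organism"] + [html.escape(c) for c in distances.columns], dist_rows)
        + '<p>Raw values: <a href="heatmap.tsv">heatmap.tsv</a></p>\n'
    )
    (out / "heatmap.html").write_text(
        _page(f"Hamming distance heatmap — {title}", heat_html), encoding="utf-8")

    # hole calls page
    rows = []
    for call in hole_calls:
        cands = "; ".join(
            f"{_kegg_link(c.gene_id)} ({c.evidence}, vs {html.escape(c.ref_organism)}:"
            f"{html.escape(c.ref_gene)}, score {c.bit_score:g})"
            for c in call.candidate_genes
        )
        rows.append([_kegg_link(str(call.ec)), f"{call.reference_support:.2f}",
                     html.escape(", ".join(call.supporting_organisms)), cands])
    holes_html = _table(
        ["EC number", "reference support", "supporting organisms", "candidate genes"], rows)
    (out / "holes.html").write_text(
        _page(f"Candidate pathway holes — {title}", holes_html), encoding="utf-8")

    # misannotation calls page
    rows = []
    for call in misannotation_calls:
        rows.append([
            _kegg_link(str(call.ec)),
            ", ".join(_kegg_link(g) for g in call.genes),
            str(call.literature_support),
            ", ".join(_kegg_link(str(e)) for e in call.alternative_ecs),
        ])
    mis_html = _table(
        ["EC number", "genes", "positive publications", "reference-supported alternatives"],
        rows)
    (out / "misannotations.html").write_text(
        _page(f"Candidate misannotations — {title}", mis_html), encoding="utf-8")

    # index
    sections = [
        ("pathway.svg", "Colour-coded pathway diagram (SVG)"),
        ("annotations.html", "Annotations by EC number"),
        ("rbh.html", "Reciprocal best hits"),
        ("top_hits.html", "Top hits per reference enzyme"),
        ("literature.html", "Literature evidence"),
        ("heatmap.html", "Hamming distance heatmap"),
        ("holes.html", f"Candidate pathway holes ({len(hole_calls)})"),
        ("misannotations.html", f"Candidate misannotations ({len(misannotation_calls)})"),
    ]
    items = "\n".join(f'<li><a href="{f}">{html.escape(label)}</a></li>'
                      for f, label in sections)
    body = (
        f"<p>Query organism: <b>{html.escape(matrix.query)}</b>; "
        f"references: {html.escape(', '.join(matrix.references))}.</p>\n"
        f"<ul>\n{items}\n</ul>\n"
    )
    (out / "index.html").write_text(_page(title, body, home=False), encoding="utf-8")
    return out
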