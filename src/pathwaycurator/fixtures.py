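"""Synthetic test-case generation.

Builds a complete, hermetic toy dataset emulating the real study design:
one query organism plus a handful of reference organisms sharing a
pathway, with *planted* pathway holes (functions every reference has but
the query annotation lacks — although a high-identity homologue of the
reference enzyme is present in the query proteome, so homology recovers
it) and *planted* misannotations (a query gene carrying a wrong EC that no
reference supports, alongside its true, reference-supported EC — mirroring
the classic dual-annotation curation case).

The generator writes exactly the formats the pipeline reads — KGML,
GenBank, annotation tables, protein FASTA, BLAST tabular (produced by the
internal aligner) and a BRENDA-style flatfile — so every parser is
exercised end-to-end.  Output is byte-identical for a fixed seed.

Sequences are random 120-300 residue chains; homologues are derived by
seeded point mutation at a 10% rate, which makes best hits unambiguous.
Unrelated distractor genes are added so hit selection is non-trivial.
This emulates presence/absence structure and clear orthology, not
realistic phylogenetic divergence.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .annotations_io import GeneAnnotation, OrganismAnnotation, write_annotation_table
from .brenda_lit import LiteratureIndex, Publication, write_brenda_flatfile
from .ec import ECNumber
from .homology import Scoring, align_proteomes, write_blast_tabular

__all__ = ["SyntheticCase", "generate_synthetic_case"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_GB_DATE = "01-JAN-2000"  # fixed so generated files are byte-stable


@dataclass
class SyntheticCase:
    seed: int
    n_references: int
    output_dir: Path
    pathway_id: str
    query_organism: str
    reference_organisms: list[str]
    ec_universe: list[ECNumber]
    planted_holes: list[ECNumber]
    planted_misannotations: list[tuple[str, ECNumber, ECNumber]]  # (gene, wrong, true)
    files: dict[str, str] = field(default_factory=dict)

    @property
    def organisms(self) -> list[str]:
        return [self.query_organism] + self.reference_organisms

    def path(self, key: str) -> Path:
        return self.output_dir / self.files[key]


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower()


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_AA) for _ in range(length))


def _mutate(seq: str, rng: random.Random, rate: float = 0.10) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(rng.choice(_AA.replace(aa, "")))
        else:
            out.append(aa)
    return "".join(out)


def _distinct_ecs(rng: random.Random, n: int) -> list[ECNumber]:
    seen: set[ECNumber] = set()
    while len(seen) < n:
        seen.add(
            ECNumber(
                (rng.randint(1, 7), rng.randint(1, 20), rng.randint(1, 30),
                 rng.randint(1, 200))
            )
        )
    return sorted(seen)


def _write_kgml(path: Path, pathway_id: str, ecs: list[ECNumber]) -> None:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<pathway name="path:ec{pathway_id}" number="{pathway_id}" '
        f'title="Synthetic comparison pathway {pathway_id}">',
    ]
    for i, ec in enumerate(ecs):
        x = 80 + 110 * (i % 5)
        y = 70 + 60 * (i // 5)
        rid = f"rn:R{10000 + i}"
        lines.append(
            f'  <entry id="{i + 1}" name="ec:{ec}" type="enzyme" reaction="{rid}">'
        )
        lines.append(
            f'    <graphics name="{ec}" type="rectangle" x="{x}" y="{y}" '
            f'width="46" height="17"/>'
        )
        lines.append("  </entry>")
    for i in range(len(ecs)):
        rid = f"rn:R{10000 + i}"
        rtype = "reversible" if i % 2 else "irreversible"
        lines.append(f'  <reaction id="{i + 1}" name="{rid}" type="{rtype}">')
        lines.append(f'    <substrate id="{1000 + i}" name="cpd:C{20000 + i}"/>')
        lines.append(f'    <product id="{2000 + i}" name="cpd:C{20001 + i}"/>')
        lines.append("  </reaction>")
    lines.append("</pathway>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_genbank(path: Path, organism: str, genes: list[GeneAnnotation]) -> None:
    records = []
    for g in genes:
        dna_len = 3 * len(g.sequence) + 3
        record = SeqRecord(
            Seq("N" * dna_len),
            id=g.gene_id,
            name=g.gene_id[:16],
            description=g.product or "synthetic CDS",
            annotations={
                "molecule_type": "DNA",
                "organism": organism,
                "source": organism,
                "date": _GB_DATE,
                "topology": "linear",
                "data_file_division": "BCT",
            },
        )
        qualifiers = {
            "locus_tag": [g.gene_id],
            "product": [g.product or "hypothetical protein"],
            "translation": [g.sequence],
        }
        if g.ec_numbers:
            qualifiers["EC_number"] = [str(ec) for ec in g.ec_numbers]
        record.features.append(
            SeqFeature(FeatureLocation(0, dna_len - 3), type="CDS", qualifiers=qualifiers)
        )
        records.append(record)
    SeqIO.write(records, str(path), "genbank")


def _write_fasta(path: Path, genes: list[GeneAnnotation]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id,
                  description=(g.product or "synthetic protein"))
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def generate_synthetic_case(
    seed: int,
    n_references: int = 5,
    n_ecs: int = 20,
    n_holes: int = 2,
    n_misannotations: int = 1,
    output_dir: str | Path = "synthetic_case",
    scoring: Scoring = Scoring(),
) -> SyntheticCase:
    """Generate a complete synthetic curation case under ``output_dir``.

    References carry every pathway EC except the planted wrong ones; the
    query lacks the hole ECs (but keeps unannotated homologues of the
    missing enzymes) and carries each wrong EC on the gene whose true EC is
    reference-supported.  The BRENDA snippet holds positive references for
    the reference organisms and none, for any organism matching the query,
    for the planted wrong ECs.
    """
    if n_ecs < n_holes + n_misannotations + 2:
        raise ValueError("n_ecs must be >= n_holes + n_misannotations + 2")
    if n_references < 1:
        raise ValueError("need at least one reference organism")

    rng = random.Random(seed)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "kgml").mkdir(exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "proteins").mkdir(exist_ok=True)
    (out / "hits").mkdir(exist_ok=True)

    pathway_id = "09901"
    query_org = "Testium exemplum NX-1"
    ref_orgs = [f"Testium referens{i + 1}" for i in range(n_references)]

    ecs = _distinct_ecs(rng, n_ecs)
    shuffled = ecs[:]
    rng.shuffle(shuffled)
    holes = sorted(shuffled[:n_holes])
    wrong = sorted(shuffled[n_holes:n_holes + n_misannotations])
    rest = [ec for ec in ecs if ec not in set(holes) | set(wrong)]
    true_for_wrong = [rest[i % len(rest)] for i in range(n_misannotations)]

    base_seq = {ec: _random_protein(rng, rng.randint(120, 300)) for ec in ecs}

    # ---- query annotation -------------------------------------------------
    query_genes: list[GeneAnnotation] = []
    gene_counter = 0

    def next_qid() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"QX{gene_counter:04d}"

    gene_for_ec: dict[ECNumber, GeneAnnotation] = {}
    for ec in rest:
        g = GeneAnnotation(
            gene_id=next_qid(), ec_numbers=[ec],
            product=f"enzyme {ec}", source="draft",
            sequence=_mutate(base_seq[ec], rng),
        )
        gene_for_ec[ec] = g
        query_genes.append(g)
    misannotations: list[tuple[str, ECNumber, ECNumber]] = []
    for w, t in zip(wrong, true_for_wrong):
        g = gene_for_ec[t]
        g.ec_numbers = list(dict.fromkeys(g.ec_numbers + [w]))
        g.product = f"bifunctional candidate {t} / {w}"
        misannotations.append((g.gene_id, w, t))
    for ec in holes:  # unannotated homologue of the missing enzyme
        query_genes.append(
            GeneAnnotation(
                gene_id=next_qid(), ec_numbers=[],
                product="hypothetical protein", source="draft",
                sequence=_mutate(base_seq[ec], rng),
            )
        )
    distractor_ecs = _distinct_ecs(random.Random(seed + 7919), n_ecs + 4)
    distractor_ecs = [e for e in distractor_ecs if e not in set(ecs)][:2]
    for j, dec in enumerate(distractor_ecs):
        query_genes.append(
            GeneAnnotation(
                gene_id=next_qid(), ec_numbers=[dec],
                product="unrelated distractor", source="draft",
                sequence=_random_protein(rng, rng.randint(120, 300)),
            )
        )
    query_ann = OrganismAnnotation(organism_id=query_org, genes=query_genes)

    # ---- reference annotations -------------------------------------------
    ref_anns: list[OrganismAnnotation] = []
    for r, org in enumerate(ref_orgs, start=1):
        genes = []
        for i, ec in enumerate(ecs):
            if ec in set(wrong):
                continue  # no reference supports the planted wrong functions
            genes.append(
                GeneAnnotation(
                    gene_id=f"R{r}G{i + 1:04d}", ec_numbers=[ec],
                    product=f"enzyme {ec}", source="reference",
                    sequence=_mutate(base_seq[ec], rng),
                )
            )
        genes.append(
            GeneAnnotation(
                gene_id=f"R{r}G{9000}", ec_numbers=[],
                product="unrelated distractor", source="reference",
                sequence=_random_protein(rng, rng.randint(120, 300)),
            )
        )
        ref_anns.append(OrganismAnnotation(organism_id=org, genes=genes))

    # ---- write all artefacts ----------------------------------------------
    files: dict[str, str] = {}
    kgml_rel = f"kgml/{pathway_id}.xml"
    _write_kgml(out / kgml_rel, pathway_id, ecs)
    files["kgml"] = kgml_rel

    for ann in [query_ann] + ref_anns:
        slug = _slug(ann.organism_id)
        gbk = f"annotations/{slug}.gbk"
        tsv = f"annotations/{slug}.tsv"
        faa = f"proteins/{slug}.faa"
        _write_genbank(out / gbk, ann.organism_id, ann.genes)
        write_annotation_table(ann, out / tsv)
        _write_fasta(out / faa, ann.genes)
        files[f"genbank:{ann.organism_id}"] = gbk
        files[f"table:{ann.organism_id}"] = tsv
        files[f"fasta:{ann.organism_id}"] = faa

    qslug = _slug(query_org)
    qseqs = query_ann.sequences()
    for ann in ref_anns:
        rslug = _slug(ann.organism_id)
        rseqs = ann.sequences()
        fwd = align_proteomes(qseqs, rseqs, direction=(query_org, ann.organism_id),
                              scoring=scoring)
        rev = align_proteomes(rseqs, qseqs, direction=(ann.organism_id, query_org),
                              scoring=scoring)
        fwd_rel = f"hits/{qslug}__vs__{rslug}.tsv"
        rev_rel = f"hits/{rslug}__vs__{qslug}.tsv"
        write_blast_tabular(fwd, out / fwd_rel)
        write_blast_tabular(rev, out / rev_rel)
        files[f"hits:{query_org}->{ann.organism_id}"] = fwd_rel
        files[f"hits:{ann.organism_id}->{query_org}"] = rev_rel

    # BRENDA snippet: positive literature for every genuinely shared EC in
    # the reference organisms; the wrong ECs get literature only for an
    # unrelated organism, so query-organism lookups stay empty.
    lit = LiteratureIndex()
    pm = 10_000_000
    for i, ec in enumerate(ecs):
        if ec in set(wrong):
            lit.add(ec, "Alius organismus",
                    Publication(citation_text=f"Synthetic report on {ec} in an unrelated taxon",
                                pubmed_id=str(pm + i)))
            continue
        for org in ref_orgs:
            lit.add(ec, org,
                    Publication(citation_text=f"Synthetic characterisation of {ec} in {org}",
                                pubmed_id=str(pm + 100 * (i + 1) + ref_orgs.index(org))))
    if rest:  # one negative-evidence example so the report section is exercised
        lit.add(rest[-1], ref_orgs[0],
                Publication(citation_text=f"Synthetic absence study of {rest[-1]}",
                            pubmed_id=str(pm + 999_999), polarity="negative"))
    brenda_rel = "brenda_snippet.txt"
    write_brenda_flatfile(lit, out / brenda_rel)
    files["brenda"] = brenda_rel

    case = SyntheticCase(
        seed=seed,
        n_references=n_references,
        output_dir=out,
        pathway_id=pathway_id,
        query_organism=query_org,
        reference_organisms=ref_orgs,
        ec_universe=ecs,
        planted_holes=holes,
        planted_misannotations=misannotations,
        files=files,
    )
    (out / "case.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "pathway_id": pathway_id,
                "query_organism": query_org,
                "reference_organisms": ref_orgs,
                "ec_universe": [str(e) for e in ecs],
                "planted_holes": [str(e) for e in holes],
                "planted_misannotations": [
                    [g, str(w), str(t)] for g, w, t in misannotations
                ],
                "files": files,
            },
            indent=2, sort_keys=True,
        ) + "\n",
        encoding="utf-8",
    )
    files["case"] = "case.json"
    return case
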