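# pathwaycurator

Support for the manual curation of genome-scale metabolic models.

Automatically generated draft metabolic reconstructions are riddled with two
complementary kinds of error: **pathway holes** (a reaction whose enzyme
gene exists but was never annotated, leaving a false gap in the network) and
**misannotated enzymes** (a function wrongly assigned to a gene, creating a
false reaction). Finding either requires cross-checking a query organism's
annotation against related genomes, homology evidence and the enzyme
literature — tedious to do by hand, pathway by pathway.

`pathwaycurator` integrates that evidence for one KEGG pathway at a time:

- **Annotations** from GenBank files, protein FASTA and user tables, each
  assignment tagged with its source, keyed by Enzyme Commission (EC) number.
- **Pathway structure** from KGML files in a local cache (enzyme boxes with
  EC links, reactions, pixel-space graphics).
- **Homology** from NCBI BLAST tabular files (`-outfmt 6`), or from a
  built-in Smith–Waterman local aligner with a shuffle-based Z-score for
  BLAST-free operation on small proteomes. Reciprocal best hits (RBH) and
  top-3 candidate lists are derived either way.
- **Literature** from a BRENDA-style flatfile, indexed as
  (EC, organism) → publications, including negative evidence
  ("no activity in …").

## Method

For a pathway with EC set $E$ and organisms $o_1$ (query), $o_2, \dots, o_n$
(references), the package builds a binary presence matrix
$P \in \{0,1\}^{n \times |E|}$ with $P_{ij} = 1$ iff some gene of $o_i$
carries EC $e_j$. From $P$ it derives:

- the **Hamming distance** between organisms $a$ and $b$,
  $d(a,b) = |\{ e \in E : P_{ae} \ne P_{be} \}|$ — the number of enzymatic
  functions present in exactly one of the two — shown as a heatmap;
- **hole calls**: ECs with $P_{1j}=0$ present in at least a fraction
  $f$ (default 0.5) of the references, with candidate filler genes ranked
  from RBH partners (preferred) and top-k hits against the reference genes
  carrying that EC;
- **misannotation calls**: ECs present *only* in the query and backed by no
  positive publication for the query organism; alternative functions are
  reference-supported ECs co-annotated on the same genes. Positive
  literature vetoes the call.

Callers never edit anything — they emit ranked suggestions, and the whole
evidence trail is rendered as a static, relocatable HTML report with a
colour-coded SVG pathway diagram (one colour band per organism inside each
enzyme box), evidence tables and KEGG/PubMed hyperlinks.

## Worked example

Generate a synthetic curation case with planted defects and run the full
pipeline on it:

```
$ pathwaycurator fixtures --seed 3 --out demo --report
synthetic case written to demo
planted holes: 2.7.23.121, 5.19.14.150
planted misannotations: QX0001: 4.7.9.173 (true 1.3.6.195)
report written to demo/report
```

The generated case has one query organism and five references sharing a
20-enzyme pathway. Two functions (`2.7.23.121`, `5.19.14.150`) were removed
from the query annotation even though the query proteome keeps close
homologues of the reference enzymes — planted pathway holes. One query gene
(`QX0001`) carries a wrong EC (`4.7.9.173`) that no reference and no
query-organism literature supports, next to its true, reference-supported
function (`1.3.6.195`) — a planted misannotation.

Running the pipeline on user-supplied files works the same way:

```
$ pathwaycurator run --kgml demo/kgml/09901.xml \
    --organism "Testium exemplum NX-1=demo/annotations/testium_exemplum_nx_1.gbk" \
    --organism "Testium referens1=demo/annotations/testium_referens1.gbk" \
    ... --brenda demo/brenda_snippet.txt --out report --max-evalue 1
report written to report
pathway ECs: 20; hole calls: 2; misannotation calls: 1
```

Both planted holes are called (each with an RBH candidate gene ranked
first) and exactly the planted misannotation is flagged, with the true
function listed as the reference-supported alternative. `report/index.html`
links the diagram, annotation, RBH, top-hits, literature, heatmap and call
tables; the TSV files next to them are the machine-readable artefacts.

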