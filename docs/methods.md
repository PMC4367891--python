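# Methods

## Comparison model

The unit of comparison is the EC number, not the KGML reaction: a
pathway's "structure" for our purposes is its set of enzymatic functions,
and an organism either has a gene asserted to carry a function or it does
not. Reaction-level colouring in the diagram is derived downstream (a box
is coloured for an organism when *any* of the box's ECs is present in that
organism — relevant only for the minority of boxes mapping to several ECs).

Presence is decided purely from user-supplied annotations (GenBank CDS
`EC_number` qualifiers, annotation tables, optional `EC=` FASTA tokens).
EC numbers are never inferred from free-text product descriptions — that
would re-introduce exactly the silent misannotation the tool exists to
catch. Wildcard ECs (e.g. `4.2.1.-`) in a pathway match only identical
wildcard annotations by default; prefix matching is an explicit opt-in
(`--prefix-wildcards`), because a wildcard match is weaker evidence.

The Hamming distance between two organisms is the size of the symmetric
difference of their present-EC sets, restricted to the pathway EC set. It
is a pseudometric (symmetric, zero on identical rows, triangle
inequality); the test suite checks this against a set-enumeration oracle
on hundreds of random matrices.

## Calling rules and their parameters

**Pathway holes.** An EC is called a candidate hole when the query lacks
it and at least `min_ref_fraction` of the references have it. The default
0.5 operationalises "most of the reference organisms"; it is a curation
sensitivity knob, not a statistical threshold — with five references the
default demands three. All references count equally; weighting close
relatives more heavily would be a reasonable extension but is not
implemented. Candidate filler genes are gathered per supporting reference
from (a) reciprocal-best-hit partners of the reference genes carrying the
EC — the standard ortholog heuristic, preferred evidence — and (b) top-k
hits (default k = 3) of those reference genes against the query proteome.
Candidates are deduplicated keeping the stronger evidence class, then
ranked RBH first, descending bit score, gene id as the final tie-break.

**Misannotations.** An EC is called when it is present in the query and in
*none* of the references (the query-only pattern of the classic
dual-annotation case), and no positive publication links the EC to the
query organism — positive literature vetoes the call, since a directly
characterised function is not a plausible annotation error. Negative
literature ("no activity in …") is displayed but does not strengthen the
call; absence of support is already the trigger. Alternative functions are
other ECs on the same gene(s) present in at least `min_ref_fraction` of
the references (the same threshold as hole calling, for coherence; the
motivating dual-function case has full reference support, so any
reasonable threshold reproduces it).

Hole ECs and misannotation ECs are disjoint by construction (query-absent
versus query-present).

## Homology evidence

BLAST tabular (`-outfmt 6`) files are consumed as-is; the tool never runs
BLAST. Hit ordering — descending bit score, then ascending E-value, then
lexicographic subject id — is fixed so best hits, RBH sets and reports are
reproducible even when scores tie. The best-hit E-value cutoff defaults to
1e-5, conventional RBH practice.

For BLAST-free operation the package aligns small proteomes itself with a
Smith–Waterman local alignment (linear gap penalty; default match +2,
mismatch −1, gap −2). The implementation delegates the dynamic programming
to Biopython's `PairwiseAligner`; the test suite validates it against an
independent hand-written full-DP oracle — exhaustively over *every*
sequence pair up to length 3 on a 4-letter alphabet (7,056 pairs) plus
seeded random pairs up to length 12, along with symmetry and
monotonicity-in-match-reward properties. Percent identity counts identical
columns over all aligned columns (gaps in the denominator, as BLAST
reports it). In aligner-produced hit tables the raw alignment score stands
in for the bit score and the E-value is recorded as 0: ranking, not
significance, is what the downstream consumers use. Karlin–Altschul
E-values are deliberately out of scope.

Alignment significance is instead available as a shuffle Z-score:
z = (S_real − mean(S_null)) / sd(S_null), with the null built from
`n_shuffles` seeded Fisher–Yates shuffles of the second sequence
(composition-preserving). The population standard deviation is used. A
degenerate null (sd = 0, e.g. homopolymers) reports +inf when the real
score beats the null mean and 0 otherwise. This is a declared definition
chosen for its simplicity and determinism, in the FASTA tradition of
shuffle statistics.

## Literature index

Only the ID (EC), PR (protein/organism with `<n,m>` reference cross-refs)
and RF (numbered references with `{Pubmed:...}`) fields of the BRENDA-style
flatfile are consumed. Negative evidence is recognised by the literal,
configurable commentary pattern "no activity in". Organism matching is
case-insensitive on genus + species, ignoring strain suffixes, because
flatfile entries rarely record strains; the lookup for
"Bacillus subtilis 168" therefore finds entries filed under
"Bacillus subtilis".

## Synthetic cases: what they emulate and what they do not

`generate_synthetic_case` builds a full study design at toy scale: one
query, several same-genus references, a shared pathway, and planted ground
truth. References carry every pathway EC except the planted wrong ones;
the query lacks the hole ECs but keeps unannotated homologues of the
missing enzymes (so homology can recover them); each planted wrong EC sits
on a query gene next to its true, reference-supported function. Protein
sequences are uniform-random 120–300-residue chains; homologues are
derived by seeded point mutation at a 10% rate, and unrelated distractor
genes are added per organism so hit selection is non-trivial. The
literature snippet supports every genuinely shared EC in the reference
organisms, gives the wrong ECs literature only in an unrelated taxon, and
plants one negative publication so the report's absence section is
exercised.

What this emulates: presence/absence structure, unambiguous orthology,
multi-source annotation provenance, literature positives/negatives, and
every file format the pipeline reads (the generator writes KGML, GenBank,
tables, FASTA, outfmt-6 hit tables via the internal aligner, and the
flatfile — each re-read through the ordinary parsers). What it does not:
realistic phylogenetic divergence, paralogy, domain fusions, annotation
noise in the references, or incomplete literature coverage. Perfect
recall/precision on these fixtures therefore demonstrates that the calling
logic is implemented correctly, not that real draft annotations will be
this clean — on real data the callers are screening aids for a human
curator, exactly as intended.

Problem sizes used by the test suite and `scripts/acceptance.py` — 10–20
pathway ECs, 2–5 references, 2 holes, 1 misannotation, 10–20 seeds — keep
the whole validation fast while covering every code path; the
generator accepts larger values.

## Determinism and rendering

Every artefact is byte-deterministic for fixed inputs: generated fixture
files (GenBank records carry a fixed LOCUS date), hit tables (fixed float
formats, sorted iteration), TSV exports, the SVG diagram and the HTML
pages. SVG and HTML are emitted by small string-building helpers rather
than a template engine, which keeps the byte-determinism contract trivial
to uphold. The heatmap TSV is the authoritative distance artefact; the PNG
is a convenience rendering. Enzyme boxes are drawn at their KGML pixel
coordinates (shifted below a legend); within a box, present organisms get
equal-height horizontal bands in palette order — absent organisms
contribute no band, so a function absent everywhere is an outline-only
box. KEGG and PubMed links are URL templates, never fetched; reports
contain only relative paths and relocate freely.

## Known limitations

- Affine gaps and heuristic seeding are not implemented; the internal
  aligner targets fixture-scale proteomes, not genome-scale searches.
- Organism-specific KGML is accepted but its gene-type entries are
  ignored; presence always comes from user annotations.
- EMBL input is not supported (GenBank, FASTA and tables cover the
  evidence model; tables are the escape hatch for any third-party source).
- The misannotation rule requires absence in *all* references; a function
  shared with even one reference is treated as plausibly real.
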