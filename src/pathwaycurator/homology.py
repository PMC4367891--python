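"""Pairwise homology evidence.

Two evidence routes feed the comparison stage:

* parsed BLAST tabular output (NCBI ``-outfmt 6``, 12 columns), produced by
  the user outside this tool;
* an internal Smith-Waterman local aligner (linear gap penalty) for
  BLAST-free operation on small proteomes, with a shuffle-based Z-score for
  alignment significance.

From either route the module derives best hits, reciprocal best hits (the
classic ortholog heuristic: each protein is the other's highest-scoring
hit) and top-k candidate lists.  Hit ordering is made fully deterministic:
descending bit score, then ascending E-value, then lexicographic subject id.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

__all__ = [
    "HitRecord",
    "HitTable",
    "RBHPair",
    "Scoring",
    "HitTableFormatError",
    "parse_blast_tabular",
    "write_blast_tabular",
    "best_hit_map",
    "reciprocal_best_hits",
    "top_k_hits",
    "local_align_score",
    "shuffle_z_score",
    "align_proteomes",
    "DEFAULT_MAX_EVALUE",
]

DEFAULT_MAX_EVALUE = 1e-5  # conventional RBH practice; CLI-overridable


class HitTableFormatError(ValueError):
    """Raised for malformed BLAST tabular input."""


@dataclass(frozen=True)
class Scoring:
    """Simple substitution scheme for the internal aligner (linear gaps)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if self.gap > 0:
            raise ValueError("gap penalty must be <= 0")


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    z_score: float | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity must be in [0, 100]")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")


def _hit_order_key(hit: HitRecord) -> tuple:
    # descending bit score, ascending e-value, lexicographic subject
    return (-hit.bit_score, hit.e_value, hit.subject_id)


@dataclass
class HitTable:
    """All hits for one search direction (organism A -> organism B).

    Hits are kept grouped by query and ordered by the deterministic tie rule.
    """

    direction: tuple[str, str]
    hits: list[HitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (h.query_id,) + _hit_order_key(h))

    def hits_for(self, query_id: str) -> list[HitRecord]:
        return [h for h in self.hits if h.query_id == query_id]


@dataclass(frozen=True)
class RBHPair:
    gene_a: str
    gene_b: str
    forward: HitRecord  # gene_a -> gene_b
    reverse: HitRecord  # gene_b -> gene_a

    def __post_init__(self) -> None:
        if self.forward.query_id != self.gene_a or self.forward.subject_id != self.gene_b:
            raise ValueError("forward hit does not connect gene_a to gene_b")
        if self.reverse.query_id != self.gene_b or self.reverse.subject_id != self.gene_a:
            raise ValueError("reverse hit does not connect gene_b to gene_a")


# ---------------------------------------------------------------------------
# BLAST tabular I/O

_OUTFMT6_COLS = 12


def parse_blast_tabular(path: str | Path, direction: tuple[str, str]) -> HitTable:
    """Parse NCBI BLAST ``-outfmt 6`` (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    path = Path(path)
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _OUTFMT6_COLS:
                raise HitTableFormatError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLS} columns, got {len(cols)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        e_value=float(cols[10]),
                        bit_score=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableFormatError(f"{path}:{lineno}: {exc}") from None
    return HitTable(direction=direction, hits=hits)


def write_blast_tabular(table: HitTable, path: str | Path) -> None:
    """Write a table back to outfmt-6 TSV (deterministic formatting)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in table.hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.e_value:.2g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Best hits / RBH / top-k

def best_hit_map(table: HitTable, max_evalue: float = DEFAULT_MAX_EVALUE) -> dict[str, HitRecord]:
    """Per query, the single best hit (under the ordering rule) with
    ``e_value <= max_evalue``; queries with no passing hit are absent."""
    best: dict[str, HitRecord] = {}
    for hit in table.hits:  # already sorted per query
        if hit.e_value > max_evalue:
            continue
        if hit.query_id not in best:
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(
    ab: HitTable, ba: HitTable, max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[RBHPair]:
    """Pairs (a, b) where b is a's best hit and a is b's best hit."""
    if ab.direction == ba.direction or ab.direction != (ba.direction[1], ba.direction[0]):
        raise ValueError(
            f"tables must have opposite directions, got {ab.direction} and {ba.direction}"
        )
    fwd = best_hit_map(ab, max_evalue)
    rev = best_hit_map(ba, max_evalue)
    pairs = []
    for a, fhit in fwd.items():
        b = fhit.subject_id
        rhit = rev.get(b)
        if rhit is not None and rhit.subject_id == a:
            pairs.append(RBHPair(gene_a=a, gene_b=b, forward=fhit, reverse=rhit))
    return sorted(pairs, key=lambda p: p.gene_a)


def top_k_hits(
    table: HitTable, k: int = 3, max_evalue: float = DEFAULT_MAX_EVALUE
) -> dict[str, list[HitRecord]]:
    """Per query, the first k passing hits under the ordering rule (fewer if
    fewer pass).  k=3 reproduces the usual 'three best hits' candidate list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[HitRecord]] = {}
    for hit in table.hits:
        if hit.e_value > max_evalue:
            continue
        bucket = out.setdefault(hit.query_id, [])
        if len(bucket) < k:
            bucket.append(hit)
    return out


# ---------------------------------------------------------------------------
# Internal local aligner

def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


def local_align_score(
    seq_a: str, seq_b: str, scoring: Scoring = Scoring()
) -> tuple[float, float]:
    """Optimal Smith-Waterman local alignment score with linear gap penalty,
    plus percent identity over the aligned columns (gaps included in the
    denominator, as BLAST does).

    Empty input: score 0 by contract, identity reported as 0.
    """
    if not seq_a or not seq_b:
        return 0.0, 0.0
    aligner = _make_aligner(scoring)
    score = float(aligner.score(seq_a, seq_b))
    if score <= 0:
        return max(score, 0.0), 0.0
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    return score, identity


def shuffle_z_score(
    seq_a: str,
    seq_b: str,
    scoring: Scoring = Scoring(),
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Significance of the local alignment score by composition-preserving
    shuffling: z = (S_real - mean(S_null)) / sd(S_null), where the null
    scores come from aligning seq_a against ``n_shuffles`` Fisher-Yates
    shuffles of seq_b.  Deterministic for a fixed seed.

    Degenerate null (sd = 0) is signalled as +inf when the real score
    exceeds the null mean, else 0.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    s_real, _ = local_align_score(seq_a, seq_b, scoring)
    rng = random.Random(seed)
    chars = list(seq_b)
    null_scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = chars[:]
        rng.shuffle(shuffled)
        null_scores[i], _ = local_align_score(seq_a, "".join(shuffled), scoring)
    mean = float(null_scores.mean())
    sd = float(null_scores.std())
    if sd == 0.0:
        return math.inf if s_real > mean else 0.0
    return (s_real - mean) / sd


def align_proteomes(
    seqs_a: Mapping[str, str],
    seqs_b: Mapping[str, str],
    direction: tuple[str, str],
    scoring: Scoring = Scoring(),
    z_shuffles: int = 0,
    seed: int = 0,
) -> HitTable:
    """All-vs-all local alignment of two small proteomes into a
    :class:`HitTable` (the BLAST-free route).

    The Smith-Waterman score stands in for the bit score and the E-value is
    reported as 0 (every hit passes thresholding; ranking is what matters).
    Zero-score pairs are omitted.  With ``z_shuffles`` > 0 a shuffle Z-score
    is attached to each hit.
    """
    hits = []
    for qid in sorted(seqs_a):
        for sid in sorted(seqs_b):
            score, identity = local_align_score(seqs_a[qid], seqs_b[sid], scoring)
            if score <= 0:
                continue
            hit = HitRecord(
                query_id=qid,
                subject_id=sid,
                percent_identity=round(identity, 2),
                alignment_length=min(len(seqs_a[qid]), len(seqs_b[sid])),
                e_value=0.0,
                bit_score=score,
                q_start=1,
                q_end=len(seqs_a[qid]),
                s_start=1,
                s_end=len(seqs_b[sid]),
            )
            if z_shuffles:
                z = shuffle_z_score(
                    seqs_a[qid], seqs_b[sid], scoring, n_shuffles=z_shuffles, seed=seed
                )
                hit = replace(hit, z_score=z)
            hits.append(hit)
    return HitTable(direction=direction, hits=hits)
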