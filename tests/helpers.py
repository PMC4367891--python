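"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (full DP tables,
exhaustive enumeration) and stay independent of the package code paths
they check.
"""

from __future__ import annotations

import random


def sw_score_oracle(a: str, b: str, match: float = 2, mismatch: float = -1,
                    gap: float = -2) -> float:
    """Full Smith-Waterman DP table, linear gaps, pure Python."""
    n, m = len(a), len(b)
    best = 0.0
    prev = [0.0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0.0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def best_hit_oracle(hits, max_evalue):
    """Exhaustive argmax per query under (bit desc, evalue asc, subject lex)."""
    out = {}
    for h in hits:
        if h.e_value > max_evalue:
            continue
        cur = out.get(h.query_id)
        key = (-h.bit_score, h.e_value, h.subject_id)
        if cur is None or key < (-cur.bit_score, cur.e_value, cur.subject_id):
            out[h.query_id] = h
    return out


def rbh_oracle(ab_hits, ba_hits, max_evalue):
    """All-pairs mutual-argmax enumeration; returns {(a, b)}."""
    fwd = best_hit_oracle(ab_hits, max_evalue)
    rev = best_hit_oracle(ba_hits, max_evalue)
    pairs = set()
    for a, fh in fwd.items():
        for b, rh in rev.items():
            if fh.subject_id == b and rh.subject_id == a:
                pairs.add((a, b))
    return pairs


def hamming_oracle(row_a, row_b) -> int:
    """Symmetric-difference enumeration over present-EC sets."""
    present_a = {ec for ec, v in row_a.items() if v}
    present_b = {ec for ec, v in row_b.items() if v}
    return len(present_a ^ present_b)


def random_hit_records(rng: random.Random, n_a: int, n_b: int, density: float = 0.7):
    """Random toy hit list A -> B with occasional score/evalue ties."""
    from pathwaycurator.homology import HitRecord

    hits = []
    for i in range(n_a):
        for j in range(n_b):
            if rng.random() > density:
                continue
            bit = float(rng.choice([20, 30, 40, 50, 60, 70]))  # ties likely
            ev = rng.choice([0.0, 1e-30, 1e-10, 1e-6, 1e-3, 1.0])
            hits.append(
                HitRecord(
                    query_id=f"a{i}", subject_id=f"b{j}",
                    percent_identity=round(rng.uniform(20, 100), 1),
                    alignment_length=rng.randint(50, 300),
                    e_value=ev, bit_score=bit,
                )
            )
    return hits
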