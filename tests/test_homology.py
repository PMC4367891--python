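import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from helpers import best_hit_oracle, random_hit_records, rbh_oracle, sw_score_oracle
from pathwaycurator.homology import (
    HitRecord,
    HitTable,
    HitTableFormatError,
    Scoring,
    align_proteomes,
    best_hit_map,
    local_align_score,
    parse_blast_tabular,
    reciprocal_best_hits,
    shuffle_z_score,
    top_k_hits,
    write_blast_tabular,
)


def _hit(q, s, bit, ev=1e-20, pid=50.0):
    return HitRecord(query_id=q, subject_id=s, percent_identity=pid,
                     alignment_length=100, e_value=ev, bit_score=bit)


class TestBlastTabular:
    ROW = "q1\ts1\t97.50\t200\t5\t0\t1\t200\t1\t200\t1e-50\t380.0\n"

    def test_parse_single_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW)
        table = parse_blast_tabular(p, direction=("A", "B"))
        assert len(table.hits) == 1
        h = table.hits[0]
        assert h.query_id == "q1" and h.subject_id == "s1"
        assert h.percent_identity == 97.5 and h.bit_score == 380.0
        assert h.e_value == 1e-50 and h.alignment_length == 200

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW + "q2\ts2\t90\t100\t1\t0\t1\t100\t1\t100\t1e-10\n")
        with pytest.raises(HitTableFormatError, match=":2"):
            parse_blast_tabular(p, direction=("A", "B"))

    def test_unparseable_numeric_field(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW.replace("380.0", "xyz"))
        with pytest.raises(HitTableFormatError, match=":1"):
            parse_blast_tabular(p, direction=("A", "B"))

    def test_round_trip(self, tmp_path):
        table = HitTable(direction=("A", "B"),
                         hits=[_hit("q1", "s1", 50), _hit("q1", "s2", 40, ev=1e-8)])
        p = tmp_path / "rt.tsv"
        write_blast_tabular(table, p)
        back = parse_blast_tabular(p, direction=("A", "B"))
        assert [(h.query_id, h.subject_id, h.bit_score) for h in back.hits] == [
            (h.query_id, h.subject_id, h.bit_score) for h in table.hits
        ]

    def test_tie_rule_equal_bits_orders_by_evalue_then_subject(self):
        hits = [_hit("q1", "s_b", 50, ev=1e-10), _hit("q1", "s_a", 50, ev=1e-10),
                _hit("q1", "s_c", 50, ev=1e-20)]
        table = HitTable(direction=("A", "B"), hits=hits)
        assert [h.subject_id for h in table.hits] == ["s_c", "s_a", "s_b"]


class TestBestAndTopHits:
    def test_best_hit_picks_max_bit_score(self):
        table = HitTable(("A", "B"), [_hit("q1", "s1", 50), _hit("q1", "s2", 40)])
        assert best_hit_map(table, 1e-5)["q1"].subject_id == "s1"

    def test_all_hits_failing_threshold_gives_empty_map(self):
        table = HitTable(("A", "B"), [_hit("q1", "s1", 50, ev=1.0)])
        assert best_hit_map(table, 1e-5) == {}

    def test_best_hit_matches_exhaustive_oracle_on_random_tables(self):
        rng = random.Random(42)
        for _ in range(30):
            hits = random_hit_records(rng, n_a=20, n_b=8)
            table = HitTable(("A", "B"), hits)
            got = best_hit_map(table, 1e-5)
            want = best_hit_oracle(hits, 1e-5)
            assert {q: h.subject_id for q, h in got.items()} == {
                q: h.subject_id for q, h in want.items()
            }

    def test_top_k_counts_and_consistency_with_best_hit(self):
        hits = [_hit("q1", f"s{i}", 60 - i) for i in range(5)]
        table = HitTable(("A", "B"), hits)
        top3 = top_k_hits(table, k=3, max_evalue=1e-5)["q1"]
        assert [h.subject_id for h in top3] == ["s0", "s1", "s2"]
        short = top_k_hits(HitTable(("A", "B"), hits[:2]), k=3, max_evalue=1e-5)["q1"]
        assert len(short) == 2
        top1 = top_k_hits(table, k=1, max_evalue=1e-5)
        best = best_hit_map(table, 1e-5)
        assert {q: v[0].subject_id for q, v in top1.items()} == {
            q: h.subject_id for q, h in best.items()
        }


class TestRBH:
    def test_mutual_best_pair_found(self):
        ab = HitTable(("A", "B"), [_hit("a1", "b1", 50)])
        ba = HitTable(("B", "A"), [_hit("b1", "a1", 50)])
        pairs = reciprocal_best_hits(ab, ba)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_asymmetric_best_excluded(self):
        ab = HitTable(("A", "B"), [_hit("a1", "b1", 50)])
        ba = HitTable(("B", "A"), [_hit("b1", "a2", 60), _hit("b1", "a1", 50)])
        assert reciprocal_best_hits(ab, ba) == []

    def test_same_direction_inputs_rejected(self):
        t = HitTable(("A", "B"), [])
        with pytest.raises(ValueError, match="opposite directions"):
            reciprocal_best_hits(t, HitTable(("A", "B"), []))

    def test_matches_brute_force_on_random_toy_tables(self):
        rng = random.Random(7)
        for _ in range(50):
            ab_hits = random_hit_records(rng, 6, 6)
            ba_hits = [
                HitRecord(query_id=h.subject_id, subject_id=h.query_id,
                          percent_identity=h.percent_identity,
                          alignment_length=h.alignment_length,
                          e_value=rng.choice([0.0, 1e-8, 1e-3]),
                          bit_score=float(rng.choice([20, 40, 60])))
                for h in random_hit_records(rng, 6, 6)
            ]
            ab = HitTable(("A", "B"), ab_hits)
            ba = HitTable(("B", "A"), ba_hits)
            got = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba)}
            assert got == rbh_oracle(ab_hits, ba_hits, 1e-5)

    def test_direction_swap_symmetry(self):
        rng = random.Random(9)
        ab_hits = random_hit_records(rng, 6, 6)
        ba_hits = random_hit_records(rng, 6, 6)
        ba_hits = [
            HitRecord(query_id=h.query_id.replace("a", "b"),
                      subject_id=h.subject_id.replace("b", "a"),
                      percent_identity=h.percent_identity,
                      alignment_length=h.alignment_length,
                      e_value=h.e_value, bit_score=h.bit_score)
            for h in ba_hits
        ]
        ab = HitTable(("A", "B"), ab_hits)
        ba = HitTable(("B", "A"), ba_hits)
        fwd = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba)}
        rev = {(p.gene_b, p.gene_a) for p in reciprocal_best_hits(ba, ab)}
        assert fwd == rev


class TestLocalAligner:
    def test_perfect_match_score_and_identity(self):
        score, identity = local_align_score("ACGT", "ACGT", Scoring(2, -1, -2))
        assert score == 8 and identity == 100.0

    def test_empty_sequence_contract(self):
        assert local_align_score("", "ACGT") == (0.0, 0.0)
        assert local_align_score("ACGT", "") == (0.0, 0.0)

    def test_single_best_residue_match(self):
        score, identity = local_align_score("ACGT", "TTTT", Scoring(2, -1, -2))
        assert score == 2 and identity == 100.0  # the lone T aligns to a T

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(3)
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            score, _ = local_align_score(a, b, Scoring(2, -1, -2))
            assert score == sw_score_oracle(a, b, 2, -1, -2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.text(alphabet="ACDEFG", min_size=0, max_size=15),
           st.text(alphabet="ACDEFG", min_size=0, max_size=15))
    def test_symmetry_property(self, a, b):
        assert local_align_score(a, b)[0] == local_align_score(b, a)[0]

    def test_monotone_in_match_reward(self):
        rng = random.Random(5)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(10))
            b = "".join(rng.choice("ACGT") for _ in range(10))
            s1, _ = local_align_score(a, b, Scoring(1, -1, -2))
            s2, _ = local_align_score(a, b, Scoring(2, -1, -2))
            assert s2 >= s1


class TestShuffleZ:
    SEQ = "".join(random.Random(1).choices("ACDEFGHIKLMNPQRSTVWY", k=200))

    def test_self_alignment_is_highly_significant(self):
        z = shuffle_z_score(self.SEQ, self.SEQ, n_shuffles=50, seed=1)
        assert z > 5

    def test_deterministic_for_fixed_seed(self):
        z1 = shuffle_z_score(self.SEQ[:60], self.SEQ[60:120], n_shuffles=20, seed=4)
        z2 = shuffle_z_score(self.SEQ[:60], self.SEQ[60:120], n_shuffles=20, seed=4)
        assert z1 == z2

    def test_degenerate_null_reports_inf_or_zero(self):
        # single-letter sequences: every shuffle scores identically
        z = shuffle_z_score("AAAA", "AAAA", n_shuffles=10, seed=0)
        assert z == math.inf or z == 0.0

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            shuffle_z_score("ACGT", "ACGT", n_shuffles=5)


def test_align_proteomes_produces_ranked_table():
    seqs_a = {"a1": "MKLVITGAAKRLVIT", "a2": "WWWWYYYYFFFF"}
    seqs_b = {"b1": "MKLVITGAAKRLVIT", "b2": "PPPPGGGGSSSS"}
    table = align_proteomes(seqs_a, seqs_b, direction=("A", "B"))
    best = best_hit_map(table, max_evalue=1.0)
    assert best["a1"].subject_id == "b1"
    assert best["a1"].percent_identity == 100.0
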