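import itertools
import random

import pandas as pd
import pytest

from helpers import hamming_oracle
from pathwaycurator.annotations_io import GeneAnnotation, OrganismAnnotation
from pathwaycurator.brenda_lit import LiteratureIndex, Publication
from pathwaycurator.comparison import (
    PresenceMatrix,
    build_presence_matrix,
    call_misannotations,
    call_pathway_holes,
    distance_matrix,
    hamming_distance,
)
from pathwaycurator.ec import normalize_ec
from pathwaycurator.homology import HitRecord, RBHPair
from pathwaycurator.kegg_pathway import parse_kgml_string


def kgml_for(ecs):
    entries = "\n".join(
        f'<entry id="{i + 1}" name="ec:{ec}" type="enzyme">'
        f'<graphics name="{ec}" x="{50 + 60 * i}" y="50" width="46" height="17"/></entry>'
        for i, ec in enumerate(ecs)
    )
    return parse_kgml_string(
        f'<pathway name="path:ec00001" number="00001" title="toy">{entries}</pathway>'
    )


def org(org_id, mapping, source="src"):
    genes = [
        GeneAnnotation(g, [normalize_ec(e) for e in ecs], source=source)
        for g, ecs in mapping.items()
    ]
    return OrganismAnnotation(organism_id=org_id, genes=genes)


def random_matrix(rng, n_orgs=None, n_ecs=None):
    n_orgs = n_orgs or rng.randint(2, 6)
    n_ecs = n_ecs or rng.randint(1, 8)
    orgs = [f"org{i}" for i in range(n_orgs)]
    ecs = [normalize_ec(f"1.1.1.{i + 1}") for i in range(n_ecs)]
    data = [[rng.randint(0, 1) for _ in ecs] for _ in orgs]
    presence = pd.DataFrame(data, index=orgs, columns=[str(e) for e in ecs], dtype=int)
    return PresenceMatrix(pathway_id="00001", organisms=orgs, ecs=ecs, presence=presence)


class TestBuildPresenceMatrix:
    def test_direct_membership(self):
        pathway = kgml_for(["1.1.1.1", "2.2.2.2"])
        m = build_presence_matrix(
            pathway,
            [org("q", {"g1": ["1.1.1.1"], "g2": ["2.2.2.2"]}),
             org("r", {"h1": ["1.1.1.1"]})],
        )
        assert m.presence.loc["q"].tolist() == [1, 1]
        assert m.presence.loc["r"].tolist() == [1, 0]
        assert m.supporting_genes("r", normalize_ec("1.1.1.1")) == [("h1", "src")]

    def test_unannotated_organism_gives_zero_row(self):
        pathway = kgml_for(["1.1.1.1", "2.2.2.2"])
        m = build_presence_matrix(pathway, [org("q", {"g1": ["1.1.1.1"]}), org("r", {})])
        assert m.presence.loc["r"].sum() == 0

    def test_two_sources_both_recorded_in_cell(self):
        pathway = kgml_for(["1.1.1.1"])
        a = org("q", {"g1": ["1.1.1.1"]}, source="A")
        b = org("q", {"g1": ["1.1.1.1"]}, source="B")
        from pathwaycurator.annotations_io import merge_sources

        m = build_presence_matrix(pathway, [merge_sources([a, b]), org("r", {})])
        support = m.supporting_genes("q", normalize_ec("1.1.1.1"))
        assert support == [("g1", "A"), ("g1", "B")]

    def test_empty_pathway_ec_set_is_an_error(self):
        empty = parse_kgml_string('<pathway name="path:ec00002" number="00002"></pathway>')
        with pytest.raises(ValueError, match="empty EC set"):
            build_presence_matrix(empty, [org("q", {})])

    def test_wildcard_matches_only_identical_wildcard_by_default(self):
        pathway = kgml_for(["4.2.1.-"])
        concrete = org("q", {"g1": ["4.2.1.109"]})
        wild = org("r", {"h1": ["4.2.1.-"]})
        m = build_presence_matrix(pathway, [concrete, wild])
        assert m.presence.loc["q"].tolist() == [0]
        assert m.presence.loc["r"].tolist() == [1]
        m2 = build_presence_matrix(pathway, [concrete, wild], prefix_wildcards=True)
        assert m2.presence.loc["q"].tolist() == [1]


class TestHammingDistance:
    def test_enumeration_oracle_and_examples(self):
        m = random_matrix(random.Random(0), n_orgs=2, n_ecs=3)
        m.presence.loc["org0"] = [1, 1, 0]
        m.presence.loc["org1"] = [1, 0, 1]
        assert hamming_distance(m, "org0", "org1") == 2
        assert hamming_distance(m, "org0", "org0") == 0

    def test_zero_row_vs_k_ones(self):
        m = random_matrix(random.Random(1), n_orgs=2, n_ecs=5)
        m.presence.loc["org0"] = 0
        m.presence.loc["org1"] = [1, 1, 1, 0, 1]
        assert hamming_distance(m, "org0", "org1") == 4

    def test_unknown_organism_rejected(self):
        m = random_matrix(random.Random(2))
        with pytest.raises(KeyError):
            hamming_distance(m, "org0", "nope")

    def test_matches_symmetric_difference_oracle_randomised(self):
        rng = random.Random(3)
        for _ in range(50):
            m = random_matrix(rng)
            for a, b in itertools.combinations(m.organisms, 2):
                want = hamming_oracle(m.presence.loc[a].to_dict(),
                                      m.presence.loc[b].to_dict())
                assert hamming_distance(m, a, b) == want


class TestDistanceMatrix:
    def test_structure_symmetry_zero_diagonal(self):
        m = random_matrix(random.Random(4), n_orgs=3)
        d = distance_matrix(m)
        assert d.shape == (3, 3)
        assert (d.values == d.values.T).all()
        assert all(d.values[i, i] == 0 for i in range(3))

    def test_duplicate_rows_give_zero_off_diagonal(self):
        m = random_matrix(random.Random(5), n_orgs=2, n_ecs=4)
        m.presence.loc["org1"] = m.presence.loc["org0"]
        assert distance_matrix(m).loc["org0", "org1"] == 0

    def test_triangle_inequality_on_random_fixture(self):
        rng = random.Random(6)
        m = random_matrix(rng, n_orgs=5, n_ecs=8)
        d = distance_matrix(m)
        for a, b, c in itertools.permutations(m.organisms, 3):
            assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c]


def _matrix_from_annotations(ec_strs, query_map, ref_maps):
    pathway = kgml_for(ec_strs)
    anns = [org("query", query_map)] + [
        org(f"ref{i + 1}", mapping) for i, mapping in enumerate(ref_maps)
    ]
    return build_presence_matrix(pathway, anns), anns


class TestHoleCalling:
    def test_ec_absent_in_query_present_in_all_refs_is_called(self):
        m, _ = _matrix_from_annotations(
            ["1.1.1.1", "2.2.2.2"],
            {"q1": ["1.1.1.1"]},
            [{"r1": ["1.1.1.1"], "r2": ["2.2.2.2"]} for _ in range(5)],
        )
        calls = call_pathway_holes(m)
        assert [str(c.ec) for c in calls] == ["2.2.2.2"]
        assert calls[0].reference_support == 1.0

    def test_ec_absent_everywhere_not_called(self):
        m, _ = _matrix_from_annotations(
            ["1.1.1.1", "2.2.2.2"], {"q1": ["1.1.1.1"]},
            [{"r1": ["1.1.1.1"]}] * 3,
        )
        assert call_pathway_holes(m) == []

    def test_below_min_ref_fraction_not_called(self):
        ref_maps = [{"r": ["2.2.2.2"]}, {"r": ["2.2.2.2"]}] + [{"r": []}] * 3
        m, _ = _matrix_from_annotations(["1.1.1.1", "2.2.2.2"], {"q1": ["1.1.1.1"]},
                                        ref_maps)
        assert call_pathway_holes(m, min_ref_fraction=0.5) == []
        assert len(call_pathway_holes(m, min_ref_fraction=0.4)) == 1

    def test_candidates_prefer_rbh_then_rank_by_bit_score(self):
        m, _ = _matrix_from_annotations(
            ["2.2.2.2"], {}, [{"rg1": ["2.2.2.2"]}],
        )
        fwd = HitRecord("qcand", "rg1", 80.0, 100, 1e-40, 200.0)
        rev = HitRecord("rg1", "qcand", 80.0, 100, 1e-40, 200.0)
        rbh = {"ref1": [RBHPair("qcand", "rg1", fwd, rev)]}
        topk = {"ref1": {"rg1": [
            HitRecord("rg1", "qother", 60.0, 100, 1e-20, 300.0),
        ]}}
        calls = call_pathway_holes(m, rbh=rbh, top_k=topk)
        cands = calls[0].candidate_genes
        assert [c.gene_id for c in cands] == ["qcand", "qother"]
        assert cands[0].evidence == "RBH" and cands[1].evidence == "top-k"


class TestMisannotationCalling:
    def test_dual_function_gene_flagged_with_alternative(self):
        m, anns = _matrix_from_annotations(
            ["3.2.2.16", "3.2.2.9"],
            {"q_gene": ["3.2.2.16", "3.2.2.9"]},
            [{"r": ["3.2.2.9"]}] * 4,
        )
        calls = call_misannotations(m, annotations=anns[0], literature=LiteratureIndex())
        assert len(calls) == 1
        call = calls[0]
        assert str(call.ec) == "3.2.2.16"
        assert call.genes == ["q_gene"]
        assert [str(e) for e in call.alternative_ecs] == ["3.2.2.9"]
        assert call.literature_support == 0

    def test_shared_presence_not_called(self):
        m, anns = _matrix_from_annotations(
            ["3.2.2.16"], {"q_gene": ["3.2.2.16"]},
            [{"r": ["3.2.2.16"]}, {"r": []}],
        )
        assert call_misannotations(m, annotations=anns[0]) == []

    def test_positive_query_literature_vetoes_call(self):
        m, anns = _matrix_from_annotations(
            ["3.2.2.16"], {"q_gene": ["3.2.2.16"]}, [{"r": []}] * 3,
        )
        lit = LiteratureIndex()
        lit.add(normalize_ec("3.2.2.16"), "query",
                Publication(citation_text="Direct assay in the query organism",
                            pubmed_id="555"))
        assert call_misannotations(m, annotations=anns[0], literature=lit) == []
        # without the publication the call fires
        assert len(call_misannotations(m, annotations=anns[0],
                                       literature=LiteratureIndex())) == 1


def test_hole_and_misannotation_ecs_are_disjoint():
    rng = random.Random(8)
    for _ in range(20):
        ec_strs = [f"1.1.1.{i + 1}" for i in range(6)]
        qmap = {f"q{i}": [rng.choice(ec_strs)] for i in range(4)}
        refs = [{f"r{i}": [rng.choice(ec_strs)] for i in range(4)} for _ in range(3)]
        m, anns = _matrix_from_annotations(ec_strs, qmap, refs)
        holes = {str(c.ec) for c in call_pathway_holes(m, min_ref_fraction=0.01)}
        mis = {str(c.ec) for c in call_misannotations(m, annotations=anns[0])}
        assert holes.isdisjoint(mis)
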