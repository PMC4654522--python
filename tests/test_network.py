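import itertools

import networkx as nx
import numpy as np
import pytest

from itraqpipe.annotation import KoAssignment
from itraqpipe.network_integration import (
    NetworkConfig,
    NetworkError,
    PathwayDB,
    build_network,
    degree_profile,
    link_pathways,
    read_pathway_db,
    select_candidates,
    tissue_subnetwork,
    write_pathway_db,
)
from itraqpipe.quant_io import filter_by_fdr
from itraqpipe.ratio_quant import compute_sample_ratios
from itraqpipe.synthetic_data import generate_ko_assignment, generate_pathway_db, generate_study

from test_ratio_quant import matrix_from_values


def ko_map(**kwargs):
    return KoAssignment(
        assignments={gm: (ko, 1e-10, 200.0) for gm, ko in kwargs.items()}
    )


def chain_db(*kos, compounds=None):
    edges = frozenset(frozenset(p) for p in zip(kos, kos[1:]))
    return PathwayDB(
        ko_pathway={k: frozenset({"path:ko00001"}) for k in kos},
        pathway_desc={"path:ko00001": "toy"},
        ko_edges=edges,
        ko_compounds={k: frozenset(v) for k, v in (compounds or {}).items()},
    )


class TestSelectCandidates:
    def test_sixfold_vs_control_qualifies(self, design):
        values = np.ones((2, 6))
        values[0, 5] = 6.0  # N6 at 6x control
        m = matrix_from_values(design, values, ["A", "B"])
        sel = select_candidates(m)
        assert "A" in sel.candidates and "B" not in sel.candidates
        assert "N6" in sel.candidates["A"].contrasts

    def test_flat_profile_never_qualifies(self, design):
        m = matrix_from_values(design, np.full((5, 6), 3.0))
        assert len(select_candidates(m).candidates) == 0

    def test_monotone_in_fold_min(self, design, planted_matrix):
        sizes = [
            len(select_candidates(planted_matrix, NetworkConfig(fold_min=f)).candidates)
            for f in (2.0, 3.0, 5.0, 8.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_fold_min_must_exceed_one(self):
        with pytest.raises(NetworkError):
            NetworkConfig(fold_min=1.0)

    def test_planted_candidates_and_tissues_recovered(self, design, planted_study, planted_matrix):
        _, truth = planted_study
        sel = select_candidates(planted_matrix)
        assert sel.accessions() == truth.candidates
        for acc, cand in sel.candidates.items():
            assert cand.tissues == truth.candidate_tissues[acc]


class TestBuildNetwork:
    def test_toy_network_matches_hand_enumeration(self):
        # protein on K1; K1-K2 edge; K2 has compound C1
        db = chain_db("K00001", "K00002", compounds={"K00002": {"C00001"}})
        net = build_network({"P1"}, ko_map(p1="K00001"), db, gene_models={"P1": "p1"})
        g = net.graph
        assert set(g.nodes) == {"P1", "ko:K00002", "cpd:C00001"}
        assert g.nodes["P1"]["type"] == "study_protein"
        assert g.edges["P1", "ko:K00002"]["type"] == "ko_ko_interaction"
        assert g.edges["ko:K00002", "cpd:C00001"]["type"] == "ko_compound"

    def test_unmapped_candidates_listed(self):
        db = chain_db("K00001")
        net = build_network({"P1", "P2"}, ko_map(p1="K00001"), db,
                            gene_models={"P1": "p1", "P2": "p2"})
        assert net.unmapped == ("P2",)
        assert net.study_proteins() == ["P1"]

    def test_shared_ko_proteins_get_relation_edge(self):
        db = chain_db("K00001", "K00002")
        net = build_network(
            {"P1", "P2"}, ko_map(p1="K00001", p2="K00001"), db,
            gene_models={"P1": "p1", "P2": "p2"},
        )
        assert net.graph.edges["P1", "P2"]["type"] == "protein_ko_relation"

    def test_serialization_stable_under_shuffled_input(self, tmp_path, toy_db):
        gms = {f"P{i}": f"g{i}" for i in range(10)}
        ko = generate_ko_assignment(list(gms.values()), toy_db, seed=3)
        n1 = build_network(list(gms), ko, toy_db, gene_models=gms)
        n2 = build_network(list(reversed(list(gms))), ko, toy_db, gene_models=gms)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        n1.write_edge_list(p1)
        n2.write_edge_list(p2)
        assert p1.read_bytes() == p2.read_bytes()
        g1, g2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        n1.write_graphml(g1)
        n2.write_graphml(g2)
        assert g1.read_bytes() == g2.read_bytes()


class TestLinkPathways:
    def test_two_proteins_sharing_a_pathway_count_two(self):
        db = chain_db("K00001", "K00002")
        net = build_network(
            {"P1", "P2"}, ko_map(p1="K00001", p2="K00002"), db,
            gene_models={"P1": "p1", "P2": "p2"},
        )
        ranked = link_pathways(net)
        assert ranked == [("path:ko00001", "toy", 2)]

    def test_empty_ko_set_is_empty_ranking(self, toy_db):
        assert link_pathways([], toy_db) == []

    def test_ranking_matches_exhaustive_tally(self, toy_db):
        gms = {f"P{i}": f"g{i}" for i in range(30)}
        ko = generate_ko_assignment(list(gms.values()), toy_db, seed=8)
        net = build_network(list(gms), ko, toy_db, gene_models=gms)
        ranked = link_pathways(net)
        brute = {}
        for acc, gm in gms.items():
            for pw in toy_db.ko_pathway.get(ko.ko(gm), ()):
                brute.setdefault(pw, set()).add(acc)
        assert {pw: n for pw, _, n in ranked} == {pw: len(m) for pw, m in brute.items()}
        counts = [n for _, _, n in ranked]
        assert counts == sorted(counts, reverse=True)


class TestDegreeProfile:
    def test_path_graph(self):
        db = chain_db("K00001", "K00002", "K00003")
        net = build_network({"P1"}, ko_map(p1="K00001"), db, gene_models={"P1": "p1"})
        first, second = degree_profile(net, "P1")
        assert first == {"ko:K00002"}
        assert second == {"ko:K00003"}

    def test_star_hub(self):
        spokes = [f"K{i:05d}" for i in range(2, 12)]
        db = PathwayDB(
            ko_pathway={"K00001": frozenset({"path:ko00001"})},
            ko_edges=frozenset(frozenset(("K00001", s)) for s in spokes),
        )
        net = build_network({"P1"}, ko_map(p1="K00001"), db, gene_models={"P1": "p1"})
        first, second = degree_profile(net, "P1")
        assert len(first) == 10 and second == frozenset()

    def test_unknown_protein_rejected(self, toy_db):
        net = build_network([], ko_map(), toy_db)
        with pytest.raises(KeyError):
            degree_profile(net, "nope")

    def test_matches_bfs_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            n = int(rng.integers(3, 31))
            kos = [f"K{i + 1:05d}" for i in range(n)]
            edges = set()
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.15:
                    edges.add(frozenset((kos[i], kos[j])))
            db = PathwayDB(
                ko_pathway={k: frozenset({"path:ko00001"}) for k in kos},
                ko_edges=frozenset(edges),
            )
            focal = kos[int(rng.integers(0, n))]
            net = build_network({"P"}, ko_map(p=focal), db, gene_models={"P": "p"})
            first, second = degree_profile(net, "P")
            # independent oracle: breadth-first layers on the KO graph
            g = nx.Graph([tuple(e) for e in edges])
            g.add_nodes_from(kos)
            layers = nx.single_source_shortest_path_length(g, focal, cutoff=2)
            exp_first = {k for k, d in layers.items() if d == 1}
            exp_second = {k for k, d in layers.items() if d == 2}
            label = lambda k: "P" if k == focal else f"ko:{k}"
            assert first == {label(k) for k in exp_first}
            assert second == {label(k) for k in exp_second}
            assert not (first & second) and "P" not in first | second


class TestTissueSubnetwork:
    def test_endosperm_only_study_leaves_pericarp_empty(self, design, toy_db):
        records, truth = generate_study(
            design, n_proteins=60, candidate_counts={"endosperm": 10},
            noise_sd=0.05, seed=2,
        )
        m = compute_sample_ratios(filter_by_fdr(records), design)
        sel = select_candidates(m)
        ko = generate_ko_assignment(
            [truth.gene_models[a] for a in sel.candidates], toy_db, seed=1
        )
        net = build_network(sel, ko, toy_db)
        assert tissue_subnetwork(net, "pericarp").study_proteins() == []
        assert len(tissue_subnetwork(net, "endosperm").study_proteins()) == 10

    def test_planted_tissue_counts_match_study_shape(self, design, toy_db):
        records, truth = generate_study(
            design, n_proteins=150,
            candidate_counts={"pericarp": 9, "endosperm": 77},
            noise_sd=0.05, seed=4,
        )
        m = compute_sample_ratios(filter_by_fdr(records), design)
        sel = select_candidates(m)
        ko = generate_ko_assignment(
            [truth.gene_models[a] for a in sel.candidates], toy_db, seed=1
        )
        net = build_network(sel, ko, toy_db)
        assert len(tissue_subnetwork(net, "pericarp").study_proteins()) == 9
        assert len(tissue_subnetwork(net, "endosperm").study_proteins()) == 77

    def test_idempotent(self, design, toy_db):
        records, truth = generate_study(
            design, n_proteins=40, candidate_counts={"pericarp": 5},
            noise_sd=0.05, seed=6,
        )
        m = compute_sample_ratios(filter_by_fdr(records), design)
        sel = select_candidates(m)
        ko = generate_ko_assignment(
            [truth.gene_models[a] for a in sel.candidates], toy_db, seed=1
        )
        net = build_network(sel, ko, toy_db)
        once = tissue_subnetwork(net, "pericarp")
        twice = tissue_subnetwork(once, "pericarp")
        assert set(once.graph.nodes) == set(twice.graph.nodes)
        assert set(once.graph.edges) == set(twice.graph.edges)

    def test_unknown_tissue_rejected(self, toy_db):
        net = build_network([], ko_map(), toy_db)
        with pytest.raises(NetworkError):
            tissue_subnetwork(net, "embryo")


def test_pathway_db_round_trip(tmp_path, toy_db):
    paths = write_pathway_db(toy_db, tmp_path)
    back = read_pathway_db(
        paths["ko_pathway"], paths["ko_edges"], paths["ko_compound"],
        paths["pathway_desc"],
    )
    assert back.ko_pathway == toy_db.ko_pathway
    assert back.ko_edges == toy_db.ko_edges
    assert back.ko_compounds == toy_db.ko_compounds
    assert back.pathway_desc == toy_db.pathway_desc


def test_pathway_db_rejects_self_loop(tmp_path):
    p = tmp_path / "kp.tsv"
    p.write_text("ko:K00001\tpath:ko00001\n")
    e = tmp_path / "edges.tsv"
    e.write_text("ko:K00001\tko:K00001\n")
    with pytest.raises(NetworkError, match="self-loop"):
        read_pathway_db(p, e)
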