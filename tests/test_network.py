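"""QS profiles, communication networks and phyletic tables."""

from __future__ import annotations

from collections import Counter

import pytest

from ai2net.census import SynthaseCall
from ai2net.genomes import SpeciesGenome, parse_taxonomy
from ai2net.network import (
    AI2_NODE,
    ProfileIntegrityError,
    bipartite_edge_multiset,
    build_bipartite_network,
    build_module_network,
    build_producer_receiver_projection,
    build_profiles,
    network_summary,
    phyletic_distribution,
    read_graphml,
    write_graphml,
)
from ai2net.receptors import ReceptorCall, ResidueScreenResult


def _genome(genome_id, phylum="Firmicutes"):
    return SpeciesGenome(
        genome_id=genome_id,
        taxonomy=parse_taxonomy(
            f"d__Bacteria;p__{phylum};c__;o__;f__Fam;g__Gen;s__Sp"),
        completeness=95, contamination=1)


def _luxs_call(genome_id, n=1):
    return SynthaseCall(genome_id, "AI-2",
                        tuple(f"{genome_id}_l{i}" for i in range(n)), "gene_name_match")


def _receptor(genome_id, locus, rtype="dCache_1", module="MCP"):
    screen = (ResidueScreenResult(locus, "PctA", (), True)
              if rtype in {"dCache_1", "GAPES1"} else None)
    evidence = {"operon_loci": ("a", "c", "d", "b")} if rtype == "LsrB" else {}
    return ReceptorCall(genome_id=genome_id, locus_tag=locus,
                        receptor_type=rtype, evidence=evidence,
                        screen=screen, functional_module=module)


class TestProfiles:
    def test_role_assignment(self):
        genomes = [_genome("p"), _genome("r"), _genome("b"), _genome("n")]
        profiles = build_profiles(
            [_luxs_call("p"), _luxs_call("b")],
            [_receptor("r", "r_1"), _receptor("b", "b_1")],
            genomes)
        roles = {p.genome_id: p.role for p in profiles}
        assert roles == {"p": "producer_only", "r": "receiver_only",
                         "b": "both", "n": "none"}

    def test_unknown_genome_in_calls_is_an_integrity_error(self):
        with pytest.raises(ProfileIntegrityError):
            build_profiles([], [_receptor("ghost", "g_1")], [_genome("a")])

    def test_roles_match_manifest(self, pipeline_result, manifest):
        assert {p.genome_id: p.role for p in pipeline_result.profiles} \
            == dict(manifest.roles)

    def test_role_partition_conserves_species(self, pipeline_result):
        counts = Counter(p.role for p in pipeline_result.profiles)
        assert sum(counts.values()) == len(pipeline_result.profiles)


class TestBipartiteNetwork:
    def test_producer_and_receiver_pair(self):
        genomes = [_genome("p"), _genome("r")]
        profiles = build_profiles(
            [_luxs_call("p")], [_receptor("r", "r_1")], genomes)
        graph = build_bipartite_network(profiles)
        assert graph.number_of_nodes() == 3  # two species + signal node
        edges = bipartite_edge_multiset(graph)
        assert edges == Counter({"produce": 1, "sense:MCP": 1})

    def test_both_role_species_has_produce_and_sense_edges(self):
        profiles = build_profiles(
            [_luxs_call("b")], [_receptor("b", "b_1", module="CSP")],
            [_genome("b")])
        graph = build_bipartite_network(profiles)
        assert bipartite_edge_multiset(graph) == Counter(
            {"produce": 1, "sense:CSP": 1})

    def test_none_role_nodes_are_excluded(self):
        profiles = build_profiles([], [], [_genome("n")])
        graph = build_bipartite_network(profiles)
        assert set(graph.nodes) == {AI2_NODE}

    def test_edge_count_identity_on_community(self, pipeline_result):
        profiles = pipeline_result.profiles
        graph = build_bipartite_network(profiles)
        edges = bipartite_edge_multiset(graph)
        n_producers = sum(
            1 for p in profiles if p.role in {"both", "producer_only"})
        n_sense = sum(
            len(set(p.modules)) for p in profiles
            if p.role in {"both", "receiver_only"})
        assert edges["produce"] == n_producers
        assert sum(v for k, v in edges.items() if k.startswith("sense:")) \
            == n_sense


class TestModuleNetwork:
    def test_two_module_species_gets_two_sense_edge_types(self):
        profiles = build_profiles(
            [_luxs_call("b")],
            [_receptor("b", "b_1", module="MCP"),
             _receptor("b", "b_2", rtype="dCache_1", module="HK")],
            [_genome("b")])
        graph = build_module_network(profiles)
        assert bipartite_edge_multiset(graph) == Counter(
            {"produce": 1, "sense:MCP": 1, "sense:HK": 1})

    def test_restricted_to_both_role_species(self, pipeline_result, manifest):
        graph = build_module_network(pipeline_result.profiles)
        species_nodes = {n for n in graph.nodes if n != AI2_NODE}
        expected = {g for g, role in manifest.roles.items() if role == "both"}
        assert species_nodes == expected

    def test_edge_type_multiset_matches_manifest(self, pipeline_result,
                                                 manifest):
        graph = build_module_network(pipeline_result.profiles)
        edges = bipartite_edge_multiset(graph)
        both = {g for g, role in manifest.roles.items() if role == "both"}
        expected: Counter = Counter({"produce": len(both)})
        for genome_id in both:
            modules = {
                m for (g, _l), m in manifest.modules.items() if g == genome_id}
            for module in modules:
                expected[f"sense:{module}"] += 1
        assert edges == expected


class TestPhyleticDistribution:
    def test_dual_copy_counts_two_genes_one_species(self):
        profiles = build_profiles([_luxs_call("a", n=2)], [], [_genome("a")])
        table = phyletic_distribution(profiles)
        row = table[(table["rank"] == "phylum") & (table["marker"] == "LuxS")]
        assert row["gene_count"].item() == 2
        assert row["species_count"].item() == 1

    def test_empty_profiles_give_empty_table(self):
        assert phyletic_distribution([]).empty

    def test_community_table_matches_manifest(self, pipeline_result, manifest,
                                              genomes):
        table = phyletic_distribution(pipeline_result.profiles)
        phylum_of = {g.genome_id: g.taxonomy.phylum for g in genomes}
        sub = table[(table["rank"] == "phylum") & (table["marker"] == "dCache_1")]
        got = dict(zip(sub["taxon"], sub["species_count"]))
        expected: Counter = Counter()
        for g, _l, t in manifest.receptor_calls:
            if t == "dCache_1":
                expected[phylum_of[g]] += 1
        assert got == {k: v for k, v in expected.items()}


class TestSummary:
    def test_partition_identity_on_any_profiles(self, pipeline_result):
        summary = network_summary(pipeline_result.profiles)
        assert sum(summary["role_counts"].values()) == summary["n_species"]
        assert all(summary["consistency"].values())

    def test_printed_count_fixture_satisfies_identities(self):
        # published totals: 233 dual-role species, 66 receiver-only,
        # 1806 producer-only genomes; 299 receptor species; 2039 luxS species
        fixture = {"both": 233, "receiver_only": 66, "producer_only": 1806}
        assert fixture["both"] + fixture["receiver_only"] == 299
        assert fixture["both"] + fixture["producer_only"] == 2039
        # the summary's identity checks encode exactly these relations
        profiles = []
        genomes = []
        for i in range(8):
            genomes.append(_genome(f"b{i}"))
        profiles = build_profiles(
            [_luxs_call(f"b{i}") for i in range(5)],
            [_receptor(f"b{i}", f"b{i}_1") for i in range(3, 8)],
            genomes)
        summary = network_summary(profiles)
        rc = summary["role_counts"]
        assert rc["both"] + rc["receiver_only"] == summary["n_receptor_species"]
        assert rc["both"] + rc["producer_only"] == summary["n_luxs_species"]

    def test_summary_equals_independent_recount(self, pipeline_result):
        profiles = pipeline_result.profiles
        summary = network_summary(profiles)
        recount = Counter()
        for p in profiles:
            produces, senses = p.luxS_copies > 0, bool(p.receptor_calls)
            recount[
                "both" if produces and senses else
                "producer_only" if produces else
                "receiver_only" if senses else "none"] += 1
        assert summary["role_counts"] == {
            r: recount.get(r, 0)
            for r in ("producer_only", "receiver_only", "both", "none")}


def test_graphml_roundtrip_preserves_attributes(tmp_path, pipeline_result):
    graph = build_bipartite_network(pipeline_result.profiles)
    path = tmp_path / "net.graphml"
    write_graphml(graph, path)
    loaded = read_graphml(path)
    assert set(loaded.nodes) == set(graph.nodes)
    original_edges = sorted(
        (tuple(sorted((u, v))), d.get("edge_type"))
        for u, v, d in graph.edges(data=True))
    loaded_edges = sorted(
        (tuple(sorted((u, v))), d.get("edge_type"))
        for u, v, d in loaded.edges(data=True))
    assert original_edges == loaded_edges
    for node, data in graph.nodes(data=True):
        assert loaded.nodes[node].get("role") == data.get("role")


def test_producer_receiver_projection_edges(pipeline_result, manifest):
    graph = build_producer_receiver_projection(pipeline_result.profiles)
    producers = {g for g, r in manifest.roles.items()
                 if r in {"both", "producer_only"}}
    receivers = {g for g, r in manifest.roles.items()
                 if r in {"both", "receiver_only"}}
    expected = sum(
        1 for p in producers for r in receivers if p != r)
    assert graph.number_of_edges() == expected
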