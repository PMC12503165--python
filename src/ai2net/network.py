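"""Per-species QS profiles and the AI-2 communication network.

Each genome gets a :class:`SpeciesQSProfile` combining its AI-2 synthase
(luxS) copy count and receptor calls, and a network role: ``producer_only``,
``receiver_only``, ``both`` or ``none``.  Two graph views are built with
networkx: an undirected bipartite network in which every species with a
role connects to a single AI-2 signal node through typed ``produce`` /
``sense:<module>`` edges, and a module-resolved network restricted to
``both``-role species.  A directed producer-to-receiver projection is also
exportable.  Graphs serialise to GraphML and TSV edge lists.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .census import SynthaseCall
from .genomes import SpeciesGenome, Taxonomy, format_taxonomy
from .receptors import ReceptorCall

AI2_NODE = "AI-2"

ROLES = ("producer_only", "receiver_only", "both", "none")


class ProfileIntegrityError(ValueError):
    """A call refers to a genome absent from the input collection."""


@dataclass
class SpeciesQSProfile:
    """Per-species AI-2 synthase/receptor inventory and network role."""

    genome_id: str
    taxonomy: Taxonomy
    luxS_copies: int
    receptor_calls: tuple[ReceptorCall, ...]
    role: str = field(init=False)

    def __post_init__(self) -> None:
        produces = self.luxS_copies > 0
        senses = bool(self.receptor_calls)
        self.role = (
            "both" if produces and senses
            else "producer_only" if produces
            else "receiver_only" if senses
            else "none"
        )

    @property
    def modules(self) -> Counter:
        """Multiset of functional-module names over the receptor calls."""
        return Counter(
            c.functional_module or "uncharacterized" for c in self.receptor_calls)

    @property
    def receptor_types(self) -> Counter:
        return Counter(c.receptor_type for c in self.receptor_calls)


def build_profiles(
    census_calls: Iterable[SynthaseCall],
    receptor_calls: Iterable[ReceptorCall],
    genomes: Iterable[SpeciesGenome],
) -> list[SpeciesQSProfile]:
    """One profile per genome from upstream census and receptor calls."""
    genomes = list(genomes)
    known = {g.genome_id for g in genomes}

    luxs: dict[str, int] = {}
    for call in census_calls:
        if call.signal == "AI-2":
            if call.genome_id not in known:
                raise ProfileIntegrityError(
                    f"synthase call for unknown genome {call.genome_id}")
            luxs[call.genome_id] = luxs.get(call.genome_id, 0) + len(call.locus_tags)

    receptors: dict[str, list[ReceptorCall]] = {}
    for call in receptor_calls:
        if call.genome_id not in known:
            raise ProfileIntegrityError(
                f"receptor call for unknown genome {call.genome_id}")
        receptors.setdefault(call.genome_id, []).append(call)

    return [
        SpeciesQSProfile(
            genome_id=g.genome_id,
            taxonomy=g.taxonomy,
            luxS_copies=luxs.get(g.genome_id, 0),
            receptor_calls=tuple(sorted(
                receptors.get(g.genome_id, []),
                key=lambda c: (c.receptor_type, c.locus_tag))),
        )
        for g in sorted(genomes, key=lambda g: g.genome_id)
    ]


def _node_attributes(profile: SpeciesQSProfile) -> dict[str, object]:
    return {
        "taxonomy": format_taxonomy(profile.taxonomy),
        "phylum": profile.taxonomy.phylum,
        "role": profile.role,
        "luxS_copies": profile.luxS_copies,
        "modules": ",".join(
            f"{m}:{n}" for m, n in sorted(profile.modules.items())),
        "n_qs_genes": profile.luxS_copies + len(profile.receptor_calls),
    }


def build_bipartite_network(profiles: Iterable[SpeciesQSProfile]) -> nx.Graph:
    """Species-to-signal bipartite network.

    Nodes: every species with a role other than ``none`` plus one AI-2
    signal node.  Edges: one ``produce`` edge per producer and one
    ``sense:<module>`` edge per distinct (species, module) pair.
    """
    graph = nx.Graph(kind="bipartite")
    graph.add_node(AI2_NODE, node_type="signal")
    for profile in profiles:
        if profile.role == "none":
            continue
        graph.add_node(
            profile.genome_id, node_type="species", **_node_attributes(profile))
        if profile.luxS_copies > 0:
            graph.add_edge(
                profile.genome_id, AI2_NODE, edge_type="produce",
                key="produce")
        for module in sorted(profile.modules):
            # parallel typed edges collapse onto attribute lists in a simple
            # Graph; use a MultiGraph-style key encoding instead
            edge_id = f"sense:{module}"
            if graph.has_edge(profile.genome_id, AI2_NODE):
                existing = graph.edges[profile.genome_id, AI2_NODE]
                existing["edge_type"] = ",".join(
                    sorted(set(existing["edge_type"].split(",")) | {edge_id}))
            else:
                graph.add_edge(
                    profile.genome_id, AI2_NODE, edge_type=edge_id)
    return graph


def bipartite_edge_multiset(graph: nx.Graph) -> Counter:
    """Typed-edge multiset of the bipartite network (produce / sense:<m>)."""
    counter: Counter = Counter()
    for _, _, data in graph.edges(data=True):
        for part in data["edge_type"].split(","):
            counter[part] += 1
    return counter


def build_module_network(profiles: Iterable[SpeciesQSProfile]) -> nx.Graph:
    """Module-resolved network over ``both``-role species only.

    Node size attribute ``n_qs_genes`` counts luxS plus receptor genes;
    every species keeps one ``produce`` edge and one ``sense:<module>``
    edge per distinct functional module it carries.
    """
    graph = nx.Graph(kind="module")
    graph.add_node(AI2_NODE, node_type="signal")
    for profile in profiles:
        if profile.role != "both":
            continue
        graph.add_node(
            profile.genome_id, node_type="species", **_node_attributes(profile))
        edge_types = {"produce"} | {f"sense:{m}" for m in profile.modules}
        graph.add_edge(
            profile.genome_id, AI2_NODE,
            edge_type=",".join(sorted(edge_types)))
    return graph


def build_producer_receiver_projection(
    profiles: Iterable[SpeciesQSProfile],
) -> nx.DiGraph:
    """Directed producer-to-receiver projection (derived view)."""
    profiles = list(profiles)
    producers = [p for p in profiles if p.role in {"both", "producer_only"}]
    receivers = [p for p in profiles if p.role in {"both", "receiver_only"}]
    graph = nx.DiGraph(kind="producer_receiver")
    for p in producers + receivers:
        graph.add_node(p.genome_id, **_node_attributes(p))
    for producer in producers:
        for receiver in receivers:
            if producer.genome_id == receiver.genome_id:
                continue
            graph.add_edge(producer.genome_id, receiver.genome_id)
    return graph


def phyletic_distribution(
    profiles: Iterable[SpeciesQSProfile],
    ranks: tuple[str, ...] = ("phylum", "family", "genus"),
) -> pd.DataFrame:
    """Per-taxon gene and species counts of luxS and each receptor type.

    Nested (sunburst-ready) table: one row per (rank, taxon, marker) with
    ``gene_count`` (multiplicity-aware) and ``species_count``.
    """
    rows: dict[tuple[str, str, str], dict[str, int]] = {}
    for profile in profiles:
        markers: Counter = Counter()
        if profile.luxS_copies:
            markers["LuxS"] = profile.luxS_copies
        markers.update(profile.receptor_types)
        for rank in ranks:
            taxon = getattr(profile.taxonomy, "class_" if rank == "class" else rank)
            for marker, n_genes in markers.items():
                cell = rows.setdefault(
                    (rank, taxon, marker), {"gene_count": 0, "species_count": 0})
                cell["gene_count"] += n_genes
                cell["species_count"] += 1
    if not rows:
        return pd.DataFrame(
            columns=["rank", "taxon", "marker", "gene_count", "species_count"])
    frame = pd.DataFrame(
        [
            {"rank": r, "taxon": t, "marker": m, **cell}
            for (r, t, m), cell in sorted(rows.items())
        ]
    )
    return frame


def network_summary(
    profiles: Iterable[SpeciesQSProfile],
) -> dict[str, object]:
    """Role counts, per-phylum composition, module usage and identity checks.

    The consistency report verifies the partition identities
    ``both + receiver_only == species with receptors`` and
    ``both + producer_only == species with luxS``.
    """
    profiles = list(profiles)
    role_counts = Counter(p.role for p in profiles)
    n_receptor_species = sum(1 for p in profiles if p.receptor_calls)
    n_luxs_species = sum(1 for p in profiles if p.luxS_copies > 0)

    per_phylum: dict[str, Counter] = {}
    for p in profiles:
        per_phylum.setdefault(p.taxonomy.phylum, Counter())[p.role] += 1
    module_usage: Counter = Counter()
    for p in profiles:
        module_usage.update(p.modules)

    checks = {
        "roles_partition": sum(role_counts.values()) == len(profiles),
        "both_plus_receiver_equals_receptor_species":
            role_counts["both"] + role_counts["receiver_only"]
            == n_receptor_species,
        "both_plus_producer_equals_luxs_species":
            role_counts["both"] + role_counts["producer_only"]
            == n_luxs_species,
    }
    return {
        "n_species": len(profiles),
        "role_counts": {role: role_counts.get(role, 0) for role in ROLES},
        "n_receptor_species": n_receptor_species,
        "n_luxs_species": n_luxs_species,
        "per_phylum_roles": {
            phylum: dict(counts) for phylum, counts in sorted(per_phylum.items())
        },
        "module_usage": dict(sorted(module_usage.items())),
        "consistency": checks,
    }


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export (attributes are scalars/strings by construction)."""
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list with the typed-edge attribute."""
    rows = [
        {"source": u, "target": v, "edge_type": data.get("edge_type", "")}
        for u, v, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "edge_type"]).to_csv(
        path, sep="\t", index=False)


def write_summary(summary: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True))


def profiles_to_frame(profiles: Iterable[SpeciesQSProfile]) -> pd.DataFrame:
    """Tidy per-species profile table."""
    return pd.DataFrame(
        [
            {
                "genome_id": p.genome_id,
                "phylum": p.taxonomy.phylum,
                "family": p.taxonomy.family,
                "genus": p.taxonomy.genus,
                "luxS_copies": p.luxS_copies,
                "n_receptors": len(p.receptor_calls),
                "receptor_types": ",".join(
                    f"{t}:{n}" for t, n in sorted(p.receptor_types.items())),
                "modules": ",".join(
                    f"{m}:{n}" for m, n in sorted(p.modules.items())),
                "role": p.role,
            }
            for p in profiles
        ],
        columns=["genome_id", "phylum", "family", "genus", "luxS_copies",
                 "n_receptors", "receptor_types", "modules", "role"],
    )
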