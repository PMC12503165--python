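"""End-to-end orchestration: genomes in, calls, profiles and networks out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import census as census_mod
from . import function_typing, network, receptors
from .census import SynthaseCall
from .genomes import QualityThresholds, SpeciesGenome, quality_filter
from .network import SpeciesQSProfile
from .profiles import DCACHE_ACC, GAPES1_ACC, default_registry, sensory_registry
from .receptors import (
    DomainHit,
    OperonParams,
    ReceptorCall,
    TopologyParams,
)
from .references import default_refsets


@dataclass
class PipelineResult:
    """All per-stage outputs of one pipeline run."""

    genomes: list[SpeciesGenome]
    rejected: list[tuple[SpeciesGenome, str]]
    synthase_calls: list[SynthaseCall]
    sensory_hits: list[DomainHit]
    filtered_hits: list[DomainHit]
    receptor_calls: list[ReceptorCall]
    profiles: list[SpeciesQSProfile]
    census: census_mod.CensusTables
    summary: dict = field(default_factory=dict)

    def call_tables(self) -> dict[str, pd.DataFrame]:
        """Deterministic tidy tables of every call type."""
        return {
            "synthase_calls": census_mod.calls_to_frame(self.synthase_calls),
            "domain_hits": receptors.hits_to_frame(self.filtered_hits),
            "receptor_calls": receptors.calls_to_frame(self.receptor_calls),
            "species_profiles": network.profiles_to_frame(self.profiles),
        }


def run_pipeline(
    genomes: Iterable[SpeciesGenome],
    quality: QualityThresholds | None = QualityThresholds(),
    operon_params: OperonParams = OperonParams(),
    topology_params: TopologyParams = TopologyParams(),
    gapes1_tm_filter: bool = False,
    map_mode: str = "pairwise",
) -> PipelineResult:
    """Run quality filter, synthase census, the four receptor routes,
    functional typing and profile assembly over a genome collection.

    The transmembrane topology filter applies to the dCache_1 search path;
    GAPES1 candidates skip it unless ``gapes1_tm_filter`` is set.
    """
    genomes = list(genomes)
    if quality is not None:
        passing, rejected = quality_filter(genomes, quality)
    else:
        passing, rejected = genomes, []

    refsets = default_refsets()
    sensory = sensory_registry()
    full_registry = default_registry()
    module_registry = function_typing.load_module_registry()

    synthase_calls: list[SynthaseCall] = []
    sensory_hits: list[DomainHit] = []
    filtered_hits: list[DomainHit] = []
    receptor_calls: list[ReceptorCall] = []

    classes, blacklist = census_mod.load_lexicon()
    for genome in passing:
        synthase_calls.extend(
            census_mod.scan_synthases(genome, classes, blacklist))
        receptor_calls.extend(receptors.find_luxP(genome))
        receptor_calls.extend(
            receptors.find_functional_lsrB(genome, operon_params))

        proteins = genome.coding_proteins()
        hits = receptors.scan_domains(proteins, sensory, genome.genome_id)
        sensory_hits.extend(hits)
        dcache_hits = [h for h in hits if h.accession == DCACHE_ACC]
        gapes_hits = [h for h in hits if h.accession == GAPES1_ACC]
        dcache_hits = receptors.filter_transmembrane(
            dcache_hits, proteins, topology_params)
        if gapes1_tm_filter:
            gapes_hits = receptors.filter_transmembrane(
                gapes_hits, proteins, topology_params)
        kept = dcache_hits + gapes_hits
        filtered_hits.extend(kept)

        screened = receptors.call_residue_screened_receptors(
            kept, proteins, refsets, mode=map_mode)
        if screened:
            # full-protein scan of called proteins for functional typing
            called_loci = {c.locus_tag for c in screened}
            full_hits = receptors.scan_domains(
                {lt: proteins[lt] for lt in called_loci},
                full_registry, genome.genome_id)
            screened = function_typing.assign_modules(
                screened, full_hits, module_registry)
        receptor_calls.extend(screened)

    receptor_calls = function_typing.attach_canonical_modules(receptor_calls)
    census_tables = census_mod.tabulate_census(synthase_calls, passing)
    profiles = network.build_profiles(synthase_calls, receptor_calls, passing)
    summary = network.network_summary(profiles)

    return PipelineResult(
        genomes=passing,
        rejected=rejected,
        synthase_calls=synthase_calls,
        sensory_hits=sensory_hits,
        filtered_hits=filtered_hits,
        receptor_calls=receptor_calls,
        profiles=profiles,
        census=census_tables,
        summary=summary,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Serialise call tables, networks and the JSON summary to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in result.call_tables().items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    result.census.species_per_signal.rename("n_species").to_csv(
        out_dir / "species_per_signal.tsv", sep="\t")
    result.census.signal_count_histogram.rename("n_species").to_csv(
        out_dir / "signal_count_histogram.tsv", sep="\t")
    bipartite = network.build_bipartite_network(result.profiles)
    module_net = network.build_module_network(result.profiles)
    network.write_graphml(bipartite, out_dir / "bipartite.graphml")
    network.write_graphml(module_net, out_dir / "module_network.graphml")
    network.write_edge_list(bipartite, out_dir / "bipartite_edges.tsv")
    network.phyletic_distribution(result.profiles).to_csv(
        out_dir / "phyletic_distribution.tsv", sep="\t", index=False)
    network.write_summary(result.summary, out_dir / "summary.json")
    return out_dir
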