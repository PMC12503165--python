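"""Synthetic annotated communities with machine-readable ground truth.

The generator emulates the pipeline's real inputs — annotated
species-representative genomes plus gene count tables — with every planted
feature recorded in a :class:`TruthManifest`:

* synthase genes planted by gene name and/or product wording from the
  census lexicon, including deliberately incomplete multi-gene sets;
* receptor proteins assembled as head + TM helix + sensory domain (the
  bundled reference ligand-binding domain with random substitutions away
  from the screened positions; screened residues intact or mutated per
  plan) + TM helix + output-domain sequence drawn from the synthetic domain
  bases, so profile search, topology filtering, residue screening and
  functional typing all have real work to do;
* complete and deliberately broken ``lsr`` operons;
* decoy proteins: composition-preserving shuffles of the sensory domains
  (no profile hit) and soluble intact-domain copies (profile hit, removed
  by the topology filter);
* negative-binomial count tables whose expected TPM per gene equals the
  plan's target.

Identical plan + seed always yields identical output (files are written
deterministically, byte for byte).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import synthetic
from .genomes import GeneRecord, SpeciesGenome, parse_taxonomy
from .references import ReferenceResidueSet, default_refsets

MODULE_OUTPUT_DOMAINS = {
    "MCP": ("PF00015",),
    "CSP": ("PF00990",),
    "HK": ("PF00512", "PF02518"),
    "STK": ("PF00069",),
    "SP": ("PF00481",),
    "AC/GC": ("PF00211",),
    "uncharacterized": (),
}

_HOUSEKEEPING_PRODUCTS = (
    "hypothetical protein",
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L3",
    "ABC transporter permease",
    "elongation factor Tu",
    "MFS transporter",
    "cell division protein FtsZ",
    "chaperonin GroEL",
)

_SYNTHASE_PRODUCTS = {
    "luxS": "S-ribosylhomocysteine lyase",
    "agrB": "accessory gene regulator protein B",
    "tnaA": "tryptophanase",
    "tdh": "threonine dehydrogenase",
    "cqsA": "CAI-1 autoinducer synthase",
    "lasI": "acyl-homoserine lactone synthase LasI",
    "rpfF": "DSF synthase",
    "lqsA": "autoinducer synthase LqsA",
    "phcB": "methyltransferase PhcB",
    "ppyS": "photopyrone synthase",
}

_LSR_PRODUCTS = {
    "lsrA": "Autoinducer 2 import ATP-binding protein LsrA",
    "lsrC": "Autoinducer 2 import system permease protein LsrC",
    "lsrD": "Autoinducer 2 import system permease protein LsrD",
    "lsrB": "Autoinducer 2-binding protein LsrB",
    "lsrK": "Autoinducer-2 kinase",
    "lsrR": "Transcriptional regulator LsrR",
}

LUXP_PRODUCT = "Autoinducer 2-binding periplasmic protein LuxP"


@dataclass(frozen=True)
class PlannedSynthase:
    """Plant genes for one signal; ``expect_call`` is False for decoy
    (incomplete) multi-gene sets."""

    signal: str
    genes: tuple[str, ...]
    expect_call: bool = True
    via_product_only: bool = False  # plant product wording without gene name


@dataclass(frozen=True)
class PlannedReceptor:
    """Plant one transmembrane sensory receptor protein."""

    receptor_type: str            # dCache_1 | GAPES1
    module: str = "MCP"           # output-domain module (dCache_1 only)
    intact: bool = True           # screened residues intact vs one mutated
    n_background_subs: int = 6    # substitutions away from screened sites


@dataclass(frozen=True)
class SpeciesPlan:
    genome_id: str
    taxonomy: str
    completeness: float = 97.0
    contamination: float = 1.0
    genome_type: str = "MAG"
    synthases: tuple[PlannedSynthase, ...] = ()
    receptors: tuple[PlannedReceptor, ...] = ()
    lsr_operon: str | None = None  # complete | missing_gene:<g> | broken_gap
    n_luxp: int = 0
    decoys: tuple[str, ...] = ()   # shuffled_dcache | soluble_dcache |
                                   # shuffled_gapes1 | random
    n_housekeeping: int = 8


@dataclass(frozen=True)
class CommunityPlan:
    species: tuple[SpeciesPlan, ...]
    seed: int = 0

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class TruthManifest:
    """Everything the pipeline is expected to recover, derived from the
    plan alone."""

    synthase_calls: frozenset[tuple[str, str]]          # (genome, signal)
    luxS_copies: Mapping[str, int]
    receptor_calls: frozenset[tuple[str, str, str]]     # (genome, locus, type)
    modules: Mapping[tuple[str, str], str]              # (genome, locus) -> module
    roles: Mapping[str, str]
    qs_loci: Mapping[tuple[str, str], tuple[str, ...]]  # (genome, kind) -> loci

    def signal_histogram(self) -> dict[int, int]:
        per_genome: dict[str, set[str]] = {}
        for genome_id, signal in self.synthase_calls:
            per_genome.setdefault(genome_id, set()).add(signal)
        histogram: dict[int, int] = {}
        for signals in per_genome.values():
            histogram[len(signals)] = histogram.get(len(signals), 0) + 1
        return histogram


# ---------------------------------------------------------------------------
# Default study community
# ---------------------------------------------------------------------------

_PHYLA = (
    ("Firmicutes", "Lachnospiraceae"),
    ("Proteobacteria", "Enterobacteriaceae"),
    ("Actinobacteriota", "Coriobacteriaceae"),
    ("Bacteroidota", "Bacteroidaceae"),
    ("Verrucomicrobiota", "Akkermansiaceae"),
    ("Campylobacterota", "Campylobacteraceae"),
    ("Spirochaetota", "Treponemataceae"),
)

_DEFAULT_MODULES = (
    "MCP", "MCP", "MCP", "CSP", "CSP", "HK", "STK", "SP",
    # mutated receptors (not expected to be called) reuse mixed modules
    "MCP", "CSP", "HK", "AC/GC",
)


def default_plan(seed: int = 0) -> CommunityPlan:
    """The default 60-species study community.

    40 species carry luxS (three of them in double copy, one of those via
    product wording without a gene name); 12 dCache_1
    receptor proteins of mixed output modules are planted, 4 with a mutated
    screened residue; 3 GAPES1 receptors, 1 mutated; 6 complete and 4
    deliberately broken lsr operons; 2 LuxP genes; 30 decoy proteins.
    Other signal classes (AIPs, indole, HAQs complete and incomplete,
    CAI-1, DPO, AHLs, DSFs and the remaining multi-gene classes) are
    planted on a fixed subset so the census histogram is non-trivial.
    """
    species = []
    for i in range(60):
        phylum, family = _PHYLA[i % len(_PHYLA)]
        genus = f"Genus{i:02d}"
        taxonomy = (
            f"d__Bacteria;p__{phylum};c__Class{i % 4};o__Order{i % 5};"
            f"f__{family};g__{genus};s__{genus} sp{i:03d}"
        )
        synthases: list[PlannedSynthase] = []
        if i < 40:
            copies = 2 if i in (0, 1) else 1
            for _ in range(copies):
                synthases.append(PlannedSynthase("AI-2", ("luxS",)))
        if i in (5, 6, 7, 8, 9):
            synthases.append(PlannedSynthase("AIPs", ("agrB",)))
        if i in (10, 11, 12, 13):
            synthases.append(PlannedSynthase("indole", ("tnaA",)))
        if i == 2:
            synthases.append(PlannedSynthase(
                "HAQs", ("pqsA", "pqsB", "pqsC", "pqsD")))
        if i == 3:  # incomplete gene set: must NOT be called
            synthases.append(PlannedSynthase(
                "HAQs", ("pqsA", "pqsB", "pqsC"), expect_call=False))
        if i == 4:
            synthases.append(PlannedSynthase("CAI-1", ("cqsA",)))
        if i == 6:
            synthases.append(PlannedSynthase(
                "2-(2-hydroxyphenyl)-thiazole-4-carbaldehyde",
                ("ambB", "ambC", "ambD", "ambE")))
        if i == 7:
            synthases.append(PlannedSynthase(
                "dialkylresorcinols", ("darA", "darB", "darC")))
        if i == 8:
            synthases.append(PlannedSynthase("DPO", ("tdh",)))
        if i == 9:
            synthases.append(PlannedSynthase("DSFs", ("rpfF",)))
        if i == 16:
            synthases.append(PlannedSynthase("AHLs", ("lasI",)))
        if i == 17:  # product wording only, no gene name
            synthases.append(PlannedSynthase(
                "AI-2", ("luxS",), via_product_only=True))

        receptors: list[PlannedReceptor] = []
        if i < 12:
            receptors.append(PlannedReceptor(
                receptor_type="dCache_1",
                module=_DEFAULT_MODULES[i],
                intact=i < 8,
            ))
        if i in (12, 13, 14):
            receptors.append(PlannedReceptor(
                receptor_type="GAPES1", module="CSP", intact=i != 14))

        lsr = None
        if 36 <= i <= 41:
            lsr = "complete"
        elif i == 42:
            lsr = "missing_gene:lsrK"
        elif i == 43:
            lsr = "missing_gene:lsrR"
        elif i == 44:
            lsr = "missing_gene:lsrD"
        elif i == 45:
            lsr = "broken_gap"

        decoys: tuple[str, ...] = ()
        if i < 10:
            decoys = ("soluble_dcache",)
        elif i < 20:
            decoys = ("shuffled_dcache",)
        elif i < 25:
            decoys = ("shuffled_gapes1",)
        elif i < 30:
            decoys = ("random",)

        species.append(SpeciesPlan(
            genome_id=f"SYN{i:04d}",
            taxonomy=taxonomy,
            completeness=91.0 + (i % 9),
            contamination=0.5 + (i % 4),
            genome_type="isolate" if i % 5 == 0 else "MAG",
            synthases=tuple(synthases),
            receptors=tuple(receptors),
            lsr_operon=lsr,
            n_luxp=1 if i in (46, 47) else 0,
            decoys=decoys,
        ))
    return CommunityPlan(species=tuple(species), seed=seed)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _PlannedGene:
    gene_name: str | None
    product: str
    protein: str
    extra_gap_before: int = 0  # bp added before this gene


def _receptor_protein(
    planned: PlannedReceptor,
    refsets: Mapping[str, ReferenceResidueSet],
    rng: np.random.Generator,
) -> tuple[str, str | None]:
    """Build a receptor protein sequence; returns (sequence, mutated_pos)."""
    refset = refsets[planned.receptor_type]
    domain = refset.domain_sequence
    window_positions = refset.window_positions()
    forbidden = frozenset(
        p + d for p, _ in window_positions for d in range(-2, 3))
    domain = synthetic.mutate(
        domain, rng, planned.n_background_subs, forbidden=forbidden)
    mutated_pos = None
    if not planned.intact:
        pos, expected = window_positions[
            int(rng.integers(len(window_positions)))]
        alternatives = [a for a in synthetic.AMINO_ACIDS if a != expected]
        domain = domain[:pos - 1] + str(rng.choice(alternatives)) + domain[pos:]
        mutated_pos = pos
    head = synthetic.sample_soluble(rng, 6)
    tm1 = synthetic.sample_tm_helix(rng)
    linker = synthetic.sample_soluble(rng, 5)
    tm2 = synthetic.sample_tm_helix(rng)
    if planned.receptor_type == "GAPES1":
        output_accs = MODULE_OUTPUT_DOMAINS["CSP"]
    else:
        output_accs = MODULE_OUTPUT_DOMAINS[planned.module]
    parts = [head, tm1, domain, linker, tm2]
    if output_accs:
        for acc in output_accs:
            parts.append(synthetic.domain_variant(acc, rng))
    else:
        parts.append(synthetic.sample_soluble(rng, 120))
    return "".join(parts), mutated_pos


def _decoy_protein(
    kind: str,
    refsets: Mapping[str, ReferenceResidueSet],
    rng: np.random.Generator,
) -> str:
    if kind == "shuffled_dcache":
        domain = refsets["dCache_1"].domain_sequence
        return "".join(rng.permutation(list(domain)))
    if kind == "shuffled_gapes1":
        domain = refsets["GAPES1"].domain_sequence
        return "".join(rng.permutation(list(domain)))
    if kind == "soluble_dcache":
        refset = refsets["dCache_1"]
        forbidden = frozenset(
            p + d for p, _ in refset.window_positions() for d in range(-2, 3))
        domain = synthetic.mutate(
            refset.domain_sequence, rng, 6, forbidden=forbidden)
        return synthetic.sample_soluble(rng, 15) + domain + \
            synthetic.sample_soluble(rng, 15)
    if kind == "random":
        return synthetic.sample_soluble(rng, int(rng.integers(150, 250)))
    raise ValueError(f"unknown decoy kind {kind!r}")


def _species_genes(
    plan: SpeciesPlan,
    refsets: Mapping[str, ReferenceResidueSet],
    rng: np.random.Generator,
) -> tuple[list[_PlannedGene], dict[str, list[int]]]:
    """Planned genes in final genomic order, plus index bookkeeping
    (kind -> gene indices) for the manifest."""
    genes: list[_PlannedGene] = []
    loci_of: dict[str, list[int]] = {}

    def add(gene: _PlannedGene, kind: str | None = None) -> None:
        if kind is not None:
            loci_of.setdefault(kind, []).append(len(genes))
        genes.append(gene)

    half = plan.n_housekeeping // 2
    for j in range(half):
        add(_PlannedGene(
            None, _HOUSEKEEPING_PRODUCTS[j % len(_HOUSEKEEPING_PRODUCTS)],
            synthetic.sample_soluble(rng, int(rng.integers(150, 250)))))

    for planted in plan.synthases:
        for gene_name in planted.genes:
            product = _SYNTHASE_PRODUCTS.get(gene_name, f"{gene_name} protein")
            add(_PlannedGene(
                None if planted.via_product_only else gene_name,
                product,
                synthetic.sample_soluble(rng, int(rng.integers(150, 300)))),
                kind=f"synthase:{planted.signal}"
                if planted.expect_call else None)

    for k, planted in enumerate(plan.receptors):
        protein, _ = _receptor_protein(planted, refsets, rng)
        kind = (f"receptor:{planted.receptor_type}:{planted.module}"
                if planted.intact else None)
        add(_PlannedGene(None, "transmembrane signal transduction protein",
                         protein), kind=kind)

    if plan.lsr_operon is not None:
        missing = (plan.lsr_operon.split(":", 1)[1]
                   if plan.lsr_operon.startswith("missing_gene") else None)
        for name in ("lsrA", "lsrC", "lsrD", "lsrB"):
            if name == missing:
                continue
            gap = 0
            if plan.lsr_operon == "broken_gap" and name == "lsrD":
                gap = 2000  # exceeds the default 500 bp operon gap
            kind = None
            if name == "lsrB" and plan.lsr_operon == "complete":
                kind = "receptor:LsrB"
            add(_PlannedGene(
                name, _LSR_PRODUCTS[name],
                synthetic.sample_soluble(rng, int(rng.integers(150, 340))),
                extra_gap_before=gap), kind=kind)
        for name in ("lsrK", "lsrR"):
            if name == missing:
                continue
            # regulators sit away from the transporter block
            add(_PlannedGene(
                name, _LSR_PRODUCTS[name],
                synthetic.sample_soluble(rng, int(rng.integers(150, 300))),
                extra_gap_before=3000 if name == "lsrK" else 0))

    for _ in range(plan.n_luxp):
        add(_PlannedGene(None, LUXP_PRODUCT,
                         synthetic.sample_soluble(rng, int(rng.integers(280, 360)))),
            kind="receptor:LuxP")

    for kind in plan.decoys:
        add(_PlannedGene(None, "hypothetical protein",
                         _decoy_protein(kind, refsets, rng)))

    for j in range(plan.n_housekeeping - half):
        add(_PlannedGene(
            None, _HOUSEKEEPING_PRODUCTS[(half + j) % len(_HOUSEKEEPING_PRODUCTS)],
            synthetic.sample_soluble(rng, int(rng.integers(150, 250)))))

    return genes, loci_of


def _assemble_genome(
    plan: SpeciesPlan,
    refsets: Mapping[str, ReferenceResidueSet],
    seed: int,
    index: int,
) -> tuple[SpeciesGenome, dict[str, list[str]]]:
    rng = np.random.default_rng([seed % 2**31, index])
    planned_genes, loci_of_idx = _species_genes(plan, refsets, rng)

    records: dict[str, GeneRecord] = {}
    proteins: dict[str, str] = {}
    cursor = 101
    locus_by_index: list[str] = []
    for j, gene in enumerate(planned_genes):
        cursor += gene.extra_gap_before
        locus = f"{plan.genome_id}_{j + 1:05d}"
        start = cursor
        end = start + 3 * len(gene.protein) + 2
        records[locus] = GeneRecord(
            locus_tag=locus, contig=f"{plan.genome_id}_contig1",
            start=start, end=end, strand="+",
            product=gene.product, gene_name=gene.gene_name,
            aa_length=len(gene.protein), has_protein=True,
        )
        proteins[locus] = gene.protein
        locus_by_index.append(locus)
        cursor = end + 101  # default intergenic distance 100 bp

    genome = SpeciesGenome(
        genome_id=plan.genome_id,
        taxonomy=parse_taxonomy(plan.taxonomy),
        completeness=plan.completeness,
        contamination=plan.contamination,
        is_isolate=plan.genome_type == "isolate",
        genes=records,
        proteins=proteins,
    )
    loci_of = {
        kind: [locus_by_index[i] for i in indices]
        for kind, indices in loci_of_idx.items()
    }
    return genome, loci_of


def generate_community(
    plan: CommunityPlan,
) -> tuple[list[SpeciesGenome], TruthManifest]:
    """Generate the community in memory with its truth manifest."""
    refsets = default_refsets()
    genomes = []
    synthase_calls: set[tuple[str, str]] = set()
    luxs_copies: dict[str, int] = {}
    receptor_calls: set[tuple[str, str, str]] = set()
    modules: dict[tuple[str, str], str] = {}
    qs_loci: dict[tuple[str, str], tuple[str, ...]] = {}

    canonical = {"LsrB": "Lsr-import", "LuxP": "LuxPQ"}
    for index, species in enumerate(plan.species):
        genome, loci_of = _assemble_genome(species, refsets, plan.seed, index)
        genomes.append(genome)
        for kind, loci in loci_of.items():
            if kind.startswith("synthase:"):
                signal = kind.split(":", 1)[1]
                synthase_calls.add((species.genome_id, signal))
                if signal == "AI-2":
                    luxs_copies[species.genome_id] = len(loci)
                    qs_loci[(species.genome_id, "luxS")] = tuple(loci)
            else:
                parts = kind.split(":")
                rtype = parts[1]
                for locus in loci:
                    receptor_calls.add((species.genome_id, locus, rtype))
                    modules[(species.genome_id, locus)] = (
                        parts[2] if rtype == "dCache_1"
                        else "CSP" if rtype == "GAPES1"
                        else canonical[rtype]
                    )
                key = (species.genome_id, rtype)
                qs_loci[key] = qs_loci.get(key, ()) + tuple(loci)

    roles = {}
    receptor_genomes = {g for g, _, _ in receptor_calls}
    for species in plan.species:
        produces = luxs_copies.get(species.genome_id, 0) > 0
        senses = species.genome_id in receptor_genomes
        roles[species.genome_id] = (
            "both" if produces and senses
            else "producer_only" if produces
            else "receiver_only" if senses
            else "none"
        )

    manifest = TruthManifest(
        synthase_calls=frozenset(synthase_calls),
        luxS_copies=luxs_copies,
        receptor_calls=frozenset(receptor_calls),
        modules=modules,
        roles=roles,
        qs_loci=qs_loci,
    )
    return genomes, manifest


def write_community(
    genomes: Iterable[SpeciesGenome], out_dir: str | Path
) -> Path:
    """Write GFF3 + protein FASTA per genome plus ``metadata.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for genome in genomes:
        with open(out_dir / f"{genome.genome_id}.gff3", "w") as gff:
            gff.write("##gff-version 3\n")
            for gene in sorted(genome.genes.values(), key=lambda g: g.start):
                attrs = [f"ID={gene.locus_tag}", f"locus_tag={gene.locus_tag}"]
                if gene.gene_name:
                    attrs.append(f"gene={gene.gene_name}")
                attrs.append(f"product={gene.product}")
                gff.write("\t".join([
                    gene.contig, "ai2net_synth", "CDS", str(gene.start),
                    str(gene.end), ".", gene.strand, "0", ";".join(attrs),
                ]) + "\n")
        with open(out_dir / f"{genome.genome_id}.faa", "w") as faa:
            for locus in sorted(genome.proteins):
                seq = genome.proteins[locus]
                if not seq:
                    continue
                faa.write(f">{locus}\n")
                for i in range(0, len(seq), 60):
                    faa.write(seq[i:i + 60] + "\n")
        meta_rows.append({
            "genome_id": genome.genome_id,
            "completeness": genome.completeness,
            "contamination": genome.contamination,
            "genome_type": "isolate" if genome.is_isolate else "MAG",
            "taxonomy": ";".join(
                p + v for p, v in zip(
                    ("d__", "p__", "c__", "o__", "f__", "g__", "s__"),
                    genome.taxonomy)),
        })
    pd.DataFrame(meta_rows).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionPlanEntry:
    """Target mean TPM for the QS genes of one species in one state."""

    genome_id: str
    kind: str            # luxS | LuxP | LsrB | dCache_1 | GAPES1
    target_tpm: Mapping[str, float]  # state -> TPM


@dataclass(frozen=True)
class ExpressionPlan:
    entries: tuple[ExpressionPlanEntry, ...]
    n_samples_per_state: int = 10
    states: tuple[str, ...] = ("healthy", "unhealthy")
    dispersion: float = 0.3    # negative-binomial overdispersion
    depth: float = 50.0        # expected counts per (TPM x kb) unit

    def __post_init__(self) -> None:
        for entry in self.entries:
            if any(t < 0 for t in entry.target_tpm.values()):
                raise ValueError(
                    f"negative target TPM for {entry.genome_id}/{entry.kind}")


def default_expression_plan(manifest: TruthManifest) -> ExpressionPlan:
    """A two-state expression design over the default community.

    Healthy state: strong luxS expression with receptor co-expression in a
    Lachnospiraceae-dominated subset; unhealthy state: co-expression shifts
    to the Enterobacteriaceae lsr-carrying species, with luxS levels
    dropping below the 'high' threshold.  Targets keep at least a twofold
    margin from every decision threshold.
    """
    entries = [
        # healthy co-expressers: Lachnospiraceae-dominated (SYN0000/SYN0007)
        ExpressionPlanEntry("SYN0000", "luxS", {"healthy": 0.8, "unhealthy": 0.05}),
        ExpressionPlanEntry("SYN0000", "dCache_1", {"healthy": 0.06, "unhealthy": 0.0}),
        ExpressionPlanEntry("SYN0007", "luxS", {"healthy": 0.5, "unhealthy": 0.05}),
        ExpressionPlanEntry("SYN0007", "dCache_1", {"healthy": 0.04, "unhealthy": 0.0}),
        ExpressionPlanEntry("SYN0012", "luxS", {"healthy": 0.45, "unhealthy": 0.08}),
        ExpressionPlanEntry("SYN0012", "GAPES1", {"healthy": 0.05, "unhealthy": 0.0}),
        # unhealthy co-expressers: Enterobacteriaceae (SYN0001/SYN0036)
        ExpressionPlanEntry("SYN0001", "luxS", {"healthy": 0.05, "unhealthy": 0.45}),
        ExpressionPlanEntry("SYN0001", "dCache_1", {"healthy": 0.0, "unhealthy": 0.05}),
        ExpressionPlanEntry("SYN0036", "luxS", {"healthy": 0.06, "unhealthy": 0.5}),
        ExpressionPlanEntry("SYN0036", "LsrB", {"healthy": 0.0, "unhealthy": 0.3}),
        ExpressionPlanEntry("SYN0020", "luxS", {"healthy": 0.08, "unhealthy": 0.08}),
    ]
    entries = [
        e for e in entries if (e.genome_id, e.kind) in manifest.qs_loci
        or e.kind == "luxS" and (e.genome_id, "luxS") in manifest.qs_loci
    ]
    return ExpressionPlan(entries=tuple(entries))


def generate_counts(
    genomes: Iterable[SpeciesGenome],
    expression_plan: ExpressionPlan,
    manifest: TruthManifest,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str], pd.DataFrame]:
    """Simulate a gene x sample count table.

    Returns (counts, lengths_bp, sample->state map, expected flag table).
    Gene keys are ``genome_id|locus_tag``.  Per state, the focal QS genes
    get their planned target TPM and all remaining genes share the residual
    TPM budget uniformly, so the expected TPM of every gene equals its
    target exactly; counts are negative-binomial around
    ``target_tpm x length_kb x depth``.
    """
    genomes = list(genomes)
    gene_keys, lengths = [], []
    for genome in genomes:
        for locus in sorted(genome.genes):
            gene = genome.genes[locus]
            gene_keys.append(f"{genome.genome_id}|{locus}")
            lengths.append(gene.end - gene.start + 1)
    lengths = pd.Series(lengths, index=gene_keys, dtype=float)

    # every QS gene is under explicit control: target 0 unless planned,
    # so expression is confined to the planned species/states
    focal_target: dict[str, dict[str, float]] = {}
    for (genome_id, _kind), loci in manifest.qs_loci.items():
        for locus in loci:
            focal_target.setdefault(f"{genome_id}|{locus}", {})
    for entry in expression_plan.entries:
        loci = manifest.qs_loci.get((entry.genome_id, entry.kind), ())
        for locus in loci:
            key = f"{entry.genome_id}|{locus}"
            for state, tpm in entry.target_tpm.items():
                # split the kind-level target evenly over its genes
                focal_target.setdefault(key, {})[state] = tpm / len(loci)

    rng = np.random.default_rng([seed % 2**31, 7])
    samples: dict[str, str] = {}
    columns = {}
    for state in expression_plan.states:
        focal_sum = sum(t.get(state, 0.0) for t in focal_target.values())
        n_other = len(gene_keys) - len(focal_target)
        baseline = (1e6 - focal_sum) / n_other
        targets = np.full(len(gene_keys), baseline)
        for i, key in enumerate(gene_keys):
            if key in focal_target:
                targets[i] = focal_target[key].get(state, 0.0)
        means = targets * (lengths.to_numpy() / 1000.0) * expression_plan.depth
        for s in range(expression_plan.n_samples_per_state):
            sample_id = f"{state}_{s + 1:02d}"
            samples[sample_id] = state
            n = 1.0 / expression_plan.dispersion
            with np.errstate(divide="ignore"):
                p = n / (n + means)
            counts = np.where(
                means > 0, rng.negative_binomial(n, np.where(means > 0, p, 1.0)), 0)
            columns[sample_id] = counts
    counts = pd.DataFrame(columns, index=gene_keys, dtype=int)

    # analytic expected flags per planned species/state
    from .expression import ExpressionThresholds
    thresholds = ExpressionThresholds()
    rows = []
    for entry in expression_plan.entries:
        for state in expression_plan.states:
            target = entry.target_tpm.get(state, 0.0)
            rows.append({
                "genome_id": entry.genome_id, "kind": entry.kind,
                "state": state, "target_tpm": target,
                "expected_expressed": target > thresholds.expressed,
                "expected_high": target > thresholds.high_for(entry.kind),
            })
    expected = pd.DataFrame(rows)
    return counts, lengths, samples, expected


def write_counts(
    counts: pd.DataFrame,
    lengths: pd.Series,
    genomes: Iterable[SpeciesGenome],
    path: str | Path,
) -> None:
    """Write the counts as a featureCounts-style TSV."""
    meta = {}
    for genome in genomes:
        for locus, gene in genome.genes.items():
            meta[f"{genome.genome_id}|{locus}"] = gene
    rows = []
    for key in counts.index:
        gene = meta[key]
        rows.append({
            "Geneid": key, "Chr": gene.contig, "Start": gene.start,
            "End": gene.end, "Strand": gene.strand,
            "Length": int(lengths[key]),
        })
    frame = pd.DataFrame(rows).set_index("Geneid")
    pd.concat([frame, counts], axis=1).reset_index().rename(
        columns={"index": "Geneid"}).to_csv(path, sep="\t", index=False)
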