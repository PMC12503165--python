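"""Annotated genome ingestion, taxonomy parsing and quality filtering.

The pipeline consumes species-representative genomes that were annotated
upstream (Prokka-style GFF3 or GenBank flat files plus a protein FASTA) and
carry CheckM-style quality metrics.  Coordinates are stored 1-based inclusive
throughout (the GFF3/GenBank convention).  Genes without a protein
translation (RNAs, pseudogenes) are retained for neighbourhood analysis with
an empty sequence and ``has_protein=False``; they are excluded from protein
scans downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import gffutils
import pandas as pd
from Bio import SeqIO


class GenomeParseError(ValueError):
    """Malformed annotation or FASTA input."""


class GenomeIntegrityError(ValueError):
    """Cross-file inconsistency (duplicate or dangling locus tags)."""


class TaxonomyError(ValueError):
    """Unparseable GTDB-style taxonomy token."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates are 1-based inclusive."""

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    gene_name: str | None = None
    aa_length: int = 0
    has_protein: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeParseError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeParseError(f"{self.locus_tag}: bad strand {self.strand!r}")


RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


class Taxonomy(NamedTuple):
    """GTDB-style seven-rank taxonomy; unnamed ranks are empty strings."""

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""


def parse_taxonomy(label: str | Taxonomy) -> Taxonomy:
    """Parse a GTDB taxonomy string ``d__...;p__...;...;s__...``.

    Ranks may be truncated; missing or empty ranks come back as ``""``.
    """
    if isinstance(label, Taxonomy):
        return label
    ranks = [""] * 7
    if label.strip() == "":
        return Taxonomy()
    for token in label.split(";"):
        token = token.strip()
        if token == "":
            continue
        prefix = token[:3]
        if prefix not in RANK_PREFIXES:
            raise TaxonomyError(f"unrecognised rank prefix in token {token!r}")
        ranks[RANK_PREFIXES.index(prefix)] = token[3:]
    return Taxonomy(*ranks)


def format_taxonomy(taxonomy: Taxonomy, n_ranks: int = 7) -> str:
    """Render a :class:`Taxonomy` back to its GTDB string form."""
    return ";".join(
        prefix + value
        for prefix, value in zip(RANK_PREFIXES[:n_ranks], taxonomy[:n_ranks])
    )


@dataclass
class SpeciesGenome:
    """One species-representative genome with its proteins and metadata."""

    genome_id: str
    taxonomy: Taxonomy = Taxonomy()
    completeness: float | None = None
    contamination: float | None = None
    is_isolate: bool = False
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric in (self.completeness, self.contamination):
            if metric is not None and not (0 <= metric <= 100):
                raise ValueError(f"{self.genome_id}: metric {metric} outside [0,100]")
        dangling = set(self.proteins) - set(self.genes)
        if dangling:
            raise GenomeIntegrityError(
                f"{self.genome_id}: proteins without gene records: {sorted(dangling)}"
            )

    def coding_proteins(self) -> dict[str, str]:
        """Proteins of genes with a real translation (scan input)."""
        return {lt: seq for lt, seq in self.proteins.items() if seq}

    def genes_on_contig(self, contig: str) -> list[GeneRecord]:
        """Genes of one contig ordered by start coordinate."""
        genes = [g for g in self.genes.values() if g.contig == contig]
        return sorted(genes, key=lambda g: (g.start, g.locus_tag))


@dataclass(frozen=True)
class QualityThresholds:
    """Strict completeness/contamination bounds (pass iff ``>`` and ``<``)."""

    min_completeness: float = 90.0
    max_contamination: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.min_completeness <= 100):
            raise ValueError("min_completeness must lie in (0, 100]")
        if not (0 <= self.max_contamination < 100):
            raise ValueError("max_contamination must lie in [0, 100)")


def _parse_gff3_genes(path: Path) -> list[GeneRecord]:
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GenomeParseError(f"{path}: {exc}") from exc
    genes = []
    featuretypes = set(db.featuretypes())
    # Prokka-style files annotate CDS/RNA features directly; fall back to
    # bare `gene` features only when no such rows exist.
    wanted = {"CDS", "tRNA", "rRNA", "tmRNA"}
    if not wanted & featuretypes:
        wanted = {"gene"}
    for feature in db.all_features():
        if feature.featuretype not in wanted:
            continue
        locus = (feature.attributes.get("locus_tag") or feature.attributes.get("ID"))
        if not locus:
            raise GenomeParseError(f"{path}: feature without locus_tag/ID at "
                                   f"{feature.seqid}:{feature.start}")
        product = (feature.attributes.get("product") or [""])[0]
        gene_name = (feature.attributes.get("gene") or [None])[0]
        genes.append(GeneRecord(
            locus_tag=locus[0],
            contig=feature.seqid,
            start=feature.start,
            end=feature.end,
            strand=feature.strand if feature.strand in "+-" else "+",
            product=product,
            gene_name=gene_name,
            has_protein=feature.featuretype == "CDS",
        ))
    return genes


def _parse_genbank_genes(path: Path) -> tuple[list[GeneRecord], dict[str, str]]:
    genes: list[GeneRecord] = []
    translations: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise GenomeParseError(f"{path}: {exc}") from exc
    for record in records:
        for feat in record.features:
            if feat.type not in {"CDS", "tRNA", "rRNA", "tmRNA"}:
                continue
            quals = feat.qualifiers
            locus = quals.get("locus_tag", [None])[0]
            if locus is None:
                raise GenomeParseError(f"{path}: feature without locus_tag in "
                                       f"{record.id}")
            genes.append(GeneRecord(
                locus_tag=locus,
                contig=record.id,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                product=quals.get("product", [""])[0],
                gene_name=quals.get("gene", [None])[0],
                has_protein=feat.type == "CDS",
            ))
            if "translation" in quals:
                translations[locus] = quals["translation"][0]
    return genes, translations


def load_genome(
    annotation_path: str | Path,
    proteins_path: str | Path | None,
    metadata: Mapping[str, object],
) -> SpeciesGenome:
    """Load one annotated genome into the pipeline data model.

    ``annotation_path`` may be GFF3 (``.gff``/``.gff3``) or GenBank
    (``.gbk``/``.gb``/``.gbff``).  ``proteins_path`` is a protein FASTA whose
    record ids are locus tags; for GenBank it may be omitted, in which case
    the embedded ``/translation`` qualifiers are used.  ``metadata`` supplies
    ``genome_id`` plus optional ``completeness``, ``contamination``,
    ``taxonomy`` and ``genome_type`` (``isolate``/``MAG``).
    """
    annotation_path = Path(annotation_path)
    suffix = annotation_path.suffix.lower()
    if suffix in {".gbk", ".gb", ".gbff", ".genbank"}:
        gene_list, translations = _parse_genbank_genes(annotation_path)
    elif suffix in {".gff", ".gff3"}:
        gene_list = _parse_gff3_genes(annotation_path)
        translations = {}
    else:
        raise GenomeParseError(f"unrecognised annotation format: {annotation_path}")

    genes: dict[str, GeneRecord] = {}
    for gene in gene_list:
        if gene.locus_tag in genes:
            raise GenomeIntegrityError(
                f"{annotation_path}: duplicate locus_tag {gene.locus_tag}")
        genes[gene.locus_tag] = gene

    proteins: dict[str, str] = {}
    if proteins_path is not None:
        for record in SeqIO.parse(str(proteins_path), "fasta"):
            if record.id in proteins:
                raise GenomeIntegrityError(
                    f"{proteins_path}: duplicate protein id {record.id}")
            if record.id not in genes:
                raise GenomeIntegrityError(
                    f"{proteins_path}: protein {record.id} has no gene record")
            proteins[record.id] = str(record.seq)
    else:
        proteins = dict(translations)

    # Retain translation-less genes with an empty sequence, flagged.
    full_genes = {}
    for locus, gene in genes.items():
        seq = proteins.get(locus, "")
        full_genes[locus] = replace(
            gene, aa_length=len(seq), has_protein=bool(seq))
        proteins.setdefault(locus, "")

    taxonomy = parse_taxonomy(str(metadata.get("taxonomy", "")))
    completeness = metadata.get("completeness")
    contamination = metadata.get("contamination")
    return SpeciesGenome(
        genome_id=str(metadata["genome_id"]),
        taxonomy=taxonomy,
        completeness=None if completeness is None else float(completeness),
        contamination=None if contamination is None else float(contamination),
        is_isolate=str(metadata.get("genome_type", "MAG")).lower() == "isolate",
        genes=full_genes,
        proteins=proteins,
    )


def read_metadata_table(path: str | Path) -> dict[str, dict[str, object]]:
    """Read the metadata TSV (genome_id, completeness, contamination,
    genome_type, taxonomy) into per-genome metadata dicts."""
    table = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    return {row["genome_id"]: row.to_dict() for _, row in table.iterrows()}


def load_genome_directory(
    directory: str | Path, metadata_path: str | Path | None = None
) -> list[SpeciesGenome]:
    """Load every ``<genome_id>.gff3`` + ``<genome_id>.faa`` pair in a
    directory, joined with ``metadata.tsv`` (or ``metadata_path``)."""
    directory = Path(directory)
    metadata_path = Path(metadata_path or directory / "metadata.tsv")
    metadata = read_metadata_table(metadata_path)
    genomes = []
    for gff in sorted(directory.glob("*.gff3")) + sorted(directory.glob("*.gff")):
        genome_id = gff.stem
        faa = gff.with_suffix(".faa")
        meta = metadata.get(genome_id, {"genome_id": genome_id})
        genomes.append(load_genome(gff, faa if faa.exists() else None, meta))
    return genomes


def quality_filter(
    genomes: Iterable[SpeciesGenome],
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[list[SpeciesGenome], list[tuple[SpeciesGenome, str]]]:
    """Partition genomes by the strict quality rule.

    A genome passes iff ``completeness > min_completeness`` **and**
    ``contamination < max_contamination`` (strict on both sides).  Genomes
    missing either metric are rejected with reason ``missing_metrics``.
    """
    passing: list[SpeciesGenome] = []
    rejected: list[tuple[SpeciesGenome, str]] = []
    for genome in genomes:
        if genome.completeness is None or genome.contamination is None:
            rejected.append((genome, "missing_metrics"))
        elif genome.completeness <= thresholds.min_completeness:
            rejected.append((genome, "low_completeness"))
        elif genome.contamination >= thresholds.max_contamination:
            rejected.append((genome, "high_contamination"))
        else:
            passing.append(genome)
    return passing, rejected


def select_genus_representative(
    genomes_in_genus: list[SpeciesGenome],
) -> SpeciesGenome:
    """Choose a genus representative.

    Isolates are preferred outright; among the preferred tier the genome
    with the highest completeness wins, ties broken by lowest contamination
    and then lexicographic genome_id (for determinism).
    """
    if not genomes_in_genus:
        raise ValueError("cannot select a representative from an empty genus")
    genera = {g.taxonomy.genus for g in genomes_in_genus}
    if len(genera) > 1:
        raise ValueError(f"genomes span multiple genera: {sorted(genera)}")
    pool = [g for g in genomes_in_genus if g.is_isolate] or list(genomes_in_genus)
    return min(
        pool,
        key=lambda g: (
            -(g.completeness if g.completeness is not None else -1.0),
            g.contamination if g.contamination is not None else 101.0,
            g.genome_id,
        ),
    )


def group_by_genus(
    genomes: Iterable[SpeciesGenome],
) -> dict[str, list[SpeciesGenome]]:
    """Group genomes by GTDB genus name (empty genus groups under ``""``)."""
    grouped: dict[str, list[SpeciesGenome]] = {}
    for genome in genomes:
        grouped.setdefault(genome.taxonomy.genus, []).append(genome)
    return grouped
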