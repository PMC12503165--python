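"""Independent oracles shared between unit and acceptance tests."""

from __future__ import annotations

import itertools

from ai2net.genomes import GeneRecord, SpeciesGenome, Taxonomy


def genome_from_layout(layout, genome_id="G"):
    """Build a genome from (gene_name, contig, start, end, strand) rows."""
    records = {}
    for i, (name, contig, start, end, strand) in enumerate(layout):
        locus = f"{genome_id}_{i:03d}"
        records[locus] = GeneRecord(
            locus_tag=locus, contig=contig, start=start, end=end,
            strand=strand, product=f"{name or 'hypothetical'} protein",
            gene_name=name)
    return SpeciesGenome(
        genome_id=genome_id, taxonomy=Taxonomy(), completeness=95,
        contamination=1, genes=records,
        proteins={lt: "M" + "A" * 30 for lt in records})


def oracle_functional_lsrB(genome, params):
    """Brute-force enumeration of all candidate lsr gene windows.

    Returns the set of lsrB locus tags that head a valid transporter block
    (one gene each of lsrA/C/D/B on one contig, same strand when required,
    bounded intergenic gaps and intervening-gene counts) in a genome that
    also carries lsrK and lsrR.
    """
    def named(name):
        return [g for g in genome.genes.values()
                if (g.gene_name or "").lower() == name.lower()]

    if not (named("lsrK") and named("lsrR")):
        return set()
    called = set()
    for ga, gc, gd, gb in itertools.product(
            named("lsrA"), named("lsrC"), named("lsrD"), named("lsrB")):
        block = [ga, gc, gd, gb]
        if len({g.contig for g in block}) != 1:
            continue
        if params.require_same_strand and len({g.strand for g in block}) != 1:
            continue
        ordered = sorted(block, key=lambda g: g.start)
        tags = {g.locus_tag for g in block}
        ok = True
        for left, right in zip(ordered, ordered[1:]):
            if right.start - left.end - 1 > params.max_intergenic_gap:
                ok = False
                break
            between = [
                g for g in genome.genes.values()
                if g.contig == left.contig
                and left.start < g.start < right.start
                and g.locus_tag not in tags
            ]
            if len(between) > params.max_intervening_genes:
                ok = False
                break
        if ok:
            called.add(gb.locus_tag)
    return called


def random_operon_genome(rng, genome_id):
    """Small randomized genome (<=50 genes) with lsr-ish gene content."""
    n_genes = int(rng.integers(8, 50))
    pool = (["lsrA", "lsrC", "lsrD", "lsrB", "lsrK", "lsrR"] * 2
            + [None] * 20)
    layout = []
    for contig in ["c1", "c2"][: int(rng.integers(1, 3))]:
        cursor = int(rng.integers(1, 500))
        for _ in range(n_genes // 2 + 1):
            name = pool[int(rng.integers(len(pool)))]
            length = int(rng.integers(300, 1500))
            strand = "+" if rng.random() < 0.7 else "-"
            layout.append((name, contig, cursor, cursor + length - 1, strand))
            cursor += length + int(rng.integers(0, 1200))  # straddles 500 bp
    return genome_from_layout(layout, genome_id)
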