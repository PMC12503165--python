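"""Census of quorum-sensing signal synthase genes.

Thirteen signal classes are screened semantically against Prokka-style
annotations using a versioned lexicon (``data/lexicon.yaml``): exact
case-insensitive gene-name matches, whole-word product-keyword matches with
a trailing-qualifier blacklist, and, for the multi-gene biosynthetic
pathways (HAQs, the aminophenol-thiazole signal, dialkylresorcinols), a
complete-gene-set rule — the call is emitted only when every member of at
least one alternative gene set co-occurs anywhere in the genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .genomes import SpeciesGenome, group_by_genus, select_genus_representative


class LexiconError(ValueError):
    """Bad lexicon file or unknown signal class."""


@dataclass(frozen=True)
class SignalClass:
    """One signal class with its detection lexicon."""

    name: str
    gene_names: frozenset[str] = frozenset()
    product_keywords: frozenset[str] = frozenset()
    required_gene_sets: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if not (self.gene_names or self.product_keywords or self.required_gene_sets):
            raise LexiconError(f"signal {self.name!r} has an empty lexicon")
        if any(not s for s in self.required_gene_sets):
            raise LexiconError(f"signal {self.name!r} has an empty required set")

    @property
    def is_multi_gene(self) -> bool:
        return bool(self.required_gene_sets)


@dataclass(frozen=True)
class SynthaseCall:
    """One synthase detection in one genome."""

    genome_id: str
    signal: str
    locus_tags: tuple[str, ...]
    evidence: str  # gene_name_match | product_keyword_match | complete_gene_set

    def __post_init__(self) -> None:
        if not self.locus_tags:
            raise ValueError("SynthaseCall with no locus tags")


def load_lexicon(path: str | Path | None = None) -> tuple[list[SignalClass], list[str]]:
    """Load the signal lexicon; returns (signal classes, qualifier blacklist)."""
    if path is None:
        source = resources.files("ai2net.data").joinpath("lexicon.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    classes = []
    for name, entry in raw["signals"].items():
        classes.append(SignalClass(
            name=str(name),
            gene_names=frozenset(entry.get("gene_names", [])),
            product_keywords=frozenset(entry.get("product_keywords", [])),
            required_gene_sets=tuple(
                frozenset(s) for s in entry.get("required_gene_sets", [])
            ),
        ))
    return classes, list(raw.get("qualifier_blacklist", []))


def _keyword_matches(product: str, keyword: str, blacklist: Iterable[str]) -> bool:
    """Whole-word, case-insensitive keyword match with qualifier guards.

    The keyword must appear with no word character or hyphen butting against
    either end (so "tryptophanase" does not match "tryptophanase-like"), and
    the following word must not be a blacklisted qualifier.
    """
    pattern = rf"(?<![\w-]){re.escape(keyword)}(?![\w-])"
    match = re.search(pattern, product, flags=re.IGNORECASE)
    if match is None:
        return False
    trailing = product[match.end():].lstrip(" ,;:")
    next_word = trailing.split()[0].lower() if trailing.split() else ""
    return next_word not in {w.lower() for w in blacklist}


def scan_synthases(
    genome: SpeciesGenome,
    classes: Iterable[SignalClass] | None = None,
    blacklist: Iterable[str] | None = None,
) -> list[SynthaseCall]:
    """Detect synthase genes for every signal class in one genome."""
    if classes is None:
        classes, default_blacklist = load_lexicon()
        blacklist = blacklist if blacklist is not None else default_blacklist
    blacklist = list(blacklist or [])

    calls: list[SynthaseCall] = []
    genes = sorted(genome.genes.values(), key=lambda g: g.locus_tag)
    names = {
        (g.gene_name or "").lower(): None for g in genes if g.gene_name
    }
    for signal in classes:
        if signal.is_multi_gene:
            lowered = {n.lower() for n in names}
            for gene_set in signal.required_gene_sets:
                wanted = {n.lower() for n in gene_set}
                if wanted <= lowered:
                    loci = tuple(sorted(
                        g.locus_tag for g in genes
                        if (g.gene_name or "").lower() in wanted
                    ))
                    calls.append(SynthaseCall(
                        genome.genome_id, signal.name, loci, "complete_gene_set"))
                    break
            continue
        gene_names = {n.lower() for n in signal.gene_names}
        for gene in genes:
            if (gene.gene_name or "").lower() in gene_names:
                calls.append(SynthaseCall(
                    genome.genome_id, signal.name, (gene.locus_tag,),
                    "gene_name_match"))
            elif any(
                _keyword_matches(gene.product, kw, blacklist)
                for kw in signal.product_keywords
            ):
                calls.append(SynthaseCall(
                    genome.genome_id, signal.name, (gene.locus_tag,),
                    "product_keyword_match"))
    return calls


@dataclass
class CensusTables:
    """Tabulated synthase census over a genome collection."""

    species_per_signal: pd.Series        # signal -> number of species
    signal_count_histogram: pd.Series    # k distinct signals -> n species
    luxS_copies: pd.Series               # genome_id -> luxS gene copy count

    def n_species_with_calls(self) -> int:
        return int(self.signal_count_histogram.sum())


def tabulate_census(
    calls: Iterable[SynthaseCall],
    genomes: Iterable[SpeciesGenome],
) -> CensusTables:
    """Per-signal species counts, per-species signal-type histogram and the
    AI-2 synthase (luxS) copy-number table."""
    calls = list(calls)
    genome_ids = [g.genome_id for g in genomes]

    by_genome: dict[str, list[SynthaseCall]] = {}
    for call in calls:
        by_genome.setdefault(call.genome_id, []).append(call)

    species_per_signal: dict[str, int] = {}
    histogram: dict[int, int] = {}
    luxs_copies: dict[str, int] = {}
    for genome_id in genome_ids:
        genome_calls = by_genome.get(genome_id, [])
        signals = {c.signal for c in genome_calls}
        for signal in signals:
            species_per_signal[signal] = species_per_signal.get(signal, 0) + 1
        if signals:
            histogram[len(signals)] = histogram.get(len(signals), 0) + 1
        copies = sum(
            len(c.locus_tags) for c in genome_calls if c.signal == "AI-2")
        if copies:
            luxs_copies[genome_id] = copies

    return CensusTables(
        species_per_signal=pd.Series(species_per_signal, dtype=int).sort_index(),
        signal_count_histogram=pd.Series(histogram, dtype=int).sort_index(),
        luxS_copies=pd.Series(luxs_copies, dtype=int).sort_index(),
    )


def genus_presence_matrix(
    calls: Iterable[SynthaseCall],
    genomes: list[SpeciesGenome],
    mode: str = "union",
) -> pd.DataFrame:
    """Genus x signal boolean presence matrix.

    ``mode="union"`` (default) marks a signal present if any genus member
    carries a call; ``mode="representative"`` consults only the genus
    representative chosen by :func:`select_genus_representative`.
    """
    if mode not in {"union", "representative"}:
        raise ValueError(f"unknown mode {mode!r}")
    calls = list(calls)
    signals = sorted({c.signal for c in calls})
    by_genome: dict[str, set[str]] = {}
    for call in calls:
        by_genome.setdefault(call.genome_id, set()).add(call.signal)

    grouped = group_by_genus(genomes)
    rows = {}
    for genus in sorted(grouped):
        members = grouped[genus]
        if mode == "representative":
            members = [select_genus_representative(members)]
        present: set[str] = set()
        for member in members:
            present |= by_genome.get(member.genome_id, set())
        rows[genus] = [signal in present for signal in signals]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=signals).sort_index()


def calls_to_frame(calls: Iterable[SynthaseCall]) -> pd.DataFrame:
    """Flatten synthase calls to a tidy table (one row per call)."""
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "signal": c.signal,
                "locus_tags": ",".join(c.locus_tags),
                "evidence": c.evidence,
            }
            for c in sorted(calls, key=lambda c: (c.genome_id, c.signal, c.locus_tags))
        ],
        columns=["genome_id", "signal", "locus_tags", "evidence"],
    )
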