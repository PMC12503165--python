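"""Detection of the four AI-2 receptor types.

Four routes, mirroring how each receptor class is recognisable from an
annotated genome:

* **LuxP** — annotation keyword search (periplasmic borate-form receptor).
* **LsrB** — annotation keyword/gene-name search, accepted as *functional*
  only when the genome carries an intact ``lsrACDB`` transporter operon
  (same contig, same strand, bounded intergenic gaps) plus the regulator
  genes ``lsrK`` and ``lsrR`` anywhere in the genome.
* **dCache_1** — profile-HMM search (PF02743), restriction to transmembrane
  proteins with the domain between two predicted membrane helices, then the
  five-residue conservation screen against PctA numbering
  (R126, W128, Y144, D146, D173).
* **GAPES1** — profile-HMM search (PF17155) followed by the two-residue
  screen against YeaJ numbering (Y210, D239); no transmembrane filter by
  default (a flag enables it).

Residue mapping is done by deterministic global pairwise alignment
(BLOSUM62, gap open 10, extend 0.5) of the candidate domain against the
reference domain window; an MSA mode (external ``mafft``) is available and
is what the conservation profile uses.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

import pyhmmer

from .genomes import GeneRecord, SpeciesGenome
from .profiles import (
    ALPHABET,
    DCACHE_ACC,
    GAPES1_ACC,
    DomainProfile,
    sensory_registry,
)
from .references import ReferenceResidueSet, default_refsets

LUXP_KEYWORD = "Autoinducer 2-binding periplasmic protein LuxP"
LSRB_KEYWORD = "Autoinducer 2-binding protein LsrB"


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain envelope on a protein (1-based inclusive)."""

    genome_id: str
    locus_tag: str
    accession: str
    env_start: int
    env_end: int
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(f"bad envelope {self.env_start}-{self.env_end}")


@dataclass(frozen=True)
class ResidueScreenResult:
    """Mapping of the numbered reference positions onto one candidate.

    ``mapped`` holds ``(reference_position, candidate_position or None,
    observed residue or '-')`` per screened position; candidate positions
    are 1-based within the candidate sequence that was aligned.
    """

    locus_tag: str
    reference_name: str
    mapped: tuple[tuple[int, int | None, str], ...]
    all_conserved: bool


@dataclass(frozen=True)
class ReceptorCall:
    """One protein judged an AI-2 receptor."""

    genome_id: str
    locus_tag: str
    receptor_type: str  # LuxP | LsrB | dCache_1 | GAPES1
    evidence: Mapping[str, object] = field(default_factory=dict)
    screen: ResidueScreenResult | None = None
    functional_module: str | None = None

    def __post_init__(self) -> None:
        if self.receptor_type in {"dCache_1", "GAPES1"}:
            if self.screen is None or not self.screen.all_conserved:
                raise ValueError(
                    f"{self.receptor_type} call for {self.locus_tag} lacks a "
                    "passing residue screen")
        if self.receptor_type == "LsrB" and "operon_loci" not in self.evidence:
            raise ValueError(f"LsrB call for {self.locus_tag} lacks operon evidence")


# ---------------------------------------------------------------------------
# LuxP and functional LsrB
# ---------------------------------------------------------------------------

def find_luxP(genome: SpeciesGenome, keyword: str = LUXP_KEYWORD) -> list[ReceptorCall]:
    """LuxP calls: one per gene whose product contains the LuxP keyword
    (case-insensitive)."""
    calls = []
    for gene in sorted(genome.genes.values(), key=lambda g: g.locus_tag):
        if keyword.lower() in gene.product.lower():
            calls.append(ReceptorCall(
                genome_id=genome.genome_id,
                locus_tag=gene.locus_tag,
                receptor_type="LuxP",
                evidence={"keyword": keyword, "product": gene.product},
            ))
    return calls


@dataclass(frozen=True)
class OperonParams:
    """Geometry of an acceptable ``lsrACDB`` gene block."""

    max_intergenic_gap: int = 500      # bp between consecutive member genes
    max_intervening_genes: int = 0     # non-member genes between members
    require_same_strand: bool = True
    strict_order: bool = False         # require A-C-D-B along the strand

    def __post_init__(self) -> None:
        if self.max_intergenic_gap < 0 or self.max_intervening_genes < 0:
            raise ValueError("operon parameters must be non-negative")


_LSR_MEMBERS = ("lsrA", "lsrC", "lsrD", "lsrB")


def _genes_named(genome: SpeciesGenome, name: str) -> list[GeneRecord]:
    return [
        g for g in genome.genes.values()
        if (g.gene_name or "").lower() == name.lower()
    ]


def _valid_lsr_block(
    members: dict[str, GeneRecord],
    genome: SpeciesGenome,
    params: OperonParams,
) -> bool:
    genes = list(members.values())
    contigs = {g.contig for g in genes}
    if len(contigs) != 1:
        return False
    if params.require_same_strand and len({g.strand for g in genes}) != 1:
        return False
    ordered = sorted(genes, key=lambda g: g.start)
    member_tags = {g.locus_tag for g in genes}
    contig_genes = genome.genes_on_contig(genes[0].contig)
    for left, right in zip(ordered, ordered[1:]):
        gap = right.start - left.end - 1
        if gap > params.max_intergenic_gap:
            return False
        intervening = sum(
            1 for g in contig_genes
            if left.start < g.start < right.start
            and g.locus_tag not in member_tags
        )
        if intervening > params.max_intervening_genes:
            return False
    if params.strict_order:
        by_name = {g.locus_tag: name for name, g in members.items()}
        observed = [by_name[g.locus_tag] for g in ordered]
        expected = list(_LSR_MEMBERS)
        if ordered[0].strand == "-":
            expected = expected[::-1]
        if observed != expected:
            return False
    return True


def find_functional_lsrB(
    genome: SpeciesGenome,
    params: OperonParams = OperonParams(),
) -> list[ReceptorCall]:
    """Functional LsrB calls.

    An ``lsrB`` annotation (gene name or product keyword) is accepted only
    when (a) one gene each of ``lsrA/C/D/B`` forms a block satisfying
    ``params`` and containing that lsrB, and (b) ``lsrK`` and ``lsrR`` occur
    anywhere in the genome.
    """
    lsrb_genes = {
        g.locus_tag: g
        for g in genome.genes.values()
        if (g.gene_name or "").lower() == "lsrb"
        or LSRB_KEYWORD.lower() in g.product.lower()
    }
    if not lsrb_genes:
        return []
    lsrk = _genes_named(genome, "lsrK")
    lsrr = _genes_named(genome, "lsrR")
    if not (lsrk and lsrr):
        return []

    candidates = {name: _genes_named(genome, name) for name in _LSR_MEMBERS}
    calls = []
    for locus_tag, lsrb in sorted(lsrb_genes.items()):
        found = None
        for g_a in candidates["lsrA"]:
            for g_c in candidates["lsrC"]:
                for g_d in candidates["lsrD"]:
                    block = {"lsrA": g_a, "lsrC": g_c, "lsrD": g_d, "lsrB": lsrb}
                    if _valid_lsr_block(block, genome, params):
                        found = block
                        break
                if found:
                    break
            if found:
                break
        if found:
            calls.append(ReceptorCall(
                genome_id=genome.genome_id,
                locus_tag=locus_tag,
                receptor_type="LsrB",
                evidence={
                    "operon_loci": tuple(
                        found[name].locus_tag for name in _LSR_MEMBERS),
                    "lsrK": tuple(sorted(g.locus_tag for g in lsrk)),
                    "lsrR": tuple(sorted(g.locus_tag for g in lsrr)),
                    "params": params,
                },
            ))
    return calls


# ---------------------------------------------------------------------------
# Profile-HMM domain search
# ---------------------------------------------------------------------------

def scan_domains(
    proteins: Mapping[str, str],
    registry: Mapping[str, DomainProfile] | None = None,
    genome_id: str = "",
) -> list[DomainHit]:
    """Search every registered profile against a protein set.

    A protein may carry several envelopes of the same accession.  Synthetic
    profiles use a conditional E-value threshold; profiles with gathering
    cutoffs are searched in gathering-cutoff mode.
    """
    if registry is None:
        registry = sensory_registry()
    items = sorted((lt, s) for lt, s in proteins.items() if s)
    if not items:
        return []
    block = pyhmmer.easel.DigitalSequenceBlock(ALPHABET, [
        pyhmmer.easel.TextSequence(name=lt.encode(), sequence=s).digitize(ALPHABET)
        for lt, s in items
    ])
    hits_out: list[DomainHit] = []
    for accession in sorted(registry):
        profile = registry[accession]
        cutoffs = (
            "gathering" if profile.threshold_mode == "gathering_cutoff" else None
        )
        pipeline = pyhmmer.plan7.Pipeline(ALPHABET, bit_cutoffs=cutoffs)
        for hit in pipeline.search_hmm(profile.hmm, block):
            for domain in hit.domains.reported:
                if (profile.threshold_mode == "evalue"
                        and domain.i_evalue > profile.evalue):
                    continue
                hits_out.append(DomainHit(
                    genome_id=genome_id,
                    locus_tag=(hit.name.decode()
                               if isinstance(hit.name, bytes) else str(hit.name)),
                    accession=profile.accession,
                    env_start=domain.env_from,
                    env_end=domain.env_to,
                    bit_score=float(domain.score),
                    e_value=float(domain.i_evalue),
                ))
    return sorted(
        hits_out, key=lambda h: (h.locus_tag, h.accession, h.env_start))


# ---------------------------------------------------------------------------
# Transmembrane topology
# ---------------------------------------------------------------------------

from .data.synthetic import window_hydropathy  # noqa: E402


def predict_tm_segments(
    sequence: str, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Hydropathy sliding-window transmembrane segments (1-based inclusive).

    Windows whose mean Kyte-Doolittle hydropathy reaches ``threshold`` are
    marked and overlapping windows merged.  Sequences shorter than the
    window yield no segments.  Deterministic by construction.
    """
    if len(sequence) < window:
        return []
    means = window_hydropathy(sequence, window)
    segments: list[tuple[int, int]] = []
    for i, mean in enumerate(means):
        if mean < threshold:
            continue
        start, end = i + 1, i + window
        if segments and start <= segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))
    return segments


@dataclass(frozen=True)
class TopologyParams:
    """Rule for keeping domain hits on transmembrane proteins."""

    min_segments: int = 2
    require_flanking: bool = True   # envelope between two TM segments
    flank_margin: int = 10          # bp of overlap tolerance at the edges
    permissive: bool = False        # keep any protein with >=1 TM segment


def filter_transmembrane(
    hits: Iterable[DomainHit],
    proteins: Mapping[str, str],
    params: TopologyParams = TopologyParams(),
    segments_by_locus: Mapping[str, list[tuple[int, int]]] | None = None,
) -> list[DomainHit]:
    """Keep hits whose protein shows periplasmic-sensor topology.

    Default: at least two predicted TM segments with the domain envelope
    lying between two of them (``flank_margin`` residues of edge overlap
    tolerated).  ``permissive`` keeps any hit on a protein with one or more
    segments.  ``segments_by_locus`` lets callers supply precomputed TM
    tables from an external predictor.
    """
    cache: dict[str, list[tuple[int, int]]] = {}

    def segments_of(locus: str) -> list[tuple[int, int]]:
        if segments_by_locus is not None:
            return list(segments_by_locus.get(locus, []))
        if locus not in cache:
            cache[locus] = predict_tm_segments(proteins[locus])
        return cache[locus]

    kept = []
    for hit in hits:
        segments = segments_of(hit.locus_tag)
        if params.permissive:
            if segments:
                kept.append(hit)
            continue
        if len(segments) < params.min_segments:
            continue
        if not params.require_flanking:
            kept.append(hit)
            continue
        m = params.flank_margin
        before = any(
            end <= hit.env_start + m and start < hit.env_start
            for start, end in segments
        )
        after = any(
            start >= hit.env_end - m and end > hit.env_end
            for start, end in segments
        )
        if before and after:
            kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Residue mapping and screening
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def map_reference_positions(
    candidate_domain_seq: str,
    refset: ReferenceResidueSet,
    locus_tag: str = "",
) -> ResidueScreenResult:
    """Map the reference's numbered positions onto a candidate domain.

    Deterministic global pairwise alignment of the candidate against the
    reference domain window (BLOSUM62, gap open 10, extend 0.5; the first
    optimal traceback reported by the aligner is used, which is stable for
    a given pair).  Reference positions aligned to a candidate gap map to
    ``None``/``'-'`` and fail the screen.
    """
    if not candidate_domain_seq:
        raise ValueError("empty candidate sequence")
    aligner = _make_aligner()
    alignment = aligner.align(refset.domain_sequence, candidate_domain_seq)[0]
    ref_blocks, cand_blocks = alignment.aligned
    ref_to_cand: dict[int, int] = {}
    for (r0, r1), (c0, c1) in zip(ref_blocks, cand_blocks):
        for offset in range(r1 - r0):
            ref_to_cand[r0 + offset] = c0 + offset

    mapped = []
    conserved = True
    for pos, expected in refset.numbered_positions:
        w0 = pos - refset.domain_window[0]  # 0-based within the window
        cand_idx = ref_to_cand.get(w0)
        if cand_idx is None:
            mapped.append((pos, None, "-"))
            conserved = False
        else:
            observed = candidate_domain_seq[cand_idx]
            mapped.append((pos, cand_idx + 1, observed))
            if observed != expected:
                conserved = False
    return ResidueScreenResult(
        locus_tag=locus_tag,
        reference_name=refset.reference_name,
        mapped=tuple(mapped),
        all_conserved=conserved,
    )


def screen_conserved_residues(
    mapping: ResidueScreenResult, refset: ReferenceResidueSet
) -> ResidueScreenResult:
    """Recompute the pass/fail verdict of a mapping against the reference
    residue set (gap at any screened position fails)."""
    expected = dict(refset.numbered_positions)
    conserved = all(
        cand_pos is not None and observed == expected[pos]
        for pos, cand_pos, observed in mapping.mapped
    )
    if conserved == mapping.all_conserved:
        return mapping
    return ResidueScreenResult(
        mapping.locus_tag, mapping.reference_name, mapping.mapped, conserved)


def _run_mafft(sequences: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Align (name, seq) records with mafft, preserving input order."""
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError(
            "mafft executable not found; MSA mode needs it on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        with open(infile, "w") as fh:
            for name, seq in sequences:
                fh.write(f">{name}\n{seq}\n")
        result = subprocess.run(
            [mafft, "--auto", "--quiet", str(infile)],
            capture_output=True, text=True, check=True,
        )
    aligned = []
    name, chunks = None, []
    for line in result.stdout.splitlines():
        if line.startswith(">"):
            if name is not None:
                aligned.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        aligned.append((name, "".join(chunks)))
    return aligned


def map_reference_positions_msa(
    candidates: Mapping[str, str],
    refset: ReferenceResidueSet,
) -> dict[str, ResidueScreenResult]:
    """MSA-mode mapping: one progressive alignment of reference plus all
    candidates, then column lookup of each numbered reference position."""
    if not candidates:
        return {}
    records = [("__reference__", refset.domain_sequence)] + [
        (lt, seq) for lt, seq in sorted(candidates.items())
    ]
    aligned = dict(_run_mafft(records))
    ref_row = aligned["__reference__"]
    # column index of each reference window position
    col_of: dict[int, int] = {}
    ref_pos = 0
    for col, char in enumerate(ref_row):
        if char != "-":
            ref_pos += 1
            col_of[ref_pos] = col

    expected = dict(refset.numbered_positions)
    results = {}
    for locus, _ in sorted(candidates.items()):
        row = aligned[locus]
        mapped = []
        conserved = True
        for pos, _aa in refset.numbered_positions:
            w = pos - refset.domain_window[0] + 1
            col = col_of[w]
            char = row[col]
            if char == "-":
                mapped.append((pos, None, "-"))
                conserved = False
            else:
                cand_pos = sum(1 for c in row[:col + 1] if c != "-")
                mapped.append((pos, cand_pos, char.upper()))
                if char.upper() != expected[pos]:
                    conserved = False
        results[locus] = ResidueScreenResult(
            locus_tag=locus,
            reference_name=refset.reference_name,
            mapped=tuple(mapped),
            all_conserved=conserved,
        )
    return results


def call_residue_screened_receptors(
    hits: Iterable[DomainHit],
    proteins: Mapping[str, str],
    refsets: Mapping[str, ReferenceResidueSet] | None = None,
    mode: str = "pairwise",
) -> list[ReceptorCall]:
    """dCache_1/GAPES1 receptor calls from residue-screened domain hits.

    One call per hit whose extracted envelope passes the conserved-residue
    screen of its receptor type; the screen result rides on the call.
    """
    if refsets is None:
        refsets = default_refsets()
    type_of = {DCACHE_ACC: "dCache_1", GAPES1_ACC: "GAPES1"}
    hits = [h for h in hits if h.accession in type_of]

    screens: dict[tuple[str, str, int], ResidueScreenResult] = {}
    if mode == "pairwise":
        for hit in hits:
            candidate = proteins[hit.locus_tag][hit.env_start - 1:hit.env_end]
            screens[(hit.locus_tag, hit.accession, hit.env_start)] = (
                map_reference_positions(
                    candidate, refsets[type_of[hit.accession]], hit.locus_tag))
    elif mode == "msa":
        for accession in (DCACHE_ACC, GAPES1_ACC):
            batch = {
                f"{h.locus_tag}|{h.env_start}":
                    proteins[h.locus_tag][h.env_start - 1:h.env_end]
                for h in hits if h.accession == accession
            }
            if not batch:
                continue
            for key, screen in map_reference_positions_msa(
                    batch, refsets[type_of[accession]]).items():
                locus, env_start = key.rsplit("|", 1)
                screens[(locus, accession, int(env_start))] = screen
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")

    calls = []
    for hit in hits:
        screen = screens[(hit.locus_tag, hit.accession, hit.env_start)]
        if not screen.all_conserved:
            continue
        calls.append(ReceptorCall(
            genome_id=hit.genome_id,
            locus_tag=hit.locus_tag,
            receptor_type=type_of[hit.accession],
            evidence={
                "accession": hit.accession,
                "envelope": (hit.env_start, hit.env_end),
                "bit_score": hit.bit_score,
                "e_value": hit.e_value,
                "map_mode": mode,
            },
            screen=screen,
        ))
    return calls


def conservation_profile(
    candidate_domains: Mapping[str, str],
    refset: ReferenceResidueSet,
) -> pd.DataFrame:
    """Per-reference-position residue frequencies across candidate domains.

    All candidates are aligned together with the reference (MSA mode);
    columns gapped in the reference are dropped so rows are indexed by
    full-length reference position.  Frequencies (including the ``gap``
    column) sum to 1 per position.
    """
    if len(candidate_domains) < 2:
        raise ValueError("need at least two candidate domains")
    records = [("__reference__", refset.domain_sequence)] + [
        (lt, seq) for lt, seq in sorted(candidate_domains.items())
    ]
    aligned = dict(_run_mafft(records))
    ref_row = aligned.pop("__reference__")
    n = len(aligned)

    window_start = refset.domain_window[0]
    rows = []
    index = []
    ref_pos = 0
    residues = sorted(set("ACDEFGHIKLMNPQRSTVWY"))
    for col, char in enumerate(ref_row):
        if char == "-":
            continue
        ref_pos += 1
        counts = {aa: 0 for aa in residues}
        counts["gap"] = 0
        for row in aligned.values():
            c = row[col].upper()
            if c == "-":
                counts["gap"] += 1
            else:
                counts[c] = counts.get(c, 0) + 1
        index.append(window_start + ref_pos - 1)
        rows.append({k: v / n for k, v in counts.items()})
    frame = pd.DataFrame(rows, index=pd.Index(index, name="reference_position"))
    return frame


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    """Flatten domain hits to a tidy table."""
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id, "locus_tag": h.locus_tag,
                "accession": h.accession, "env_start": h.env_start,
                "env_end": h.env_end, "bit_score": h.bit_score,
                "e_value": h.e_value,
            }
            for h in hits
        ],
        columns=["genome_id", "locus_tag", "accession", "env_start",
                 "env_end", "bit_score", "e_value"],
    )


def calls_to_frame(calls: Iterable[ReceptorCall]) -> pd.DataFrame:
    """Flatten receptor calls to a tidy table."""
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "locus_tag": c.locus_tag,
                "receptor_type": c.receptor_type,
                "functional_module": c.functional_module or "",
                "all_conserved": "" if c.screen is None else c.screen.all_conserved,
            }
            for c in sorted(
                calls, key=lambda c: (c.genome_id, c.receptor_type, c.locus_tag))
        ],
        columns=["genome_id", "locus_tag", "receptor_type",
                 "functional_module", "all_conserved"],
    )
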