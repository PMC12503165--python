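"""Metatranscriptome expression of AI-2 synthase and receptor genes.

Consumes featureCounts-style gene count tables, computes TPM with
genome-wide denominators, and applies the expression thresholds used to
decide which species express the AI-2 synthase (luxS) and/or its receptors
in each sample state (healthy vs unhealthy): a gene is *expressed* when its
aggregated TPM exceeds 0, and *highly expressed* when it exceeds the
per-kind threshold (luxS 0.2, LsrB 0.1, dCache_1 0.01 TPM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionThresholds:
    """TPM thresholds for 'expressed' and per-kind 'high' flags."""

    luxS_high: float = 0.2
    lsrB_high: float = 0.1
    dcache_high: float = 0.01
    gapes1_high: float = 0.01
    expressed: float = 0.0  # strict: aggregated TPM must exceed this

    def __post_init__(self) -> None:
        if min(self.luxS_high, self.lsrB_high, self.dcache_high,
               self.gapes1_high, self.expressed) < 0:
            raise ValueError("thresholds must be non-negative")

    def high_for(self, kind: str) -> float:
        return {
            "luxS": self.luxS_high,
            "LsrB": self.lsrB_high,
            "dCache_1": self.dcache_high,
            "GAPES1": self.gapes1_high,
            # LuxP has no stated high threshold; reuse the receptor floor.
            "LuxP": self.dcache_high,
        }[kind]


@dataclass
class CountTable:
    """Gene-level read counts with per-gene lengths.

    ``counts`` is genes x samples (non-negative integers); ``lengths`` is
    the per-gene length in bp; the index identifies genes as
    ``genome_id|locus_tag`` strings (or any unique gene key).
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            bad = self.lengths[self.lengths <= 0].index.tolist()
            raise ValueError(f"non-positive gene lengths: {bad[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise ValueError("lengths missing for some genes")


def read_featurecounts(path: str | Path) -> CountTable:
    """Read a featureCounts output TSV.

    Expects the standard columns ``Geneid, Chr, Start, End, Strand,
    Length`` followed by one column per sample; comment lines starting with
    ``#`` are skipped.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]
    missing = [c for c in meta_cols if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing featureCounts columns {missing}")
    table = table.set_index("Geneid")
    counts = table.drop(columns=[c for c in meta_cols if c != "Geneid"])
    return CountTable(counts=counts.astype(int), lengths=table["Length"].astype(float))


def compute_tpm(table: CountTable) -> pd.DataFrame:
    """Transcripts per million, genome-wide denominators.

    ``TPM(g, s) = (count/length_kb) / sum_genes(count/length_kb) * 1e6``.
    Every sample with any reads sums to 1e6; an all-zero sample yields
    all-zero TPM with a warning.
    """
    length_kb = table.lengths / 1000.0
    rate = table.counts.div(length_kb, axis=0)
    totals = rate.sum(axis=0)
    zero_samples = totals[totals == 0].index.tolist()
    if zero_samples:
        warnings.warn(
            f"samples with no reads, TPM set to 0: {zero_samples}",
            RuntimeWarning, stacklevel=2)
    safe_totals = totals.replace(0, np.nan)
    tpm = rate.div(safe_totals, axis=1) * 1e6
    return tpm.fillna(0.0)


@dataclass(frozen=True)
class GeneAssignment:
    """Maps one gene to its species and QS role for expression flagging."""

    gene_id: str     # index key in the count table
    genome_id: str
    kind: str        # luxS | LuxP | LsrB | dCache_1 | GAPES1


def summarize_expression(
    tpm: pd.DataFrame,
    assignments: Iterable[GeneAssignment],
    sample_states: Mapping[str, str],
    thresholds: ExpressionThresholds = ExpressionThresholds(),
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-species, per-state expression flags.

    TPM is aggregated over each state's samples (``mean`` by default,
    ``max`` optionally) and per-gene aggregates are summed within a species
    and kind.  Output rows: (genome_id, state) with columns
    ``expressed_<kind>``, ``high_<kind>`` and ``coexpression`` (synthase and
    at least one receptor kind expressed in the same state).
    """
    if aggregation not in {"mean", "max"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    states = sorted(set(sample_states.values()))
    kinds = ["luxS", "LuxP", "LsrB", "dCache_1", "GAPES1"]

    by_species: dict[str, dict[str, list[str]]] = {}
    for a in assignments:
        if a.gene_id not in tpm.index:
            logger.warning("gene %s not present in TPM table; skipped", a.gene_id)
            continue
        by_species.setdefault(a.genome_id, {}).setdefault(a.kind, []).append(a.gene_id)

    rows = []
    for genome_id in sorted(by_species):
        for state in states:
            samples = [s for s, st in sample_states.items() if st == state]
            row: dict[str, object] = {"genome_id": genome_id, "state": state}
            expressed_kinds = set()
            for kind in kinds:
                gene_ids = by_species[genome_id].get(kind, [])
                if gene_ids:
                    sub = tpm.loc[gene_ids, samples]
                    agg = sub.mean(axis=1) if aggregation == "mean" else sub.max(axis=1)
                    level = float(agg.sum())
                else:
                    level = 0.0
                expressed = level > thresholds.expressed
                row[f"tpm_{kind}"] = level
                row[f"expressed_{kind}"] = expressed
                row[f"high_{kind}"] = level > thresholds.high_for(kind)
                if expressed:
                    expressed_kinds.add(kind)
            row["coexpression"] = (
                "luxS" in expressed_kinds
                and bool(expressed_kinds - {"luxS"})
            )
            rows.append(row)
    return pd.DataFrame(rows)


def compare_states(
    flags: pd.DataFrame,
    taxonomy_by_genome: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Healthy-vs-unhealthy comparison of expression flags.

    Returns per-state species counts for each flag category, the
    between-state difference, and (when taxonomy is supplied) per-family
    species tallies of co-expressing species per state.  A single-state
    input yields a partial result with a warning.
    """
    states = sorted(flags["state"].unique())
    if len(states) < 2:
        warnings.warn(
            f"only one state present ({states}); partial comparison",
            RuntimeWarning, stacklevel=2)

    flag_cols = [
        c for c in flags.columns
        if c.startswith(("expressed_", "high_")) or c == "coexpression"
    ]
    counts = flags.groupby("state")[flag_cols].sum().astype(int)
    result: dict[str, pd.DataFrame] = {"category_counts": counts}
    if len(states) >= 2:
        result["delta"] = (counts.loc[states[1]] - counts.loc[states[0]]).to_frame(
            name=f"{states[1]}-{states[0]}")

    if taxonomy_by_genome is not None:
        co = flags[flags["coexpression"]]
        tallies = (
            co.assign(family=co["genome_id"].map(taxonomy_by_genome))
            .groupby(["state", "family"]).size().rename("n_species")
            .reset_index()
        )
        result["family_tallies"] = tallies
    return result
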