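"""Profile-HMM registry for sensory and output domains.

Profiles are built at run time with pyhmmer from bundled synthetic seed
alignments (see :mod:`ai2net.data.synthetic`): the two sensory domains
(dCache_1 under accession PF02743, GAPES1 under PF17155, seeded from the
bundled reference ligand-binding domains) and the output-domain repertoire
used for functional typing.  External HMMER3 files can be loaded into the
same registry, in which case their gathering cutoffs are honoured;
synthetic profiles have no cutoffs and use a conditional E-value threshold
(default 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import pyhmmer

from .data import synthetic
from .references import ReferenceResidueSet, default_refsets

ALPHABET = pyhmmer.easel.Alphabet.amino()

DCACHE_ACC = "PF02743"
GAPES1_ACC = "PF17155"

DEFAULT_EVALUE = 1e-5


@dataclass(frozen=True)
class DomainProfile:
    """One registered profile HMM with its reporting threshold."""

    accession: str
    name: str
    hmm: pyhmmer.plan7.HMM
    threshold_mode: str = "evalue"  # or "gathering_cutoff"
    evalue: float = DEFAULT_EVALUE

    def __post_init__(self) -> None:
        if self.threshold_mode not in {"evalue", "gathering_cutoff"}:
            raise ValueError(f"bad threshold_mode {self.threshold_mode!r}")


def build_hmm(name: str, sequences: list[str]) -> pyhmmer.plan7.HMM:
    """Build an HMM from an ungapped seed alignment of equal-length rows."""
    msa = pyhmmer.easel.TextMSA(
        name=name.encode(),
        sequences=[
            pyhmmer.easel.TextSequence(name=f"{name}_{i}".encode(), sequence=s)
            for i, s in enumerate(sequences)
        ],
    )
    builder = pyhmmer.plan7.Builder(ALPHABET)
    background = pyhmmer.plan7.Background(ALPHABET)
    hmm, _, _ = builder.build_msa(msa.digitize(ALPHABET), background)
    return hmm


def _sensory_seed(refset: ReferenceResidueSet, tag: str) -> list[str]:
    # Screened positions (+/- 2 residues) are kept invariant in the seed so
    # the profile consensus retains them.
    forbidden = {
        p + d
        for p, _ in refset.window_positions()
        for d in range(-2, 3)
    }
    return synthetic.seed_alignment(
        refset.domain_sequence, tag=tag, forbidden=frozenset(forbidden))


@lru_cache(maxsize=1)
def default_registry() -> dict[str, DomainProfile]:
    """The default profile registry: sensory plus output domains."""
    refsets = default_refsets()
    registry: dict[str, DomainProfile] = {}
    registry[DCACHE_ACC] = DomainProfile(
        accession=DCACHE_ACC, name="dCache_1",
        hmm=build_hmm("dCache_1", _sensory_seed(refsets["dCache_1"], "dCache_1")),
    )
    registry[GAPES1_ACC] = DomainProfile(
        accession=GAPES1_ACC, name="GAPES1",
        hmm=build_hmm("GAPES1", _sensory_seed(refsets["GAPES1"], "GAPES1")),
    )
    for accession, (name, _) in synthetic.OUTPUT_DOMAINS.items():
        base = synthetic.domain_base(accession)
        registry[accession] = DomainProfile(
            accession=accession, name=name,
            hmm=build_hmm(name, synthetic.seed_alignment(base, tag=accession)),
        )
    return registry


def sensory_registry() -> dict[str, DomainProfile]:
    """Just the two sensory-domain profiles (receptor candidate search)."""
    registry = default_registry()
    return {acc: registry[acc] for acc in (DCACHE_ACC, GAPES1_ACC)}


def load_hmm_files(paths: list[str | Path]) -> dict[str, DomainProfile]:
    """Load external HMMER3 profile files into a registry."""
    registry: dict[str, DomainProfile] = {}
    for path in paths:
        with pyhmmer.plan7.HMMFile(str(path)) as handle:
            for hmm in handle:
                accession = (hmm.accession or hmm.name).decode().split(".")[0]
                if accession in registry:
                    raise ValueError(f"duplicate profile accession {accession}")
                has_ga = hmm.cutoffs.gathering_available()
                registry[accession] = DomainProfile(
                    accession=accession,
                    name=hmm.name.decode(),
                    hmm=hmm,
                    threshold_mode="gathering_cutoff" if has_ga else "evalue",
                )
    return registry
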