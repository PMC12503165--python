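"""Deterministic synthetic protein sequence material.

Everything in this module is synthetic: profile seed alignments and domain
"base" sequences are drawn from a seeded pseudo-random source with a typical
globular amino-acid composition, not taken from any sequence database.  They
exist so that domain profiles can be built at run time with pyhmmer and so
that the community generator can plant receptors whose domains those profiles
recognise, without any download.

Soluble stretches are rejection-sampled so that no Kyte-Doolittle window of
the transmembrane predictor's size crosses its threshold; transmembrane
helices are sampled from strongly hydrophobic residues only.  This keeps the
hydropathy-based topology filter unambiguous on generated proteins.
"""

from __future__ import annotations

import zlib

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Roughly UniProt-wide residue frequencies, renormalised over the 20 standard
# residues.
AA_FREQ = np.array([
    0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.096,
    0.024, 0.041, 0.047, 0.039, 0.055, 0.066, 0.054, 0.069, 0.011, 0.029,
])
AA_FREQ = AA_FREQ / AA_FREQ.sum()

# Kyte-Doolittle hydropathy scale.
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

TM_RESIDUES = "LIVFAM"
TM_WEIGHTS = np.array([0.30, 0.22, 0.20, 0.13, 0.10, 0.05])

#: Window/threshold the soluble sampler guards against; kept slightly below
#: the predictor's threshold (1.6) so sampled stretches have margin.
_GUARD_WINDOW = 19
_GUARD_LEVEL = 1.4

# Output-domain repertoire: field-standard accession -> (name, length).
# The profile HMMs built from these seeds are synthetic stand-ins that carry
# the accessions only as registry keys.
OUTPUT_DOMAINS = {
    "PF00015": ("MCPsignal", 140),
    "PF00990": ("GGDEF", 160),
    "PF00563": ("EAL", 170),
    "PF00512": ("HisKA", 65),
    "PF02518": ("HATPase_c", 110),
    "PF00481": ("PP2C", 180),
    "PF00069": ("Pkinase", 250),
    "PF00211": ("Guanylate_cyc", 160),
}


def _rng_for(tag: str, seed: int = 0) -> np.random.Generator:
    """Stable per-tag generator, independent of call order."""
    return np.random.default_rng((zlib.crc32(tag.encode()) + seed) % 2**31)


def window_hydropathy(seq: str, window: int = _GUARD_WINDOW) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy of each full window in ``seq``."""
    values = np.array([KD_SCALE[a] for a in seq], dtype=float)
    if len(values) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def sample_soluble(rng: np.random.Generator, n: int) -> str:
    """Sample an ``n``-residue globular stretch with no TM-like window."""
    seq = list(rng.choice(list(AMINO_ACIDS), size=n, p=AA_FREQ))
    for _ in range(200):
        means = window_hydropathy("".join(seq))
        offending = np.flatnonzero(means >= _GUARD_LEVEL)
        if offending.size == 0:
            return "".join(seq)
        start = int(offending[0])
        for i in range(start, start + _GUARD_WINDOW):
            seq[i] = rng.choice(list("DEKNQRST"))
    raise RuntimeError("soluble sampling did not converge")  # pragma: no cover


def sample_tm_helix(rng: np.random.Generator, n: int = 21) -> str:
    """Sample an ``n``-residue strongly hydrophobic membrane-spanning helix."""
    return "".join(rng.choice(list(TM_RESIDUES), size=n, p=TM_WEIGHTS))


def mutate(
    seq: str,
    rng: np.random.Generator,
    n_subs: int,
    forbidden: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Apply ``n_subs`` random substitutions, avoiding ``forbidden`` 1-based
    positions.  Substituted residues always differ from the original."""
    allowed = [i for i in range(len(seq)) if (i + 1) not in forbidden]
    sites = rng.choice(allowed, size=min(n_subs, len(allowed)), replace=False)
    out = list(seq)
    for i in sites:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def domain_base(accession: str) -> str:
    """The fixed synthetic base sequence of an output domain."""
    name, length = OUTPUT_DOMAINS[accession]
    return sample_soluble(_rng_for(f"base:{accession}:{name}"), length)


def seed_alignment(
    base: str,
    tag: str,
    n_seqs: int = 8,
    sub_rate: float = 0.08,
    forbidden: frozenset[int] | set[int] = frozenset(),
) -> list[str]:
    """An ungapped synthetic seed alignment: the base plus diverged variants."""
    rng = _rng_for(f"seed:{tag}")
    n_subs = max(1, int(round(sub_rate * len(base))))
    return [base] + [
        mutate(base, rng, n_subs, forbidden=forbidden) for _ in range(n_seqs - 1)
    ]


def domain_variant(accession: str, rng: np.random.Generator, sub_rate: float = 0.08) -> str:
    """A fresh diverged copy of an output-domain base (for planted proteins)."""
    base = domain_base(accession)
    return mutate(base, rng, max(1, int(round(sub_rate * len(base)))))
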