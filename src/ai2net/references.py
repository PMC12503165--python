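"""Reference receptors used for residue-numbered screening.

Two references anchor the conserved-residue screens:

* **PctA** (a *Pseudomonas aeruginosa* chemoreceptor) numbers the five
  positions whose residues an AI-2-binding dCache_1 domain must carry:
  R126, W128, Y144, D146 and D173.
* **YeaJ** (a *Salmonella* Typhimurium c-di-GMP synthase) numbers the two
  positions an AI-2-binding GAPES1 domain must carry: Y210 and D239.

The bundled sequences (``data/pcta_synthetic.fasta``,
``data/yeaj_synthetic.fasta``) are synthetic stand-ins constructed to carry
exactly those residues at those full-length positions, with the sensory
domain flanked by two transmembrane helices as in the real receptors.  All
numbering throughout the package is 1-based on the full-length reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

#: (position, expected residue) in full-length reference numbering.
PCTA_POSITIONS: tuple[tuple[int, str], ...] = (
    (126, "R"), (128, "W"), (144, "Y"), (146, "D"), (173, "D"),
)
YEAJ_POSITIONS: tuple[tuple[int, str], ...] = ((210, "Y"), (239, "D"))

#: 1-based inclusive span of the sensory domain within each reference.
PCTA_DOMAIN_WINDOW = (40, 280)   # dCache_1 ligand-binding domain
YEAJ_DOMAIN_WINDOW = (35, 300)   # GAPES1 ligand-binding domain


class ReferenceError(ValueError):
    """A bundled reference fixture violates its documented residue layout."""


@dataclass(frozen=True)
class ReferenceResidueSet:
    """A reference sequence plus the numbered residues its screen requires."""

    reference_name: str
    reference_sequence: str
    numbered_positions: tuple[tuple[int, str], ...]
    domain_window: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.domain_window
        if not (1 <= start <= end <= len(self.reference_sequence)):
            raise ReferenceError(
                f"{self.reference_name}: domain window {self.domain_window} "
                f"outside sequence of length {len(self.reference_sequence)}"
            )
        for pos, expected in self.numbered_positions:
            observed = self.reference_sequence[pos - 1]
            if observed != expected:
                raise ReferenceError(
                    f"{self.reference_name}: expected {expected} at position "
                    f"{pos}, found {observed}"
                )
            if not (start <= pos <= end):
                raise ReferenceError(
                    f"{self.reference_name}: screened position {pos} lies "
                    f"outside the domain window {self.domain_window}"
                )

    @property
    def domain_sequence(self) -> str:
        """The sensory-domain subsequence (the alignment target)."""
        start, end = self.domain_window
        return self.reference_sequence[start - 1:end]

    def window_positions(self) -> tuple[tuple[int, str], ...]:
        """Numbered positions re-expressed 1-based within the domain window."""
        start = self.domain_window[0]
        return tuple((pos - start + 1, aa) for pos, aa in self.numbered_positions)


def _read_bundled_fasta(filename: str) -> str:
    ref = resources.files("ai2net.data").joinpath(filename)
    with ref.open() as handle:
        record = next(SeqIO.parse(handle, "fasta"))
    return str(record.seq)


def load_pcta() -> ReferenceResidueSet:
    """The PctA stand-in with its five screened dCache_1 positions."""
    return ReferenceResidueSet(
        reference_name="PctA",
        reference_sequence=_read_bundled_fasta("pcta_synthetic.fasta"),
        numbered_positions=PCTA_POSITIONS,
        domain_window=PCTA_DOMAIN_WINDOW,
    )


def load_yeaj() -> ReferenceResidueSet:
    """The YeaJ stand-in with its two screened GAPES1 positions."""
    return ReferenceResidueSet(
        reference_name="YeaJ",
        reference_sequence=_read_bundled_fasta("yeaj_synthetic.fasta"),
        numbered_positions=YEAJ_POSITIONS,
        domain_window=YEAJ_DOMAIN_WINDOW,
    )


def default_refsets() -> dict[str, ReferenceResidueSet]:
    """Reference sets keyed by the receptor type they screen."""
    return {"dCache_1": load_pcta(), "GAPES1": load_yeaj()}
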