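"""Enumeration and validation of the xAALx pentapeptide library.

The screening library is built by double mutation of the two terminal
residues of the parent inhibitor TAALS, keeping the conserved central
A-A-L motif fixed.  With the full 20-letter amino-acid alphabet this
yields 20 x 20 = 400 unique pentapeptides of the form x-A-A-L-z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

#: Standard one-letter amino-acid alphabet, alphabetical.
STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Conserved core of the library: positions 2-4 (1-based) of every peptide.
CORE_MOTIF: str = "AAL"

PEPTIDE_LENGTH: int = 5


class PeptideError(ValueError):
    """Base class for peptide validation failures."""

    code = "invalid"


class PeptideLengthError(PeptideError):
    code = "length"


class PeptideAlphabetError(PeptideError):
    code = "alphabet"


class PeptideMotifError(PeptideError):
    code = "motif"


@dataclass(frozen=True)
class PeptideSequence:
    """A validated x-A-A-L-z library member, stored N-to-C.

    Termini of the synthesized peptides (free amine / free acid) are not
    modelled; the sequence is a plain one-letter string.
    """

    residues: str

    def __post_init__(self) -> None:
        validate_peptide(self.residues, _typed=False)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.residues


def validate_peptide(seq: str, *, _typed: bool = True) -> "PeptideSequence | str":
    """Validate ``seq`` as an xAALx library peptide.

    Raises
    ------
    PeptideLengthError
        if the sequence is not exactly 5 residues long.
    PeptideAlphabetError
        if any letter is outside the 20 standard amino acids.
    PeptideMotifError
        if positions 2-4 are not the conserved ``AAL`` core.
    """
    if not isinstance(seq, str):
        raise PeptideError(f"peptide must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if len(seq) != PEPTIDE_LENGTH:
        raise PeptideLengthError(
            f"peptide {seq!r} has length {len(seq)}, expected {PEPTIDE_LENGTH}"
        )
    bad = sorted(set(seq) - set(STANDARD_AMINO_ACIDS))
    if bad:
        raise PeptideAlphabetError(
            f"peptide {seq!r} contains non-standard letters {bad}"
        )
    if seq[1:4] != CORE_MOTIF:
        raise PeptideMotifError(
            f"peptide {seq!r} breaks the conserved {CORE_MOTIF} core at positions 2-4"
        )
    return PeptideSequence(seq) if _typed else seq


def enumerate_double_mutants(
    alphabet: Iterable[str] = STANDARD_AMINO_ACIDS,
) -> list[str]:
    """Enumerate every x-A-A-L-z double mutant over ``alphabet``.

    Returns ``|alphabet|**2`` unique sequences in lexicographic order.
    The parent TAALS is a member whenever T and S are in the alphabet.
    """
    letters = sorted(set(alphabet))
    if not letters:
        raise PeptideError("alphabet must be non-empty")
    bad = sorted(set(letters) - set(STANDARD_AMINO_ACIDS))
    if bad:
        raise PeptideAlphabetError(f"alphabet contains non-standard letters {bad}")
    return [f"{x}{CORE_MOTIF}{z}" for x in letters for z in letters]


def write_fasta(peptides: Sequence[str], path) -> None:
    """Write the library as FASTA, one record per peptide (id = sequence)."""
    records = [
        SeqRecord(Seq(validate_peptide(p, _typed=False)), id=p, description="")
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[str]:
    """Read a peptide library written by :func:`write_fasta`."""
    return [validate_peptide(str(rec.seq), _typed=False) for rec in SeqIO.parse(str(path), "fasta")]
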