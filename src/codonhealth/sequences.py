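"""Coding sequences: validation, codon access, translation, FASTA I/O.

A :class:`CodingSequence` is an in-frame DNA coding region. Recoding
workflows conventionally hold the first ``fixed_prefix_len`` codons constant
(the 5' region interacts with initiation and is kept byte-identical across
designs); 17 codons (51 nt) is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import DNA_ALPHABET, GeneticCode, standard_code

#: Default number of 5' codons held constant during recoding.
DEFAULT_FIXED_PREFIX = 17


class FrameError(ValueError):
    """Sequence length is not a positive multiple of 3."""


class AlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/T."""


class InternalStopError(ValueError):
    """A stop codon occurs before the final codon."""


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame DNA coding sequence with an optional fixed 5' prefix.

    Parameters
    ----------
    id : str
        Record identifier.
    nucleotides : str
        Uppercase DNA (A/C/G/T), length a positive multiple of 3.
    fixed_prefix_len : int
        Number of leading codons treated as immutable by recoders.
    validate_internal_stops : bool
        When True (default), reject stop codons anywhere before the final
        codon. Disable for pseudo-CDS concatenations (e.g. operons).
    """

    id: str
    nucleotides: str
    fixed_prefix_len: int = 0
    validate_internal_stops: bool = True
    code: GeneticCode = field(default_factory=standard_code, compare=False)

    def __post_init__(self):
        seq = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise FrameError(
                f"{self.id!r}: length {len(seq)} is not a positive multiple of 3"
            )
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(f"{self.id!r}: non-ACGT characters {sorted(bad)}")
        if len(seq) < 3 * self.fixed_prefix_len:
            raise ValueError(
                f"{self.id!r}: {len(seq) // 3} codons is shorter than the "
                f"fixed prefix ({self.fixed_prefix_len} codons)"
            )
        if self.validate_internal_stops:
            for i, codon in enumerate(self.codons[:-1]):
                if self.code.is_stop(codon):
                    raise InternalStopError(
                        f"{self.id!r}: internal stop {codon} at codon {i}"
                    )

    @property
    def codons(self) -> tuple[str, ...]:
        n = self.nucleotides
        return tuple(n[i : i + 3] for i in range(0, len(n), 3))

    @property
    def length_codons(self) -> int:
        return len(self.nucleotides) // 3

    @property
    def prefix_codons(self) -> tuple[str, ...]:
        return self.codons[: self.fixed_prefix_len]

    @property
    def variable_codons(self) -> tuple[str, ...]:
        """Codons after the fixed prefix (stop codon included if present)."""
        return self.codons[self.fixed_prefix_len :]

    @property
    def protein(self) -> str:
        """Amino-acid translation; a single trailing stop renders as ``*``."""
        return self.code.translate(self.nucleotides)

    def with_codons(self, codons: Iterable[str], id: str | None = None) -> "CodingSequence":
        return CodingSequence(
            id=id or self.id,
            nucleotides="".join(codons),
            fixed_prefix_len=self.fixed_prefix_len,
            validate_internal_stops=self.validate_internal_stops,
            code=self.code,
        )


def read_fasta(
    path: str | Path,
    fixed_prefix_len: int = 0,
    validate_internal_stops: bool = True,
) -> list[CodingSequence]:
    """Read a multi-record FASTA of coding sequences."""
    return [
        CodingSequence(
            id=rec.id,
            nucleotides=str(rec.seq),
            fixed_prefix_len=fixed_prefix_len,
            validate_internal_stops=validate_internal_stops,
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences to FASTA (wrapped lines, via biopython)."""
    records = [SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, amino-acid sequence) pairs from a protein FASTA."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
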