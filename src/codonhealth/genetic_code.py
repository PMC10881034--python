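"""Genetic-code tables: codon→amino-acid maps, synonymous families, degeneracy.

The standard bacterial/nuclear code has 61 sense codons for 20 amino acids
plus 3 stop codons. Synonymous "families" (all codons of one amino acid) are
the unit over which RSCU, relative adaptiveness and ENC are defined. The
table is data-driven so alternative codes could be supplied, but only the
standard code ships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

#: Nucleotide alphabet accepted in coding sequences (DNA, T not U).
DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon→amino acid map plus synonymous-family structure.

    Attributes
    ----------
    codon_to_aa : dict
        Maps each of the 61 sense codons to its one-letter amino acid.
    stop_codons : tuple
        The stop codons (not part of any family).
    families : dict
        Amino acid → ordered (lexicographic) tuple of synonymous codons.
    """

    codon_to_aa: dict[str, str]
    stop_codons: tuple[str, ...]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.families:
            fams: dict[str, list[str]] = {}
            for codon in sorted(self.codon_to_aa):
                fams.setdefault(self.codon_to_aa[codon], []).append(codon)
            object.__setattr__(
                self, "families", {aa: tuple(v) for aa, v in fams.items()}
            )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.families))

    def degeneracy(self, aa: str) -> int:
        """Number of synonymous codons for amino acid ``aa``."""
        return len(self.families[aa])

    def family_of(self, codon: str) -> tuple[str, ...]:
        """All synonymous codons of ``codon``'s amino acid."""
        return self.families[self.codon_to_aa[codon]]

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Map degeneracy k → amino acids with exactly k codons."""
        out: dict[int, list[str]] = {}
        for aa in self.amino_acids:
            out.setdefault(self.degeneracy(aa), []).append(aa)
        return {k: tuple(v) for k, v in sorted(out.items())}

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, nucleotides: str) -> str:
        """Translate an in-frame DNA string; stop codons render as ``*``."""
        aas = []
        for i in range(0, len(nucleotides) - 2, 3):
            codon = nucleotides[i : i + 3]
            aas.append("*" if self.is_stop(codon) else self.codon_to_aa[codon])
        return "".join(aas)


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI table 1), built from biopython."""
    table = CodonTable.unambiguous_dna_by_id[1]
    return GeneticCode(
        codon_to_aa=dict(table.forward_table),
        stop_codons=tuple(sorted(table.stop_codons)),
    )
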