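import pytest

import codonhealth as ch
from codonhealth import io as chio


@pytest.fixture(scope="session")
def code():
    return ch.standard_code()


@pytest.fixture(scope="session")
def chi_weights():
    """The bundled synthetic χ weight table (unique family maxima)."""
    return chio.read_weight_table(
        ch.bundled_path("chi_weights_synthetic.csv"), label="chi"
    )


@pytest.fixture(scope="session")
def cfp_protein():
    """The bundled synthetic CFP-type protein (238 aa)."""
    (name, seq), = ch.read_protein_fasta(ch.bundled_path("cfp_synthetic.fasta"))
    return seq


@pytest.fixture(scope="session")
def all_aa_parent(chi_weights):
    """An ENC=20-style CDS containing all 20 amino acids, 17-codon prefix.

    Built by maximal-index recoding of a protein that cycles through the
    full amino-acid alphabet, so the variable region uses exactly one codon
    per amino acid.
    """
    protein = "M" + "ACDEFGHIKLMNPQRSTVWY" * 3
    cds = ch.max_index_recode(protein, chi_weights)
    return ch.CodingSequence(
        id="parent", nucleotides=cds.nucleotides, fixed_prefix_len=17
    )


@pytest.fixture(scope="session")
def uniform_counts(code):
    """Codon counts with every synonymous codon of every family used 6×."""
    return ch.CodonCounts(
        counts={c: 6 for c in code.sense_codons}, total=6 * 61
    )
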