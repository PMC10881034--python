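"""codonhealth: codon-usage bias quantification and fitness-aware recoding.

Quantifies codon usage (RSCU, CAI, ENC, nTE), derives fitness-based codon
weights (the Codon Health Index, χ) from per-codon co-expression fitness
data, designs synonymous recodes (maximal, systematic sweeps, greedy
target-index, diverse sets, CUB matching), simulates translation with a
ribosome flow model, turns plate-reader curves into fitness metrics, and
maps codon-usage landscapes with PCA and clustering.
"""

from importlib import resources

from .genetic_code import GeneticCode, standard_code
from .sequences import (
    DEFAULT_FIXED_PREFIX,
    CodingSequence,
    read_fasta,
    read_protein_fasta,
    write_fasta,
)
from .bias import (
    CodonCounts,
    RSCUVector,
    WeightTable,
    count_codons,
    pooled_counts,
    rscu,
    relative_adaptiveness,
    geometric_index,
    enc,
    enc_from_homozygosity,
    nte_weights,
    expected_rscu,
)
from .chi import (
    ChiTable,
    FitnessRecord,
    compare_scales,
    derive_chi_weights,
    fitness_distance,
)
from .recode import (
    RecodeResult,
    RecodeSpec,
    achievable_range,
    diverse_recode_set,
    greedy_recode,
    match_cub_recode,
    max_index_recode,
    scientific_notation,
    synonymous_space_size,
    systematic_recodes,
)
from .rfm import ChunkProfile, RFMState, build_profile, initiation_sweep, steady_state
from .plates import (
    FitnessSummary,
    PlateTimeseries,
    auc_signal,
    common_window,
    fitness_summary,
    fold_change_summary,
)
from .landscape import (
    PCAResult,
    RSCUMatrix,
    aggregate_operons,
    hcluster,
    pca_rscu,
    rscu_matrix,
)
from .simulate import (
    FixtureConfig,
    random_cds,
    random_protein,
    random_weight_table,
    simulate_fitness_table,
    simulate_plate,
    synthetic_codon_times,
)

__version__ = "0.1.0"


def bundled_path(name: str):
    """Path to a bundled data file (synthetic stand-in tables/sequences)."""
    return resources.files("codonhealth.data").joinpath(name)
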