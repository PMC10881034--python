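"""Codon-usage bias indices: RSCU, relative adaptiveness, CAI-style geometric
means, the effective number of codons (ENC), and nTE weight construction.

All CAI-family indices share one scoring engine, :func:`geometric_index`: a
geometric mean of per-codon relative-adaptiveness weights W over a sequence.
What distinguishes CAI, χ, sTAI-referenced CAI and nTE is only the
:class:`WeightTable` supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .genetic_code import GeneticCode, standard_code
from .sequences import CodingSequence

#: Default substitute for W = 0 inside geometric means.
DEFAULT_EPSILON_FLOOR = 0.01


class ScoringError(ValueError):
    """A codon could not be scored (missing weight, absent family, ...)."""


@dataclass(frozen=True)
class CodonCounts:
    """Per-codon occurrence counts for a sequence (or pooled sequences)."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts do not sum to total")

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, x in other.counts.items():
            merged[c] = merged.get(c, 0) + x
        return CodonCounts(counts=merged, total=self.total + other.total)


@dataclass(frozen=True)
class RSCUVector:
    """Relative synonymous codon usage values, one per sense codon.

    ``absent_aas`` lists amino acids with zero observations — their codons
    have no defined RSCU (0/0) and are *flagged*, never silently zeroed.
    """

    values: Mapping[str, float]
    absent_aas: frozenset[str] = frozenset()

    def get(self, codon: str) -> float:
        return self.values[codon]


@dataclass(frozen=True)
class WeightTable:
    """Per-codon relative adaptiveness W ∈ [0, 1], family maximum = 1.

    Backs every geometric-mean index (CAI referenced to highly expressed
    genes, χ, sTAI, nTE). ``absent_aas`` flags families with undefined
    weights; ``epsilon_floor`` substitutes for W = 0 during scoring.
    """

    weights: Mapping[str, float]
    label: str = "W"
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR
    absent_aas: frozenset[str] = frozenset()

    def __post_init__(self):
        for codon, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {codon}: {w}")

    def get(self, codon: str) -> float | None:
        return self.weights.get(codon)

    def family_max_codon(self, code: GeneticCode, aa: str) -> str:
        fam = code.families[aa]
        return max(fam, key=lambda c: (self.weights.get(c, float("-inf")), c))


def count_codons(seq: CodingSequence) -> CodonCounts:
    """Count every codon of ``seq`` in reading frame 0."""
    counts: dict[str, int] = {}
    for codon in seq.codons:
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, total=seq.length_codons)


def pooled_counts(seqs: list[CodingSequence]) -> CodonCounts:
    """Sum codon counts over a sequence set (e.g. a reference gene set)."""
    total = CodonCounts(counts={}, total=0)
    for s in seqs:
        total = total + count_codons(s)
    return total


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> RSCUVector:
    """Relative synonymous codon usage.

    For amino acid i with n_i synonymous codons and X_ij observations of
    codon j, RSCU_ij = X_ij / ((1/n_i) Σ_j X_ij): observed over expected
    frequency under uniform synonymous usage. The family mean is 1 by
    construction; RSCU = 1 means no bias. Amino acids with no observations
    are flagged absent.
    """
    code = code or standard_code()
    values: dict[str, float] = {}
    absent: set[str] = set()
    for aa, fam in code.families.items():
        family_total = sum(counts.get(c) for c in fam)
        if family_total == 0:
            absent.add(aa)
            continue
        expected = family_total / len(fam)
        for c in fam:
            values[c] = counts.get(c) / expected
    return RSCUVector(values=values, absent_aas=frozenset(absent))


def relative_adaptiveness(
    rscu_vec: RSCUVector,
    code: GeneticCode | None = None,
    label: str = "W",
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR,
) -> WeightTable:
    """W_ij = RSCU_ij / max_j' RSCU_ij' within each synonymous family.

    The most-used codon of every present family gets W = 1. Absent families
    stay flagged and are excluded from downstream scoring.
    """
    code = code or standard_code()
    weights: dict[str, float] = {}
    for aa, fam in code.families.items():
        if aa in rscu_vec.absent_aas:
            continue
        fam_max = max(rscu_vec.get(c) for c in fam)
        for c in fam:
            weights[c] = rscu_vec.get(c) / fam_max
    return WeightTable(
        weights=weights,
        label=label,
        epsilon_floor=epsilon_floor,
        absent_aas=rscu_vec.absent_aas,
    )


def _scored_codons(
    codons: tuple[str, ...],
    code: GeneticCode,
    exclude_single_codon_aas: bool,
) -> list[str]:
    out = []
    for codon in codons:
        if code.is_stop(codon):
            continue  # stops are never scored
        if exclude_single_codon_aas and len(code.family_of(codon)) == 1:
            continue
        out.append(codon)
    return out


def geometric_index(
    seq: CodingSequence,
    w: WeightTable,
    *,
    exclude_single_codon_aas: bool = True,
    variable_region_only: bool = False,
    strict: bool = False,
    code: GeneticCode | None = None,
) -> float:
    """Geometric mean of W over a sequence's scored codons (CAI, χ, nTE...).

    Stop codons are always excluded. Single-codon amino acids (Met, Trp)
    carry W = 1 and are excluded by default, the classical Sharp–Li
    convention; including them changes only the effective L. Zero weights
    are floored at ``w.epsilon_floor`` unless ``strict``, in which case a
    zero or missing weight raises :class:`ScoringError`.
    """
    code = code or standard_code()
    codons = seq.variable_codons if variable_region_only else seq.codons
    scored = _scored_codons(codons, code, exclude_single_codon_aas)
    if not scored:
        raise ScoringError(f"{seq.id!r}: no scorable codons")
    log_sum = 0.0
    for codon in scored:
        wk = w.get(codon)
        if wk is None:
            raise ScoringError(
                f"{seq.id!r}: no weight for codon {codon} in table {w.label!r}"
            )
        if wk <= 0:
            if strict:
                raise ScoringError(
                    f"{seq.id!r}: zero weight for codon {codon} "
                    f"in table {w.label!r} (strict mode)"
                )
            wk = w.epsilon_floor
        log_sum += math.log(wk)
    return math.exp(log_sum / len(scored))


def enc_from_homozygosity(f2: float, f3: float, f4: float, f6: float) -> float:
    """Effective number of codons from class-mean homozygosities.

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where F_k is the mean probability,
    over amino acids with k synonymous codons, that two randomly drawn
    codons of that amino acid are identical. Ranges from 20 (one codon used
    exclusively per amino acid) to 61 (uniform synonymous usage).
    """
    return 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6


def _wright_homozygosity(counts: CodonCounts, fam: tuple[str, ...]) -> float | None:
    """Bias-corrected homozygosity F̂ = (n Σ p̂² − 1)/(n − 1); None if n ≤ 1."""
    n = sum(counts.get(c) for c in fam)
    if n <= 1:
        return None
    sum_p2 = sum((counts.get(c) / n) ** 2 for c in fam)
    return (n * sum_p2 - 1) / (n - 1)


def enc(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Effective number of codons of a sequence (Wright's estimator).

    Per amino acid, homozygosity uses the bias-corrected estimator; amino
    acids observed ≤ 1 time are dropped from their class mean. A degeneracy
    class with no estimable amino acid (or a non-positive class mean, which
    the corrected estimator can produce at extreme evenness) is imputed
    from the mean standardized homozygosity of the estimable classes,
    mapped onto that class's [1/k, 1] range, with a warning. The result is
    capped at 61: finite samples of perfectly uniform usage estimate
    F̂ < 1/k, which would otherwise push the formula above the theoretical
    maximum.
    """
    code = code or standard_code()
    class_means: dict[int, float | None] = {}
    for k, aas in code.degeneracy_classes().items():
        if k == 1:
            continue  # Met, Trp contribute the constant 2 in the ENC formula
        fs = []
        for aa in aas:
            f = _wright_homozygosity(counts, code.families[aa])
            if f is not None:
                fs.append(f)
        mean = sum(fs) / len(fs) if fs else None
        class_means[k] = mean if (mean is None or mean > 0) else None

    estimable = {k: f for k, f in class_means.items() if f is not None}
    if not estimable:
        raise ScoringError("no degeneracy class has an estimable homozygosity")
    if len(estimable) < len(class_means):
        # standardized homozygosity b in [0, 1]: F = 1/k + b (1 - 1/k)
        b = sum((f - 1 / k) / (1 - 1 / k) for k, f in estimable.items()) / len(
            estimable
        )
        b = min(max(b, 1e-9), 1.0)
        missing = sorted(set(class_means) - set(estimable))
        warnings.warn(
            f"ENC: degeneracy classes {missing} unestimable; imputed from "
            f"mean standardized homozygosity {b:.3f} of the other classes",
            stacklevel=2,
        )
        for k in missing:
            estimable[k] = 1 / k + b * (1 - 1 / k)

    value = enc_from_homozygosity(
        estimable[2], estimable[3], estimable[4], estimable[6]
    )
    return min(value, 61.0)


def nte_weights(
    stai: WeightTable,
    genome_freq: Mapping[str, float],
    *,
    strict: bool = True,
    epsilon: float = 1e-9,
    code: GeneticCode | None = None,
) -> WeightTable:
    """Normalized translational efficiency weights: tRNA supply over demand.

    nTE_ij = sTAI_ij / Frequency_ij per sense codon, where Frequency is the
    genomic codon frequency (demand). The raw ratios are then renormalized
    within each synonymous family to a maximum of 1 so they can serve as W
    values in :func:`geometric_index`.
    """
    code = code or standard_code()
    ratios: dict[str, float] = {}
    for codon in code.sense_codons:
        s = stai.get(codon)
        if s is None:
            raise ScoringError(f"sTAI weight missing for codon {codon}")
        if codon not in genome_freq:
            raise ScoringError(f"genomic frequency missing for codon {codon}")
        freq = genome_freq[codon]
        if freq <= 0:
            if strict:
                raise ScoringError(f"non-positive genomic frequency for {codon}")
            warnings.warn(f"nTE: frequency of {codon} floored at {epsilon}")
            freq = epsilon
        ratios[codon] = s / freq
    weights: dict[str, float] = {}
    for fam in code.families.values():
        fam_max = max(ratios[c] for c in fam)
        for c in fam:
            weights[c] = ratios[c] / fam_max
    return WeightTable(weights=weights, label="nTE")


def expected_rscu(
    w: WeightTable,
    mode: str = "perfect",
    code: GeneticCode | None = None,
) -> RSCUVector:
    """Expected RSCU of a gene perfectly adapted to a weight scale.

    ``perfect``: a gene that always uses each family's W = 1 codon — that
    codon's RSCU is the degeneracy n_i, all synonyms are 0. Requires a
    unique family maximum. ``proportional``: codon usage proportional to W,
    giving RSCU_ij = n_i W_ij / Σ_j' W_ij'.
    """
    code = code or standard_code()
    values: dict[str, float] = {}
    for aa, fam in code.families.items():
        if aa in w.absent_aas:
            continue
        ws = [w.weights[c] for c in fam]
        n_i = len(fam)
        if mode == "perfect":
            top = max(ws)
            ties = [c for c, wv in zip(fam, ws) if wv == top]
            if len(ties) > 1:
                raise ValueError(
                    f"tied family maxima for {aa}: {ties} — perfect-adaptation "
                    "RSCU is undefined"
                )
            for c, wv in zip(fam, ws):
                values[c] = float(n_i) if wv == top else 0.0
        elif mode == "proportional":
            total = sum(ws)
            for c, wv in zip(fam, ws):
                values[c] = n_i * wv / total
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return RSCUVector(values=values, absent_aas=w.absent_aas)
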