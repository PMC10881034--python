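"""Codon Health Index (χ): codon weights derived from co-expression fitness.

Each codon is assayed by recoding every instance of its amino acid in two
reporter genes (CFP, mCherry) and measuring the host's Co-Expression
Fitness fold change relative to the parent sequence — once per reporter,
giving a coordinate (c, m) per codon with the parent codons at (1, 1). A
codon's raw score is its Euclidean distance from the origin, so codons that
preserve fitness under *both* overexpression contexts score highest. The
distances are then normalized within each synonymous family (family max →
W = 1), exactly as relative adaptiveness is built from RSCU, yielding a
weight table scored with the usual geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .bias import RSCUVector, WeightTable, expected_rscu
from .genetic_code import GeneticCode, standard_code


@dataclass(frozen=True)
class FitnessRecord:
    """Normalized Co-Expression Fitness pair for one codon.

    ``c``: fold change under CFP overexpression; ``m``: under mCherry.
    Parent codons (the high-CAI scheme the fold changes are normalized to)
    sit at (1, 1) by construction.
    """

    codon: str
    c: float
    m: float
    is_parent: bool = False

    def __post_init__(self):
        if self.c < 0 or self.m < 0:
            raise ValueError(
                f"{self.codon}: fitness fold changes cannot be negative "
                f"(got c={self.c}, m={self.m})"
            )

    @property
    def distance(self) -> float:
        return fitness_distance(self.c, self.m)


@dataclass(frozen=True)
class ChiTable:
    """Per-codon fitness distances plus the derived χ weight table."""

    records: tuple[FitnessRecord, ...]
    weights: WeightTable

    @property
    def distances(self) -> dict[str, float]:
        return {r.codon: r.distance for r in self.records}


def fitness_distance(c: float, m: float) -> float:
    """Euclidean distance of a codon's (c, m) fitness pair from the origin.

    The parent coordinate (1, 1) maps to √2. Distance-from-origin rewards a
    codon that strongly helps one reporter even if it mildly hurts the
    other; see :func:`fitness_score_min` for a conservative alternative.
    """
    if not (math.isfinite(c) and math.isfinite(m)):
        raise ValueError(f"non-finite fitness pair ({c}, {m})")
    if c < 0 or m < 0:
        raise ValueError(f"fitness fold changes cannot be negative: ({c}, {m})")
    return math.hypot(c, m)


def fitness_score_min(c: float, m: float) -> float:
    """Worst-case fitness score min(c, m) — a penalty-symmetric alternative
    to :func:`fitness_distance`, provided for sensitivity analysis only."""
    if c < 0 or m < 0:
        raise ValueError(f"fitness fold changes cannot be negative: ({c}, {m})")
    return min(c, m)


def derive_chi_weights(
    records: list[FitnessRecord],
    code: GeneticCode | None = None,
    *,
    score: str = "distance",
) -> ChiTable:
    """Turn per-codon fitness records into χ relative-adaptiveness weights.

    Per codon the raw score d = √(c² + m²) (or min(c, m) if
    ``score='min'``); within each synonymous family W_ij = d_ij / d_imax so
    the fittest codon gets W = 1. Ties at the family maximum resolve toward
    the parent codon, else lexicographically (a deterministic convention;
    it only matters to which codon downstream "perfect" designs collapse).
    Families with no records are flagged absent.
    """
    code = code or standard_code()
    score_fn = {"distance": fitness_distance, "min": fitness_score_min}[score]
    by_codon: dict[str, FitnessRecord] = {}
    for r in records:
        if r.codon in by_codon:
            raise ValueError(f"duplicate fitness record for codon {r.codon}")
        if code.is_stop(r.codon):
            raise ValueError(f"stop codon {r.codon} cannot carry fitness data")
        by_codon[r.codon] = r

    weights: dict[str, float] = {}
    absent: set[str] = set()
    for aa, fam in code.families.items():
        fam_records = [by_codon[c] for c in fam if c in by_codon]
        if not fam_records:
            absent.add(aa)
            continue
        missing = [c for c in fam if c not in by_codon]
        if missing:
            raise ValueError(
                f"family {aa} has records for some codons but not {missing}"
            )
        dist = {r.codon: score_fn(r.c, r.m) for r in fam_records}
        d_max = max(dist.values())
        if d_max == 0:
            raise ValueError(f"family {aa}: all fitness distances are zero")
        # tie-break toward the parent codon, else lexicographic
        tied = sorted(c for c, d in dist.items() if d == d_max)
        best = next((c for c in tied if by_codon[c].is_parent), tied[0])
        for c in fam:
            weights[c] = dist[c] / d_max if c != best else 1.0
    table = WeightTable(weights=weights, label="chi", absent_aas=frozenset(absent))
    ordered = tuple(by_codon[c] for c in sorted(by_codon))
    return ChiTable(records=ordered, weights=table)


def compare_scales(
    a: WeightTable,
    b: WeightTable,
    *,
    basis: str = "expected_rscu",
    codon_set: int = 61,
    expected_mode: str = "perfect",
    code: GeneticCode | None = None,
) -> tuple[float, float]:
    """Pearson correlation between two codon-weight scales.

    ``basis='weights'`` pairs the raw W values; ``basis='expected_rscu'``
    pairs the expected RSCU of a gene perfectly adapted to each scale — the
    comparison that exposes whether two scales *prefer* the same codons.
    ``codon_set`` is 61 (all sense codons) or 59 (Met/Trp dropped: their
    single-codon values are constant across scales). Returns (r, two-tailed
    p) with p from the t transform at n − 2 degrees of freedom.
    """
    code = code or standard_code()
    codons = list(code.sense_codons)
    if codon_set == 59:
        codons = [c for c in codons if len(code.family_of(c)) > 1]
    elif codon_set != 61:
        raise ValueError("codon_set must be 61 or 59")

    if basis == "weights":
        va, vb = dict(a.weights), dict(b.weights)
    elif basis == "expected_rscu":
        va = dict(expected_rscu(a, mode=expected_mode, code=code).values)
        vb = dict(expected_rscu(b, mode=expected_mode, code=code).values)
    else:
        raise ValueError(f"unknown basis {basis!r}")

    missing = [c for c in codons if c not in va or c not in vb]
    if missing:
        raise ValueError(f"codon coverage mismatch; missing values for {missing}")
    xs = [va[c] for c in codons]
    ys = [vb[c] for c in codons]
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def rscu_from_chi(chi: ChiTable, code: GeneticCode | None = None) -> RSCUVector:
    """Expected RSCU of a gene perfectly adapted to the χ scale."""
    return expected_rscu(chi.weights, mode="perfect", code=code)
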