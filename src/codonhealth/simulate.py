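"""Seeded synthetic-data generators with known ground truth.

Every input format the toolkit consumes can be generated here: random
coding sequences drawn under a codon-weight distribution, per-codon fitness
tables built from a known weight table (the exact inverse of the χ
derivation), logistic plate-reader growth/fluorescence curves with a
programmable burden, codon elongation-time tables, and random weight
tables. All generators are pure functions of their seed, so analyses can be
round-tripped against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bias import WeightTable
from .chi import FitnessRecord
from .genetic_code import GeneticCode, standard_code
from .plates import PlateTimeseries
from .sequences import CodingSequence


def random_weight_table(
    seed: int,
    label: str = "synthetic",
    min_w: float = 0.05,
    code: GeneticCode | None = None,
) -> WeightTable:
    """A random relative-adaptiveness table with a unique family maximum.

    One random codon per family gets W = 1; the rest draw uniformly from
    [min_w, 0.95], so the maximum is unique and all weights are positive.
    """
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    weights: dict[str, float] = {}
    for fam in code.families.values():
        best = fam[rng.integers(len(fam))]
        for c in fam:
            weights[c] = 1.0 if c == best else float(rng.uniform(min_w, 0.95))
    return WeightTable(weights=weights, label=label)


def random_protein(length: int, seed: int, code: GeneticCode | None = None) -> str:
    """A uniform-random amino-acid sequence starting with Met."""
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    aas = code.amino_acids
    return "M" + "".join(aas[i] for i in rng.integers(len(aas), size=length - 1))


def random_cds(
    protein_or_length: str | int,
    w: WeightTable,
    seed: int,
    id: str = "synthetic_cds",
    code: GeneticCode | None = None,
) -> CodingSequence:
    """Random CDS for a protein, codons drawn with probability ∝ W in-family.

    With indicator weights (one W = 1, rest 0) this is deterministic and
    identical to maximal-index recoding. An integer input first draws a
    uniform-random protein of that length.
    """
    code = code or standard_code()
    if isinstance(protein_or_length, int):
        protein = random_protein(protein_or_length, seed ^ 0x5EED, code)
    else:
        protein = protein_or_length.upper().rstrip("*")
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein:
        fam = code.families[aa]
        ws = np.array([w.weights[c] for c in fam], dtype=float)
        if ws.sum() <= 0:
            raise ValueError(f"family {aa} has no positive weights")
        codons.append(fam[rng.choice(len(fam), p=ws / ws.sum())])
    return CodingSequence(id=id, nucleotides="".join(codons), code=code)


def simulate_fitness_table(
    true_w: WeightTable,
    noise_sd: float = 0.0,
    seed: int = 0,
    code: GeneticCode | None = None,
) -> list[FitnessRecord]:
    """Fitness records whose χ derivation recovers ``true_w``.

    Inverts the χ construction: each family's W = 1 codon becomes the
    parent at exactly (1, 1) (distance √2); every other codon gets a point
    on the quarter-circle of radius W·√2 at a random angle. Gaussian noise
    of sd ``noise_sd`` is then added to both coordinates (clipped at 0).
    At ``noise_sd = 0`` the derivation is an exact inverse.
    """
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    records: list[FitnessRecord] = []
    for fam in code.families.values():
        best = max(fam, key=lambda c: (true_w.weights[c], c))
        for codon in fam:
            if codon == best:
                c_val, m_val, parent = 1.0, 1.0, True
            else:
                radius = true_w.weights[codon] * math.sqrt(2)
                theta = rng.uniform(0.1, math.pi / 2 - 0.1)
                c_val, m_val = radius * math.cos(theta), radius * math.sin(theta)
                parent = False
            if noise_sd > 0:
                c_val = max(0.0, c_val + rng.normal(0, noise_sd))
                m_val = max(0.0, m_val + rng.normal(0, noise_sd))
            records.append(FitnessRecord(codon=codon, c=c_val, m=m_val, is_parent=parent))
    return records


def synthetic_codon_times(
    w: WeightTable,
    base_time: float = 0.05,
    slow_factor: float = 8.0,
    code: GeneticCode | None = None,
) -> dict[str, float]:
    """Per-codon elongation times inversely related to a weight table.

    A W = 1 codon elongates in ``base_time``; a W → 0 codon approaches
    ``base_time · slow_factor``. Mimics the supply/demand logic in which
    poorly adapted codons wait longer for their tRNA.
    """
    code = code or standard_code()
    times = {}
    for codon in code.sense_codons:
        wv = w.weights.get(codon, 0.0)
        times[codon] = base_time * (1 + (slow_factor - 1) * (1 - wv))
    for codon in code.stop_codons:
        times[codon] = base_time
    return times


@dataclass(frozen=True)
class FixtureConfig:
    """Plate-simulation settings: growth, burden, noise and schedule.

    ``burden`` ∈ [0, 1] scales the induced culture's growth rate and
    carrying capacity by (1 − burden); ``expression_gain`` sets how fast
    the overexpressed channel accumulates per unit biomass.
    """

    seed: int = 0
    interval_min: float = 5.0
    duration_min: float = 480.0
    burden: float = 0.2
    noise_sd: float = 0.0
    od0: float = 0.02
    growth_rate: float = 0.02  # per minute
    carrying_capacity: float = 1.2
    reporter_gain: float = 2000.0  # constitutive YFP per OD unit
    expression_gain: float = 5000.0  # induced CFP per OD unit
    background: dict = field(
        default_factory=lambda: {"OD600": 0.01, "YFP": 50.0, "CFP": 40.0}
    )
    ceiling: dict = field(
        default_factory=lambda: {"YFP": 60000.0, "CFP": 5000.0}
    )

    def __post_init__(self):
        if not 0 <= self.burden <= 1:
            raise ValueError("burden must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _logistic(t: np.ndarray, od0: float, rate: float, cap: float) -> np.ndarray:
    return cap / (1 + (cap / od0 - 1) * np.exp(-rate * t))


def simulate_plate(config: FixtureConfig) -> tuple[PlateTimeseries, PlateTimeseries]:
    """Simulate one induced/uninduced pair of plate-reader time series.

    OD follows a logistic curve; induction scales rate and carrying
    capacity by (1 − burden). The constitutive reporter (YFP) and the
    overexpressed channel (CFP, induced only) are proportional to OD.
    Noise is multiplicative log-normal (Gaussian on log signal), keeping
    signals positive; backgrounds are added last and detector ceilings
    clip the stored signals.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_min + 1e-9, config.interval_min)
    curves = {}
    for condition, factor in (("uninduced", 1.0), ("induced", 1.0 - config.burden)):
        od = _logistic(
            t, config.od0, config.growth_rate * factor, config.carrying_capacity * factor
        )
        signals = {
            "OD600": od,
            "YFP": config.reporter_gain * od,
            "CFP": (config.expression_gain * od) if condition == "induced" else np.zeros_like(od),
        }
        noisy = {}
        for ch, y in signals.items():
            if config.noise_sd > 0:
                y = y * np.exp(rng.normal(0.0, config.noise_sd, size=y.shape))
            y = y + config.background.get(ch, 0.0)
            if ch in config.ceiling:
                y = np.minimum(y, config.ceiling[ch])
            noisy[ch] = y
        curves[condition] = PlateTimeseries(
            time=t,
            signals=noisy,
            condition=condition,
            background=config.background,
            upper_limit=config.ceiling,
        )
    return curves["induced"], curves["uninduced"]
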