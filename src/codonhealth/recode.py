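"""Synonymous gene-recoding algorithms.

Recoding designs a DNA sequence for a fixed protein by choosing among each
amino acid's synonymous codons. The design surface is enormous — the
degeneracy product for a small fluorescent protein already exceeds 10^100 —
so design proceeds by construction (pick each family's best codon), by
systematic sweeps (move one amino acid at a time to an alternative codon),
or by a seeded greedy walk toward a target index value. Every operation
preserves the translation exactly and never touches the fixed 5' prefix.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .bias import (
    RSCUVector,
    ScoringError,
    WeightTable,
    count_codons,
    geometric_index,
    rscu,
)
from .genetic_code import GeneticCode, standard_code
from .sequences import CodingSequence


class TargetRangeError(ValueError):
    """Requested index target lies outside the protein's achievable range."""


class ConvergenceError(RuntimeError):
    """Greedy search exhausted its iteration budget before reaching target."""

    def __init__(self, msg: str, best: "RecodeResult | None" = None):
        super().__init__(msg)
        self.best = best


@dataclass(frozen=True)
class RecodeSpec:
    """Parameters of a greedy recode toward a target index value."""

    weights: WeightTable
    target_index: float
    tolerance: float = 0.005
    fixed_prefix_len: int = 0
    seed: int = 0
    max_iterations: int | None = None  # default 50·L, set at run time
    exclude_single_codon_aas: bool = True
    variable_region_only: bool = True

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not (0 < self.target_index <= 1):
            raise ValueError("target index must lie in (0, 1]")


@dataclass(frozen=True)
class RecodeResult:
    """A designed sequence with its verified index and design metadata."""

    cds: CodingSequence
    achieved_index: float
    iterations: int
    rscu: RSCUVector
    seed: int | None = None
    target_index: float | None = None


def _protein_and_template(
    seq_or_protein: CodingSequence | str,
    fixed_prefix_len: int,
    code: GeneticCode,
) -> tuple[str, tuple[str, ...], str, int, bool]:
    """Normalize input to (protein, prefix codons, id, prefix_len, had_stop)."""
    if isinstance(seq_or_protein, CodingSequence):
        seq = seq_or_protein
        prefix_len = seq.fixed_prefix_len or fixed_prefix_len
        codons = seq.codons
        had_stop = code.is_stop(codons[-1])
        body = codons[:-1] if had_stop else codons
        protein = "".join(code.codon_to_aa[c] for c in body)
        return protein, codons[:prefix_len], seq.id, prefix_len, had_stop
    protein = seq_or_protein.upper().rstrip("*")
    if fixed_prefix_len > 0:
        raise ValueError(
            "a bare protein cannot carry fixed prefix *codons*; pass a "
            "CodingSequence to pin the 5' region"
        )
    bad = [a for a in protein if a not in code.families]
    if bad:
        raise ValueError(f"unknown amino acids {sorted(set(bad))}")
    return protein, (), "recode", 0, False


def _family_argmax(
    w: WeightTable, fam: tuple[str, ...], warn_context: str
) -> str:
    ws = [(w.weights.get(c), c) for c in fam]
    if any(v is None for v, _ in ws):
        raise ScoringError(f"{warn_context}: missing weights in family {fam}")
    top = max(v for v, _ in ws)
    tied = sorted(c for v, c in ws if v == top)
    if len(tied) > 1:
        warnings.warn(
            f"{warn_context}: tied maximal weights in family {fam}; "
            f"choosing {tied[0]} (lexicographic)",
            stacklevel=3,
        )
    return tied[0]


def max_index_recode(
    seq_or_protein: CodingSequence | str,
    w: WeightTable,
    fixed_prefix_len: int = 0,
    code: GeneticCode | None = None,
) -> CodingSequence:
    """Recode so every variable codon is its family's W = 1 codon.

    The result scores index = 1 under ``w`` and uses a single codon per
    amino acid in the variable region (ENC = 20 when all degeneracy classes
    are present). Ties at the family maximum break lexicographically with a
    warning.
    """
    code = code or standard_code()
    protein, prefix, seq_id, prefix_len, had_stop = _protein_and_template(
        seq_or_protein, fixed_prefix_len, code
    )
    codons = list(prefix)
    for aa in protein[prefix_len:]:
        codons.append(_family_argmax(w, code.families[aa], seq_id))
    if had_stop:
        codons.append(seq_or_protein.codons[-1])  # keep the original stop
    return CodingSequence(
        id=f"{seq_id}|max_{w.label}",
        nucleotides="".join(codons),
        fixed_prefix_len=prefix_len,
        code=code,
    )


def systematic_recodes(
    parent: CodingSequence,
    fixed_prefix_len: int | None = None,
    code: GeneticCode | None = None,
) -> list[tuple[str, str, CodingSequence]]:
    """Whole-amino-acid single-codon sweeps from an ENC = 20 parent.

    The parent's variable region must use exactly one codon per amino acid.
    For every amino acid present there and every alternative synonymous
    codon, emit one sequence in which *all* variable-region instances of
    that amino acid switch to the alternative. A parent containing all 20
    amino acids yields 61 − 20 = 41 recodes. Returns tuples
    ``(parent_codon, new_codon, sequence)``.
    """
    code = code or standard_code()
    prefix_len = parent.fixed_prefix_len if fixed_prefix_len is None else fixed_prefix_len
    codons = list(parent.codons)
    variable = codons[prefix_len:]

    in_use: dict[str, str] = {}
    for c in variable:
        if code.is_stop(c):
            continue
        aa = code.codon_to_aa[c]
        if aa in in_use and in_use[aa] != c:
            raise ValueError(
                f"{parent.id!r}: variable region uses both {in_use[aa]} and "
                f"{c} for {aa}; the sweep is only defined from a single-codon "
                "(ENC = 20 style) parent"
            )
        in_use[aa] = c

    out: list[tuple[str, str, CodingSequence]] = []
    for aa in sorted(in_use):
        current = in_use[aa]
        for alt in code.families[aa]:
            if alt == current:
                continue
            new_codons = [
                alt
                if i >= prefix_len and not code.is_stop(c) and code.codon_to_aa[c] == aa
                else c
                for i, c in enumerate(codons)
            ]
            out.append(
                (
                    current,
                    alt,
                    CodingSequence(
                        id=f"{parent.id}|{current}->{alt}",
                        nucleotides="".join(new_codons),
                        fixed_prefix_len=prefix_len,
                        code=code,
                    ),
                )
            )
    return out


def achievable_range(
    protein_or_seq: CodingSequence | str,
    w: WeightTable,
    *,
    exclude_single_codon_aas: bool = True,
    fixed_prefix_len: int = 0,
    variable_region_only: bool = True,
    code: GeneticCode | None = None,
) -> tuple[float, float]:
    """(min, max) geometric index achievable for a protein under ``w``.

    The extremes are the geometric means of per-position minimal/maximal W
    (zeros floored at the table's epsilon). With ``variable_region_only``
    the fixed prefix does not constrain the range (it is also not scored).
    """
    code = code or standard_code()
    protein, _, _, prefix_len, _ = _protein_and_template(
        protein_or_seq, fixed_prefix_len, code
    )
    scored_aas = [
        aa
        for aa in (protein[prefix_len:] if variable_region_only else protein)
        if not (exclude_single_codon_aas and len(code.families[aa]) == 1)
    ]
    if not scored_aas:
        return 1.0, 1.0
    lo = hi = 0.0
    for aa in scored_aas:
        fam = code.families[aa]
        ws = [max(w.weights[c], w.epsilon_floor) for c in fam]
        lo += math.log(min(ws))
        hi += math.log(max(ws))
    n = len(scored_aas)
    return math.exp(lo / n), math.exp(hi / n)


def _score(result_seq: CodingSequence, spec: RecodeSpec) -> float:
    return geometric_index(
        result_seq,
        spec.weights,
        exclude_single_codon_aas=spec.exclude_single_codon_aas,
        variable_region_only=spec.variable_region_only,
    )


def greedy_recode(
    spec: RecodeSpec,
    seq_or_protein: CodingSequence | str,
    code: GeneticCode | None = None,
) -> RecodeResult:
    """Greedy walk through synonymous space toward a target index.

    The variable region starts fully randomized (uniform over each family)
    so the walk carries no initial bias, then single codons are proposed at
    random — a uniform position, then a uniform *alternative* synonym — and
    a proposal is accepted only if it strictly shrinks |index − target|.
    Terminates when within ``tolerance`` or raises
    :class:`ConvergenceError` (carrying the best sequence found) after
    ``max_iterations`` proposals. The returned index is re-computed from
    the final sequence, not carried through the walk.
    """
    code = code or standard_code()
    protein, prefix, seq_id, prefix_len, had_stop = _protein_and_template(
        seq_or_protein, spec.fixed_prefix_len, code
    )
    lo, hi = achievable_range(
        seq_or_protein,
        spec.weights,
        exclude_single_codon_aas=spec.exclude_single_codon_aas,
        fixed_prefix_len=spec.fixed_prefix_len,
        variable_region_only=spec.variable_region_only,
        code=code,
    )
    if not (lo - spec.tolerance <= spec.target_index <= hi + spec.tolerance):
        raise TargetRangeError(
            f"target {spec.target_index} outside achievable index range "
            f"[{lo:.4f}, {hi:.4f}] for this protein"
        )
    rng = random.Random(spec.seed)
    variable_aas = protein[prefix_len:]
    codons = list(prefix) + [
        rng.choice(code.families[aa]) for aa in variable_aas
    ]
    stop = seq_or_protein.codons[-1] if had_stop else None

    def build(tag: str) -> CodingSequence:
        return CodingSequence(
            id=f"{seq_id}|{spec.weights.label}={spec.target_index}{tag}",
            nucleotides="".join(codons + ([stop] if stop else [])),
            fixed_prefix_len=prefix_len,
            code=code,
        )

    # positions worth mutating: variable region, degeneracy > 1
    mutable = [
        i
        for i in range(prefix_len, len(codons))
        if len(code.family_of(codons[i])) > 1
    ]
    max_iter = spec.max_iterations or 50 * len(codons)

    # incremental scoring: the scored-codon set is fixed (stops and, by
    # default, single-codon families never score), so a swap shifts the
    # log-sum by log w_new − log w_old
    def logw(codon: str) -> float:
        wv = spec.weights.get(codon)
        if wv is None:
            raise ScoringError(
                f"no weight for codon {codon} in table {spec.weights.label!r}"
            )
        return math.log(max(wv, spec.weights.epsilon_floor))

    scored_pos = [
        i
        for i in (range(prefix_len, len(codons)) if spec.variable_region_only
                  else range(len(codons)))
        if not code.is_stop(codons[i])
        and not (spec.exclude_single_codon_aas and len(code.family_of(codons[i])) == 1)
    ]
    n_scored = len(scored_pos)
    if n_scored == 0:
        raise ScoringError("no scorable codons in the region being designed")
    scored_set = set(scored_pos)
    log_sum = sum(logw(codons[i]) for i in scored_pos)

    def index_of(ls: float) -> float:
        return math.exp(ls / n_scored)

    current = index_of(log_sum)
    best_codons, best_err = list(codons), abs(current - spec.target_index)
    it = 0
    while abs(current - spec.target_index) > spec.tolerance and it < max_iter:
        it += 1
        pos = rng.choice(mutable)
        fam = code.family_of(codons[pos])
        alts = [c for c in fam if c != codons[pos]]
        proposal = rng.choice(alts)
        old = codons[pos]
        delta = (logw(proposal) - logw(old)) if pos in scored_set else 0.0
        new = index_of(log_sum + delta)
        if abs(new - spec.target_index) < abs(current - spec.target_index):
            codons[pos] = proposal
            log_sum += delta
            current = new
            if abs(current - spec.target_index) < best_err:
                best_codons, best_err = list(codons), abs(current - spec.target_index)
    if abs(current - spec.target_index) > spec.tolerance:
        codons = best_codons
        best = RecodeResult(
            cds=build("|best"),
            achieved_index=_score(build("|best"), spec),
            iterations=it,
            rscu=rscu(count_codons(build("|best")), code),
            seed=spec.seed,
            target_index=spec.target_index,
        )
        raise ConvergenceError(
            f"no sequence within {spec.tolerance} of target "
            f"{spec.target_index} after {it} proposals (best |err| = "
            f"{best_err:.4f})",
            best=best,
        )
    final = build("")
    achieved = _score(final, spec)  # independent re-score of the sequence
    return RecodeResult(
        cds=final,
        achieved_index=achieved,
        iterations=it,
        rscu=rscu(count_codons(final), code),
        seed=spec.seed,
        target_index=spec.target_index,
    )


def _rscu_vector_59(vec: RSCUVector, code: GeneticCode) -> np.ndarray:
    """RSCU as a 59-dim array (stop/Met/Trp excluded), absent families → 0."""
    codons = [c for c in code.sense_codons if len(code.family_of(c)) > 1]
    return np.array([vec.values.get(c, 0.0) for c in codons])


def diverse_recode_set(
    spec: RecodeSpec,
    seq_or_protein: CodingSequence | str,
    k: int = 3,
    candidates: int = 50,
    min_dissimilarity: float = 0.0,
    code: GeneticCode | None = None,
) -> list[RecodeResult]:
    """k on-target recodes chosen to differ substantially in codon usage.

    Runs ``candidates`` greedy recodes with seeds derived from the spec
    seed, clusters their 59-dimension RSCU vectors (average linkage,
    Euclidean), cuts into k clusters, and returns each cluster's member
    closest to the target index. Raises if any selected pair is closer than
    ``min_dissimilarity`` in RSCU space.
    """
    code = code or standard_code()
    if k > candidates:
        raise ValueError("k cannot exceed the candidate-pool size")
    results: list[RecodeResult] = []
    for i in range(candidates):
        sub = replace(spec, seed=spec.seed * 1000003 + i)
        try:
            results.append(greedy_recode(sub, seq_or_protein, code))
        except ConvergenceError:
            continue
    if len(results) < k:
        raise ConvergenceError(
            f"only {len(results)}/{candidates} candidates converged; "
            f"cannot select {k}"
        )
    if k == 1:
        best = min(results, key=lambda r: abs(r.achieved_index - spec.target_index))
        return [best]
    X = np.vstack([_rscu_vector_59(r.rscu, code) for r in results])
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    picked: list[RecodeResult] = []
    for cluster in range(1, k + 1):
        members = [r for r, lab in zip(results, labels) if lab == cluster]
        if not members:
            continue
        picked.append(
            min(members, key=lambda r: abs(r.achieved_index - spec.target_index))
        )
    if len(picked) < k:
        raise ConvergenceError(
            f"clustering produced only {len(picked)} non-empty clusters"
        )
    if min_dissimilarity > 0:
        P = np.vstack([_rscu_vector_59(r.rscu, code) for r in picked])
        dmin = float(pdist(P).min())
        if dmin < min_dissimilarity:
            raise ValueError(
                f"selected set's minimum pairwise RSCU distance {dmin:.3f} < "
                f"{min_dissimilarity}; try a larger candidate pool"
            )
    return picked


def match_cub_recode(
    template: CodingSequence,
    protein: str,
    fixed_prefix: tuple[str, ...] = (),
    code: GeneticCode | None = None,
) -> CodingSequence:
    """Recode ``protein`` to mirror a template's codon-usage bias.

    Used to give one gene (e.g. mCherry) the same codon-bias scheme as a
    designed recode of another (e.g. CFP). Per synonymous family the
    template's codon proportions are apportioned onto the protein's codon
    demand with largest-remainder rounding, which minimizes the per-family
    deviation from the template proportions; codons are then laid out
    deterministically along the sequence. Families absent from the template
    fall back to uniform proportions with a warning.
    """
    code = code or standard_code()
    protein = protein.upper().rstrip("*")
    template_rscu = rscu(count_codons(template), code)

    # per-family positional demand
    fam_positions: dict[str, list[int]] = {}
    for pos, aa in enumerate(protein):
        if aa not in code.families:
            raise ValueError(f"unknown amino acid {aa!r} at position {pos}")
        fam_positions.setdefault(aa, []).append(pos)

    codons: list[str | None] = [None] * len(protein)
    for i, c in enumerate(fixed_prefix):
        codons[i] = c
    for aa, positions in fam_positions.items():
        free = [p for p in positions if codons[p] is None]
        if not free:
            continue
        fam = code.families[aa]
        if aa in template_rscu.absent_aas:
            warnings.warn(
                f"amino acid {aa} absent from template {template.id!r}; "
                "using uniform synonymous proportions",
                stacklevel=2,
            )
            props = [1 / len(fam)] * len(fam)
        else:
            vals = [template_rscu.get(c) for c in fam]
            props = [v / sum(vals) for v in vals]
        # largest-remainder apportionment of len(free) slots
        quotas = [p * len(free) for p in props]
        alloc = [int(q) for q in quotas]
        short = len(free) - sum(alloc)
        order = sorted(
            range(len(fam)), key=lambda j: (quotas[j] - alloc[j], fam[j]), reverse=True
        )
        for j in order[:short]:
            alloc[j] += 1
        assignment: list[str] = []
        for c, n in zip(fam, alloc):
            assignment.extend([c] * n)
        for p, c in zip(free, assignment):
            codons[p] = c
    return CodingSequence(
        id=f"{template.id}|cub_match",
        nucleotides="".join(codons),  # type: ignore[arg-type]
        fixed_prefix_len=len(fixed_prefix),
        code=code,
    )


def synonymous_space_size(
    protein_or_seq: CodingSequence | str,
    fixed_prefix_len: int = 0,
    code: GeneticCode | None = None,
) -> int:
    """Exact count of synonymous DNA sequences for a protein.

    The product of per-position degeneracies over variable positions, as an
    arbitrary-precision integer. A trailing stop codon on a CodingSequence
    input is held fixed (not varied).
    """
    code = code or standard_code()
    if isinstance(protein_or_seq, CodingSequence):
        protein, _, _, prefix_len, _ = _protein_and_template(
            protein_or_seq, fixed_prefix_len, code
        )
    else:
        protein = protein_or_seq.upper().rstrip("*")
        prefix_len = fixed_prefix_len
    size = 1
    for aa in protein[prefix_len:]:
        size *= len(code.families[aa])
    return size


def scientific_notation(n: int, sig_figs: int = 2) -> str:
    """Round a (possibly huge) integer to ``sig_figs`` in scientific form."""
    if n <= 0:
        raise ValueError("positive integers only")
    from decimal import ROUND_HALF_UP, Decimal

    d = Decimal(n)
    exponent = d.adjusted()
    quantum = Decimal(1).scaleb(-(sig_figs - 1))
    mantissa = d.scaleb(-exponent).quantize(quantum, rounding=ROUND_HALF_UP)
    if mantissa >= 10:  # rounding carried over
        mantissa = (mantissa / 10).quantize(quantum, rounding=ROUND_HALF_UP)
        exponent += 1
    return f"{mantissa}e+{exponent}"
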