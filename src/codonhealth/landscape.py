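"""Codon-usage-bias landscapes: RSCU matrices, PCA and hierarchical
clustering over gene or operon sets.

A gene set becomes a codons × sequences RSCU matrix (61 sense codons, or
59 with the invariant single-codon families Met/Trp dropped). Principal
component analysis of that matrix — codon-wise centering, no variance
scaling, SVD — separates codon-usage regimes; agglomerative clustering on
the columns groups sequences by usage scheme. Operons are analyzed by
concatenating member coding sequences into one pseudo-CDS so the operon is
the usage unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .bias import count_codons, rscu
from .genetic_code import GeneticCode, standard_code
from .sequences import CodingSequence


@dataclass(frozen=True)
class RSCUMatrix:
    """Codons (rows) × sequences (columns) RSCU values, fill policy applied."""

    data: pd.DataFrame
    mode: int
    fill_policy: str
    filled_aas: dict[str, tuple[str, ...]]  # column id → absent amino acids

    @property
    def codons(self) -> list[str]:
        return list(self.data.index)

    @property
    def ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class PCAResult:
    """Scores (sequences × components), loadings (codons × components),
    and per-component variance fractions from an RSCU-matrix PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray

    def top_loading_codons(self, component: int = 0, k: int = 10) -> list[str]:
        """The k codons contributing most to a component (|loading|)."""
        col = self.loadings.iloc[:, component]
        return list(col.abs().sort_values(ascending=False).index[:k])


def rscu_matrix(
    seqs: list[CodingSequence],
    mode: int = 61,
    fill_policy: str = "zero",
    strict: bool = True,
    code: GeneticCode | None = None,
) -> RSCUMatrix:
    """Column-wise RSCU over a sequence set.

    ``mode`` 61 keeps all sense codons; 59 drops Met/Trp (their RSCU is
    identically 1 wherever present, contributing no variance). Amino acids
    absent from a sequence have undefined RSCU; ``fill_policy`` 'zero'
    writes 0 (the unused-codon convention), 'family_mean' writes 1 (the
    no-bias value). Filled columns are flagged in ``filled_aas``.
    """
    code = code or standard_code()
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if mode == 61:
        codons = list(code.sense_codons)
    elif mode == 59:
        codons = [c for c in code.sense_codons if len(code.family_of(c)) > 1]
    else:
        raise ValueError("mode must be 61 or 59")
    if fill_policy not in ("zero", "family_mean"):
        raise ValueError(f"unknown fill policy {fill_policy!r}")
    fill_value = 0.0 if fill_policy == "zero" else 1.0

    cols: dict[str, list[float]] = {}
    filled: dict[str, tuple[str, ...]] = {}
    for seq in seqs:
        try:
            vec = rscu(count_codons(seq), code)
        except ValueError as e:
            if strict:
                raise
            warnings.warn(f"skipping {seq.id!r}: {e}", stacklevel=2)
            continue
        if vec.absent_aas:
            filled[seq.id] = tuple(sorted(vec.absent_aas))
        cols[seq.id] = [vec.values.get(c, fill_value) for c in codons]
    return RSCUMatrix(
        data=pd.DataFrame(cols, index=codons),
        mode=mode,
        fill_policy=fill_policy,
        filled_aas=filled,
    )


def aggregate_operons(
    genes: list[CodingSequence],
    membership: dict[str, list[str]],
    min_genes: int = 2,
) -> list[CodingSequence]:
    """Concatenate operon members into pseudo-CDSs for operon-level RSCU.

    ``membership`` maps operon id → ordered gene ids. Operons with fewer
    than ``min_genes`` members are dropped — single-gene transcription
    units carry no co-transcription signal. Codon counts of the pseudo-CDS
    equal the sum of member counts by construction.
    """
    by_id = {g.id: g for g in genes}
    out: list[CodingSequence] = []
    for operon_id, gene_ids in membership.items():
        unknown = [g for g in gene_ids if g not in by_id]
        if unknown:
            raise KeyError(f"operon {operon_id!r} references unknown genes {unknown}")
        if len(gene_ids) < min_genes:
            continue
        concat = "".join(by_id[g].nucleotides for g in gene_ids)
        out.append(
            CodingSequence(
                id=operon_id,
                nucleotides=concat,
                validate_internal_stops=False,  # members keep their stops
            )
        )
    return out


def pca_rscu(m: RSCUMatrix, n_components: int = 3) -> PCAResult:
    """PCA of an RSCU matrix by SVD.

    Sequences are the observations. Each codon row is centered (mean over
    sequences removed); no unit-variance scaling, since RSCU values share
    a natural scale. Loadings are orthonormal; the sign convention makes
    each component's largest-|loading| codon positive, so results are
    reproducible across runs and libraries.
    """
    X = m.data.to_numpy(dtype=float)  # codons × sequences
    n_codons, n_seqs = X.shape
    if n_components > min(n_codons, n_seqs):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = X - X.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("degenerate RSCU matrix: all sequences identical usage")
    # observations in rows for the SVD
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    total_var = float((s**2).sum())
    var_frac = (s**2) / total_var

    loadings = Vt.T[:, :n_components]  # codons × components
    scores = (U * s)[:, :n_components]  # sequences × components
    for j in range(n_components):
        pivot = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=m.codons, columns=comp_names),
        variance_fraction=var_frac[:n_components],
    )


def hcluster(
    m: RSCUMatrix,
    linkage: str = "average",
    n_clusters: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Agglomerative clustering of sequences by RSCU (Euclidean metric).

    Returns the scipy linkage matrix and, when ``n_clusters`` is given,
    flat cluster labels from a maxclust cut. Deterministic for a given
    column order.
    """
    if linkage not in ("average", "ward"):
        raise ValueError("linkage must be 'average' or 'ward'")
    X = m.data.to_numpy(dtype=float).T  # sequences × codons
    if X.shape[0] < 2:
        raise ValueError("need at least two sequences to cluster")
    if np.isnan(X).any():
        raise ValueError("RSCU matrix contains NaN after fill")
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels
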