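"""Compendium-wide correlation structure of the chromosome.

Across a few hundred expression conditions, every unordered gene pair is
classified by its Pearson correlation: correlated at PCC >= 0.5,
anti-correlated at PCC <= -0.5, neither otherwise (both thresholds
inclusive).  Counting classified pairs per 100-kb bin pair produces two
symmetric matrices whose block structure reveals chromosomal expression
domains: within-domain bin pairs accumulate correlated pairs, cross-domain
bin pairs anti-correlated ones.  A scored exhaustive two-arc partition of
the circular bin ring extracts the domain boundaries.

Pair classification streams over gene blocks so the dense gene-by-gene
correlation matrix is never materialized in one piece.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .core_genome import ChromosomeMap, GeneAnnotation, assign_gene_bin

__all__ = [
    "PairBlock",
    "PairClassification",
    "BinPairMatrix",
    "DomainPartition",
    "iter_classified_pairs",
    "classify_pairs",
    "binpair_matrix",
    "domain_boundaries",
]

#: tolerance on the PCC thresholds so exact-boundary pairs (r = 0.5) are
#: classified inclusively despite floating-point rounding
PCC_EPS = 1e-9


@dataclass
class PairBlock:
    """Classified pairs from one block: parallel arrays of row indices,
    column indices and classes (+1 correlated, -1 anti-correlated)."""

    i: np.ndarray
    j: np.ndarray
    klass: np.ndarray
    n_pairs_seen: int  # pairs examined in this block, classified or not


@dataclass
class PairClassification:
    """All classified pairs of a compendium plus bookkeeping totals."""

    gene_ids: list[str]
    i: np.ndarray
    j: np.ndarray
    klass: np.ndarray
    n_neither: int
    excluded_genes: list[str]

    @property
    def n_correlated(self) -> int:
        return int((self.klass == 1).sum())

    @property
    def n_anticorrelated(self) -> int:
        return int((self.klass == -1).sum())

    @property
    def n_excluded_pairs(self) -> int:
        """Pairs dropped because at least one member is constant-valued."""
        n = len(self.gene_ids)
        k = len(self.excluded_genes)
        return k * (n - k) + k * (k - 1) // 2


def _standardize(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized matrix and a constant-gene mask."""
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc * xc).sum(axis=1))
    constant = norm == 0
    norm[constant] = 1.0
    return xc / norm[:, None], constant


def iter_classified_pairs(
    expr: pd.DataFrame, threshold: float = 0.5, block_size: int = 1024
) -> Iterator[PairBlock]:
    """Stream classified gene pairs (i < j) block by block.

    Yields only pairs reaching |PCC| >= threshold; pairs involving
    constant genes are skipped entirely and never counted as examined.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 conditions")
    z, constant = _standardize(expr)
    n = len(z)
    ok = ~constant
    for a in range(0, n, block_size):
        za = z[a : a + block_size]
        for b in range(a, n, block_size):
            r = za @ z[b : b + block_size].T
            ii, jj = np.meshgrid(
                np.arange(a, min(a + block_size, n)),
                np.arange(b, min(b + block_size, n)),
                indexing="ij",
            )
            upper = ii < jj
            valid = upper & ok[ii] & ok[jj]
            corr = valid & (r >= threshold - PCC_EPS)
            anti = valid & (r <= -threshold + PCC_EPS)
            sel = corr | anti
            yield PairBlock(
                i=ii[sel],
                j=jj[sel],
                klass=np.where(corr[sel], 1, -1).astype(np.int8),
                n_pairs_seen=int(valid.sum()),
            )


def classify_pairs(
    expr: pd.DataFrame, threshold: float = 0.5, block_size: int = 1024
) -> PairClassification:
    """Classify every unordered gene pair of a compendium.

    Thresholds are inclusive; constant-valued genes are excluded from
    classification and reported.
    """
    _, constant = _standardize(expr)
    blocks = list(iter_classified_pairs(expr, threshold, block_size))
    i = np.concatenate([b.i for b in blocks]) if blocks else np.array([], dtype=int)
    j = np.concatenate([b.j for b in blocks]) if blocks else np.array([], dtype=int)
    klass = (
        np.concatenate([b.klass for b in blocks]) if blocks else np.array([], dtype=np.int8)
    )
    seen = sum(b.n_pairs_seen for b in blocks)
    return PairClassification(
        gene_ids=list(expr.index),
        i=i,
        j=j,
        klass=klass,
        n_neither=seen - len(klass),
        excluded_genes=list(expr.index[constant]),
    )


@dataclass
class BinPairMatrix:
    """Counts of correlated (C) and anti-correlated (A) gene pairs per
    100-kb bin pair; within-bin pairs sit on the diagonal and each
    cross-bin pair appears symmetrically at [i, j] and [j, i]."""

    bin_size: int
    C: np.ndarray
    A: np.ndarray
    genes_per_bin: np.ndarray
    n_neither: int
    n_excluded_pairs: int

    @property
    def n_bins(self) -> int:
        return len(self.genes_per_bin)

    @staticmethod
    def _pair_total(m: np.ndarray) -> int:
        return int((m.sum() + np.trace(m)) // 2)

    @property
    def n_correlated(self) -> int:
        return self._pair_total(self.C)

    @property
    def n_anticorrelated(self) -> int:
        return self._pair_total(self.A)


def binpair_matrix(
    pairs: PairClassification,
    genes: Sequence[GeneAnnotation],
    chrom: ChromosomeMap,
    bin_size: int = 100_000,
) -> BinPairMatrix:
    """Aggregate classified pairs into symmetric bin-pair count matrices."""
    by_id = {g.gene_id: g for g in genes}
    missing = set(pairs.gene_ids) - set(by_id)
    if missing:
        raise ValueError(f"genes without annotation: {sorted(missing)[:3]}")
    n_bins = -(-chrom.length_bp // bin_size)
    gene_bins = np.array(
        [assign_gene_bin(by_id[g], bin_size) for g in pairs.gene_ids]
    )
    genes_per_bin = np.bincount(gene_bins, minlength=n_bins)
    C = np.zeros((n_bins, n_bins), dtype=np.int64)
    A = np.zeros((n_bins, n_bins), dtype=np.int64)
    for m, sign in ((C, 1), (A, -1)):
        sel = pairs.klass == sign
        bi, bj = gene_bins[pairs.i[sel]], gene_bins[pairs.j[sel]]
        np.add.at(m, (bi, bj), 1)
        off = bi != bj
        np.add.at(m, (bj[off], bi[off]), 1)
    return BinPairMatrix(
        bin_size=bin_size,
        C=C,
        A=A,
        genes_per_bin=genes_per_bin,
        n_neither=pairs.n_neither,
        n_excluded_pairs=pairs.n_excluded_pairs,
    )


@dataclass
class DomainPartition:
    """Two-arc partition of the circular bin ring."""

    boundary_bins: tuple[int, int]
    score: int
    domain_1: list[int]  # bins in [b1, b2)
    domain_2: list[int]  # bins in [b2, b1)


def _partition_score(bpm: BinPairMatrix, member: np.ndarray) -> int:
    """Anti-correlated cross-domain pairs plus correlated same-domain pairs."""
    m = member.astype(float)
    cross_a = float(m @ bpm.A @ (1.0 - m))
    cross_c = float(m @ bpm.C @ (1.0 - m))
    total_c = bpm.n_correlated
    return int(round(cross_a + (total_c - cross_c)))


def domain_boundaries(bpm: BinPairMatrix) -> DomainPartition:
    """Extract the two-domain partition maximizing domain coherence.

    Exhaustive search over all ordered boundary pairs (b1 < b2) on the
    circular ring; the score is the number of anti-correlated pairs that
    cross the partition plus the number of correlated pairs that do not.
    Ties go to the smallest first boundary, then the smallest second.
    """
    B = bpm.n_bins
    if B < 4:
        raise ValueError("need at least 4 bins")
    if bpm.A.sum() == 0 and bpm.C.sum() == 0:
        raise ValueError("no structure: no classified pairs at all")
    if bpm.A.sum() == 0:
        raise ValueError("no structure: no anti-correlated pairs")
    best: Optional[DomainPartition] = None
    for b1 in range(B):
        member = np.zeros(B)
        for b2 in range(b1 + 1, B):
            member[b1:b2] = 1.0
            score = _partition_score(bpm, member)
            member[b1:b2] = 0.0
            if best is None or score > best.score:
                best = DomainPartition(
                    boundary_bins=(b1, b2),
                    score=score,
                    domain_1=list(range(b1, b2)),
                    domain_2=[b for b in range(B) if b < b1 or b >= b2],
                )
    assert best is not None
    return best
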