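"""Pair classification, bin-pair matrices and the two-domain partition."""

import numpy as np
import pandas as pd
import pytest

from oriterscan.core_genome import ChromosomeMap, GeneAnnotation
from oriterscan.expression_domains import (
    BinPairMatrix,
    binpair_matrix,
    classify_pairs,
    domain_boundaries,
)
from oriterscan.synthetic_data import (
    CompendiumSpec,
    gen_compendium,
    gen_gene_annotations,
)


def _expr(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T


class TestClassifyPairs:
    def test_identical_copies_correlated(self):
        expr = _expr({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        pc = classify_pairs(expr)
        assert pc.n_correlated == 1 and pc.n_anticorrelated == 0

    def test_negated_vector_anticorrelated(self):
        expr = _expr({"a": [1, 2, 3, 4], "b": [-1, -2, -3, -4]})
        pc = classify_pairs(expr)
        assert pc.n_anticorrelated == 1

    def test_exact_half_correlation_inclusive(self):
        # r((1,2,3),(1,3,2)) = 0.5 by hand; the >= 0.5 boundary is inclusive
        expr = _expr({"a": [1, 2, 3], "b": [1, 3, 2]})
        r = np.corrcoef([1, 2, 3], [1, 3, 2])[0, 1]
        assert r == pytest.approx(0.5)
        pc = classify_pairs(expr)
        assert pc.n_correlated == 1

    def test_constant_gene_excluded_and_reported(self):
        expr = _expr({"a": [1, 2, 3], "b": [5, 5, 5], "c": [3, 2, 1]})
        pc = classify_pairs(expr)
        assert pc.excluded_genes == ["b"]
        assert pc.n_excluded_pairs == 2
        assert pc.n_anticorrelated == 1  # a vs c

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = _expr({"a": x, "b": y})
        scaled = _expr({"a": 3.0 * x + 7.0, "b": 0.5 * y - 2.0})
        assert classify_pairs(base).klass.tolist() == classify_pairs(scaled).klass.tolist()

    def test_conservation_of_pair_counts(self, desk_chrom):
        genes = gen_gene_annotations(desk_chrom, 150)
        spec = CompendiumSpec(chrom=desk_chrom, n_conditions=50, loading=1.0, seed=1)
        expr = gen_compendium(spec, genes)
        expr.iloc[3] = 7.0  # plant one constant gene
        pc = classify_pairs(expr)
        n = len(expr)
        total = pc.n_correlated + pc.n_anticorrelated + pc.n_neither + pc.n_excluded_pairs
        assert total == n * (n - 1) // 2

    def test_blocking_does_not_change_result(self, desk_chrom):
        genes = gen_gene_annotations(desk_chrom, 100)
        spec = CompendiumSpec(chrom=desk_chrom, n_conditions=40, loading=2.0, seed=2)
        expr = gen_compendium(spec, genes)
        a = classify_pairs(expr, block_size=7)
        b = classify_pairs(expr, block_size=1000)
        assert a.n_correlated == b.n_correlated
        assert a.n_anticorrelated == b.n_anticorrelated

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            classify_pairs(_expr({"a": [1, 2], "b": [2, 1]}))


class TestBinPairMatrix:
    def test_four_genes_two_bins_all_correlated(self):
        chrom = ChromosomeMap(length_bp=200_000)
        genes = [
            GeneAnnotation("a", 10_000, 12_000),
            GeneAnnotation("b", 50_000, 52_000),
            GeneAnnotation("c", 110_000, 112_000),
            GeneAnnotation("d", 150_000, 152_000),
        ]
        t = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame([t, t + 1, t * 2, t + 3], index=["a", "b", "c", "d"])
        pc = classify_pairs(expr)
        bpm = binpair_matrix(pc, genes, chrom, bin_size=100_000)
        assert bpm.C.tolist() == [[1, 4], [4, 1]]
        assert bpm.A.sum() == 0

    def test_no_pairs_pass_thresholds(self, desk_chrom):
        genes = gen_gene_annotations(desk_chrom, 80)
        spec = CompendiumSpec(chrom=desk_chrom, n_conditions=300, loading=0.0, seed=3)
        expr = gen_compendium(spec, genes)
        pc = classify_pairs(expr)
        bpm = binpair_matrix(pc, genes, desk_chrom, bin_size=10_000)
        assert bpm.C.sum() == 0 and bpm.A.sum() == 0

    def test_anticorrelated_pairs_concentrate_cross_domain(self, desk_chrom, desk_genes):
        spec = CompendiumSpec(chrom=desk_chrom, n_conditions=300, loading=3.0, seed=4)
        expr = gen_compendium(spec, desk_genes)
        pc = classify_pairs(expr)
        bpm = binpair_matrix(pc, desk_genes, desk_chrom, bin_size=10_000)
        from oriterscan.synthetic_data import domain_signs

        s = domain_signs(desk_genes, desk_chrom, desk_chrom.boundary_candidates[:2])
        # map bins to domains via majority gene sign
        gi = pc.i
        gj = pc.j
        anti = pc.klass == -1
        cross = s[gi[anti]] != s[gj[anti]]
        assert cross.mean() >= 0.80

    def test_symmetry_and_totals(self, desk_chrom):
        genes = gen_gene_annotations(desk_chrom, 120)
        spec = CompendiumSpec(chrom=desk_chrom, n_conditions=100, loading=2.0, seed=5)
        expr = gen_compendium(spec, genes)
        pc = classify_pairs(expr)
        bpm = binpair_matrix(pc, genes, desk_chrom, bin_size=20_000)
        assert (bpm.C == bpm.C.T).all() and (bpm.A == bpm.A.T).all()
        assert bpm.n_correlated == pc.n_correlated
        assert bpm.n_anticorrelated == pc.n_anticorrelated


class TestDomainBoundaries:
    def test_planted_boundaries_recovered(self, desk_chrom, desk_genes):
        spec = CompendiumSpec(
            chrom=desk_chrom, n_conditions=300, loading=3.0, noise_sd=1.0, seed=6
        )
        expr = gen_compendium(spec, desk_genes)
        pc = classify_pairs(expr)
        bpm = binpair_matrix(pc, desk_genes, desk_chrom, bin_size=10_000)
        part = domain_boundaries(bpm)
        truth = {desk_chrom.boundary_candidates[0] // 10_000,
                 desk_chrom.boundary_candidates[1] // 10_000}
        for b in part.boundary_bins:
            assert min(abs(b - t) for t in truth) <= 1

    def test_single_cross_entry_forces_partition(self):
        B = 6
        A = np.zeros((B, B), dtype=np.int64)
        A[1, 4] = A[4, 1] = 1
        bpm = BinPairMatrix(
            bin_size=100, C=np.zeros_like(A), A=A, genes_per_bin=np.ones(B, dtype=int),
            n_neither=0, n_excluded_pairs=0,
        )
        part = domain_boundaries(bpm)
        d1 = set(part.domain_1)
        assert (1 in d1) != (4 in d1)
        assert part.score == 1

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        B = 12
        # planted structure: bins 0..5 vs 6..11
        A = np.zeros((B, B), dtype=np.int64)
        for i in range(6):
            for j in range(6, 12):
                A[i, j] = A[j, i] = rng.integers(5, 10)
        C = np.zeros_like(A)
        bpm = BinPairMatrix(bin_size=100, C=C, A=A, genes_per_bin=np.ones(B, dtype=int),
                            n_neither=0, n_excluded_pairs=0)
        part = domain_boundaries(bpm)
        shift = 3
        perm = (np.arange(B) - shift) % B  # rotate bin indices by +3
        A2 = A[np.ix_(perm, perm)]
        bpm2 = BinPairMatrix(bin_size=100, C=C, A=A2, genes_per_bin=np.ones(B, dtype=int),
                             n_neither=0, n_excluded_pairs=0)
        part2 = domain_boundaries(bpm2)
        rotated = {(b + shift) % B for b in part.boundary_bins}
        assert set(part2.boundary_bins) == rotated

    def test_no_structure_rejected(self):
        B = 5
        z = np.zeros((B, B), dtype=np.int64)
        bpm = BinPairMatrix(bin_size=100, C=z, A=z, genes_per_bin=np.ones(B, dtype=int),
                            n_neither=0, n_excluded_pairs=0)
        with pytest.raises(ValueError):
            domain_boundaries(bpm)

    def test_null_compendium_score_matches_rotation_null(self, desk_chrom):
        genes = gen_gene_annotations(desk_chrom, 150)
        spec = CompendiumSpec(chrom=desk_chrom, n_conditions=300, loading=0.0, seed=8)
        expr = gen_compendium(spec, genes)
        pc = classify_pairs(expr)
        n_pairs = len(genes) * (len(genes) - 1) // 2
        assert (pc.n_correlated + pc.n_anticorrelated) / n_pairs <= 0.001
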