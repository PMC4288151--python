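"""Circular-chromosome coordinate arithmetic, binning and gene placement.

All coordinates are 0-based, half-open ``[start, end)`` internally.  File
readers convert on the way in (GFF3 is 1-based inclusive, BED is already
0-based half-open).  A single circular replicon is assumed throughout: a
segment whose ``start >= end`` wraps through the coordinate origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChromosomeMap",
    "GenomicSegment",
    "Bin",
    "GeneAnnotation",
    "make_bins",
    "in_segment",
    "segment_length",
    "gene_midpoint",
    "assign_gene_bin",
    "rotate_position",
]


@dataclass(frozen=True)
class ChromosomeMap:
    """A single circular replicon with origin/terminus landmarks.

    Parameters
    ----------
    length_bp
        Chromosome length in base pairs.
    circular
        Whether coordinates wrap (the default; linear chromosomes are
        accepted but segments may not wrap on them).
    ori_pos, ter_pos
        Positions of the origin and terminus of replication.
    boundary_candidates
        Candidate breakpoint coordinates, typically positions of repeated
        elements (e.g. the two identical IS2 copies insC1/insC5 that can
        mediate a segmental duplication by unequal recombination).
    """

    length_bp: int
    circular: bool = True
    ori_pos: int = 0
    ter_pos: int = 0
    boundary_candidates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        for name in ("ori_pos", "ter_pos"):
            v = getattr(self, name)
            if not 0 <= v < self.length_bp:
                raise ValueError(f"{name}={v} outside [0, {self.length_bp})")
        cand = tuple(int(b) for b in self.boundary_candidates)
        if any(not 0 <= b < self.length_bp for b in cand):
            raise ValueError("boundary candidate outside chromosome")
        object.__setattr__(self, "boundary_candidates", cand)


@dataclass(frozen=True)
class GenomicSegment:
    """Half-open segment ``[start, end)``; wraps through 0 when start >= end."""

    start: int
    end: int

    @property
    def wraps(self) -> bool:
        return self.start >= self.end

    def length(self, chrom: ChromosomeMap) -> int:
        return segment_length(self, chrom)

    def midpoint(self, chrom: ChromosomeMap) -> int:
        """Circular midpoint of the segment."""
        return (self.start + self.length(chrom) // 2) % chrom.length_bp


@dataclass(frozen=True)
class Bin(GenomicSegment):
    """A tiling bin; ``partial`` marks a short terminal remainder bin."""

    index: int = 0
    partial: bool = False


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval in the unwrapped representation (start < end).

    Strand is carried for provenance but ignored by every computation.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end in unwrapped coords"
            )


def segment_length(seg: GenomicSegment, chrom: ChromosomeMap) -> int:
    """Length of ``seg`` on the circle: ``(end - start) mod L``, > 0."""
    n = (seg.end - seg.start) % chrom.length_bp
    if n == 0:
        raise ValueError("degenerate segment (zero length)")
    if seg.wraps and not chrom.circular:
        raise ValueError("wrapping segment on a linear chromosome")
    return n


def make_bins(chrom: ChromosomeMap, width_bp: int) -> list[Bin]:
    """Tile the chromosome with non-overlapping windows of ``width_bp``.

    The final bin is shorter whenever the length is not a multiple of the
    width; it is flagged ``partial`` so that mode and Rc statistics can
    exclude it while the tiling stays an exact partition.
    """
    if width_bp < 1:
        raise ValueError("width_bp must be >= 1")
    if width_bp > chrom.length_bp:
        raise ValueError("bin width exceeds chromosome length")
    starts = range(0, chrom.length_bp, width_bp)
    bins = []
    for i, s in enumerate(starts):
        e = min(s + width_bp, chrom.length_bp)
        bins.append(Bin(start=s, end=e, index=i, partial=(e - s) < width_bp))
    return bins


def in_segment(pos: int, seg: GenomicSegment, chrom: ChromosomeMap) -> bool:
    """Membership of a position in a (possibly wrapping) half-open segment."""
    if not 0 <= pos < chrom.length_bp:
        raise ValueError(f"position {pos} outside [0, {chrom.length_bp})")
    if seg.wraps:
        return pos >= seg.start or pos < seg.end
    return seg.start <= pos < seg.end


def positions_in_segment(
    positions: np.ndarray, seg: GenomicSegment, chrom: ChromosomeMap | None = None
) -> np.ndarray:
    """Vectorized :func:`in_segment` over an integer position array.

    Membership depends only on the segment's wrap flag, so ``chrom`` is
    accepted for interface symmetry and may be ``None``.
    """
    positions = np.asarray(positions)
    if seg.wraps:
        return (positions >= seg.start) | (positions < seg.end)
    return (positions >= seg.start) & (positions < seg.end)


def gene_midpoint(gene: GeneAnnotation) -> int:
    return (gene.start + gene.end) // 2


def assign_gene_bin(gene: GeneAnnotation, bin_size_bp: int) -> int:
    """Bin index of a gene: floor(midpoint / bin size).

    The midpoint convention is symmetric and strand-free; genes are treated
    as points for every positional statistic in the package.
    """
    if bin_size_bp < 1:
        raise ValueError("bin_size_bp must be >= 1")
    return gene_midpoint(gene) // bin_size_bp


def rotate_position(pos: int, shift: int, chrom: ChromosomeMap) -> int:
    """Shift a coordinate by ``shift`` modulo the chromosome length."""
    return (pos + shift) % chrom.length_bp


def rotate_segment(seg: GenomicSegment, shift: int, chrom: ChromosomeMap) -> GenomicSegment:
    return GenomicSegment(
        rotate_position(seg.start, shift, chrom),
        rotate_position(seg.end, shift, chrom),
    )


def check_unique_ids(genes: Sequence[GeneAnnotation]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
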