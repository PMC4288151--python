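"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators cover the pipeline's inputs:

* :func:`gen_population_coverage` — per-bin Poisson read coverage of a
  circular chromosome sequenced from a population of DNA molecules in
  which a tandem duplication (or deletion) is present at a chosen
  prevalence.  Sequencing a bin is reduced to its sufficient statistic, a
  Poisson count with the mixture-mean rate; an optional read-start mode
  emits individual positions for exercising the binning code.
* :func:`gen_de_counts` — replicate RNA-seq count matrices for two strains
  with planted regulon effects (transcriptional, in log2 units) and a
  gene-dosage effect over an amplified segment.
* :func:`gen_compendium` — a multi-condition log-scale expression matrix
  with one latent factor loading positively on an origin-centred domain
  and negatively on a terminus-centred domain, emulating the structure a
  large microarray compendium shows across ~300 conditions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_genome import (
    ChromosomeMap,
    GeneAnnotation,
    GenomicSegment,
    gene_midpoint,
    in_segment,
    positions_in_segment,
)
from .coverage_amplification import CoverageTrack, bin_coverage
from .dosage_de import CountMatrix

__all__ = [
    "PopulationSpec",
    "CompendiumSpec",
    "DEScenario",
    "full_scale_chromosome",
    "desk_scale_chromosome",
    "default_dup_segment",
    "gen_gene_annotations",
    "gen_population_coverage",
    "gen_read_starts",
    "gen_compendium",
    "domain_signs",
    "gen_de_counts",
]


def full_scale_chromosome() -> ChromosomeMap:
    """4.6-Mb circular chromosome with a 2-Mb origin-centred duplication arc.

    The two boundary candidates stand in for the identical IS2 copies that
    flank the duplication, placed symmetrically 1 Mb either side of the
    origin so that the duplicated arc [2,925,000, 325,000) wraps through
    coordinate 0 and covers ~43% of the chromosome.
    """
    return ChromosomeMap(
        length_bp=4_600_000,
        ori_pos=3_925_000,
        ter_pos=1_625_000,
        boundary_candidates=(2_925_000, 325_000),
    )


def desk_scale_chromosome() -> ChromosomeMap:
    """One-tenth-scale chromosome (460 kb) for fast tests."""
    return ChromosomeMap(
        length_bp=460_000,
        ori_pos=392_500,
        ter_pos=162_500,
        boundary_candidates=(292_500, 32_500),
    )


def default_dup_segment(chrom: ChromosomeMap) -> GenomicSegment:
    """The origin-centred arc between the two boundary candidates."""
    b1, b2 = chrom.boundary_candidates[:2]
    seg = GenomicSegment(b1, b2)
    if not in_segment(chrom.ori_pos, seg, chrom):
        seg = GenomicSegment(b2, b1)
    return seg


def gen_gene_annotations(
    chrom: ChromosomeMap, n_genes: int, gene_length: int = 900
) -> list[GeneAnnotation]:
    """Evenly spaced, non-overlapping gene models over the chromosome."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    spacing = chrom.length_bp / n_genes
    if gene_length >= spacing:
        gene_length = max(1, int(spacing) - 1)
    genes = []
    for i in range(n_genes):
        start = int(round(i * spacing))
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:05d}",
                start=start,
                end=start + gene_length,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# population coverage

@dataclass(frozen=True)
class PopulationSpec:
    """A sequenced DNA population carrying a segmental variant.

    ``prevalence`` is the fraction of genomic DNA molecules carrying the
    variant (f for a duplication, q for a deletion); ``mean_depth`` is the
    expected reads per bin contributed by a single-copy locus.
    """

    chrom: ChromosomeMap
    dup_segment: GenomicSegment
    prevalence: float
    scenario: str = "duplication"
    mean_depth: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.scenario not in ("duplication", "deletion"):
            raise ValueError("scenario must be 'duplication' or 'deletion'")


def _bin_rates(spec: PopulationSpec, width_bp: int) -> np.ndarray:
    n_bins = -(-spec.chrom.length_bp // width_bp)
    starts = np.arange(n_bins) * width_bp
    ends = np.minimum(starts + width_bp, spec.chrom.length_bp)
    mids = (starts + ends) // 2
    inside = positions_in_segment(mids, spec.dup_segment, spec.chrom)
    lam = np.full(n_bins, spec.mean_depth, dtype=float)
    if spec.scenario == "duplication":
        # carrier molecules have two tandem copies of the segment
        lam[inside] *= 1.0 + spec.prevalence
    else:
        # carriers lack the complementary (terminus) segment entirely
        lam[~inside] *= 1.0 - spec.prevalence
    # partial terminal bin accumulates proportionally fewer reads
    lam *= (ends - starts) / width_bp
    return lam


def gen_population_coverage(spec: PopulationSpec, width_bp: int = 200) -> CoverageTrack:
    """Per-bin Poisson coverage of the mixed population."""
    rng = np.random.default_rng(spec.seed)
    lam = _bin_rates(spec, width_bp)
    counts = rng.poisson(lam)
    n_bins = len(lam)
    starts = np.arange(n_bins) * width_bp
    partial = np.minimum(starts + width_bp, spec.chrom.length_bp) - starts < width_bp
    return CoverageTrack(
        chrom=spec.chrom, width_bp=width_bp, counts=counts, partial=partial
    )


def gen_read_starts(spec: PopulationSpec, n_reads: int, width_bp: int = 200) -> np.ndarray:
    """Individual read-start positions (for exercising the binning code).

    Bins are drawn with probability proportional to their mixture rate and
    a uniform offset is added within the bin; the marginal per-bin counts
    are multinomial with the same relative rates as the Poisson model.
    """
    rng = np.random.default_rng(spec.seed)
    lam = _bin_rates(spec, width_bp)
    p = lam / lam.sum()
    bins = rng.choice(len(lam), size=n_reads, p=p)
    starts = bins * width_bp
    widths = np.minimum(starts + width_bp, spec.chrom.length_bp) - starts
    return starts + rng.integers(0, widths)


# ---------------------------------------------------------------------------
# expression compendium

@dataclass(frozen=True)
class CompendiumSpec:
    """A latent-factor model of two anti-correlated expression domains.

    Per gene g and condition c the log-scale value is
    ``mu_g + s_g * a * z_c + eps`` with ``z_c`` standard normal per
    condition, ``s_g = +1`` for genes in the origin-centred domain and
    ``-1`` for the terminus-centred domain, and residual noise of SD
    ``noise_sd``.  ``domain_boundaries`` are the two coordinates splitting
    the circle; the arc containing the origin is the +1 domain.
    """

    chrom: ChromosomeMap
    n_genes: int = 460
    n_conditions: int = 300
    domain_boundaries: Optional[tuple[int, int]] = None
    loading: float = 3.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loading < 0:
            raise ValueError("loading must be >= 0")
        if self.n_conditions < 3:
            raise ValueError("need at least 3 conditions")


def _boundaries_or_default(spec: CompendiumSpec) -> tuple[int, int]:
    if spec.domain_boundaries is not None:
        return spec.domain_boundaries
    b = spec.chrom.boundary_candidates
    if len(b) >= 2:
        return (b[0], b[1])
    raise ValueError("no domain boundaries given and chromosome has no candidates")


def domain_signs(
    genes: Sequence[GeneAnnotation],
    chrom: ChromosomeMap,
    boundaries: tuple[int, int],
) -> np.ndarray:
    """+1 for genes in the origin-containing arc, -1 for the other arc."""
    seg = GenomicSegment(boundaries[0], boundaries[1])
    if not in_segment(chrom.ori_pos, seg, chrom):
        seg = GenomicSegment(boundaries[1], boundaries[0])
    mids = np.array([gene_midpoint(g) for g in genes])
    return np.where(positions_in_segment(mids, seg, chrom), 1, -1)


def gen_compendium(
    spec: CompendiumSpec, genes: Optional[Sequence[GeneAnnotation]] = None
) -> pd.DataFrame:
    """Genes x conditions log-scale expression matrix with planted domains."""
    if genes is None:
        genes = gen_gene_annotations(spec.chrom, spec.n_genes)
    rng = np.random.default_rng(spec.seed)
    s = domain_signs(genes, spec.chrom, _boundaries_or_default(spec))
    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    z = rng.standard_normal(spec.n_conditions)
    eps = rng.normal(0.0, spec.noise_sd, size=(len(genes), spec.n_conditions))
    values = mu[:, None] + spec.loading * s[:, None] * z[None, :] + eps
    return pd.DataFrame(
        values,
        index=[g.gene_id for g in genes],
        columns=[f"cond{c:03d}" for c in range(spec.n_conditions)],
    )


# ---------------------------------------------------------------------------
# differential-expression count matrices

@dataclass(frozen=True)
class DEScenario:
    """Planted transcriptional and dosage effects for a two-strain design.

    ``gene_sets`` are disjoint id lists (e.g. xenogeneically silenced
    targets, highly expressed growth genes, a stress regulon); ``effects``
    gives the log2 change each set undergoes in strain A relative to
    strain B.  Strain-A samples additionally carry ``dosage_factor`` on
    every gene inside ``amplified_segment``, emulating a segmental
    duplication's copy-number effect on the library.
    """

    gene_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    effects: Mapping[str, float] = field(default_factory=dict)
    amplified_segment: Optional[GenomicSegment] = None
    dosage_factor: float = 1.0
    replicates: int = 2
    library_sizes_a: Sequence[float] = (1.0, 1.0)
    library_sizes_b: Sequence[float] = (1.0, 1.0)
    dispersion: str = "poisson"
    nb_size: float = 10.0
    baseline_mean: float = 500.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids: set[str] = set()
        for name, members in self.gene_sets.items():
            members = set(members)
            if ids & members:
                raise ValueError(f"gene set {name!r} overlaps another set")
            ids |= members
        for name, e in self.effects.items():
            if not np.isfinite(e):
                raise ValueError(f"effect for {name!r} must be finite")
        if self.dispersion not in ("poisson", "negative-binomial"):
            raise ValueError("dispersion must be 'poisson' or 'negative-binomial'")
        if any(s <= 0 for s in self.library_sizes_a) or any(
            s <= 0 for s in self.library_sizes_b
        ):
            raise ValueError("library sizes must be positive")


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, scenario: DEScenario) -> np.ndarray:
    if scenario.dispersion == "poisson":
        return rng.poisson(mean)
    size = scenario.nb_size
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_de_counts(
    scenario: DEScenario,
    genes: Sequence[GeneAnnotation],
    chrom: ChromosomeMap,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Count matrices for strain A and strain B plus the planted truth.

    The truth table records, per gene, the planted transcriptional log2
    effect and the dosage factor applied in strain A; the raw expected
    count ratio A/B is ``2**log2_effect * dosage``.
    """
    known = {g.gene_id for g in genes}
    for name, members in scenario.gene_sets.items():
        missing = set(members) - known
        if missing:
            raise ValueError(f"gene set {name!r} has unknown ids: {sorted(missing)[:3]}")
    rng = np.random.default_rng(scenario.seed)
    n = len(genes)
    ids = [g.gene_id for g in genes]
    mu = scenario.baseline_mean * np.exp2(
        rng.normal(0.0, scenario.baseline_log2_sd, size=n)
    )
    effect = np.zeros(n)
    set_name = np.array(["-"] * n, dtype=object)
    idx = {g: i for i, g in enumerate(ids)}
    for name, members in scenario.gene_sets.items():
        e = scenario.effects.get(name, 0.0)
        for g in members:
            effect[idx[g]] = e
            set_name[idx[g]] = name
    dosage = np.ones(n)
    if scenario.amplified_segment is not None and scenario.dosage_factor != 1.0:
        mids = np.array([gene_midpoint(g) for g in genes])
        amplified = positions_in_segment(mids, scenario.amplified_segment, chrom)
        dosage[amplified] = scenario.dosage_factor

    def _matrix(strain: str, libsizes: Sequence[float], mean_per_gene: np.ndarray) -> CountMatrix:
        libsizes = np.atleast_1d(np.asarray(libsizes, dtype=float))
        if libsizes.size == 1:
            libsizes = np.repeat(libsizes, scenario.replicates)
        if libsizes.size < scenario.replicates:
            raise ValueError("fewer library sizes than replicates")
        cols = {}
        meta = []
        for r, ls in enumerate(libsizes[: scenario.replicates], start=1):
            sample = f"{strain}_r{r}"
            cols[sample] = _draw_counts(rng, mean_per_gene * ls, scenario)
            meta.append(
                {
                    "sample": sample,
                    "strain": strain,
                    "replicate": r,
                    "amplified_segment": (
                        f"{scenario.amplified_segment.start}-{scenario.amplified_segment.end}"
                        if strain == "A" and scenario.amplified_segment is not None
                        and scenario.dosage_factor != 1.0
                        else "-"
                    ),
                }
            )
        counts = pd.DataFrame(cols, index=ids)
        return CountMatrix(counts=counts, samples=pd.DataFrame(meta).set_index("sample"))

    mean_a = mu * np.exp2(effect) * dosage
    cm_a = _matrix("A", scenario.library_sizes_a, mean_a)
    cm_b = _matrix("B", scenario.library_sizes_b, mu)
    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "set": set_name,
            "log2_effect": effect,
            "dosage": dosage,
            "expected_raw_ratio": np.exp2(effect) * dosage,
        }
    ).set_index("gene_id")
    return cm_a, cm_b, truth
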