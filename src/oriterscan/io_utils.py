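"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: internal coordinates are 0-based half-open.  BED and bedGraph
arrive that way; GFF3 is converted from 1-based inclusive on read.  TSV
matrices carry the gene id in the first column, a header row of sample or
condition ids, tab delimiters, UTF-8, no quoting.  Every writer prefixes a
provenance comment header (tool version, config hash, seed); readers skip
``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_genome import ChromosomeMap, GeneAnnotation
from .coverage_amplification import CoverageTrack, NormalizedCoverage, make_bins

__all__ = [
    "provenance_header",
    "config_hash",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_annotations_bed",
    "read_annotations_gff3",
    "read_coverage_bedgraph",
    "write_coverage_bedgraph",
    "write_normalized_coverage_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_sheet",
    "read_gene_set",
    "parse_segment",
]


def config_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_header(seed: Optional[int] = None, params: Optional[dict] = None) -> str:
    parts = [f"oriterscan v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if params is not None:
        parts.append(f"config={config_hash(params)}")
    return "# " + " | ".join(parts) + "\n"


# ---------------------------------------------------------------------------
# annotations

def _frame_to_genes(df: pd.DataFrame) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(getattr(r, "strand", "?")),
        )
        for r in df.itertuples(index=False)
    ]


def read_annotations_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Plain TSV annotation: gene_id, start, end[, strand] (0-based, half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}")
    if "strand" not in df.columns:
        df["strand"] = "?"
    return _frame_to_genes(df)


def write_annotations_tsv(
    genes: Sequence[GeneAnnotation], path: str | Path, seed: Optional[int] = None
) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed))
        df.to_csv(fh, sep="\t", index=False)


def read_annotations_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED (0-based, half-open): chrom, start, end, name[, score, strand]."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs at least 4 columns (incl. name)")
    genes = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5].astype(str) if df.shape[1] > 5 else "?",
        }
    )
    return _frame_to_genes(genes)


def read_annotations_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """GFF3 (1-based, inclusive) via gffutils; converts to internal coords."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        attrs = feat.attributes
        gene_id = (
            attrs.get("ID", [None])[0]
            or attrs.get("gene_id", [None])[0]
            or attrs.get("locus_tag", [feat.id])[0]
        )
        genes.append(
            GeneAnnotation(
                gene_id=str(gene_id),
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "?",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# coverage

def read_coverage_bedgraph(
    path: str | Path, chrom: ChromosomeMap, width_bp: Optional[int] = None
) -> CoverageTrack:
    """bedGraph (chrom, start, end, value) or 2-column TSV (start, value)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] >= 4:
        starts, values = df[1].to_numpy(int), df[3].to_numpy(float)
    elif df.shape[1] == 2:
        starts, values = df[0].to_numpy(int), df[1].to_numpy(float)
    else:
        raise ValueError(f"{path}: expected bedGraph (4 cols) or start/count TSV (2 cols)")
    if width_bp is None:
        if len(starts) < 2:
            raise ValueError(f"{path}: cannot infer bin width from a single bin")
        width_bp = int(np.diff(np.sort(starts)).min())
    bins = make_bins(chrom, width_bp)
    counts = np.zeros(len(bins))
    idx = starts // width_bp
    if idx.max() >= len(bins) or (starts % width_bp).any():
        raise ValueError(f"{path}: bin starts are not a {width_bp}-bp tiling of the chromosome")
    counts[idx] = values
    partial = np.array([b.partial for b in bins])
    return CoverageTrack(chrom=chrom, width_bp=width_bp, counts=counts.astype(np.int64), partial=partial)


def write_coverage_bedgraph(
    track: CoverageTrack, path: str | Path, name: str = "chr",
    seed: Optional[int] = None,
) -> None:
    starts = track.bin_starts
    ends = np.minimum(starts + track.width_bp, track.chrom.length_bp)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed))
        for s, e, c in zip(starts, ends, track.counts):
            fh.write(f"{name}\t{s}\t{e}\t{c}\n")


def write_normalized_coverage_tsv(
    norm: NormalizedCoverage, path: str | Path, seed: Optional[int] = None
) -> None:
    track = norm.source
    df = pd.DataFrame(
        {
            "bin_start": track.bin_starts,
            "count": track.counts,
            "log2_norm": norm.log2_values,
            "partial": track.partial.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, params={"mode_factor": norm.mode_factor}))
        fh.write(f"# mode_factor={norm.mode_factor:.6g}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices and sheets

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples/conditions TSV; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    return df


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, params=params))
        df.to_csv(fh, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample, strain, replicate, amplified_segment ("-" if none)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"amplified_segment": str})
    required = {"sample", "strain", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    if "amplified_segment" not in df.columns:
        df["amplified_segment"] = "-"
    return df.set_index("sample")


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and # comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if not ids:
        raise ValueError(f"{path}: empty gene set")
    return ids


def parse_segment(text: str):
    """Parse "start-end" into a GenomicSegment (wrapping allowed)."""
    from .core_genome import GenomicSegment

    try:
        start, end = (int(x) for x in text.split("-", 1))
    except ValueError as exc:
        raise ValueError(f"cannot parse segment {text!r}; expected 'start-end'") from exc
    return GenomicSegment(start, end)
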