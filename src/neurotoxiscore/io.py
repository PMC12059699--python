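"""File input/output: TIFF channels, annotations, peaks, count matrices.

All genomic coordinates are 0-based half-open in memory. BED is read as-is
(already half-open); GTF records (1-based, end-inclusive) are converted on
read. Masks and label maps are written as 16-bit TIFF for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .images import BinaryMask, ChannelImage, Channel, LabelMap
from .genomics import ExpressionTable, GeneAnnotation, PeakSet

__all__ = [
    "read_channel_tiff",
    "write_tiff",
    "read_annotation_tsv",
    "read_annotation_gtf",
    "read_bed",
    "write_bed",
    "read_expression",
    "write_json",
]


def read_channel_tiff(path: str | Path, channel: Channel = "other",
                      page: int = 0, scale: Optional[float] = None,
                      ) -> ChannelImage:
    """Read one page of a (possibly multi-page) TIFF as a ChannelImage."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.pages[page].asarray()
    return ChannelImage(np.asarray(data, dtype=float), channel, scale)


def write_tiff(path: str | Path, raster: ChannelImage | BinaryMask | LabelMap,
               ) -> None:
    """Write a raster as 16-bit TIFF (masks as 0/1, intensities clipped)."""
    px = raster.pixels
    if px.dtype == bool:
        data = px.astype(np.uint16)
    else:
        data = np.clip(px, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_annotation_tsv(path: str | Path) -> GeneAnnotation:
    """Read a minimal annotation TSV: gene_id, chrom, start, end, strand, length_bp.

    Coordinates in the TSV are already 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df)


def read_annotation_gtf(path: str | Path, feature: str = "gene",
                        length_from_span: bool = True) -> GeneAnnotation:
    """Read gene records from a GTF file (1-based inclusive -> half-open).

    ``length_bp`` defaults to the genomic span; supply a proper
    transcript-model length via a TSV if exon-union lengths are required.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(" ", 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                continue
            start0 = int(start) - 1
            end0 = int(end)
            rows.append({"gene_id": gene_id, "chrom": chrom, "start": start0,
                         "end": end0, "strand": strand,
                         "length_bp": float(end0 - start0) if length_from_span
                         else np.nan})
    return GeneAnnotation(pd.DataFrame(rows))


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ file (0-based half-open, as BED is defined)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return PeakSet(tuple(intervals))


def write_bed(path: str | Path, peaks: PeakSet) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_expression(counts_path: str | Path, meta_path: str | Path,
                    lengths: pd.Series | None = None,
                    annotation: GeneAnnotation | None = None,
                    ) -> ExpressionTable:
    """Read a count matrix (genes x samples CSV/TSV) plus sample metadata.

    Gene lengths come either from an explicit Series or from an annotation's
    ``length_bp`` column.
    """
    sep = "\t" if str(counts_path).endswith((".tsv", ".txt")) else ","
    counts = pd.read_csv(counts_path, sep=sep, index_col=0)
    meta = pd.read_csv(meta_path, sep="\t" if str(meta_path).endswith(
        (".tsv", ".txt")) else ",")
    if lengths is None:
        if annotation is None:
            raise ValueError("supply gene lengths or an annotation")
        lengths = annotation.lengths()
    return ExpressionTable(counts, meta, lengths)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
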