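"""Genomic metaprofiles: coverage binning around TSSs and over scaled gene
bodies, fragment-length filtering, and RPKM.

Coordinates are 0-based half-open (BED convention) throughout. The TSS of a
minus-strand gene is ``end - 1`` and its TES ``start``; profile matrices are
always oriented 5' -> 3' in transcription direction, so column 0 is the
5'-most bin for every gene regardless of strand. Bin values are mean coverage
over the bin's bases; bases beyond chromosome edges contribute 0 (with a
logged warning), matching how aggregate coverage plots treat edge genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_bed, read_bedgraph, write_bed, write_bedgraph, write_table

logger = logging.getLogger(__name__)


class MalformedIntervalError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise MalformedIntervalError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise MalformedIntervalError(f"gene {self.gene_id}: bad strand")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def genes_from_bed(
    path: str | Path, protein_coding_only: bool = True
) -> list[GeneModel]:
    """Read gene models from BED6 (optionally BED6+1 with a biotype column;
    when that column is present and ``protein_coding_only`` is set, only
    protein_coding genes are kept)."""
    df = read_bed(path)
    if "extra1" in df.columns and protein_coding_only:
        df = df[df["extra1"] == "protein_coding"]
    return [
        GeneModel(str(r.chrom), int(r.start), int(r.end), str(r.strand), str(r.name))
        for r in df.itertuples(index=False)
    ]


def genes_to_bed(path: str | Path, genes: list[GeneModel]) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )
    write_bed(path, df)


class CoverageTrack:
    """Per-base coverage over a (small) genome, held densely per chromosome.

    Step intervals from a bedGraph are materialized to per-base values;
    intervals must be sorted, non-overlapping, and within chromosome bounds.
    """

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for chrom, v in self.data.items():
            if (v < 0).any():
                raise ValueError(f"negative coverage on {chrom}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n) for c, n in chrom_sizes.items()})

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, chrom_sizes: dict[str, int]
    ) -> "CoverageTrack":
        track = cls.zeros(chrom_sizes)
        df = read_bedgraph(path)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"bedGraph chromosome {chrom} not in sizes")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts < 0).any() or (ends > chrom_sizes[chrom]).any():
                raise ValueError(f"bedGraph interval outside {chrom} bounds")
            if (ends[:-1] > starts[1:]).any():
                raise ValueError(f"bedGraph intervals overlap/unsorted on {chrom}")
            arr = track.data[str(chrom)]
            for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
                arr[s:e] = v
        return track

    def to_bedgraph(self, path: str | Path, include_zero: bool = False) -> None:
        rows = []
        for chrom in self.data:
            v = self.data[chrom]
            change = np.flatnonzero(np.diff(v)) + 1
            bounds = np.concatenate(([0], change, [len(v)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                val = v[s]
                if val != 0 or include_zero:
                    rows.append((chrom, int(s), int(e), float(val)))
        write_bedgraph(path, pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values on [start, end); out-of-chromosome bases are 0."""
        arr = self.data[chrom]
        n = len(arr)
        out = np.zeros(end - start)
        lo, hi = max(start, 0), min(end, n)
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        if start < 0 or end > n:
            logger.warning(
                "window [%d, %d) extends beyond %s (length %d); padding with 0",
                start, end, chrom, n,
            )
        return out


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def filter_fragments(
    fragments: pd.DataFrame, min_len: int, max_len: int
) -> pd.DataFrame:
    """Keep fragments with min_len <= end-start <= max_len (both bounds
    inclusive); order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lengths = fragments["end"] - fragments["start"]
    if (lengths < 0).any():
        bad = fragments[lengths < 0].index[0]
        raise MalformedIntervalError(f"negative-length interval at row {bad}")
    return fragments[(lengths >= min_len) & (lengths <= max_len)]


def fragments_to_coverage(
    fragments: pd.DataFrame, chrom_sizes: dict[str, int]
) -> CoverageTrack:
    """Per-base overlap count of fragments; the genome-wide coverage sum
    equals the summed fragment lengths."""
    track = CoverageTrack.zeros(chrom_sizes)
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"fragment chromosome {chrom} not in sizes")
        n = chrom_sizes[str(chrom)]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts < 0).any() or (ends > n).any():
            raise ValueError(f"fragment outside {chrom} bounds")
        # difference-array trick: +1 at starts, -1 at ends, then cumsum
        delta = np.zeros(n + 1)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        track.data[str(chrom)] = np.cumsum(delta[:-1])
    return track


# ---------------------------------------------------------------------------
# Profile matrices
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Genes x bins signal matrix, rows oriented 5' -> 3'."""

    values: np.ndarray
    gene_ids: list[str]
    bin_size: int
    anchor: str  # "reference_point_TSS" or "scale_regions"
    upstream_bp: int = 0
    downstream_bp: int = 0
    body_bins: int = 0
    n_skipped: int = 0

    def bin_positions(self) -> np.ndarray:
        """Bin-center coordinates: bp relative to the TSS for reference-point
        matrices, fractional bin index otherwise."""
        if self.anchor == "reference_point_TSS":
            return (
                -self.upstream_bp
                + self.bin_size * np.arange(self.values.shape[1])
                + self.bin_size / 2
            )
        return np.arange(self.values.shape[1], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"bin{i}" for i in range(self.values.shape[1])]
        )
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def write(self, path: str | Path, metadata: dict | None = None) -> None:
        meta = {
            "anchor": self.anchor,
            "bin_size": self.bin_size,
            "upstream_bp": self.upstream_bp,
            "downstream_bp": self.downstream_bp,
            "body_bins": self.body_bins,
            "n_skipped": self.n_skipped,
        }
        meta.update(metadata or {})
        write_table(path, self.to_frame(), meta)


def reference_point_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    bin_size: int = 25,
) -> ProfileMatrix:
    """Mean coverage in fixed-width bins across a TSS-anchored window.

    The window spans ``upstream_bp`` before to ``downstream_bp`` after the
    TSS in transcription direction; minus-strand windows are mirrored so that
    column 0 is always the 5'-most (most upstream) bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if upstream_bp % bin_size or downstream_bp % bin_size:
        raise ValueError("window extents must be divisible by bin_size")
    nbins = (upstream_bp + downstream_bp) // bin_size
    rows = np.empty((len(genes), nbins))
    for i, g in enumerate(genes):
        if g.strand == "+":
            win = track.values(g.chrom, g.tss - upstream_bp, g.tss + downstream_bp)
        else:
            win = track.values(
                g.chrom, g.tss - downstream_bp + 1, g.tss + upstream_bp + 1
            )[::-1]
        rows[i] = win.reshape(nbins, bin_size).mean(axis=1)
    return ProfileMatrix(
        values=rows,
        gene_ids=[g.gene_id for g in genes],
        bin_size=bin_size,
        anchor="reference_point_TSS",
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
    )


def scale_regions_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    body_bins: int = 40,
    flank_bp: int = 1000,
    bin_size: int = 25,
) -> ProfileMatrix:
    """TSS-to-TES matrix: gene bodies rescaled onto ``body_bins`` equal
    fractions, flanks binned at ``bin_size``.

    Base j of an L-bp body maps to body bin floor(j*body_bins/L); the bin
    value is the mean coverage of its bases. Genes shorter than ``body_bins``
    bases are skipped (count reported on the matrix). Minus-strand genes are
    mirrored into transcription orientation.
    """
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if flank_bp % bin_size:
        raise ValueError("flank_bp must be divisible by bin_size")
    flank_bins = flank_bp // bin_size
    kept_rows = []
    kept_ids = []
    skipped = 0
    for g in genes:
        L = g.length
        if L < body_bins:
            skipped += 1
            continue
        if g.strand == "+":
            body = track.values(g.chrom, g.start, g.end)
            up = track.values(g.chrom, g.start - flank_bp, g.start)
            down = track.values(g.chrom, g.end, g.end + flank_bp)
        else:
            body = track.values(g.chrom, g.start, g.end)[::-1]
            up = track.values(g.chrom, g.end, g.end + flank_bp)[::-1]
            down = track.values(g.chrom, g.start - flank_bp, g.start)[::-1]
        idx = (np.arange(L) * body_bins) // L
        sums = np.bincount(idx, weights=body, minlength=body_bins)
        sizes = np.bincount(idx, minlength=body_bins)
        body_means = sums / sizes
        if flank_bins:
            up_means = up.reshape(flank_bins, bin_size).mean(axis=1)
            down_means = down.reshape(flank_bins, bin_size).mean(axis=1)
            row = np.concatenate([up_means, body_means, down_means])
        else:
            row = body_means
        kept_rows.append(row)
        kept_ids.append(g.gene_id)
    if skipped:
        logger.warning("skipped %d genes shorter than %d bp", skipped, body_bins)
    values = (
        np.vstack(kept_rows)
        if kept_rows
        else np.empty((0, 2 * flank_bins + body_bins))
    )
    return ProfileMatrix(
        values=values,
        gene_ids=kept_ids,
        bin_size=bin_size,
        anchor="scale_regions",
        upstream_bp=flank_bp,
        downstream_bp=flank_bp,
        body_bins=body_bins,
        n_skipped=skipped,
    )


def aggregate_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column means over genes — the aggregate metaprofile curve."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot aggregate an empty profile matrix")
    return matrix.values.mean(axis=0)


def rpkm(
    read_count_per_gene: np.ndarray,
    gene_length_bp: np.ndarray,
    total_mapped_reads: float,
) -> np.ndarray:
    """Reads per kilobase of gene per million mapped reads."""
    counts = np.asarray(read_count_per_gene, dtype=float)
    lengths = np.asarray(gene_length_bp, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return counts / ((lengths / 1e3) * (total_mapped_reads / 1e6))
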