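"""Synthetic genome fixtures for the metaprofile stage.

Builds a small two-chromosome genome with non-overlapping stranded genes and
writes per-mark coverage tracks whose spatial templates are specified
relative to the TSS in transcription coordinates — a peak hugging the TSS
(the localization pattern of H2A.Z, which sits around the +1/-1 nucleosomes)
versus a plateau over the gene body (the pattern of H2BK120ub) — plus
nucleosome-sized fragment intervals for the coverage/occupancy path. Every
output is deterministic for a fixed seed; at noise 0 the tracks equal their
templates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_bed, write_chrom_sizes
from .metaprofile import CoverageTrack, GeneModel, genes_to_bed
from .utils import derive_seed

DEFAULT_CHROM_SIZES = {"chrS1": 600_000, "chrS2": 400_000}

TEMPLATE_KINDS = ("flat", "boxcar", "tss_peak", "gene_body")


@dataclass(frozen=True)
class MarkShape:
    """Deterministic spatial template of one synthetic mark.

    kind:
      flat      — constant ``height`` everywhere (background signal);
      boxcar    — ``height`` on [offset, offset+width) in transcription
                  coordinates relative to the TSS;
      tss_peak  — Gaussian bump of ``height`` and ``sigma`` bp centered
                  ``offset`` bp from the TSS (default 0, i.e. at the TSS);
      gene_body — ramps from 0 at the TSS to ``height`` over ``rise`` bp,
                  stays flat to the TES, decays to 0 over ``decay`` bp after.
    ``noise_sd`` adds i.i.d. Gaussian noise per base (clipped at 0).
    """

    kind: str
    height: float = 1.0
    offset: int = 0
    width: int = 100
    sigma: float = 80.0
    rise: int = 300
    decay: int = 200
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in TEMPLATE_KINDS:
            raise ValueError(f"unknown template kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_gene_models(
    chrom_sizes: dict[str, int] | None = None,
    n_genes: int = 120,
    length_range: tuple[int, int] = (2_000, 10_000),
    margin: int = 2_500,
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping genes on both strands, at least ``margin`` bp
    from chromosome ends and from each other (so flanking windows do not
    collide)."""
    chrom_sizes = chrom_sizes or DEFAULT_CHROM_SIZES
    rng = np.random.default_rng(derive_seed(seed, "genes"))
    total = sum(chrom_sizes.values())
    genes: list[GeneModel] = []
    gid = 0
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        target = max(1, round(n_genes * size / total))
        pos = margin
        placed = 0
        while placed < target:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            gap = int(rng.integers(margin, 2 * margin))
            start = pos + gap
            end = start + length
            if end > size - margin:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(chrom, start, end, strand, f"gene_{gid:04d}"))
            pos = end
            placed += 1
    if not genes:
        raise ValueError("genome too small to place any gene")
    return genes


def _add_template(
    arr: np.ndarray, gene: GeneModel, shape: MarkShape
) -> None:
    """Add a gene-anchored template to a dense chromosome array, in place.

    Transcription coordinate d (0 at the TSS, increasing 5'->3') maps to the
    genomic base ``tss + d`` on the plus strand and ``tss - d`` on the minus
    strand.
    """
    if shape.kind == "flat":
        return  # handled genome-wide
    L = gene.length
    if shape.kind == "boxcar":
        d = np.arange(shape.offset, shape.offset + shape.width)
        vals = np.full(d.size, float(shape.height))
    elif shape.kind == "tss_peak":
        half = int(np.ceil(4 * shape.sigma))
        d = np.arange(shape.offset - half, shape.offset + half + 1)
        vals = shape.height * np.exp(-((d - shape.offset) ** 2) / (2 * shape.sigma**2))
    else:  # gene_body
        d = np.arange(0, L + shape.decay)
        vals = np.where(
            d < L,
            shape.height * np.minimum(d / max(shape.rise, 1), 1.0),
            shape.height * np.maximum(1.0 - (d - L + 1) / max(shape.decay, 1), 0.0),
        )
    g = gene.tss + d if gene.strand == "+" else gene.tss - d
    inside = (g >= 0) & (g < len(arr))
    np.add.at(arr, g[inside], vals[inside])


def simulate_coverage_tracks(
    chrom_sizes: dict[str, int],
    genes: list[GeneModel],
    shapes: dict[str, MarkShape],
    seed: int = 0,
    outdir: str | Path | None = None,
    n_fragments: int = 20_000,
    fragment_length: tuple[float, float] = (147.0, 30.0),
    fragment_bounds: tuple[int, int] = (80, 250),
) -> dict[str, object]:
    """Build per-mark coverage tracks, fragment intervals, and gene models.

    Genes must fit their chromosomes (a gene extending past an end is
    rejected). When ``outdir`` is given, tracks are written as bedGraph and
    the genes/fragments as BED6, alongside a chrom-sizes TSV.

    Returns ``{"tracks": {mark: CoverageTrack}, "fragments": DataFrame,
    "genes": genes, "paths": {...}}``.
    """
    if sum(chrom_sizes.values()) > 5_000_000:
        raise ValueError("synthetic genome capped at 5 Mb")
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.start < 0 or g.end > chrom_sizes[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id} extends past chromosome {g.chrom} bounds"
            )

    tracks: dict[str, CoverageTrack] = {}
    for mark in sorted(shapes):
        shape = shapes[mark]
        data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
        if shape.kind == "flat":
            for arr in data.values():
                arr += shape.height
        else:
            for g in genes:
                _add_template(data[g.chrom], g, shape)
        if shape.noise_sd > 0:
            rng = np.random.default_rng(derive_seed(seed, f"noise:{mark}"))
            for chrom in sorted(data):
                data[chrom] = np.clip(
                    data[chrom] + rng.normal(0, shape.noise_sd, len(data[chrom])),
                    0,
                    None,
                )
        tracks[mark] = CoverageTrack(data)

    fragments = _simulate_fragments(
        chrom_sizes, n_fragments, fragment_length, fragment_bounds, seed
    )

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mark, track in tracks.items():
            p = outdir / f"{mark}.bedGraph"
            track.to_bedgraph(p)
            paths[f"track:{mark}"] = p
        genes_to_bed(outdir / "genes.bed", genes)
        write_bed(outdir / "fragments.bed", fragments)
        write_chrom_sizes(outdir / "chrom.sizes", chrom_sizes)
        paths["genes"] = outdir / "genes.bed"
        paths["fragments"] = outdir / "fragments.bed"
        paths["chrom_sizes"] = outdir / "chrom.sizes"
    return {"tracks": tracks, "fragments": fragments, "genes": genes, "paths": paths}


def _simulate_fragments(
    chrom_sizes: dict[str, int],
    n_fragments: int,
    length_params: tuple[float, float],
    bounds: tuple[int, int],
    seed: int,
) -> pd.DataFrame:
    """Nucleosome-footprint-like fragments: truncated-normal lengths (mean /
    SD ``length_params``, resampled into ``bounds``), uniform placement."""
    rng = np.random.default_rng(derive_seed(seed, "fragments"))
    mean, sd = length_params
    lo, hi = bounds
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(chroms), size=n_fragments, p=weights)
    lengths = np.rint(rng.normal(mean, sd, n_fragments)).astype(int)
    bad = (lengths < lo) | (lengths > hi)
    while bad.any():
        lengths[bad] = np.rint(rng.normal(mean, sd, int(bad.sum()))).astype(int)
        bad = (lengths < lo) | (lengths > hi)
    rows = {
        "chrom": [chroms[i] for i in chrom_idx],
        "start": np.empty(n_fragments, dtype=int),
        "end": np.empty(n_fragments, dtype=int),
    }
    sizes = np.array([chrom_sizes[c] for c in chroms])
    starts = (rng.random(n_fragments) * (sizes[chrom_idx] - lengths)).astype(int)
    rows["start"] = starts
    rows["end"] = starts + lengths
    df = pd.DataFrame(rows)
    df["name"] = [f"frag_{i}" for i in range(n_fragments)]
    df["score"] = 0
    df["strand"] = np.where(rng.random(n_fragments) < 0.5, "+", "-")
    return df
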