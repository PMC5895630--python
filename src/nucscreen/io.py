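"""Plain-text file I/O: FASTQ streams, TSV tables with metadata headers,
BED/bedGraph, chromosome sizes.

All tabular outputs carry a ``# key: value`` comment header (package version,
seed, config hash, ...) so that any result file is self-describing; the
readers here round-trip that metadata.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam


class PairingError(ValueError):
    """Raised when two FASTQ streams that should be record-aligned are not."""


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` for each record of a FASTQ file.

    Gzipped input is handled transparently by htslib.
    """
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence


def paired_fastq_chunks(
    r1: str | Path,
    r2: str | Path,
    chunk_size: int = 500_000,
) -> Iterator[tuple[list[str], list[str], list[str]]]:
    """Stream two record-aligned FASTQ files in chunks.

    Yields ``(ids, seqs1, seqs2)`` lists of equal length. Record ids must
    match pairwise after stripping a trailing ``/1`` / ``/2``; a mismatch or a
    length difference raises :class:`PairingError` naming the offending
    record.
    """
    ids: list[str] = []
    s1: list[str] = []
    s2: list[str] = []
    n = 0
    with pysam.FastxFile(str(r1)) as fh1, pysam.FastxFile(str(r2)) as fh2:
        it1, it2 = iter(fh1), iter(fh2)
        while True:
            a = next(it1, None)
            b = next(it2, None)
            if a is None and b is None:
                break
            n += 1
            if a is None or b is None:
                short = "R1" if a is None else "R2"
                raise PairingError(f"{short} stream ends early at record {n}")
            name_a = _strip_mate(a.name)
            name_b = _strip_mate(b.name)
            if name_a != name_b:
                raise PairingError(
                    f"id mismatch at record {n}: {a.name!r} vs {b.name!r}"
                )
            ids.append(name_a)
            s1.append(a.sequence)
            s2.append(b.sequence)
            if len(ids) >= chunk_size:
                yield ids, s1, s2
                ids, s1, s2 = [], [], []
    if ids:
        yield ids, s1, s2


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write ``(name, sequence, quality)`` records as 4-line FASTQ
    (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# TSV with '# key: value' metadata headers
# ---------------------------------------------------------------------------

def write_table(
    path: str | Path, df: pd.DataFrame, metadata: dict[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, metadata


# ---------------------------------------------------------------------------
# Genomic interval formats (BED, bedGraph, chrom sizes)
# ---------------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED into a DataFrame; 0-based half-open coordinates.

    Columns beyond the sixth are kept with generic names (``extra1`` ...),
    which lets a seventh biotype column through for gene annotations.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = BED6_COLUMNS[:ncol] + [f"extra{i}" for i in range(1, ncol - 5)]
    df.columns = names[:ncol]
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=BEDGRAPH_COLUMNS
    )
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    # %g-style formatting keeps integral values compact and exact
    out["value"] = out["value"].map(lambda v: f"{v:.10g}")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
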