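"""Dual-barcode read processing: pair merging, demultiplexing, counting.

Each sequenced fragment carries two reads — one covering the nucleosomal
barcode (which library member) and one covering the multiplexing barcode
(which sample/replicate). Processing merges the two reads of a fragment into
one record, splits records by multiplexing barcode, and counts nucleosomal
barcodes per sample into a member x sample count table.

Matching policy: exact by default. With ``max_mismatch > 0``, a read is
assigned to the unique barcode within that Hamming distance that is strictly
closer than every other barcode; ties and non-matches go to the unassigned
tally (counted, never dropped). The nucleosomal barcode sits at a fixed
configured offset in its read (default 0); the multiplexing barcode is
matched against the read prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .io import PairingError, paired_fastq_chunks, read_table, write_table
from .manifest import LibraryMember
from .utils import encode_sequences

logger = logging.getLogger(__name__)

UNASSIGNED_NUC_ROW = "UNASSIGNED_NUC"


class SampleSheetError(ValueError):
    """Sample sheet violates a precondition (e.g. duplicate barcodes)."""


@dataclass(frozen=True)
class BarcodeRecord:
    """The merged dual-barcode record of one sequenced fragment."""

    fragment_id: str
    nuc_read: str
    multiplex_read: str

    def __post_init__(self):
        if not self.nuc_read or not self.multiplex_read:
            raise ValueError(f"empty read in record {self.fragment_id!r}")


def merge_read_pairs(
    fastq_r1: str | Path, fastq_r2: str | Path
) -> Iterator[BarcodeRecord]:
    """Merge two record-aligned FASTQ streams (nucleosomal-barcode read,
    multiplexing-barcode read) into one BarcodeRecord per fragment.

    Raises :class:`nucscreen.io.PairingError` on id mismatch or unequal
    stream lengths, naming the offending record.
    """
    for ids, s1, s2 in paired_fastq_chunks(fastq_r1, fastq_r2):
        for fid, a, b in zip(ids, s1, s2):
            yield BarcodeRecord(fid, a, b)


# ---------------------------------------------------------------------------
# Vectorized nearest-unique barcode assignment
# ---------------------------------------------------------------------------

def assign_nearest_unique(
    seq_mat: np.ndarray,
    code_mat: np.ndarray,
    max_mismatch: int,
    chunk: int = 200_000,
) -> np.ndarray:
    """Assign each encoded read (rows of ``seq_mat``) to the unique nearest
    code (rows of ``code_mat``) within ``max_mismatch`` substitutions.

    Returns an int array with the code index, or -1 for non-matching or
    ambiguous (tied-minimum) reads. With ``max_mismatch == 0`` this reduces
    to an exact dictionary lookup.
    """
    n = seq_mat.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return out
    if max_mismatch == 0:
        k = code_mat.shape[1]
        lut = {code_mat[j].tobytes(): j for j in range(code_mat.shape[0])}
        blob = seq_mat.tobytes()
        out[:] = [lut.get(blob[i * k : (i + 1) * k], -1) for i in range(n)]
        return out
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        # (rows, codes) mismatch-count matrix
        dists = (seq_mat[lo:hi, None, :] != code_mat[None, :, :]).sum(axis=2)
        best = dists.argmin(axis=1)
        dmin = dists[np.arange(hi - lo), best]
        ties = (dists == dmin[:, None]).sum(axis=1) > 1
        ok = (dmin <= max_mismatch) & ~ties
        out[lo:hi] = np.where(ok, best, -1)
    return out


def _sheet_codes(sample_sheet: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    codes = [str(c) for c in sample_sheet["multiplex_barcode"]]
    if len(set(codes)) != len(codes):
        raise SampleSheetError("duplicate multiplex barcodes in sample sheet")
    if len({len(c) for c in codes}) != 1:
        raise SampleSheetError("multiplex barcodes must be equal length")
    return codes, encode_sequences(codes, len(codes[0]))


def demultiplex(
    records: Iterable[BarcodeRecord],
    sample_sheet: pd.DataFrame,
    max_mismatch: int = 0,
) -> tuple[dict[str, list[BarcodeRecord]], list[BarcodeRecord]]:
    """Partition records by multiplexing barcode (read-prefix match).

    Returns ``(per_sample, unassigned)``; the partition is exhaustive and
    disjoint.
    """
    records = list(records)
    codes, code_mat = _sheet_codes(sample_sheet)
    sample_ids = list(sample_sheet["sample_id"].astype(str))
    seq_mat = encode_sequences(
        [r.multiplex_read for r in records], code_mat.shape[1]
    )
    assignment = assign_nearest_unique(seq_mat, code_mat, max_mismatch)
    per_sample: dict[str, list[BarcodeRecord]] = {s: [] for s in sample_ids}
    unassigned: list[BarcodeRecord] = []
    for rec, j in zip(records, assignment):
        if j < 0:
            unassigned.append(rec)
        else:
            per_sample[sample_ids[j]].append(rec)
    return per_sample, unassigned


def count_barcodes(
    records: Iterable[BarcodeRecord],
    manifest: Sequence[LibraryMember],
    max_mismatch: int = 0,
    offset: int = 0,
) -> tuple[np.ndarray, int]:
    """Count nucleosomal barcodes in one sample's records.

    Returns ``(counts, unassigned)`` with counts ordered as the manifest.
    A record increments member i iff the k-mer at ``offset`` in its
    nucleosomal read is within ``max_mismatch`` of barcode i and strictly
    closer to i than to any other member.
    """
    barcodes = [m.barcode for m in manifest]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("manifest barcodes are not unique")
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("manifest barcodes must be equal length")
    k = len(barcodes[0])
    code_mat = encode_sequences(barcodes, k)
    seqs = [r.nuc_read for r in records]
    assignment = assign_nearest_unique(
        encode_sequences(seqs, k, offset), code_mat, max_mismatch
    )
    counts = np.bincount(assignment[assignment >= 0], minlength=len(barcodes))
    return counts.astype(np.int64), int((assignment < 0).sum())


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Member x sample count matrix with unassigned tallies.

    Conservation invariant: per sample, member counts plus that sample's
    unassigned-nucleosomal tally equal the records demultiplexed to it, and
    summing those over samples plus ``unassigned_multiplex`` recovers the
    total record count.
    """

    members: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_members, n_samples) int64
    unassigned_nuc: np.ndarray  # per sample
    unassigned_multiplex: int
    total_records: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.unassigned_nuc = np.asarray(self.unassigned_nuc, dtype=np.int64)
        if self.counts.shape != (len(self.members), len(self.samples)):
            raise ValueError("counts shape does not match members x samples")
        if (self.counts < 0).any() or (self.unassigned_nuc < 0).any():
            raise ValueError("counts must be nonnegative")
        assigned = int(self.counts.sum() + self.unassigned_nuc.sum())
        if assigned + self.unassigned_multiplex != self.total_records:
            raise ValueError(
                "conservation violated: "
                f"{assigned} assigned + {self.unassigned_multiplex} unassigned "
                f"!= {self.total_records} records"
            )

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "member_id", self.members)
        unrow = pd.DataFrame(
            [[UNASSIGNED_NUC_ROW, *self.unassigned_nuc.tolist()]],
            columns=df.columns,
        )
        return pd.concat([df, unrow], ignore_index=True)

    def write(self, path: str | Path, metadata: dict | None = None) -> None:
        meta = dict(metadata or {})
        meta["unassigned_multiplex"] = self.unassigned_multiplex
        meta["total_records"] = self.total_records
        write_table(path, self.to_frame(), meta)

    @classmethod
    def read(cls, path: str | Path) -> "CountTable":
        df, meta = read_table(path)
        unmask = df["member_id"] == UNASSIGNED_NUC_ROW
        samples = [c for c in df.columns if c != "member_id"]
        body = df[~unmask]
        return cls(
            members=list(body["member_id"].astype(str)),
            samples=samples,
            counts=body[samples].to_numpy(dtype=np.int64),
            unassigned_nuc=df[unmask][samples].to_numpy(dtype=np.int64).ravel(),
            unassigned_multiplex=int(meta.get("unassigned_multiplex", 0)),
            total_records=int(meta["total_records"]),
        )


def count_run(
    fastq_pairs: Sequence[tuple[str | Path, str | Path]],
    manifest: Sequence[LibraryMember],
    sample_sheet: pd.DataFrame,
    max_mismatch_nuc: int = 0,
    max_mismatch_mx: int = 0,
    offset: int = 0,
    chunk_size: int = 500_000,
) -> CountTable:
    """Stream all FASTQ pairs of a run (their concatenation is the pooled
    sequencing output), demultiplex, count nucleosomal barcodes, and return
    the CountTable. Memory is bounded by ``chunk_size`` records."""
    barcodes = [m.barcode for m in manifest]
    k = len(barcodes[0])
    code_mat = encode_sequences(barcodes, k)
    mx_codes, mx_mat = _sheet_codes(sample_sheet)

    M, S = len(barcodes), len(mx_codes)
    counts = np.zeros((M, S), dtype=np.int64)
    unassigned_nuc = np.zeros(S, dtype=np.int64)
    unassigned_mx = 0
    total = 0
    for r1, r2 in fastq_pairs:
        for ids, s1, s2 in paired_fastq_chunks(r1, r2, chunk_size):
            total += len(ids)
            sample_asn = assign_nearest_unique(
                encode_sequences(s2, mx_mat.shape[1]), mx_mat, max_mismatch_mx
            )
            member_asn = assign_nearest_unique(
                encode_sequences(s1, k, offset), code_mat, max_mismatch_nuc
            )
            unassigned_mx += int((sample_asn < 0).sum())
            in_sample = sample_asn >= 0
            nuc_missing = in_sample & (member_asn < 0)
            np.add.at(unassigned_nuc, sample_asn[nuc_missing], 1)
            both = in_sample & (member_asn >= 0)
            np.add.at(counts, (member_asn[both], sample_asn[both]), 1)
    table = CountTable(
        members=[m.member_id for m in manifest],
        samples=list(sample_sheet["sample_id"].astype(str)),
        counts=counts,
        unassigned_nuc=unassigned_nuc,
        unassigned_multiplex=unassigned_mx,
        total_records=total,
    )
    frac_mx = unassigned_mx / total if total else 0.0
    logger.info(
        "counted %d records: %.3f%% unassigned at multiplex split, "
        "%d unassigned nucleosomal reads",
        total, 100 * frac_mx, int(unassigned_nuc.sum()),
    )
    return table


def write_split_fastq(
    per_sample: dict[str, list[BarcodeRecord]], outdir: str | Path
) -> dict[str, Path]:
    """Optionally mirror the intermediate per-sample FASTQ split of the
    modeled workflow: one file of nucleosomal-barcode reads per sample."""
    from .io import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample_id, recs in per_sample.items():
        p = outdir / f"{sample_id}.fastq"
        write_fastq(
            p,
            ((r.fragment_id, r.nuc_read, "?" * len(r.nuc_read)) for r in recs),
        )
        paths[sample_id] = p
    return paths
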