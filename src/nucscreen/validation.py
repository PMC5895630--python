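"""Self-validation experiments: parameter recovery, SEM scaling, and
metaprofile shape recovery on fully synthetic data.

These drive the whole pipeline end to end against the generator's ground
truth and summarize how well the readout recovers it. They are used by the
acceptance machinery and are handy as user-level sanity checks after
installation.
"""

from __future__ import annotations

import shutil
import tempfile
from pathlib import Path

import numpy as np

from .barcodes import BarcodeRecord, count_barcodes
from .enrichment import aggregate_replicates, compare_to_truth, enrich
from .manifest import generate_manifest
from .metaprofile import aggregate_profile, reference_point_matrix
from .pipeline import RunConfig, run_screen
from .simulate import SimulationConfig, generate_truth, simulate_screen
from .simulate_tracks import (
    DEFAULT_CHROM_SIZES,
    MarkShape,
    make_gene_models,
    simulate_coverage_tracks,
)
from .utils import BASES, derive_seed, hamming


def recovery_experiment(
    seed: int,
    read_depth: int = 500_000,
    n_replicates: int = 3,
    min_expected_ip_count: float = 500.0,
    workdir: str | Path | None = None,
) -> dict[str, float]:
    """Run one full synthetic screen and score ground-truth recovery.

    Returns Spearman correlation and RMSE between estimated and true log2
    fold changes over members whose expected IP count reaches
    ``min_expected_ip_count``, plus the shallowest negative-control rank
    fraction (bottom-decile placement means a fraction above 0.9).
    """
    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp(prefix="nucscreen_")) if own_tmp else Path(workdir)
    try:
        config = RunConfig(
            seed=seed,
            outdir=str(workdir / f"run_seed{seed}"),
            read_depth=read_depth,
            n_replicates=n_replicates,
        )
        result = run_screen(config)
        _, stats = compare_to_truth(
            result["enrichment"], result["truth_table"],
            min_expected_count=min_expected_ip_count,
        )
        return stats
    finally:
        if own_tmp:
            shutil.rmtree(workdir, ignore_errors=True)


def sem_scaling_experiment(
    seed: int,
    n_values: tuple[int, ...] = (3, 12, 48),
    read_depth: int = 20_000,
) -> dict[int, float]:
    """Root-mean-square per-member SEM of the log2FC for nested replicate
    subsets.

    One screen is simulated with max(n_values) IP replicates; for each n the
    first n replicates are aggregated. Pooling across members is done on the
    squared scale because sem^2 is the unbiased estimator of sigma^2/n (the
    raw sample SD is biased low at few degrees of freedom), so under the
    generative model the pooled SEM shrinks as 1/sqrt(n).
    """
    n_max = max(n_values)
    manifest = generate_manifest(seed=seed)
    truth = generate_truth(manifest, seed=seed)
    workdir = Path(tempfile.mkdtemp(prefix="nucscreen_sem_"))
    try:
        sim = simulate_screen(
            manifest, truth,
            SimulationConfig(read_depth=read_depth, n_replicates=n_max, seed=seed),
            workdir,
        )
        from .barcodes import count_run

        table = count_run(sim.all_pairs, manifest, sim.sample_sheet)
        df = enrich(table, manifest, sim.sample_sheet)
        lfc_cols = [c for c in df.columns if c.startswith("log2fc_")]
        lfc = df[lfc_cols].to_numpy()
        out = {}
        for n in n_values:
            _, sem = aggregate_replicates(lfc[:, :n])
            out[n] = float(np.sqrt(np.mean(sem**2)))
        return out
    finally:
        shutil.rmtree(workdir, ignore_errors=True)


def counting_oracle_check(
    seed: int, n_reads: int = 10_000, error_rate: float = 0.01, max_mismatch: int = 1
) -> dict[str, float]:
    """Compare the vectorized counter against an exhaustive nearest-barcode
    search on error-laden reads; returns the disagreement count (0 when the
    two agree everywhere)."""
    manifest = generate_manifest(seed=seed)
    barcodes = [m.barcode for m in manifest]
    k = len(barcodes[0])
    rng = np.random.default_rng(derive_seed(seed, "oracle-reads"))
    picks = rng.integers(0, len(barcodes), n_reads)
    reads = []
    for j in picks:
        b = list(barcodes[j])
        for pos in range(k):
            if rng.random() < error_rate:
                b[pos] = BASES[rng.integers(0, 4)]
        reads.append("".join(b))
    records = [BarcodeRecord(f"f{i}", r, "AAAA") for i, r in enumerate(reads)]
    counts, unassigned = count_barcodes(records, manifest, max_mismatch=max_mismatch)

    expected = np.zeros(len(barcodes), dtype=np.int64)
    n_un = 0
    for read in reads:
        dists = [hamming(read, b) for b in barcodes]
        dmin = min(dists)
        if dmin > max_mismatch or dists.count(dmin) > 1:
            n_un += 1
        else:
            expected[dists.index(dmin)] += 1
    mismatches = int(np.abs(counts - expected).sum() + abs(unassigned - n_un))
    return {"mismatches": mismatches, "n_reads": n_reads}


def shape_recovery_experiment(
    seed: int,
    upstream_bp: int = 1_000,
    downstream_bp: int = 1_000,
    bin_size: int = 25,
) -> dict[str, float]:
    """Noise-free two-mark genome: a TSS-peaked mark and a gene-body mark.

    Returns each mark's aggregate-profile argmax as a bin offset from the
    TSS bin. The TSS mark should peak within two bins of the TSS; the
    gene-body mark strictly downstream.
    """
    genes = make_gene_models(DEFAULT_CHROM_SIZES, seed=seed)
    shapes = {
        "tss_mark": MarkShape("tss_peak", height=8.0, sigma=80.0),
        "body_mark": MarkShape("gene_body", height=5.0, rise=300),
    }
    res = simulate_coverage_tracks(DEFAULT_CHROM_SIZES, genes, shapes, seed=seed)
    tss_bin = upstream_bp // bin_size
    out: dict[str, float] = {"n_genes": float(len(genes))}
    for mark in shapes:
        matrix = reference_point_matrix(
            res["tracks"][mark], genes, upstream_bp, downstream_bp, bin_size
        )
        agg = aggregate_profile(matrix)
        out[f"{mark}_peak_offset_bins"] = float(int(np.argmax(agg)) - tss_bin)
    return out
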