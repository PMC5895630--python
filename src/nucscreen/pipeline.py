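"""End-to-end orchestration: simulate -> count -> enrich, with reproducible
seeding, logging, and self-describing outputs.

A run is described by one :class:`RunConfig`; the single run seed governs all
stochastic stages through a documented derivation (the stage name is hashed
into the seed), so any stage can be rerun in isolation. Every output table
carries a header with the package version, the config hash, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .barcodes import count_run
from .enrichment import compare_to_truth, enrich
from .io import write_table
from .manifest import CompositionConfig, generate_manifest
from .simulate import SimulationConfig, generate_truth, simulate_screen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one screen run."""

    seed: int = 0
    outdir: str = "nucscreen_run"
    # simulation
    read_depth: int = 500_000
    n_replicates: int = 3
    decoy_fraction: float = 0.05
    error_rate: float = 0.005
    background: float = 0.01
    log2_range: tuple[float, float] = (-3.0, 2.0)
    # matching policy
    max_mismatch_nuc: int = 0
    max_mismatch_mx: int = 0
    barcode_offset: int = 0
    # normalization & reporting
    pseudocount: float = 0.5
    control_scale: str = "arithmetic"
    fc_threshold: float = 0.5
    z_threshold: float = 2.0
    keep_fastq: bool = False

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "log2_range" in raw:
            raw["log2_range"] = tuple(raw["log2_range"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["log2_range"] = list(self.log2_range)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (the output location does
        not change the science, so two runs into different directories carry
        the same hash)."""
        d = self.as_dict()
        d.pop("outdir")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def metadata(self) -> dict:
        return {
            "nucscreen_version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }


def run_screen(config: RunConfig, composition: CompositionConfig | None = None) -> dict:
    """Execute one full synthetic screen and write its result files.

    Output directory contents: ``config.yaml`` (echoed verbatim),
    ``manifest.tsv``, ``truth.tsv``, ``sample_sheet.tsv``, ``counts.tsv``,
    ``enrichment.tsv``, ``truth_comparison.tsv``, and ``run.log``. Returns a
    dict with the key tables and recovery statistics.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("nucscreen")
    root.addHandler(handler)
    prior_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run_screen_inner(config, composition, outdir)
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()


def _run_screen_inner(
    config: RunConfig, composition: CompositionConfig | None, outdir: Path
) -> dict:
    meta = config.metadata()
    config.to_yaml(outdir / "config.yaml")
    logger.info("run start: seed=%d hash=%s", config.seed, config.config_hash)

    manifest = generate_manifest(composition, seed=config.seed)
    truth = generate_truth(
        manifest,
        seed=config.seed,
        background=config.background,
        log2_range=config.log2_range,
    )
    sim_config = SimulationConfig(
        read_depth=config.read_depth,
        n_replicates=config.n_replicates,
        decoy_fraction=config.decoy_fraction,
        error_rate=config.error_rate,
        seed=config.seed,
    )
    fastq_dir = outdir / "fastq"
    sim = simulate_screen(manifest, truth, sim_config, fastq_dir)
    logger.info("simulated %d samples at depth %d",
                len(sim.fastq_pairs), config.read_depth)

    table = count_run(
        sim.all_pairs,
        manifest,
        sim.sample_sheet,
        max_mismatch_nuc=config.max_mismatch_nuc,
        max_mismatch_mx=config.max_mismatch_mx,
        offset=config.barcode_offset,
    )
    expected_total = config.read_depth * len(sim.fastq_pairs)
    if table.total_records != expected_total:
        raise RuntimeError(
            f"counting stage: {table.total_records} records != "
            f"{expected_total} simulated"
        )
    table.write(outdir / "counts.tsv", meta)

    enrichment_df = enrich(
        table,
        manifest,
        sim.sample_sheet,
        pseudocount=config.pseudocount,
        control_scale=config.control_scale,
        fc_threshold=config.fc_threshold,
        z_threshold=config.z_threshold,
    )
    wt_ratio_residual = float(
        abs(
            np.mean(
                2.0
                ** enrichment_df.loc[
                    enrichment_df["role"] == "wt_control",
                    [c for c in enrichment_df.columns if c.startswith("log2fc_")],
                ].to_numpy()
            )
            - 1.0
        )
    )
    logger.info("wt-centering residual (mean wt ratio - 1): %.3e", wt_ratio_residual)
    write_table(outdir / "enrichment.tsv", enrichment_df, meta)

    comparison, recovery = compare_to_truth(enrichment_df, sim.truth_table)
    write_table(
        outdir / "truth_comparison.tsv",
        comparison,
        {**meta, **{k: v for k, v in recovery.items()}},
    )
    logger.info(
        "recovery: spearman=%.4f rmse=%.4f (n=%d)",
        recovery["spearman"], recovery["rmse"], recovery["n_scored"],
    )
    # screen-scale FASTQ is bulky; drop it unless the config asks to keep it
    if not config.keep_fastq:
        for r1, r2 in sim.all_pairs:
            r1.unlink(missing_ok=True)
            r2.unlink(missing_ok=True)
        if not any(fastq_dir.glob("*.fastq")):
            for leftover in fastq_dir.iterdir():
                shutil.move(str(leftover), outdir / leftover.name)
            fastq_dir.rmdir()

    return {
        "outdir": outdir,
        "manifest": manifest,
        "truth": truth,
        "sample_sheet": sim.sample_sheet,
        "truth_table": sim.truth_table,
        "count_table": table,
        "enrichment": enrichment_df,
        "comparison": comparison,
        "recovery": recovery,
        "wt_ratio_residual": wt_ratio_residual,
    }
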