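"""Generative model of the barcoded-nucleosome ubiquitylation screen.

The screen is modeled with three scalar quantities per library member i:

* ``a_i`` — input abundance (proportion of the pooled library), summing to 1;
* ``e_i`` — relative de novo ubiquitylation efficiency, with the wild-type
  controls sharing a reference efficiency ``e_wt``;
* ``b``  — a shared additive background rate for nonspecific pull-down
  (motivated by the wet protocol's blocker nucleosomes: some material is
  captured by the beads regardless of its ubiquitylation state).

The input sample draws fragments multinomially with weights ``a_i``; each
immunoprecipitation (IP) replicate draws with weights ``a_i * (e_i + b)``.
Every fragment emits two reads: one covering the nucleosomal barcode and one
covering that sample's multiplexing barcode. A configurable fraction of
fragments is replaced by random decoy sequence (emulating a PhiX spike-in,
whose only relevant property is that it matches no barcode), and i.i.d.
per-base substitution errors are applied. Qualities are constant Q30
placeholders; nothing downstream consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_table
from .manifest import LibraryMember, assign_barcodes, manifest_to_frame
from .utils import derive_seed, encode_sequences, indices_to_bytes

DECOY_ID = "*decoy*"


@dataclass
class EnrichmentTruth:
    """Ground-truth generative parameters, keyed by member_id."""

    abundance: dict[str, float]
    efficiency: dict[str, float]
    background: float = 0.0

    def __post_init__(self):
        total = sum(self.abundance.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"abundances must sum to 1 (got {total})")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("abundances must be nonnegative")
        if any(v < 0 for v in self.efficiency.values()):
            raise ValueError("efficiencies must be nonnegative")
        if self.background < 0:
            raise ValueError("background must be nonnegative")

    def validate_against(self, manifest: list[LibraryMember]) -> None:
        ids = {m.member_id for m in manifest}
        missing = ids - set(self.abundance) | ids - set(self.efficiency)
        if missing:
            raise ValueError(f"truth missing members: {sorted(missing)[:5]} ...")
        wt_eff = {
            self.efficiency[m.member_id]
            for m in manifest
            if m.role == "wt_control"
        }
        if len(wt_eff) > 1:
            raise ValueError("wt controls must share one reference efficiency")
        if wt_eff:
            e_wt = wt_eff.pop()
            for m in manifest:
                if m.role == "negative_control" and self.efficiency[m.member_id] > e_wt:
                    raise ValueError(
                        f"negative control {m.member_id} more efficient than wt"
                    )

    def wt_efficiency(self, manifest: list[LibraryMember]) -> float:
        for m in manifest:
            if m.role == "wt_control":
                return self.efficiency[m.member_id]
        raise ValueError("manifest has no wt controls")

    def input_weights(self, manifest: list[LibraryMember]) -> np.ndarray:
        a = np.array([self.abundance[m.member_id] for m in manifest])
        return a / a.sum()

    def ip_weights(self, manifest: list[LibraryMember]) -> np.ndarray:
        a = self.input_weights(manifest)
        e = np.array([self.efficiency[m.member_id] for m in manifest])
        w = a * (e + self.background)
        return w / w.sum()

    def expected_log2fc(self, manifest: list[LibraryMember]) -> np.ndarray:
        """Exact expectation of the pipeline readout: input-normalized,
        wt-normalized log2 fold change, i.e. log2((e_i + b)/(e_wt + b))."""
        e_wt = self.wt_efficiency(manifest)
        e = np.array([self.efficiency[m.member_id] for m in manifest])
        return np.log2((e + self.background) / (e_wt + self.background))


def generate_truth(
    manifest: list[LibraryMember],
    seed: int = 0,
    background: float = 0.01,
    log2_range: tuple[float, float] = (-3.0, 2.0),
    neg_control_efficiency: float = 0.05,
    abundance_sigma: float = 0.25,
) -> EnrichmentTruth:
    """Draw a ground-truth parameter set for a manifest.

    Experimental members receive log2 efficiencies inside ``log2_range``,
    structured by modification class so that the synthetic screen reproduces
    the biology the real screen reported: acetylation of the H2A N-terminal
    tail (K13/K15 strongly, K5/K9 moderately) and the H2A.Z variant inhibit
    H2B ubiquitylation; DNA entry/exit marks (H3Y41ph) and H2BS112GlcNAc
    stimulate it; most other marks are near-neutral. Pre-modified-H2BK120
    negative controls and free DNA are poor substrates at
    ``neg_control_efficiency * e_wt``. Input abundances are mildly lognormal
    around equimolar (sigma ``abundance_sigma``), emulating pooling error.
    """
    rng = np.random.default_rng(derive_seed(seed, "truth"))
    lo, hi = log2_range
    h2a_tail_strong = {"K13ac", "K15ac"}
    h2a_tail_mild = {"K5ac", "K9ac"}
    stimulatory = {("H2B", "S112GlcNAc"), ("H3", "Y41ph")}

    def draw(a: float, b: float) -> float:
        a, b = max(a, lo), min(b, hi)
        return float(rng.uniform(a, b))

    efficiency: dict[str, float] = {}
    for m in manifest:
        if m.role == "wt_control":
            efficiency[m.member_id] = 1.0
            continue
        if m.role in ("negative_control", "free_dna"):
            efficiency[m.member_id] = neg_control_efficiency
            continue
        mods = {(x.histone, x.mark) for x in m.modifications}
        if m.variant and m.variant.startswith("H2A.Z"):
            log2e = draw(-2.5, -1.5)
        elif any(h == "H2A" and mk in h2a_tail_strong for h, mk in mods):
            log2e = draw(-3.0, -2.0)
        elif any(h == "H2A" and mk in h2a_tail_mild for h, mk in mods):
            log2e = draw(-1.5, -0.5)
        elif mods & stimulatory:
            log2e = draw(1.0, 2.0)
        elif ("H2B", "S123GlcNAc") in mods:
            log2e = draw(-2.0, -1.0)
        else:
            log2e = draw(-0.5, 0.5)
        efficiency[m.member_id] = float(2.0**log2e)

    raw = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(manifest))
    abundance = {m.member_id: float(v / raw.sum()) for m, v in zip(manifest, raw)}
    truth = EnrichmentTruth(abundance, efficiency, background)
    truth.validate_against(manifest)
    return truth


@dataclass
class SimulationConfig:
    """Sequencing-run parameters for the synthetic screen."""

    read_depth: int = 500_000
    n_replicates: int = 3
    decoy_fraction: float = 0.05
    error_rate: float = 0.005
    multiplex_length: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("decoy_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.multiplex_length < 4:
            raise ValueError("multiplex_length must be >= 4")


@dataclass
class ScreenOutput:
    """Paths and tables produced by :func:`simulate_screen`."""

    outdir: Path
    sample_sheet: pd.DataFrame
    fastq_pairs: dict[str, tuple[Path, Path]]
    truth_table: pd.DataFrame
    manifest_path: Path
    sample_sheet_path: Path
    truth_path: Path

    @property
    def all_pairs(self) -> list[tuple[Path, Path]]:
        return [self.fastq_pairs[s] for s in self.sample_sheet["sample_id"]]


def simulate_screen(
    manifest: list[LibraryMember],
    truth: EnrichmentTruth,
    config: SimulationConfig,
    outdir: str | Path,
) -> ScreenOutput:
    """Simulate one screen: an input sample plus ``n_replicates`` IP
    replicates, written as per-sample FASTQ pairs with a sample sheet and a
    ground-truth table. Byte-identical for a fixed (manifest, truth, config).
    """
    truth.validate_against(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = len(manifest[0].barcode)

    sample_ids = ["input"] + [f"ip_rep{r}" for r in range(1, config.n_replicates + 1)]
    mx_codes = assign_barcodes(
        len(sample_ids), config.multiplex_length, 3, derive_seed(config.seed, "multiplex")
    )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "replicate": [0] + list(range(1, config.n_replicates + 1)),
            "multiplex_barcode": mx_codes,
            "role": ["input"] + ["ip"] * config.n_replicates,
        }
    )

    member_ids = [m.member_id for m in manifest]
    barc_mat = encode_sequences([m.barcode for m in manifest], k)
    input_w = truth.input_weights(manifest)
    ip_w = truth.ip_weights(manifest)
    expected_lfc = truth.expected_log2fc(manifest)

    fastq_pairs: dict[str, tuple[Path, Path]] = {}
    truth_rows: list[pd.DataFrame] = []
    for sample_id, mx_code, role in zip(
        sheet["sample_id"], sheet["multiplex_barcode"], sheet["role"]
    ):
        weights = input_w if role == "input" else ip_w
        rng = np.random.default_rng(derive_seed(config.seed, f"reads:{sample_id}"))
        counts, n_decoy, r1_mat, r2_mat = _sample_reads(
            rng, config, weights, barc_mat, mx_code
        )
        r1 = outdir / f"{sample_id}_R1.fastq"
        r2 = outdir / f"{sample_id}_R2.fastq"
        _write_fastq_matrix(r1, sample_id, r1_mat)
        _write_fastq_matrix(r2, sample_id, r2_mat)
        fastq_pairs[sample_id] = (r1, r2)
        expected = (config.read_depth - n_decoy) * weights
        block = pd.DataFrame(
            {
                "sample_id": sample_id,
                "member_id": member_ids + [DECOY_ID],
                "sampled_count": np.append(counts, n_decoy),
                "abundance": np.append(input_w, np.nan),
                "efficiency": np.append(
                    [truth.efficiency[i] for i in member_ids], np.nan
                ),
                "true_log2fc": np.append(expected_lfc, np.nan),
                "expected_count": np.append(expected, n_decoy),
            }
        )
        truth_rows.append(block)

    truth_table = pd.concat(truth_rows, ignore_index=True)
    manifest_path = outdir / "manifest.tsv"
    sheet_path = outdir / "sample_sheet.tsv"
    truth_path = outdir / "truth.tsv"
    meta = {"seed": config.seed, "read_depth": config.read_depth,
            "decoy_fraction": config.decoy_fraction,
            "error_rate": config.error_rate,
            "background": truth.background}
    write_table(manifest_path, manifest_to_frame(manifest), meta)
    write_table(sheet_path, sheet, meta)
    write_table(truth_path, truth_table, meta)
    return ScreenOutput(
        outdir=outdir,
        sample_sheet=sheet,
        fastq_pairs=fastq_pairs,
        truth_table=truth_table,
        manifest_path=manifest_path,
        sample_sheet_path=sheet_path,
        truth_path=truth_path,
    )


def _sample_reads(
    rng: np.random.Generator,
    config: SimulationConfig,
    weights: np.ndarray,
    barc_mat: np.ndarray,
    mx_code: str,
) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """Draw one sample's fragments and build its two read matrices
    (base-index uint8, rows = fragments)."""
    depth = config.read_depth
    k = barc_mat.shape[1]
    mx = encode_sequences([mx_code], len(mx_code))[0]

    n_decoy = int(rng.binomial(depth, config.decoy_fraction))
    n_assigned = depth - n_decoy
    counts = rng.multinomial(n_assigned, weights)
    member_idx = np.repeat(np.arange(len(weights)), counts)

    r1 = np.empty((depth, k), dtype=np.uint8)
    r1[:n_assigned] = barc_mat[member_idx]
    r1[n_assigned:] = rng.integers(0, 4, size=(n_decoy, k), dtype=np.uint8)
    r2 = np.empty((depth, len(mx)), dtype=np.uint8)
    r2[:n_assigned] = mx
    r2[n_assigned:] = rng.integers(0, 4, size=(n_decoy, len(mx)), dtype=np.uint8)

    order = rng.permutation(depth)
    r1, r2 = r1[order], r2[order]
    for mat in (r1, r2):
        _apply_substitutions(rng, mat, config.error_rate)
    return counts, n_decoy, r1, r2


def _apply_substitutions(
    rng: np.random.Generator, mat: np.ndarray, rate: float
) -> None:
    """I.i.d. substitution errors in place: an erroneous base becomes one of
    the three *other* bases uniformly."""
    if rate <= 0:
        return
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n, dtype=np.uint8)
        mat[mask] = (mat[mask] + shift) % 4


def _write_fastq_matrix(path: Path, sample_id: str, mat: np.ndarray) -> None:
    n, k = mat.shape
    blob = indices_to_bytes(mat)
    qual = b"?" * k  # constant Q30 (Phred+33) placeholder
    sid = sample_id.encode()
    parts = [
        b"@%b:%d\n%b\n+\n%b\n" % (sid, i, blob[i * k : (i + 1) * k], qual)
        for i in range(n)
    ]
    path.write_bytes(b"".join(parts))


# ---------------------------------------------------------------------------
# Truth TSV round trip
# ---------------------------------------------------------------------------

def truth_from_table(table: pd.DataFrame, background: float) -> EnrichmentTruth:
    """Rebuild an EnrichmentTruth from one sample's block of a truth table."""
    sub = table[table["member_id"] != DECOY_ID].drop_duplicates("member_id")
    return EnrichmentTruth(
        abundance=dict(zip(sub["member_id"], sub["abundance"])),
        efficiency=dict(zip(sub["member_id"], sub["efficiency"])),
        background=background,
    )
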