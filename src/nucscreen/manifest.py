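"""Library manifest: barcoded mononucleosome species and barcode design.

A screen library is a pool of mononucleosomes, each carrying a defined set of
histone/DNA modifications (or a histone variant) and a unique DNA barcode
embedded in its nucleosomal DNA. The default composition mirrors the screen
this package models: 36 lysine-acetylation members spread over all four core
histones, six unmodified wild-type control nucleosomes that define the
fold-change zero point, two negative controls whose H2BK120 site is already
occupied (and which are therefore poor substrates for de novo ubiquitylation),
H2A.Z-variant members, one free-DNA member, and a handful of additional marks
(H2BS112GlcNAc, H3Y41ph, ...) known to modulate the ubiquitylation machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import read_table, write_table
from .utils import BASES, derive_seed, hamming

ROLES = ("experimental", "wt_control", "negative_control", "free_dna")

_KAC_RE = re.compile(r"K\d+ac")


class ManifestError(ValueError):
    """Manifest violates a structural invariant."""


class BarcodeCapacityError(ValueError):
    """No barcode set of the requested size exists (or was found) for the
    given length / minimum-distance constraints."""


@dataclass(frozen=True)
class Modification:
    """One chemical mark: which molecule carries it and what it is.

    ``mark`` includes the residue/coordinate label, e.g. ``K15ac``,
    ``K120ub``, ``S112GlcNAc``, or ``5mC`` for a DNA mark.
    """

    histone: str  # H2A, H2B, H3, H4, or DNA
    mark: str

    def __post_init__(self):
        if self.histone not in ("H2A", "H2B", "H3", "H4", "DNA"):
            raise ManifestError(f"unknown carrier {self.histone!r}")

    @property
    def is_kac(self) -> bool:
        """True for a lysine-acetylation mark (KNNac)."""
        return bool(_KAC_RE.fullmatch(self.mark))

    def __str__(self) -> str:
        return f"{self.histone}:{self.mark}"

    @classmethod
    def parse(cls, text: str) -> "Modification":
        histone, _, mark = text.partition(":")
        if not mark:
            raise ManifestError(f"cannot parse modification {text!r}")
        return cls(histone, mark)


@dataclass(frozen=True)
class LibraryMember:
    member_id: str
    barcode: str
    modifications: frozenset[Modification]
    variant: str | None
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ManifestError(f"unknown role {self.role!r}")

    @property
    def has_kac(self) -> bool:
        return any(m.is_kac for m in self.modifications)


# Default lysine-acetylation survey sites across all four core histones.
# Together with the pre-modified H2BK120ac negative control (also an H2B
# acetylation), the default library carries exactly 36 Kac-bearing members.
DEFAULT_KAC_SITES: dict[str, tuple[str, ...]] = {
    "H3": ("K4", "K9", "K14", "K18", "K23", "K27", "K36", "K56", "K64", "K79",
           "K115", "K122"),
    "H4": ("K5", "K8", "K12", "K16", "K20", "K31", "K44", "K59", "K77", "K79",
           "K91"),
    "H2A": ("K5", "K9", "K13", "K15", "K36", "K74", "K95", "K99"),
    "H2B": ("K5", "K11", "K12", "K16"),
}

DEFAULT_EXTRA_MARKS: tuple[tuple[str, str], ...] = (
    ("H2B", "S112GlcNAc"),
    ("H2B", "S123GlcNAc"),
    ("H3", "Y41ph"),
    ("H3", "K4me3"),
    ("H3", "K9me3"),
    ("H3", "K27me3"),
    ("H3", "K79me2"),
    ("DNA", "5mC"),
)


@dataclass(frozen=True)
class CompositionConfig:
    """Counts-per-category description of the library.

    Defaults reproduce the composition stated for the modeled screen; any
    category may be emptied or extended for custom libraries.
    """

    kac_sites: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_KAC_SITES)
    )
    n_wt_controls: int = 6
    premodified_h2bk120: tuple[str, ...] = ("K120ub", "K120ac")
    h2az_variants: tuple[str, ...] = ("H2A.Z", "H2A.Z+H3.3")
    n_free_dna: int = 1
    extra_marks: tuple[tuple[str, str], ...] = DEFAULT_EXTRA_MARKS
    barcode_length: int = 8
    min_hamming: int = 3

    @property
    def n_members(self) -> int:
        return (
            sum(len(v) for v in self.kac_sites.values())
            + self.n_wt_controls
            + len(self.premodified_h2bk120)
            + len(self.h2az_variants)
            + self.n_free_dna
            + len(self.extra_marks)
        )


def assign_barcodes(
    n_members: int, k: int, min_hamming: int, seed: int
) -> list[str]:
    """Design ``n_members`` distinct DNA k-mers with all pairwise Hamming
    distances >= ``min_hamming``, reproducibly for a fixed seed.

    Uses rejection sampling against the accepted set. Infeasible requests are
    refused: the Singleton bound caps any code of length k and distance d at
    ``4**(k-d+1)`` words, and a request the sampler cannot satisfy within its
    attempt budget is also reported as a capacity error.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if k < 4:
        raise ValueError("barcode length must be >= 4")
    if min_hamming < 1:
        raise ValueError("min_hamming must be >= 1")
    if min_hamming > k:
        raise BarcodeCapacityError(
            f"minimum distance {min_hamming} exceeds barcode length {k}"
        )
    singleton_cap = 4 ** (k - min_hamming + 1)
    if n_members > singleton_cap:
        raise BarcodeCapacityError(
            f"no code of {n_members} barcodes exists for length {k} and "
            f"distance {min_hamming} (Singleton bound: {singleton_cap})"
        )
    rng = np.random.default_rng(derive_seed(seed, "barcodes"))
    accepted: list[np.ndarray] = []
    max_attempts = 4000 * n_members + 20_000
    attempts = 0
    while len(accepted) < n_members:
        if attempts >= max_attempts:
            raise BarcodeCapacityError(
                f"could not place {n_members} barcodes of length {k} at "
                f"distance {min_hamming} within {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.integers(0, 4, size=k, dtype=np.uint8)
        if all(int((cand != a).sum()) >= min_hamming for a in accepted):
            accepted.append(cand)
    return ["".join(BASES[i] for i in word) for word in accepted]


def generate_manifest(
    config: CompositionConfig | None = None, seed: int = 0
) -> list[LibraryMember]:
    """Build the library manifest: one member per configured species, each
    with a unique distance-separated barcode. Deterministic for fixed
    (config, seed)."""
    config = config or CompositionConfig()
    specs: list[tuple[str, frozenset[Modification], str | None, str]] = []
    for histone in sorted(config.kac_sites):
        for site in config.kac_sites[histone]:
            mod = Modification(histone, f"{site}ac")
            specs.append((f"{histone}{site}ac", frozenset([mod]), None, "experimental"))
    for variant in config.h2az_variants:
        member_id = variant.replace("+", "_")
        specs.append((member_id, frozenset(), variant, "experimental"))
    for histone, mark in config.extra_marks:
        mod = Modification(histone, mark)
        specs.append((f"{histone}{mark}", frozenset([mod]), None, "experimental"))
    for i in range(1, config.n_wt_controls + 1):
        specs.append((f"wt_{i}", frozenset(), None, "wt_control"))
    for mark in config.premodified_h2bk120:
        mod = Modification("H2B", mark)
        specs.append((f"H2B{mark}_ctrl", frozenset([mod]), None, "negative_control"))
    for i in range(1, config.n_free_dna + 1):
        specs.append((f"free_DNA_{i}", frozenset(), None, "free_dna"))

    barcodes = assign_barcodes(
        len(specs), config.barcode_length, config.min_hamming, seed
    )
    members = [
        LibraryMember(member_id, bc, mods, variant, role)
        for (member_id, mods, variant, role), bc in zip(specs, barcodes)
    ]
    validate_manifest(members, config.min_hamming, config.n_wt_controls)
    return members


def validate_manifest(
    members: list[LibraryMember],
    min_hamming: int = 1,
    expected_wt: int | None = None,
) -> None:
    """Check the structural invariants of a manifest; raise ManifestError."""
    ids = [m.member_id for m in members]
    if len(set(ids)) != len(ids):
        raise ManifestError("member_ids are not unique")
    barcodes = [m.barcode for m in members]
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ManifestError(f"barcodes have mixed lengths {sorted(lengths)}")
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            d = hamming(barcodes[i], barcodes[j])
            if d < min_hamming:
                raise ManifestError(
                    f"barcodes {ids[i]}/{ids[j]} at Hamming distance {d} "
                    f"< required {min_hamming}"
                )
    for m in members:
        if m.role == "wt_control" and (m.modifications or m.variant):
            raise ManifestError(
                f"wt control {m.member_id} carries modifications or a variant"
            )
    if expected_wt is not None:
        n_wt = sum(m.role == "wt_control" for m in members)
        if n_wt != expected_wt:
            raise ManifestError(f"expected {expected_wt} wt controls, found {n_wt}")


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def manifest_to_frame(members: list[LibraryMember]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "member_id": [m.member_id for m in members],
            "barcode": [m.barcode for m in members],
            "role": [m.role for m in members],
            "variant": [m.variant or "" for m in members],
            "modifications": [
                ";".join(sorted(str(x) for x in m.modifications)) for m in members
            ],
        }
    )


def write_manifest(
    path, members: list[LibraryMember], metadata: dict | None = None
) -> None:
    write_table(path, manifest_to_frame(members), metadata)


def read_manifest(path) -> list[LibraryMember]:
    df, _ = read_table(path)
    df = df.fillna("")
    members = []
    for row in df.itertuples(index=False):
        mods = frozenset(
            Modification.parse(tok) for tok in str(row.modifications).split(";") if tok
        )
        members.append(
            LibraryMember(
                member_id=str(row.member_id),
                barcode=str(row.barcode),
                modifications=mods,
                variant=str(row.variant) or None,
                role=str(row.role),
            )
        )
    validate_manifest(members)
    return members
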