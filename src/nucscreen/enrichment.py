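"""Enrichment readout: input- and wt-control-normalized log2 fold changes.

The screen readout for member i in one pull-down (IP) replicate is

    r_i = p_i(IP) / p_i(input)            (input normalization)
    r_i' = r_i / mean({r_w : w in wt set})  (wt-control normalization)
    log2FC_i = log2(r_i')

where p_i are count proportions after a symmetric pseudocount. Replicates are
summarized as mean +/- SEM (sample SD with n-1 denominator over sqrt(n)),
members are ranked by descending mean log2FC, and hits are labeled by a joint
magnitude/z gate. The wt-control average is arithmetic on the ratio scale by
default (a geometric alternative is available), so the mean of normalized wt
ratios is exactly 1 in every replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .barcodes import CountTable
from .manifest import LibraryMember
from .simulate import DECOY_ID

HIT_LABELS = ("enhanced", "impeded", "neutral")


def normalize_to_input(
    ip_counts: np.ndarray, input_counts: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """Proportion ratio IP/input with a symmetric pseudocount.

    r_i = ((ip_i+a)/sum_j(ip_j+a)) / ((in_i+a)/sum_j(in_j+a)).
    With pseudocount 0, any zero input count is a domain error.
    """
    ip = np.asarray(ip_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    if ip.shape != inp.shape:
        raise ValueError("ip and input count vectors differ in length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (inp == 0).any():
        raise ZeroDivisionError(
            "zero input count with pseudocount 0; use a positive pseudocount"
        )
    ip = ip + pseudocount
    inp = inp + pseudocount
    return (ip / ip.sum()) / (inp / inp.sum())


def normalize_to_controls(
    ratios: np.ndarray, wt_mask: np.ndarray, scale: str = "arithmetic"
) -> np.ndarray:
    """Divide each ratio by the average of the wt-control ratios.

    ``scale`` selects the averaging: "arithmetic" (default) or "geometric".
    """
    ratios = np.asarray(ratios, dtype=float)
    wt_mask = np.asarray(wt_mask, dtype=bool)
    if not wt_mask.any():
        raise ValueError("wt control set is empty")
    wt = ratios[wt_mask]
    if scale == "arithmetic":
        ref = wt.mean()
    elif scale == "geometric":
        if (wt <= 0).any():
            raise ValueError("geometric mean undefined for nonpositive ratios")
        ref = float(np.exp(np.log(wt).mean()))
    else:
        raise ValueError(f"unknown control-average scale {scale!r}")
    if ref <= 0:
        raise ValueError("wt-control average ratio is nonpositive")
    return ratios / ref


def log2_fold_change(normalized_ratios: np.ndarray) -> np.ndarray:
    r = np.asarray(normalized_ratios, dtype=float)
    if (r <= 0).any():
        raise ValueError("log2 fold change requires strictly positive ratios")
    return np.log2(r)


def aggregate_replicates(
    log2fc: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-member mean and SEM over replicates.

    ``log2fc`` is (members, replicates). SEM is the n-1 sample SD over
    sqrt(n); with a single replicate it is NaN (undefined).
    """
    mat = np.asarray(log2fc, dtype=float)
    if mat.ndim != 2:
        raise ValueError("log2fc matrix must be 2-D (members x replicates)")
    n = mat.shape[1]
    mean = mat.mean(axis=1)
    if n == 1:
        sem = np.full(mat.shape[0], np.nan)
    else:
        sem = mat.std(axis=1, ddof=1) / np.sqrt(n)
        # exactly-equal replicates have exactly zero spread; suppress the
        # mean-subtraction rounding residue so downstream z-scores see 0
        sem[np.all(mat == mat[:, :1], axis=1)] = 0.0
    return mean, sem


def rank_members(mean_log2fc: np.ndarray, member_ids: list[str]) -> np.ndarray:
    """Ranks 1..M by descending mean log2FC; ties broken lexicographically
    by member_id."""
    order = np.lexsort((np.asarray(member_ids, dtype=object), -np.asarray(mean_log2fc)))
    ranks = np.empty(len(member_ids), dtype=np.int64)
    ranks[order] = np.arange(1, len(member_ids) + 1)
    return ranks


def call_hits(
    mean: np.ndarray,
    sem: np.ndarray,
    roles: list[str],
    fc_threshold: float = 0.5,
    z_threshold: float = 2.0,
) -> list[str]:
    """Label members enhanced / impeded / neutral.

    A member is enhanced when mean >= fc_threshold and mean/sem >=
    z_threshold (impeded symmetric); wt controls are neutral by definition.
    This is a reporting convention, not a formal test.
    """
    if fc_threshold <= 0 or z_threshold <= 0:
        raise ValueError("thresholds must be positive")
    labels = []
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(mean) / np.asarray(sem, dtype=float)
    for m, zi, role in zip(mean, z, roles):
        if role == "wt_control":
            labels.append("neutral")
        elif m >= fc_threshold and zi >= z_threshold:
            labels.append("enhanced")
        elif m <= -fc_threshold and zi >= z_threshold:
            labels.append("impeded")
        else:
            labels.append("neutral")
    return labels


def enrich(
    count_table: CountTable,
    manifest: list[LibraryMember],
    sample_sheet: pd.DataFrame,
    pseudocount: float = 0.5,
    control_scale: str = "arithmetic",
    fc_threshold: float = 0.5,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full enrichment readout from a count table.

    Uses the (single) input sample from the sample sheet; every IP sample is
    one replicate. Returns a DataFrame with one row per member: role,
    per-replicate log2FC columns, mean, SEM, rank, and hit label.
    """
    by_id = {m.member_id: m for m in manifest}
    if set(count_table.members) - set(by_id):
        raise ValueError("count table contains members absent from manifest")
    roles = [by_id[i].role for i in count_table.members]
    wt_mask = np.array([r == "wt_control" for r in roles])

    input_samples = list(sample_sheet.loc[sample_sheet["role"] == "input", "sample_id"])
    ip_samples = list(sample_sheet.loc[sample_sheet["role"] == "ip", "sample_id"])
    if len(input_samples) != 1:
        raise ValueError(f"expected exactly one input sample, got {input_samples}")
    if not ip_samples:
        raise ValueError("no IP samples in sample sheet")
    input_counts = count_table.column(str(input_samples[0]))

    lfc = np.empty((len(count_table.members), len(ip_samples)))
    for j, sample_id in enumerate(ip_samples):
        ratios = normalize_to_input(
            count_table.column(str(sample_id)), input_counts, pseudocount
        )
        normalized = normalize_to_controls(ratios, wt_mask, control_scale)
        lfc[:, j] = log2_fold_change(normalized)

    mean, sem = aggregate_replicates(lfc)
    ranks = rank_members(mean, count_table.members)
    labels = call_hits(mean, sem, roles, fc_threshold, z_threshold)
    out = pd.DataFrame({"member_id": count_table.members, "role": roles})
    for j, sample_id in enumerate(ip_samples):
        out[f"log2fc_{sample_id}"] = lfc[:, j]
    out["mean_log2fc"] = mean
    out["sem_log2fc"] = sem
    out["rank"] = ranks
    out["hit_label"] = labels
    return out


def compare_to_truth(
    enrichment: pd.DataFrame,
    truth_table: pd.DataFrame,
    min_expected_count: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Join estimates with simulator ground truth and score recovery.

    Returns the joined table and summary statistics: Spearman correlation and
    RMSE of mean log2FC vs the generative expectation, restricted to members
    whose expected IP count reaches ``min_expected_count``; plus the worst
    (highest) rank fraction among negative controls.
    """
    ip_truth = truth_table[
        (truth_table["member_id"] != DECOY_ID)
        & (truth_table["sample_id"].astype(str).str.startswith("ip"))
    ]
    per_member = (
        ip_truth.groupby("member_id", sort=False)
        .agg(true_log2fc=("true_log2fc", "first"),
             expected_ip_count=("expected_count", "mean"))
        .reset_index()
    )
    joined = enrichment.merge(per_member, on="member_id", how="left")
    sub = joined[joined["expected_ip_count"] >= min_expected_count]
    rho = float(
        stats.spearmanr(sub["mean_log2fc"], sub["true_log2fc"]).statistic
    )
    rmse = float(
        np.sqrt(np.mean((sub["mean_log2fc"] - sub["true_log2fc"]) ** 2))
    )
    # bottom-decile placement is rank_fraction > 0.9; the binding value is the
    # *least deep* negative control, i.e. the minimum rank fraction
    neg = joined[joined["role"] == "negative_control"]
    neg_min_rank_frac = (
        float((neg["rank"] / len(joined)).min()) if len(neg) else float("nan")
    )
    stats_out = {
        "spearman": rho,
        "rmse": rmse,
        "n_scored": int(len(sub)),
        "negative_control_min_rank_fraction": neg_min_rank_frac,
    }
    return joined, stats_out
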