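"""Per-TE summaries: average log2(Dam-fusion/Dam) occupancy and average
Dam-only methylation (accessibility proxy) per condition.

Reads aggregated on each TE consensus are counted in 50-bp bins and
converted to CPM with the number of genome-mapped reads as the denominator,
so TE signal is comparable across samples of different depth.  The per-TE
average is the mean of per-bin log2 ratios over defined bins (bin-level
averaging, not a ratio of summed counts), and the condition contrast is the
difference of those averages (delta = condition B − condition A).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .counting import FeatureCounts
from .genome import BinScheme, TEConsensusSet
from .occupancy import log2_ratio_profile, to_cpm

logger = logging.getLogger(__name__)


def te_bin_profile(
    fusion_counts: FeatureCounts,
    dam_only_counts: FeatureCounts,
    bins: BinScheme,
    tes: TEConsensusSet,
    pseudocount: float = 1.0,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Per-bin TE table for one condition: fusion CPM, Dam-only CPM and
    log2 ratio per 50-bp consensus bin.

    CPM uses each sample's genome-mapped read total as the denominator.
    Bins below ``min_coverage`` raw reads in both samples are missing (NaN
    log2 ratio).
    """
    known = set(tes.names)
    bin_tes = set(bins.frame["seq_name"])
    unknown = bin_tes - known
    if unknown:
        raise ValueError(f"TEs absent from consensus set: {sorted(unknown)}")
    if fusion_counts.total_genome_mapped is None or (
        dam_only_counts.total_genome_mapped is None
    ):
        raise ValueError("TE quantification requires total_genome_mapped")
    fusion_cpm = to_cpm(fusion_counts, fusion_counts.total_genome_mapped)
    dam_cpm = to_cpm(dam_only_counts, dam_only_counts.total_genome_mapped)
    profile = log2_ratio_profile(
        fusion_cpm,
        dam_cpm,
        pseudocount=pseudocount,
        min_coverage=min_coverage,
        fusion_counts=fusion_counts,
        dam_only_counts=dam_only_counts,
    )
    out = bins.frame.rename(
        columns={"seq_name": "te_name", "start": "bin_start", "end": "bin_end"}
    )[["te_name", "bin_start", "bin_end"]].copy()
    out["fusion_cpm"] = fusion_cpm.cpm
    out["dam_only_cpm"] = dam_cpm.cpm
    out["log2_ratio"] = profile.log2_ratio
    return out


def summarize_te(
    profiles: dict[str, pd.DataFrame],
    tes: TEConsensusSet,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-TE quantification table contrasting two conditions.

    Columns: te_name, family_class, n_bins, avg_log2_ratio_<A/B> (mean of
    defined bin log2 ratios), avg_dam_only_cpm_<A/B> (mean bin Dam-only
    CPM), delta_log2_ratio (B − A) and log2_fc_dam_only (log2 of the ratio
    of Dam-only means, with pseudocount).  TEs with zero defined bins in a
    condition get missing averages and are excluded from downstream ranking.
    """
    for cond in (condition_a, condition_b):
        if cond not in profiles:
            raise ValueError(f"no TE profile for condition {cond!r}")

    def per_te(profile: pd.DataFrame) -> pd.DataFrame:
        grouped = profile.groupby("te_name", sort=False)
        return pd.DataFrame(
            {
                "n_bins": grouped.size(),
                "avg_log2_ratio": grouped["log2_ratio"].mean(),
                "avg_dam_only_cpm": grouped["dam_only_cpm"].mean(),
            }
        )

    a = per_te(profiles[condition_a])
    b = per_te(profiles[condition_b])
    table = tes.frame[["te_name", "family_class"]].copy()
    table = table.set_index("te_name")
    table["n_bins"] = a["n_bins"]
    table[f"avg_log2_ratio_{condition_a}"] = a["avg_log2_ratio"]
    table[f"avg_log2_ratio_{condition_b}"] = b["avg_log2_ratio"]
    table[f"avg_dam_only_cpm_{condition_a}"] = a["avg_dam_only_cpm"]
    table[f"avg_dam_only_cpm_{condition_b}"] = b["avg_dam_only_cpm"]
    table["delta_log2_ratio"] = (
        table[f"avg_log2_ratio_{condition_b}"]
        - table[f"avg_log2_ratio_{condition_a}"]
    )
    table["log2_fc_dam_only"] = np.log2(
        table[f"avg_dam_only_cpm_{condition_b}"] + pseudocount
    ) - np.log2(table[f"avg_dam_only_cpm_{condition_a}"] + pseudocount)
    n_undefined = int(table["delta_log2_ratio"].isna().sum())
    if n_undefined:
        logger.info(
            "summarize_te: %d TEs with undefined delta (no defined bins)",
            n_undefined,
        )
    return table.reset_index()


def rank_te_by_delta(
    table: pd.DataFrame, k: int, direction: str = "decrease"
) -> list[str]:
    """The k TEs with the strongest occupancy change.

    ``decrease`` sorts delta ascending (strongest reduction first),
    ``increase`` descending; ties broken by te_name lexicographically, so
    the ranking is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    defined = table.dropna(subset=["delta_log2_ratio"])
    if k > len(defined):
        raise ValueError(
            f"k={k} exceeds {len(defined)} TEs with defined delta"
        )
    ascending = direction == "decrease"
    ranked = defined.sort_values(
        ["delta_log2_ratio", "te_name"],
        ascending=[ascending, True],
        kind="stable",
    )
    return list(ranked["te_name"].head(k))


def heatmap_matrix(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """TE × metric matrix (heatmap-ready export)."""
    return table.set_index("te_name")[columns]
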