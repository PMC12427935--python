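"""CPM normalization and log2(Dam-fusion/Dam-only) occupancy profiles.

The DamID signal for a chromatin protein is the methylation of the fusion
sample relative to the untethered Dam-only control, which itself methylates
chromatin according to its accessibility.  Profiles are therefore
log2((fusion CPM + c) / (Dam-only CPM + c)) per feature, with a small
pseudocount c guarding against zeros.  Missing entries (below a raw-count
floor in both samples) are NaN and propagate as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .counting import FeatureCounts


@dataclass
class CPMVector:
    """Counts-per-million per feature with the denominator used."""

    feature_ids: np.ndarray
    cpm: np.ndarray
    library_size: int

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids)
        self.cpm = np.asarray(self.cpm, dtype=float)
        if (self.cpm < 0).any():
            raise ValueError("CPM values must be non-negative")


def to_cpm(counts: FeatureCounts, library_size: int | str = "assigned") -> CPMVector:
    """cpm_i = counts_i * 1e6 / library_size.

    ``library_size="assigned"`` uses the sample's assigned-read total (the
    genome-profile mode); TE-consensus quantification instead passes the
    number of reads mapped to the genome as the denominator.
    """
    if library_size == "assigned":
        denom = counts.total_assigned
    else:
        denom = int(library_size)
    if denom <= 0:
        raise ValueError("library size must be positive")
    cpm = counts.counts * (1e6 / denom)
    return CPMVector(counts.feature_ids, cpm, denom)


@dataclass
class OccupancyProfile:
    """Per-feature log2(fusion/Dam-only) track; NaN marks missing entries."""

    feature_ids: np.ndarray
    log2_ratio: np.ndarray
    pseudocount: float
    min_coverage: int

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids)
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.log2_ratio)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "log2_ratio": self.log2_ratio}
        )


def log2_ratio_profile(
    fusion: CPMVector,
    dam_only: CPMVector,
    pseudocount: float = 1.0,
    min_coverage: int = 0,
    fusion_counts: FeatureCounts | None = None,
    dam_only_counts: FeatureCounts | None = None,
) -> OccupancyProfile:
    """log2((fusion_i + c) / (dam_only_i + c)) on the CPM scale.

    Entries whose raw counts are below ``min_coverage`` in both samples are
    marked missing (NaN); this needs the raw FeatureCounts and is opt-in
    (default 0 keeps every feature, since per-TE summaries are reported for
    all TEs).
    """
    if not np.array_equal(fusion.feature_ids, dam_only.feature_ids):
        raise ValueError("fusion and dam_only feature universes differ")
    if pseudocount <= 0 and (
        (fusion.cpm == 0).any() or (dam_only.cpm == 0).any()
    ):
        raise ValueError(
            "zero CPM entries present: use a positive pseudocount"
        )
    ratio = np.log2(fusion.cpm + pseudocount) - np.log2(dam_only.cpm + pseudocount)
    if min_coverage > 0:
        if fusion_counts is None or dam_only_counts is None:
            raise ValueError("min_coverage > 0 requires raw FeatureCounts")
        low = (fusion_counts.counts < min_coverage) & (
            dam_only_counts.counts < min_coverage
        )
        ratio = np.where(low, np.nan, ratio)
    return OccupancyProfile(fusion.feature_ids, ratio, pseudocount, min_coverage)


class CorrelationResult(NamedTuple):
    r: float
    n_joint: int


def replicate_correlation(
    profile_a: OccupancyProfile, profile_b: OccupancyProfile
) -> CorrelationResult:
    """Pearson r of two profiles over jointly defined features.

    Degenerate inputs (zero variance in either profile) give NaN rather
    than an exception.
    """
    if not np.array_equal(profile_a.feature_ids, profile_b.feature_ids):
        raise ValueError("profiles on different feature universes")
    joint = profile_a.defined & profile_b.defined
    n = int(joint.sum())
    if n < 3:
        raise ValueError("need at least 3 jointly defined features")
    x = profile_a.log2_ratio[joint]
    y = profile_b.log2_ratio[joint]
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), n)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r, n)


def write_bedgraph(
    profile: OccupancyProfile,
    features: pd.DataFrame,
    path,
    track_name: str | None = None,
    meta: dict | None = None,
) -> None:
    """Write a genome-mode profile as bedGraph (defined features only)."""
    seq_col = "chrom" if "chrom" in features.columns else "seq_name"
    mask = profile.defined
    with open(path, "w") as fh:
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        chroms = features[seq_col].to_numpy()
        starts = features["start"].to_numpy()
        ends = features["end"].to_numpy()
        values = profile.log2_ratio
        for i in np.flatnonzero(mask):
            fh.write(f"{chroms[i]}\t{starts[i]}\t{ends[i]}\t{values[i]:.6g}\n")
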