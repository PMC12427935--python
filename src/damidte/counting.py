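"""Assign alignments to features with MAPQ filtering and replicate pooling.

Alignments are held as a pandas DataFrame with columns
``target, start, end, strand, mapq, read_id`` (0-based half-open
coordinates; SAM input is converted on read).  A read is assigned to exactly
one feature by its midpoint, which matches the fragment-centric logic of
DamID: the amplified unit is the whole GATC fragment, so fractional overlap
splitting would only blur the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ["target", "start", "end", "strand", "mapq", "read_id"]
FUSION_KINDS = ("dam_only", "dam_fusion")


def empty_alignments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "mapq": pd.Series(dtype=np.int64),
            "read_id": pd.Series(dtype=object),
        }
    )


def read_sam(path) -> pd.DataFrame:
    """Minimal SAM reader: QNAME, FLAG (strand/unmapped), RNAME, POS, MAPQ
    and the CIGAR-derived end coordinate."""
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    rec.mapping_quality,
                    rec.query_name,
                )
            )
    if not rows:
        return empty_alignments()
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_sam(alignments: pd.DataFrame, lengths: dict[str, int], path) -> None:
    """Write alignments as a minimal valid text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(ln)} for name, ln in lengths.items()],
    }
    name_to_tid = {name: i for i, name in enumerate(lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for row in alignments.itertuples(index=False):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = row.read_id
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = name_to_tid[row.target]
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            a.cigarstring = f"{int(row.end) - int(row.start)}M"
            a.query_sequence = None
            fh.write(a)


def read_bed6(path) -> pd.DataFrame:
    """BED6 alternative alignment input: chrom, start, end, name, score
    (used as MAPQ), strand."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["target", "start", "end", "read_id", "mapq", "strand"],
        dtype={
            "target": str,
            "start": np.int64,
            "end": np.int64,
            "read_id": str,
            "mapq": np.int64,
            "strand": str,
        },
    )
    return frame[ALIGNMENT_COLUMNS]


def write_bed6(alignments: pd.DataFrame, path) -> None:
    out = alignments[["target", "start", "end", "read_id", "mapq", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_alignments(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".sam":
        return read_sam(path)
    if path.suffix == ".bed":
        return read_bed6(path)
    raise ValueError(f"unsupported alignment format: {path}")


def filter_mapq(alignments: pd.DataFrame, threshold: int | None) -> pd.DataFrame:
    """Keep records with mapq >= threshold; ``None`` is the identity
    (the no-mapping-quality-threshold mode)."""
    if threshold is None:
        return alignments
    if threshold < 0:
        raise ValueError("mapq threshold must be None or >= 0")
    return alignments.loc[alignments["mapq"] >= threshold].reset_index(drop=True)


def dedup_alignments(alignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse paired mates and multi-hits so each read_id counts once.

    Mates (same read_id on the same target) are merged into one spanning
    record; a read_id still present on several targets keeps its best hit by
    mapq, ties broken by first-seen order.
    """
    if alignments.empty or not alignments["read_id"].duplicated().any():
        return alignments
    frame = alignments.reset_index(drop=True)
    frame = frame.groupby(["read_id", "target"], sort=False, as_index=False).agg(
        start=("start", "min"),
        end=("end", "max"),
        strand=("strand", "first"),
        mapq=("mapq", "max"),
    )
    # best hit per read_id: highest mapq, then first-seen (stable sort keeps
    # the original groupby order within equal mapq)
    frame = frame.sort_values("mapq", ascending=False, kind="stable")
    frame = frame.drop_duplicates("read_id", keep="first")
    frame = frame.sort_index().reset_index(drop=True)
    return frame[["target", "start", "end", "strand", "mapq", "read_id"]]


@dataclass
class FeatureCounts:
    """Integer read counts per feature for one sample (or pooled sample).

    ``total_genome_mapped`` is the library-size denominator used for
    TE-consensus CPMs: the number of reads mapped to the genome, recorded
    before any MAPQ filtering of the TE alignments.
    """

    feature_ids: np.ndarray
    counts: np.ndarray
    total_assigned: int
    total_genome_mapped: int | None = None

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.total_assigned:
            raise ValueError("sum(counts) must equal total_assigned")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids, "count": self.counts})


def count_features(alignments: pd.DataFrame, scheme) -> FeatureCounts:
    """Count alignments per feature of a tiling scheme by read midpoint.

    A midpoint exactly on a bin boundary goes to the right-hand bin
    (half-open convention).  Alignments on targets absent from the scheme
    are dropped with a logged count.
    """
    if len(scheme) == 0:
        raise ValueError("empty feature scheme")
    n = len(scheme)
    if alignments.empty:
        return FeatureCounts(scheme.feature_ids, np.zeros(n, dtype=np.int64), 0)
    mids = (
        alignments["start"].to_numpy(np.int64) + alignments["end"].to_numpy(np.int64)
    ) // 2
    idx = scheme.assign(alignments["target"].to_numpy(), mids)
    dropped = int((idx < 0).sum())
    if dropped:
        logger.info("count_features: dropped %d alignments on unknown targets", dropped)
    idx = idx[idx >= 0]
    counts = np.bincount(idx, minlength=n).astype(np.int64)
    return FeatureCounts(scheme.feature_ids, counts, int(len(idx)))


def pool_replicates(counts_list: list[FeatureCounts]) -> FeatureCounts:
    """Element-wise sum of replicate counts and totals.

    Pooling precedes normalization: counts are summed and CPM is recomputed
    from the pooled totals, so pooled CPM of equal-depth replicates equals
    the mean of the replicate CPMs.
    """
    if not counts_list:
        raise ValueError("no replicates to pool")
    first = counts_list[0]
    for other in counts_list[1:]:
        if not np.array_equal(first.feature_ids, other.feature_ids):
            raise ValueError("replicates have mismatched feature universes")
    counts = np.sum([c.counts for c in counts_list], axis=0)
    total_assigned = int(sum(c.total_assigned for c in counts_list))
    genome_totals = [c.total_genome_mapped for c in counts_list]
    if all(t is None for t in genome_totals):
        pooled_genome = None
    elif any(t is None for t in genome_totals):
        raise ValueError("mixed presence of total_genome_mapped across replicates")
    else:
        pooled_genome = int(sum(genome_totals))
    return FeatureCounts(first.feature_ids, counts, total_assigned, pooled_genome)


@dataclass
class SampleManifest:
    """Sample sheet: one row per sequenced sample.

    Columns: sample_id, condition, fusion (dam_only | dam_fusion),
    replicate, genome_alignments, te_alignments.  Each
    (condition, fusion, replicate) triple must be unique and every condition
    must have both fusion kinds.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "sample_id",
            "condition",
            "fusion",
            "replicate",
            "genome_alignments",
            "te_alignments",
        }
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.frame["fusion"]) - set(FUSION_KINDS)
        if bad:
            raise ValueError(f"unknown fusion kinds: {sorted(bad)}")
        key = self.frame[["condition", "fusion", "replicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (condition, fusion, replicate) in manifest")
        for condition, group in self.frame.groupby("condition", sort=False):
            kinds = set(group["fusion"])
            if kinds != set(FUSION_KINDS):
                raise ValueError(
                    f"condition {condition!r} lacks a "
                    f"{(set(FUSION_KINDS) - kinds).pop()} partner"
                )
        self.frame = self.frame.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.frame["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str, fusion: str) -> pd.DataFrame:
        mask = (self.frame["condition"] == condition) & (
            self.frame["fusion"] == fusion
        )
        return self.frame.loc[mask]

    @classmethod
    def from_tsv(cls, path) -> "SampleManifest":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls._resolve(frame, Path(path).parent)

    @classmethod
    def from_yaml(cls, path) -> "SampleManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        frame = pd.DataFrame(doc["samples"])
        return cls._resolve(frame, Path(path).parent)

    @classmethod
    def _resolve(cls, frame: pd.DataFrame, base: Path) -> "SampleManifest":
        for col in ("genome_alignments", "te_alignments"):
            frame[col] = [
                str(p) if Path(p).is_absolute() else str(base / p)
                for p in frame[col]
            ]
        return cls(frame)

    def to_yaml(self, path) -> None:
        doc = {"samples": self.frame.to_dict(orient="records")}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
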