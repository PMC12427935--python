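"""GATC-fragment and binning model of a genome and of TE consensus sequences.

DamID amplifies genomic fragments delimited by adenine-methylated GATC
motifs (DpnI cuts at G\\ :sup:`m6`\\ ATC).  The natural quantification unit is
therefore the *GATC fragment*: the interval between consecutive GATC motif
occurrences.  This module builds that fragment map, plus fixed-width bin
schemes used for transposable-element (TE) consensus sequences, and reads
the FASTA inputs.

Coordinate convention: 0-based half-open throughout.  The fragment boundary
is placed at the motif *start* (the position of the G), so a fragment owns
the GATC at its left edge.  GATC is palindromic, so scanning the forward
strand suffices; ``N`` bases never match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GATC_MOTIF = "GATC"
FAMILY_CLASSES = ("LTR", "LINE", "DNA", "other")

_VALID_BASES = set("ACGTN")


@dataclass
class GenomeSequence:
    """A set of named chromosome sequences over the alphabet {A,C,G,T,N}.

    Sequences are uppercased on construction; names must be unique and
    sequences non-empty.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.records, dict):
            self.records = dict(self.records)
        clean: dict[str, str] = {}
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )
            clean[name] = seq
        self.records = clean

    @property
    def names(self) -> list[str]:
        return list(self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq)
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(records)

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.records.items()
        ]
        SeqIO.write(recs, str(path), "fasta")


def scan_gatc_sites(genome: GenomeSequence) -> dict[str, np.ndarray]:
    """Return, per chromosome, the sorted 0-based start positions of every
    GATC occurrence on the forward strand.

    The motif is its own reverse complement, so one strand suffices;
    occurrences cannot overlap (GATC has no non-trivial self-overlap).
    """
    if not genome.records:
        raise ValueError("no sequences")
    sites: dict[str, np.ndarray] = {}
    for name, seq in genome.records.items():
        positions = []
        i = seq.find(GATC_MOTIF)
        while i != -1:
            positions.append(i)
            i = seq.find(GATC_MOTIF, i + 1)
        sites[name] = np.asarray(positions, dtype=np.int64)
    return sites


class _IntervalIndex:
    """Shared midpoint-assignment machinery for tiling feature schemes.

    Each sequence is tiled left-to-right by features whose start coordinates
    are stored sorted; a position is assigned to the feature whose half-open
    interval contains it, i.e. the right-hand feature when the position sits
    exactly on a boundary.
    """

    def __init__(self, frame: pd.DataFrame, seq_col: str) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._base: dict[str, int] = {}
        for seq_name, group in frame.groupby(seq_col, sort=False):
            self._starts[seq_name] = group["start"].to_numpy(dtype=np.int64)
            self._base[seq_name] = int(group.index[0])

    @property
    def seq_names(self) -> set[str]:
        return set(self._starts)

    def assign(self, targets: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Feature index for each (target sequence, position) pair; -1 for
        unknown targets."""
        out = np.full(len(targets), -1, dtype=np.int64)
        targets = np.asarray(targets, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        for seq_name, starts in self._starts.items():
            mask = targets == seq_name
            if not mask.any():
                continue
            idx = np.searchsorted(starts, positions[mask], side="right") - 1
            out[mask] = self._base[seq_name] + idx
        return out


@dataclass
class GatcFragmentMap:
    """DpnI-defined genomic fragments bounded by GATC motif starts.

    Fragments per chromosome are sorted, non-overlapping and tile the
    chromosome exactly; fragment count = motif count + 1 on a linear
    chromosome.  Fragment ids are ``chrom:start-end``.
    """

    frame: pd.DataFrame  # columns: chrom, start, end, fragment_id
    _index: _IntervalIndex | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_genome(cls, genome: GenomeSequence) -> "GatcFragmentMap":
        sites = scan_gatc_sites(genome)
        rows: list[tuple[str, int, int]] = []
        for name, seq in genome.records.items():
            bounds = np.concatenate(
                ([0], sites[name][sites[name] > 0], [len(seq)])
            )
            for s, e in zip(bounds[:-1], bounds[1:]):
                rows.append((name, int(s), int(e)))
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        frame["fragment_id"] = (
            frame["chrom"]
            + ":"
            + frame["start"].astype(str)
            + "-"
            + frame["end"].astype(str)
        )
        return cls(frame)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame

    @property
    def feature_ids(self) -> np.ndarray:
        return self.frame["fragment_id"].to_numpy()

    @property
    def seq_col(self) -> str:
        return "chrom"

    def __len__(self) -> int:
        return len(self.frame)

    def _interval_index(self) -> _IntervalIndex:
        if self._index is None:
            self._index = _IntervalIndex(self.frame, "chrom")
        return self._index

    def assign(self, targets: np.ndarray, positions: np.ndarray) -> np.ndarray:
        return self._interval_index().assign(targets, positions)

    def to_bed(self, path) -> None:
        write_bed4(self.frame, "chrom", "fragment_id", path)


@dataclass
class BinScheme:
    """Fixed-width tiling of sequences; last bin per sequence may be short."""

    frame: pd.DataFrame  # columns: seq_name, start, end, feature_id
    bin_width: int
    _index: _IntervalIndex | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_lengths(cls, lengths: dict[str, int], bin_width: int) -> "BinScheme":
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        rows: list[tuple[str, int, int]] = []
        for name, length in lengths.items():
            if length < 1:
                raise ValueError(f"sequence {name!r} has non-positive length")
            starts = range(0, length, bin_width)
            for s in starts:
                rows.append((name, s, min(s + bin_width, length)))
        frame = pd.DataFrame(rows, columns=["seq_name", "start", "end"])
        frame["feature_id"] = (
            frame["seq_name"]
            + ":"
            + frame["start"].astype(str)
            + "-"
            + frame["end"].astype(str)
        )
        return cls(frame, bin_width)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame

    @property
    def feature_ids(self) -> np.ndarray:
        return self.frame["feature_id"].to_numpy()

    @property
    def seq_col(self) -> str:
        return "seq_name"

    def __len__(self) -> int:
        return len(self.frame)

    def _interval_index(self) -> _IntervalIndex:
        if self._index is None:
            self._index = _IntervalIndex(self.frame, "seq_name")
        return self._index

    def assign(self, targets: np.ndarray, positions: np.ndarray) -> np.ndarray:
        return self._interval_index().assign(targets, positions)

    def to_bed(self, path) -> None:
        write_bed4(self.frame, "seq_name", "feature_id", path)


@dataclass
class TEConsensusSet:
    """Canonical (consensus) TE sequences with family-class labels.

    ``frame`` has columns te_name, family_class, length; ``sequences`` keeps
    the consensus sequences when they were loaded/generated (the pipeline
    itself only needs the lengths and classes).
    """

    frame: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.frame["te_name"].duplicated().any():
            raise ValueError("TE names must be unique")
        if (self.frame["length"] < 1).any():
            raise ValueError("TE lengths must be >= 1")
        bad = set(self.frame["family_class"]) - set(FAMILY_CLASSES)
        if bad:
            raise ValueError(f"unknown family classes: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return list(self.frame["te_name"])

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.frame["te_name"], self.frame["length"]))

    def family_of(self, te_name: str) -> str:
        row = self.frame.loc[self.frame["te_name"] == te_name]
        if row.empty:
            raise KeyError(te_name)
        return row["family_class"].iloc[0]

    @classmethod
    def from_fasta(cls, path) -> "TEConsensusSet":
        """Load consensus sequences; the family class is parsed from a
        ``class=LTR|LINE|DNA|other`` token in the header, defaulting to
        ``other`` with a warning."""
        rows = []
        sequences: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            family = None
            for token in rec.description.split():
                if token.startswith("class="):
                    family = token.split("=", 1)[1]
            if family not in FAMILY_CLASSES:
                logger.warning(
                    "TE %s: missing or unknown class token (%r); using 'other'",
                    rec.id,
                    family,
                )
                family = "other"
            rows.append((rec.id, family, len(rec.seq)))
            sequences[rec.id] = str(rec.seq).upper()
        if not rows:
            raise ValueError(f"no sequences in {path}")
        frame = pd.DataFrame(rows, columns=["te_name", "family_class", "length"])
        return cls(frame, sequences)

    def to_fasta(self, path) -> None:
        if self.sequences is None:
            raise ValueError("consensus sequences not available")
        recs = []
        for _, row in self.frame.iterrows():
            recs.append(
                SeqRecord(
                    Seq(self.sequences[row["te_name"]]),
                    id=row["te_name"],
                    description=f"class={row['family_class']}",
                )
            )
        SeqIO.write(recs, str(path), "fasta")


def build_te_bins(tes: TEConsensusSet, bin_width: int = 50) -> BinScheme:
    """Tile each TE consensus into ``bin_width``-bp bins (last bin may be
    shorter); ceil(L/bin_width) bins for a TE of length L."""
    return BinScheme.from_lengths(tes.lengths, bin_width)


def write_bed4(frame: pd.DataFrame, seq_col: str, name_col: str, path) -> None:
    out = frame[[seq_col, "start", "end", name_col]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed3(path) -> pd.DataFrame:
    """Read a BED3 file (extra columns ignored) into chrom/start/end."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    if (frame["end"] <= frame["start"]).any():
        raise ValueError(f"malformed intervals in {path}")
    return frame
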