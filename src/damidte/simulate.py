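"""Synthetic DamID-seq data generator with known ground truth.

The generator emulates the design of an HP1a DamID experiment in a small
genome: a random background sequence carrying transposable-element (TE)
copies and constitutive-heterochromatin (cHet) blocks, paired Dam-only /
Dam-fusion samples in two (or more) conditions with two replicates each,
and per-family occupancy and accessibility effects concentrated on one TE
class (LTR retrotransposons by default, mirroring the biology the pipeline
is built to detect).

Generative model
----------------
The unit of DamID amplification is the GATC fragment; a fragment is
amplified when its ends are Dam-methylated, which happens in proportion to
local chromatin accessibility (Dam-only) further scaled by the occupancy of
the tethered protein (Dam-fusion).  Reads are drawn multinomially over
fragments with weight

    w_f = length_f * (background + accessibility_f * m_f)

where m_f is the fragment's occupancy for Dam-fusion samples and 1 for
Dam-only samples.  Occupancy and accessibility multipliers are thereby
specified directly on the scale the pipeline estimates (expected CPM fold
changes), so configured effects are the ground truth the analysis should
recover: a 0.25x occupancy multiplier is a true Δlog2 occupancy of −2.
Accessibility is tied to occupancy through a declared monotone map,
accessibility = a0 * occupancy^(−γ) (condensed chromatin is less
accessible), optionally scaled by explicit per-family accessibility
multipliers; γ = 0 decouples the two.

Alignments, not raw reads, are emitted (read alignment is outside the
pipeline's scope): one record per sequenced fragment pair, with a MAPQ
model giving low MAPQ to a configurable fraction of reads from multi-copy
TE families so that both mapping-quality modes of the pipeline can be
exercised.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counting import SampleManifest, write_sam
from .genome import GatcFragmentMap, GenomeSequence, TEConsensusSet

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TEFamilySpec:
    """One TE family class: number of consensus sequences, their length,
    genomic copies per consensus, and the family's baseline HP1a occupancy
    (relative to the genomic background of 1)."""

    n_consensus: int
    consensus_length: int
    n_copies: int
    base_occupancy: float


@dataclass
class ConditionSpec:
    """Per-condition perturbation: multiplicative occupancy and
    accessibility effects per TE family class, plus an occupancy multiplier
    for non-TE cHet fragments (TE fragments already carry the family
    effect, and cHet-wide changes are also seen outside TEs)."""

    name: str
    occupancy_multipliers: dict[str, float] = field(default_factory=dict)
    accessibility_multipliers: dict[str, float] = field(default_factory=dict)
    chet_multiplier: float = 1.0


def _default_families() -> dict[str, TEFamilySpec]:
    return {
        "LTR": TEFamilySpec(10, 1000, 2, 4.0),
        "LINE": TEFamilySpec(8, 1000, 2, 3.0),
        "DNA": TEFamilySpec(8, 1000, 2, 2.0),
        "other": TEFamilySpec(6, 1000, 1, 2.0),
    }


def _default_conditions() -> list[ConditionSpec]:
    # control vs an Ago2-mutant-style perturbation: 4-fold loss of HP1a on
    # LTR retrotransposons (true Δlog2 = −2) and a 2-fold cHet-wide loss
    return [
        ConditionSpec("control"),
        ConditionSpec(
            "ago2mut",
            occupancy_multipliers={"LTR": 0.25},
            chet_multiplier=0.5,
        ),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 400_000
    n_chroms: int = 2
    te_families: dict[str, TEFamilySpec] = field(default_factory=_default_families)
    chet_fraction: float = 0.15
    chet_occupancy_boost: float = 3.0
    chet_te_placement_prob: float = 0.5
    reads_per_sample: int = 50_000
    replicates: int = 2
    conditions: list[ConditionSpec] = field(default_factory=_default_conditions)
    background_weight: float = 0.05
    baseline_occupancy: float = 1.0
    accessibility_exponent: float = 0.5  # γ in accessibility = a0 * occ^(−γ)
    accessibility_scale: float = 1.0  # a0
    substitution_rate: float = 0.02  # per-base divergence of genomic TE copies
    insert_length: int = 300  # sequenced-fragment span emitted per read pair
    multimap_mapq_fraction: float = 0.8
    multimap_mapq_max: int = 3
    unique_mapq: int = 42
    alignment_format: str = "sam"  # "sam" | "bed"

    def validate(self) -> None:
        if self.reads_per_sample < 1000:
            raise ValueError("reads_per_sample must be >= 1000")
        if not 0 <= self.chet_fraction < 1:
            raise ValueError("chet_fraction must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")
        for cond in self.conditions:
            for mult in (
                *cond.occupancy_multipliers.values(),
                *cond.accessibility_multipliers.values(),
                cond.chet_multiplier,
            ):
                if mult <= 0:
                    raise ValueError("condition multipliers must be > 0")
        for fam, spec in self.te_families.items():
            if spec.base_occupancy <= 0:
                raise ValueError(f"base_occupancy of {fam} must be > 0")

    # -- config (de)serialisation -----------------------------------------
    def to_yaml(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["te_families"] = {
            fam: TEFamilySpec(**spec) for fam, spec in doc["te_families"].items()
        }
        doc["conditions"] = [ConditionSpec(**c) for c in doc["conditions"]]
        return cls(**doc)

    def condition(self, name: str) -> ConditionSpec:
        for cond in self.conditions:
            if cond.name == name:
                return cond
        raise KeyError(name)


def reciprocal_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Three-condition design with reciprocal effects on the same TE set:
    one perturbation loses HP1a on LTR elements 4-fold, the other gains it
    4-fold (|true Δlog2| = 2), as when two perturbations converge on the
    same targets from opposite directions."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.conditions = [
        ConditionSpec("control"),
        ConditionSpec("ago2mut", occupancy_multipliers={"LTR": 0.25},
                      chet_multiplier=0.5),
        ConditionSpec("lamkd", occupancy_multipliers={"LTR": 4.0},
                      chet_multiplier=2.0),
    ]
    return cfg


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    tes: TEConsensusSet
    te_copies: pd.DataFrame  # chrom, start, end, te_name, family_class, copy_id
    chet: pd.DataFrame  # chrom, start, end


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def build_synthetic_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticGenome:
    """Random background genome + TE consensus set + genomic TE copies +
    cHet blocks.

    Under uniform base composition GATC occurs about once per 256 bp, so
    the fragment map has the expected density.  cHet blocks sit at the
    start of each chromosome (a stylised pericentromere) and attract a
    configurable share of TE copies; copies are mutated consensus sequences
    (default 2% substitutions) overwriting the background, non-overlapping.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {name: _random_bases(rng, chrom_len) for name in chrom_names}

    # consensus sequences
    cons_rows = []
    cons_seqs: dict[str, str] = {}
    for fam, spec in config.te_families.items():
        for i in range(spec.n_consensus):
            name = f"{fam}_{i + 1}"
            seq = _random_bases(rng, spec.consensus_length)
            cons_seqs[name] = seq.tobytes().decode()
            cons_rows.append((name, fam, spec.consensus_length))
    tes = TEConsensusSet(
        pd.DataFrame(cons_rows, columns=["te_name", "family_class", "length"]),
        cons_seqs,
    )

    # cHet blocks at chromosome starts
    chet_len = int(config.chet_fraction * chrom_len)
    chet_rows = [(name, 0, chet_len) for name in chrom_names] if chet_len else []
    chet = pd.DataFrame(chet_rows, columns=["chrom", "start", "end"])

    # place TE copies without overlap
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}

    def try_place(length: int, in_chet: bool) -> tuple[str, int] | None:
        for _ in range(300):
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            if in_chet and chet_len > length:
                start = int(rng.integers(0, chet_len - length))
            else:
                start = int(rng.integers(0, chrom_len - length))
            end = start + length
            if all(e <= start or s >= end for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                return chrom, start
        return None

    copy_rows = []
    copy_id = 0
    for fam, spec in config.te_families.items():
        for i in range(spec.n_consensus):
            name = f"{fam}_{i + 1}"
            cons = np.frombuffer(cons_seqs[name].encode(), dtype=np.uint8)
            for _ in range(spec.n_copies):
                in_chet = bool(rng.random() < config.chet_te_placement_prob)
                placed = try_place(spec.consensus_length, in_chet)
                if placed is None:
                    raise ValueError(
                        "TE copies exceed genome capacity; increase "
                        "genome_length or reduce copies"
                    )
                chrom, start = placed
                copy = cons.copy()
                mut = rng.random(len(copy)) < config.substitution_rate
                if mut.any():
                    # substitute with a uniformly random different base
                    shift = rng.integers(1, 4, int(mut.sum()))
                    base_idx = np.searchsorted(_BASES, copy[mut])
                    copy[mut] = _BASES[(base_idx + shift) % 4]
                arrays[chrom][start : start + len(copy)] = copy
                copy_rows.append(
                    (chrom, start, start + len(copy), name, fam, f"copy{copy_id}")
                )
                copy_id += 1
    te_copies = pd.DataFrame(
        copy_rows,
        columns=["chrom", "start", "end", "te_name", "family_class", "copy_id"],
    )
    te_copies = te_copies.sort_values(["chrom", "start"]).reset_index(drop=True)
    genome = GenomeSequence(
        {name: arrays[name].tobytes().decode() for name in chrom_names}
    )
    return SyntheticGenome(genome, tes, te_copies, chet)


# ---------------------------------------------------------------------------
# Fragment weights (per condition)
# ---------------------------------------------------------------------------

def assign_fragment_weights(
    fragment_map: GatcFragmentMap,
    syn: SyntheticGenome,
    condition: ConditionSpec,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-fragment occupancy and accessibility under one condition.

    A fragment overlapping a TE copy of family f takes that family's base
    occupancy times the condition's family multiplier (largest-overlap copy
    wins if a fragment spans two copies); cHet fragments get the static
    chet_occupancy_boost, and non-TE cHet fragments additionally the
    condition's chet_multiplier.  Accessibility is the declared monotone
    map a0 * occupancy^(−γ) times any explicit per-family accessibility
    multiplier.
    """
    frame = fragment_map.frame.copy()
    mids = (frame["start"].to_numpy() + frame["end"].to_numpy()) // 2

    te_name = np.full(len(frame), "", dtype=object)
    family = np.full(len(frame), "", dtype=object)
    copy_start = np.zeros(len(frame), dtype=np.int64)
    copy_end = np.zeros(len(frame), dtype=np.int64)
    for chrom, group in frame.groupby("chrom", sort=False):
        copies = syn.te_copies[syn.te_copies["chrom"] == chrom]
        if copies.empty:
            continue
        cs = copies["start"].to_numpy()
        ce = copies["end"].to_numpy()
        fs = group["start"].to_numpy()
        fe = group["end"].to_numpy()
        for row_pos, (s, e) in zip(group.index, zip(fs, fe)):
            cand = np.flatnonzero((cs < e) & (ce > s))
            if len(cand) == 0:
                continue
            overlaps = np.minimum(ce[cand], e) - np.maximum(cs[cand], s)
            best = cand[int(np.argmax(overlaps))]
            te_name[row_pos] = copies["te_name"].iloc[best]
            family[row_pos] = copies["family_class"].iloc[best]
            copy_start[row_pos] = cs[best]
            copy_end[row_pos] = ce[best]

    in_chet = np.zeros(len(frame), dtype=bool)
    for region in syn.chet.itertuples(index=False):
        in_chet |= (
            (frame["chrom"].to_numpy() == region.chrom)
            & (mids >= region.start)
            & (mids < region.end)
        )

    occupancy = np.full(len(frame), config.baseline_occupancy, dtype=float)
    acc_mult = np.ones(len(frame), dtype=float)
    is_te = family != ""
    for fam, spec in config.te_families.items():
        fam_mask = family == fam
        if not fam_mask.any():
            continue
        occ_mult = condition.occupancy_multipliers.get(fam, 1.0)
        occupancy[fam_mask] = spec.base_occupancy * occ_mult
        acc_mult[fam_mask] = condition.accessibility_multipliers.get(fam, 1.0)
    occupancy[in_chet] *= config.chet_occupancy_boost
    occupancy[in_chet & ~is_te] *= condition.chet_multiplier
    gamma = config.accessibility_exponent
    accessibility = (
        config.accessibility_scale * occupancy ** (-gamma) * acc_mult
    )

    frame["te_name"] = te_name
    frame["family_class"] = family
    frame["copy_start"] = copy_start
    frame["copy_end"] = copy_end
    frame["in_chet"] = in_chet
    frame["occupancy"] = occupancy
    frame["accessibility"] = accessibility
    return frame


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def simulate_sample(
    weights: pd.DataFrame,
    fusion: str,
    reads_per_sample: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    read_prefix: str = "r",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one sample's alignments on the genome and on TE consensuses.

    Reads are multinomial over fragments with weight
    length * (background + accessibility * occupancy-or-1); positions are
    uniform within the fragment (span = min(insert_length, fragment
    length)).  Each genome read overlapping a TE copy also emits a record
    in consensus coordinates; reads from multi-copy families draw a low
    MAPQ with probability multimap_mapq_fraction.
    """
    if fusion not in ("dam_only", "dam_fusion"):
        raise ValueError(f"unknown fusion kind {fusion!r}")
    length = (weights["end"] - weights["start"]).to_numpy(dtype=float)
    signal = weights["accessibility"].to_numpy().copy()
    if fusion == "dam_fusion":
        signal = signal * weights["occupancy"].to_numpy()
    w = length * (config.background_weight + signal)
    if not (w > 0).any():
        raise ValueError("zero amplifiable weight everywhere; raise background")
    counts = rng.multinomial(reads_per_sample, w / w.sum())

    frag_idx = np.repeat(np.arange(len(w)), counts)
    n = len(frag_idx)
    fs = weights["start"].to_numpy()[frag_idx]
    fe = weights["end"].to_numpy()[frag_idx]
    span = np.minimum(config.insert_length, fe - fs)
    start = fs + np.floor(rng.random(n) * (fe - fs - span + 1)).astype(np.int64)
    end = start + span
    strand = np.where(rng.random(n) < 0.5, "+", "-")

    fam = weights["family_class"].to_numpy()[frag_idx]
    multi_fams = {
        f for f, spec in config.te_families.items()
        if spec.n_consensus * spec.n_copies > 1 and spec.n_copies > 1
    }
    is_multi = np.isin(fam, list(multi_fams))
    low = is_multi & (rng.random(n) < config.multimap_mapq_fraction)
    mapq = np.full(n, config.unique_mapq, dtype=np.int64)
    mapq[low] = rng.integers(0, config.multimap_mapq_max + 1, int(low.sum()))

    read_id = np.array([f"{read_prefix}{i:07d}" for i in range(n)], dtype=object)
    genome_aln = pd.DataFrame(
        {
            "target": weights["chrom"].to_numpy()[frag_idx],
            "start": start,
            "end": end,
            "strand": strand,
            "mapq": mapq,
            "read_id": read_id,
        }
    )

    # consensus-coordinate records for reads overlapping a TE copy
    te = weights["te_name"].to_numpy()[frag_idx]
    cps = weights["copy_start"].to_numpy()[frag_idx]
    cpe = weights["copy_end"].to_numpy()[frag_idx]
    ov_start = np.maximum(start, cps)
    ov_end = np.minimum(end, cpe)
    has_te = (te != "") & (ov_end > ov_start)
    te_aln = pd.DataFrame(
        {
            "target": te[has_te],
            "start": (ov_start - cps)[has_te],
            "end": (ov_end - cps)[has_te],
            "strand": strand[has_te],
            "mapq": mapq[has_te],
            "read_id": read_id[has_te],
        }
    )
    return genome_aln, te_aln


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def true_te_effects(
    config: SimulationConfig, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Per-TE true effects of condition B relative to condition A:
    Δlog2 occupancy and log2 accessibility fold change (through the
    accessibility map plus explicit multipliers)."""
    cond_a = config.condition(condition_a)
    cond_b = config.condition(condition_b)
    rows = []
    gamma = config.accessibility_exponent
    for fam, spec in config.te_families.items():
        occ_ratio = cond_b.occupancy_multipliers.get(fam, 1.0) / (
            cond_a.occupancy_multipliers.get(fam, 1.0)
        )
        acc_ratio = occ_ratio ** (-gamma) * (
            cond_b.accessibility_multipliers.get(fam, 1.0)
            / cond_a.accessibility_multipliers.get(fam, 1.0)
        )
        for i in range(spec.n_consensus):
            rows.append(
                (
                    f"{fam}_{i + 1}",
                    fam,
                    float(np.log2(occ_ratio)),
                    float(np.log2(acc_ratio)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "te_name",
            "family_class",
            "true_delta_log2_occupancy",
            "true_log2fc_accessibility",
        ],
    )


def fragment_truth(
    weight_tables: dict[str, pd.DataFrame], config: SimulationConfig
) -> pd.DataFrame:
    """Per-fragment sampling probabilities per condition and fusion kind
    (the simulator's full truth table)."""
    out = None
    for cond_name, weights in weight_tables.items():
        length = (weights["end"] - weights["start"]).to_numpy(dtype=float)
        acc = weights["accessibility"].to_numpy()
        occ = weights["occupancy"].to_numpy()
        w_dam = length * (config.background_weight + acc)
        w_fus = length * (config.background_weight + acc * occ)
        cols = pd.DataFrame(
            {
                f"p_dam_only_{cond_name}": w_dam / w_dam.sum(),
                f"p_dam_fusion_{cond_name}": w_fus / w_fus.sum(),
            }
        )
        if out is None:
            out = weights[["fragment_id", "chrom", "start", "end", "te_name"]].copy()
        out = pd.concat([out, cols], axis=1)
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    syn: SyntheticGenome
    fragment_map: GatcFragmentMap
    weight_tables: dict[str, pd.DataFrame]  # per condition
    manifest_frame: pd.DataFrame  # sample_id, condition, fusion, replicate
    alignments: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # per sample_id
    te_truth: pd.DataFrame | None  # contrast of first two conditions


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full in-memory dataset: genome, fragment weights per
    condition, and alignments for every (condition, fusion, replicate)
    sample.  Deterministic given config.seed."""
    config.validate()
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(1 + len(config.conditions) * 2 * config.replicates)
    syn = build_synthetic_genome(config, np.random.default_rng(children[0]))
    fragment_map = GatcFragmentMap.from_genome(syn.genome)

    weight_tables = {
        cond.name: assign_fragment_weights(fragment_map, syn, cond, config)
        for cond in config.conditions
    }

    manifest_rows = []
    alignments: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    child = 1
    for cond in config.conditions:
        for fusion in ("dam_only", "dam_fusion"):
            for rep in range(1, config.replicates + 1):
                sample_id = f"{cond.name}_{fusion}_rep{rep}"
                rng = np.random.default_rng(children[child])
                child += 1
                genome_aln, te_aln = simulate_sample(
                    weight_tables[cond.name],
                    fusion,
                    config.reads_per_sample,
                    rng,
                    config,
                    read_prefix=f"{sample_id}.",
                )
                alignments[sample_id] = (genome_aln, te_aln)
                manifest_rows.append((sample_id, cond.name, fusion, rep))
    manifest_frame = pd.DataFrame(
        manifest_rows, columns=["sample_id", "condition", "fusion", "replicate"]
    )
    te_truth = None
    if len(config.conditions) >= 2:
        te_truth = true_te_effects(
            config, config.conditions[0].name, config.conditions[1].name
        )
    return SimulatedDataset(
        config, syn, fragment_map, weight_tables, manifest_frame, alignments,
        te_truth,
    )


def emit_dataset(config: SimulationConfig, outdir) -> Path:
    """Write a dataset directory directly consumable by the pipeline:
    FASTA (genome, consensus), BEDs (TE copies, cHet), SAM (or BED)
    alignments per sample, a YAML manifest, and ground-truth TSVs (never
    read by the pipeline)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    ds.syn.genome.to_fasta(outdir / "genome.fa")
    ds.syn.tes.to_fasta(outdir / "te_consensus.fa")
    ds.syn.te_copies[["chrom", "start", "end", "te_name"]].to_csv(
        outdir / "te_copies.bed", sep="\t", header=False, index=False
    )
    ds.syn.chet.to_csv(outdir / "chet.bed", sep="\t", header=False, index=False)

    ext = ".sam" if config.alignment_format == "sam" else ".bed"
    rows = []
    genome_lengths = ds.syn.genome.lengths
    te_lengths = ds.syn.tes.lengths
    for sample_id, (genome_aln, te_aln) in ds.alignments.items():
        gpath = outdir / f"{sample_id}.genome{ext}"
        tpath = outdir / f"{sample_id}.te{ext}"
        if config.alignment_format == "sam":
            write_sam(genome_aln, genome_lengths, gpath)
            write_sam(te_aln, te_lengths, tpath)
        else:
            from .counting import write_bed6

            write_bed6(genome_aln, gpath)
            write_bed6(te_aln, tpath)
        logger.info(
            "sample %s: %d genome records, %d TE records",
            sample_id,
            len(genome_aln),
            len(te_aln),
        )
        meta = ds.manifest_frame.loc[
            ds.manifest_frame["sample_id"] == sample_id
        ].iloc[0]
        rows.append(
            {
                "sample_id": sample_id,
                "condition": meta["condition"],
                "fusion": meta["fusion"],
                "replicate": int(meta["replicate"]),
                "genome_alignments": gpath.name,
                "te_alignments": tpath.name,
            }
        )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"samples": rows}, fh, sort_keys=False)
    config.to_yaml(outdir / "sim_config.yaml")
    if ds.te_truth is not None:
        ds.te_truth.to_csv(outdir / "truth_te.tsv", sep="\t", index=False)
    fragment_truth(ds.weight_tables, config).to_csv(
        outdir / "truth_fragments.tsv", sep="\t", index=False
    )
    # validate the manifest we just wrote
    SampleManifest.from_yaml(outdir / "manifest.yaml")
    return outdir
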