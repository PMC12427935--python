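"""End-to-end orchestration: fragment map → counting → replicate pooling →
occupancy profiles → TE quantification → differential statistics.

`run_analysis` is the in-memory engine (alignments as DataFrames);
`run_full` is the file-based wrapper that loads a dataset directory,
optionally runs both MAPQ modes side by side, and writes every table and
track with a run-metadata header.  Outputs are deterministic: re-running
with identical inputs and parameters reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counting import (
    FeatureCounts,
    SampleManifest,
    count_features,
    dedup_alignments,
    filter_mapq,
    pool_replicates,
    read_alignments,
)
from .genome import (
    GatcFragmentMap,
    GenomeSequence,
    TEConsensusSet,
    build_te_bins,
    read_bed3,
)
from .occupancy import (
    CorrelationResult,
    OccupancyProfile,
    log2_ratio_profile,
    replicate_correlation,
    to_cpm,
    write_bedgraph,
)
from .stats import (
    ChetComparison,
    EnrichmentResult,
    OverlapResult,
    chet_compare,
    class_enrichment_ztest,
    overlap_sets,
)
from .tequant import rank_te_by_delta, summarize_te, te_bin_profile

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Tunable parameters of one analysis pass.

    mapq_threshold: None keeps all reads (the mode used for TE work, where
    mapping is inherently non-unique); 40 excludes non-uniquely mapped
    reads.  top_k defaults to the top quartile of TEs with defined delta.
    """

    mapq_threshold: int | None = None
    pseudocount: float = 1.0
    te_bin_width: int = 50
    min_te_bin_coverage: int = 1
    min_genome_coverage: int = 0
    genome_feature_mode: str = "fragments"  # "fragments" | "bins"
    genome_bin_width: int = 500
    top_k: int | None = None
    rank_direction: str = "decrease"
    enrichment_class: str = "LTR"
    overlap_threshold_up: float = 1.0
    overlap_threshold_down: float = -1.0
    chet_bin_width: int = 1000
    contrast: tuple[str, str] | None = None  # (control, perturbed)
    overlap_contrast: tuple[str, str] | None = None  # second axis for overlap

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SampleData:
    """Per-sample deduplicated, MAPQ-filtered alignments and counts."""

    sample_id: str
    condition: str
    fusion: str
    replicate: int
    total_genome_mapped: int
    genome_counts: FeatureCounts
    te_counts: FeatureCounts


@dataclass
class AnalysisResult:
    params: AnalysisParams
    fragment_map: GatcFragmentMap
    genome_features: pd.DataFrame
    samples: list[SampleData]
    replicate_correlations: pd.DataFrame
    genome_profiles: dict[str, OccupancyProfile]  # per condition
    te_profiles: dict[str, pd.DataFrame]  # per condition
    te_table: pd.DataFrame
    top_set: list[str]
    enrichment: EnrichmentResult
    overlap: OverlapResult
    chet: ChetComparison | None
    contrast: tuple[str, str]
    overlap_contrast: tuple[str, str]
    te_table_secondary: pd.DataFrame | None = None


def _genome_scheme(genome: GenomeSequence, params: AnalysisParams):
    """Genome features in one of two selectable modes: GATC fragments
    (default; the DamID amplification unit) or fixed-width bins."""
    fragment_map = GatcFragmentMap.from_genome(genome)
    if params.genome_feature_mode == "fragments":
        return fragment_map, fragment_map
    if params.genome_feature_mode == "bins":
        from .genome import BinScheme

        scheme = BinScheme.from_lengths(genome.lengths, params.genome_bin_width)
        return fragment_map, scheme
    raise ValueError(f"unknown genome_feature_mode {params.genome_feature_mode!r}")


def run_analysis(
    genome: GenomeSequence,
    tes: TEConsensusSet,
    manifest: SampleManifest,
    alignments: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    chet_regions: pd.DataFrame | None,
    params: AnalysisParams | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory alignments.

    ``alignments`` maps sample_id to (genome alignments, TE alignments)
    DataFrames.  The contrast defaults to (first, second) condition in
    manifest order; delta columns are perturbed − control.
    """
    params = params or AnalysisParams()
    fragment_map, genome_scheme = _genome_scheme(genome, params)
    te_bins = build_te_bins(tes, params.te_bin_width)
    logger.info(
        "stage fragments: %d genome features, %d TE bins",
        len(genome_scheme),
        len(te_bins),
    )

    samples: list[SampleData] = []
    for row in manifest.frame.itertuples(index=False):
        genome_aln, te_aln = alignments[row.sample_id]
        genome_aln = dedup_alignments(genome_aln)
        te_aln = dedup_alignments(te_aln)
        # TE CPM denominator: genome-mapped reads, before MAPQ filtering
        total_genome_mapped = len(genome_aln)
        n_in = len(genome_aln) + len(te_aln)
        genome_aln = filter_mapq(genome_aln, params.mapq_threshold)
        te_aln = filter_mapq(te_aln, params.mapq_threshold)
        logger.info(
            "stage count[%s]: %d records in, %d after MAPQ filter",
            row.sample_id,
            n_in,
            len(genome_aln) + len(te_aln),
        )
        genome_counts = count_features(genome_aln, genome_scheme)
        te_counts = count_features(te_aln, te_bins)
        te_counts.total_genome_mapped = total_genome_mapped
        genome_counts.total_genome_mapped = total_genome_mapped
        samples.append(
            SampleData(
                row.sample_id,
                row.condition,
                row.fusion,
                int(row.replicate),
                total_genome_mapped,
                genome_counts,
                te_counts,
            )
        )

    # replicate agreement on per-replicate genome profiles
    corr_rows = []
    for condition in manifest.conditions:
        reps = _condition_profiles_per_replicate(samples, condition, params)
        for (ra, pa), (rb, pb) in zip(reps[:-1], reps[1:]):
            res: CorrelationResult = replicate_correlation(pa, pb)
            corr_rows.append((condition, ra, rb, res.r, res.n_joint))
    replicate_correlations = pd.DataFrame(
        corr_rows, columns=["condition", "replicate_a", "replicate_b", "r", "n_joint"]
    )

    # pool replicates, then genome occupancy profiles per condition
    genome_profiles: dict[str, OccupancyProfile] = {}
    te_profiles: dict[str, pd.DataFrame] = {}
    for condition in manifest.conditions:
        pooled = {
            fusion: pool_replicates(
                [
                    s.genome_counts
                    for s in samples
                    if s.condition == condition and s.fusion == fusion
                ]
            )
            for fusion in ("dam_only", "dam_fusion")
        }
        genome_profiles[condition] = log2_ratio_profile(
            to_cpm(pooled["dam_fusion"], "assigned"),
            to_cpm(pooled["dam_only"], "assigned"),
            pseudocount=params.pseudocount,
            min_coverage=params.min_genome_coverage,
            fusion_counts=pooled["dam_fusion"],
            dam_only_counts=pooled["dam_only"],
        )
        pooled_te = {
            fusion: pool_replicates(
                [
                    s.te_counts
                    for s in samples
                    if s.condition == condition and s.fusion == fusion
                ]
            )
            for fusion in ("dam_only", "dam_fusion")
        }
        te_profiles[condition] = te_bin_profile(
            pooled_te["dam_fusion"],
            pooled_te["dam_only"],
            te_bins,
            tes,
            pseudocount=params.pseudocount,
            min_coverage=params.min_te_bin_coverage,
        )

    contrast = params.contrast or tuple(manifest.conditions[:2])
    if len(contrast) != 2:
        raise ValueError("need at least two conditions for a contrast")
    cond_a, cond_b = contrast
    te_table = summarize_te(
        te_profiles, tes, cond_a, cond_b, pseudocount=params.pseudocount
    )

    n_defined = int(te_table["delta_log2_ratio"].notna().sum())
    k = params.top_k or max(1, round(n_defined / 4))
    k = min(k, n_defined)
    top_set = rank_te_by_delta(te_table, k, params.rank_direction)
    enrichment = class_enrichment_ztest(top_set, te_table, params.enrichment_class)

    # overlap: a second contrast when available, else the primary contrast
    # on both axes (degenerate but well-defined report)
    overlap_contrast = params.overlap_contrast or contrast
    te_table_secondary = None
    if overlap_contrast != contrast:
        te_table_secondary = summarize_te(
            te_profiles,
            tes,
            overlap_contrast[0],
            overlap_contrast[1],
            pseudocount=params.pseudocount,
        )
        delta_up = te_table_secondary.set_index("te_name")["delta_log2_ratio"]
    else:
        delta_up = te_table.set_index("te_name")["delta_log2_ratio"]
    delta_down = te_table.set_index("te_name")["delta_log2_ratio"]
    overlap = overlap_sets(
        delta_up,
        delta_down,
        params.overlap_threshold_up,
        params.overlap_threshold_down,
    )

    chet = None
    if chet_regions is not None and not chet_regions.empty:
        chet = chet_compare(
            genome_profiles[cond_b],
            genome_profiles[cond_a],
            genome_scheme.features,
            chet_regions,
            bin_width=params.chet_bin_width,
            label_a=cond_b,
            label_b=cond_a,
        )

    return AnalysisResult(
        params=params,
        fragment_map=fragment_map,
        genome_features=genome_scheme.features,
        samples=samples,
        replicate_correlations=replicate_correlations,
        genome_profiles=genome_profiles,
        te_profiles=te_profiles,
        te_table=te_table,
        top_set=top_set,
        enrichment=enrichment,
        overlap=overlap,
        chet=chet,
        contrast=(cond_a, cond_b),
        overlap_contrast=tuple(overlap_contrast),
        te_table_secondary=te_table_secondary,
    )


def _condition_profiles_per_replicate(
    samples: list[SampleData], condition: str, params: AnalysisParams
) -> list[tuple[int, OccupancyProfile]]:
    by_rep: dict[int, dict[str, FeatureCounts]] = {}
    for s in samples:
        if s.condition != condition:
            continue
        by_rep.setdefault(s.replicate, {})[s.fusion] = s.genome_counts
    out = []
    for rep in sorted(by_rep):
        kinds = by_rep[rep]
        if set(kinds) != {"dam_only", "dam_fusion"}:
            continue
        profile = log2_ratio_profile(
            to_cpm(kinds["dam_fusion"], "assigned"),
            to_cpm(kinds["dam_only"], "assigned"),
            pseudocount=params.pseudocount,
        )
        out.append((rep, profile))
    return out


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Inputs and parameters of a file-based pipeline run."""

    genome_fasta: str
    te_fasta: str
    manifest: str
    output_dir: str
    chet_bed: str | None = None
    mapq_modes: list[int | None] = field(default_factory=lambda: [None])
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        params = AnalysisParams(**doc.pop("params", {}))
        base = Path(path).parent

        def resolve(p):
            return str(p) if Path(p).is_absolute() else str(base / p)

        for key in ("genome_fasta", "te_fasta", "manifest", "chet_bed"):
            if doc.get(key):
                doc[key] = resolve(doc[key])
        return cls(params=params, **doc)

    def validate(self) -> None:
        for key in ("genome_fasta", "te_fasta", "manifest"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")
        if self.chet_bed and not Path(self.chet_bed).exists():
            raise FileNotFoundError(f"chet_bed: {self.chet_bed}")


def _meta(config: RunConfig, params: AnalysisParams) -> dict:
    return {
        "damidte_version": __version__,
        "seed": config.seed,
        "parameters": yaml.safe_dump(
            params.as_dict(), default_flow_style=True, width=1_000_000
        ).strip(),
    }


def write_table(frame: pd.DataFrame, path, meta: dict) -> None:
    """TSV with a '#'-prefixed run-metadata header; stable column order and
    float formatting so reruns are byte-identical."""
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_full(config: RunConfig) -> dict[str, AnalysisResult]:
    """Execute every stage and write the result directory.

    One output tree per MAPQ mode (``mapq_none`` / ``mapq_40`` subdirs when
    more than one mode is requested, mirroring a dual unique/non-unique
    analysis).  Returns the AnalysisResult per mode.
    """
    config.validate()
    genome = GenomeSequence.from_fasta(config.genome_fasta)
    tes = TEConsensusSet.from_fasta(config.te_fasta)
    manifest_path = Path(config.manifest)
    if manifest_path.suffix in (".yaml", ".yml"):
        manifest = SampleManifest.from_yaml(manifest_path)
    else:
        manifest = SampleManifest.from_tsv(manifest_path)
    chet_regions = read_bed3(config.chet_bed) if config.chet_bed else None

    alignments = {
        row.sample_id: (
            read_alignments(row.genome_alignments),
            read_alignments(row.te_alignments),
        )
        for row in manifest.frame.itertuples(index=False)
    }

    results: dict[str, AnalysisResult] = {}
    outdir = Path(config.output_dir)
    for mode in config.mapq_modes:
        params = dataclasses.replace(config.params, mapq_threshold=mode)
        mode_name = "mapq_none" if mode is None else f"mapq_{mode}"
        mode_dir = outdir / mode_name if len(config.mapq_modes) > 1 else outdir
        try:
            result = run_analysis(genome, tes, manifest, alignments,
                                  chet_regions, params)
        except Exception as exc:  # tag the failing stage for the operator
            raise RuntimeError(f"analysis failed in mode {mode_name}: {exc}") from exc
        write_outputs(result, mode_dir, _meta(config, params))
        results[mode_name] = result
    return results


def write_outputs(result: AnalysisResult, outdir, meta: dict) -> None:
    outdir = Path(outdir)
    for sub in ("counts", "occupancy", "tequant", "diff", "qc"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    result.fragment_map.to_bed(outdir / "fragments.bed")
    for s in result.samples:
        write_table(
            s.genome_counts.to_frame(),
            outdir / "counts" / f"{s.sample_id}.genome.tsv",
            {**meta, "total_genome_mapped": s.total_genome_mapped},
        )
        write_table(
            s.te_counts.to_frame(),
            outdir / "counts" / f"{s.sample_id}.te.tsv",
            {**meta, "total_genome_mapped": s.total_genome_mapped},
        )
    write_table(
        result.replicate_correlations,
        outdir / "qc" / "replicate_correlation.tsv",
        meta,
    )
    for condition, profile in result.genome_profiles.items():
        write_bedgraph(
            profile,
            result.genome_features,
            outdir / "occupancy" / f"{condition}.genome.bedgraph",
            track_name=f"log2_damfusion_over_dam_{condition}",
            meta={**meta, "pseudocount": profile.pseudocount},
        )
    for condition, profile in result.te_profiles.items():
        write_table(profile, outdir / "occupancy" / f"{condition}.te.tsv", meta)
    write_table(result.te_table, outdir / "tequant" / "te_table.tsv", meta)
    from .tequant import heatmap_matrix

    write_table(
        heatmap_matrix(
            result.te_table, ["delta_log2_ratio", "log2_fc_dam_only"]
        ).reset_index(),
        outdir / "tequant" / "te_matrix.tsv",
        meta,
    )
    if result.te_table_secondary is not None:
        write_table(
            result.te_table_secondary,
            outdir / "tequant" / "te_table_secondary.tsv",
            meta,
        )

    enr = result.enrichment
    write_table(
        pd.DataFrame(
            [
                {
                    "test": "two_proportion_ztest_pooled",
                    "target_class": enr.target_class,
                    "contrast": "-".join(result.contrast),
                    "top_set_size": len(result.top_set),
                    "top_set": ",".join(result.top_set),
                    "n_selected_in_class": enr.n_selected_in_class,
                    "n_universe": enr.n_universe,
                    "n_universe_in_class": enr.n_universe_in_class,
                    "p_selected": enr.p_selected,
                    "p_universe": enr.p_universe,
                    "z": enr.z,
                    "p_value": enr.p_value,
                }
            ]
        ),
        outdir / "diff" / "enrichment.tsv",
        meta,
    )
    ov = result.overlap
    write_table(
        pd.DataFrame(
            [
                {
                    "contrast_up": "-".join(result.overlap_contrast),
                    "contrast_down": "-".join(result.contrast),
                    "threshold_up": ov.threshold_up,
                    "threshold_down": ov.threshold_down,
                    "n_up": len(ov.set_up),
                    "n_down": len(ov.set_down),
                    "n_intersection": len(ov.intersection),
                    "jaccard": ov.jaccard,
                    "set_up": ",".join(sorted(ov.set_up)),
                    "set_down": ",".join(sorted(ov.set_down)),
                    "intersection": ",".join(sorted(ov.intersection)),
                }
            ]
        ),
        outdir / "diff" / "overlap.tsv",
        meta,
    )
    if result.chet is not None:
        ch = result.chet
        write_table(ch.bins, outdir / "diff" / "chet_bins.tsv", meta)
        write_table(
            pd.DataFrame(
                [
                    {
                        "condition": label,
                        "n": box.n,
                        "median": box.median,
                        "q1": box.q1,
                        "q3": box.q3,
                        "whisker_low": box.whisker_low,
                        "whisker_high": box.whisker_high,
                    }
                    for label, box in (
                        (ch.label_a, ch.box_a),
                        (ch.label_b, ch.box_b),
                    )
                ]
            ),
            outdir / "diff" / "chet_boxstats.tsv",
            meta,
        )
        write_table(
            pd.DataFrame(
                [
                    {
                        "test": "mann_whitney_u",
                        "U": ch.mwu.U,
                        "n1": ch.mwu.n1,
                        "n2": ch.mwu.n2,
                        "p_value": ch.mwu.p_value,
                        "method": ch.mwu.method,
                        "tie_corrected": ch.mwu.tie_corrected,
                    }
                ]
            ),
            outdir / "diff" / "chet_mwu.tsv",
            meta,
        )
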