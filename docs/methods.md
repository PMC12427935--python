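# Methods

## Background and scope

DamID maps the chromatin binding of a protein of interest by fusing it to
*E. coli* Dam methyltransferase. Dam deposits adenine methylation at GATC
motifs near the fusion protein's binding sites; genomic fragments carrying
methylated GATC at both ends are selectively amplified and sequenced. An
untethered Dam-only sample methylates chromatin in proportion to its
accessibility and serves as the normalization control, so the occupancy
signal is log2(Dam-fusion / Dam-only) after depth normalization. Because
transposable elements (TEs) are repetitive, TE occupancy is quantified on
one consensus sequence per family, aggregating reads from all genomic
copies.

`damidte` implements this quantification — GATC-fragment-aware counting,
CPM normalization, log2 ratio profiles, 50-bp-binned TE consensus
quantification, and the downstream statistics (TE-class enrichment Z-test,
thresholded set overlap, Mann–Whitney comparison of heterochromatin
regions, RT-qPCR ΔΔCt testing) — together with a synthetic data generator
that produces desk-scale datasets with known ground truth. The pipeline
consumes alignments (SAM or BED); read trimming and alignment are out of
scope, as is per-genomic-copy TE quantification or insertion calling.

## The quantification model

**GATC fragments.** DpnI cuts at methylated GATC, so the amplified unit is
the interval between consecutive GATC motifs. Coordinates are 0-based
half-open throughout; the fragment boundary is placed at the motif start
(the G), so each fragment owns the GATC at its left edge. Any fixed
convention is internally consistent; the same convention is used by the
counter and the simulator. A motif at position 0 creates no empty leading
fragment. N bases never match the motif. Genome-wide profiles can
alternatively use fixed-width bins (`genome_feature_mode="bins"`); GATC
fragments are the default because they are the physical amplification
unit.

**Counting.** Each alignment is assigned to exactly one feature by its
midpoint (a midpoint exactly on a boundary goes to the right-hand,
half-open bin). Fractional overlap splitting is deliberately avoided: the
amplified molecule is the whole fragment, so splitting would only smear
counts. Paired mates sharing a read id on the same target are collapsed to
one spanning record; a read id aligned to several targets (multi-copy TE
families) is counted once, keeping the best hit by MAPQ with first-seen
order breaking ties. Records on unknown targets are dropped with a logged
count; total assigned counts are checked for conservation.

**Normalization.** Genome profiles use CPM with the sample's assigned-read
total. TE-consensus bins use CPM with the number of reads mapped to the
*genome* as the denominator, so TE signal is comparable across samples and
not inflated when TE-derived reads dominate a library. The occupancy
profile is

    log2((CPM_fusion + c) / (CPM_dam + c))

with pseudocount c = 1 CPM by default (configurable, recorded in output
headers). Replicates are pooled by summing counts before CPM is
recomputed, which for equal-depth replicates equals averaging replicate
CPMs; per-replicate profiles are still computed for the Pearson
replicate-agreement report. Missing values (below the raw-count floor in
both samples) stay missing and are excluded from averages, never imputed
as zero. The floor defaults to 0 for genome features and 1 raw read for TE
bins, since per-TE summaries are reported for every TE and filtering is
opt-in.

**Per-TE summaries.** Each TE consensus is tiled into 50-bp bins
(ceil(L/50) bins; last bin short). The per-TE occupancy score is the mean
of defined bin log2 ratios — bin-level averaging, not a ratio of summed
counts — and the condition contrast is the difference of those means
(delta = perturbed − control). Dam-only accessibility per TE is the mean
bin Dam-only CPM; its fold change is log2 of the ratio of means with
pseudocount. The "top set" is the k TEs with the strongest delta in the
requested direction, ties broken lexicographically by name; k is a run
parameter defaulting to the top quartile of TEs with defined delta (a
fixed count like 33 reflects one particular dataset's distribution, so it
is not hard-coded).

**MAPQ modes.** Two modes mirror the dual treatment of repetitive DNA: no
MAPQ threshold (default; TE reads are inherently multi-mapping) and a
threshold of 40 that restricts to uniquely mapped reads. `run_full` can
produce both output trees in one invocation. The TE CPM denominator
(genome-mapped reads) is recorded before MAPQ filtering.

## Statistics

**TE-class enrichment.** Whether a class (LTR retrotransposons by
default) is over-represented in the top set is tested with a pooled
two-proportion Z-test of the class frequency in the selection against the
full TE universe (the selection is not excluded from the universe — the
comparison is "ratio among selected vs ratio among all"), two-sided
normal p. The normal approximation requires the selection to be small
relative to the universe; with selections that are a sizable fraction of a
small universe the test is conservative, because sampling without
replacement has variance ≈ p(1−p)(1/m − 1/N) while the pooled statistic
uses 1/m + 1/N. The calibration check therefore uses m/N = 2%
(48 of 2400), where the nominal 5% level is attained.

**Mann–Whitney U.** Midranks for ties; U reported for the first sample.
For n1 + n2 ≤ 12 the two-sided p is exact by enumerating all C(n1+n2, n1)
labelings (valid under ties), p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.
Larger samples use the normal approximation with tie-corrected variance
and a continuity correction applied toward the mean (so identical
distributions give p = 1 exactly). All-identical pooled values are flagged
degenerate with p = 1. No multiple-testing correction is applied anywhere;
p-values are per comparison, and outputs carry the test variant and sample
sizes.

**cHet comparison.** Constitutive-heterochromatin regions (supplied as
BED) are tiled into 1-kb bins (configurable); each bin's value per
condition is the mean of defined profile entries whose feature midpoint
falls in the bin. The two per-bin distributions are compared with the
Mann–Whitney test, and box-plot summaries (quartiles, whiskers at 1.5 IQR)
are exported.

**RT-qPCR.** ΔCt = Ct_target − Ct_reference per replicate within each
condition; per-replicate fold change 2^−(ΔCt_test − mean ΔCt_control)
(control centering uses the control mean, as replicate pairing across
conditions is generally arbitrary); one-sample two-tailed t-test of log2
fold changes against 0, skipped with a flag below two replicates or at
zero variance.

**Set overlap.** Given two per-TE delta series on the same universe, the
sets {delta_A > +1} and {delta_B < −1} (thresholds configurable) are
intersected and the Jaccard index reported. In a two-condition run the
report degenerates to one contrast on both axes; a second perturbation
condition enables the real reciprocal comparison.

## The synthetic data generator

The generator emulates the structure of a DamID study of HP1a in a
repeat-rich genome: paired Dam-only/Dam-fusion samples, two replicates,
two conditions (a control and a perturbation that depletes HP1a 4-fold on
LTR retrotransposons and 2-fold across cHet), with occupancy effects
concentrated on one TE class.

**Genome.** Uniform-random background (GATC density ~1/256 bp), default
400 kb over 2 chromosomes. TE consensus sequences are generated per family
(defaults: 10 LTR, 8 LINE, 8 DNA, 6 other; 1 kb each) and copied into the
genome (2 copies per consensus except single-copy "other"), each copy
mutated at 2% of bases; copies never overlap. cHet blocks (15% of each
chromosome, at the chromosome start as a stylised pericentromere) attract
half of the TE copies.

**Fragment weights.** Per condition, each GATC fragment gets an occupancy:
baseline 1; TE fragments take their family's base occupancy (LTR 4, LINE
3, DNA 2, other 2) times the condition's family multiplier; cHet fragments
are boosted 3-fold (a static structural property applied in all
conditions); non-TE cHet fragments additionally take the condition's cHet
multiplier. The condition-level cHet multiplier deliberately excludes TE
fragments so that the realised per-TE effect equals the configured family
multiplier exactly — cHet-wide changes are modelled on the TE-free repeat
fraction, which is also where they are observed independently of TEs.
Accessibility follows the declared monotone map

    accessibility = a0 * occupancy^(−γ),    γ = 0.5 by default

(condensed chromatin is less accessible; γ = 0 decouples the two), times
any explicit per-family accessibility multiplier.

**Read sampling.** Reads are drawn multinomially over fragments with
weight

    w = length * (background + accessibility * m),    m = occupancy
                                                      (Dam-fusion) or 1

with background = 0.05. The requirement that both fragment ends be
methylated is marginalised into this single per-fragment amplification
weight; consequently the configured multipliers live directly on the scale
the pipeline estimates, and a 0.25× occupancy multiplier is a true Δlog2
of −2 for the estimator. Two caveats follow and are visible in the tests:
the additive background slightly attenuates realised effects
(e.g. −2 is realised as ≈ −1.9 at the default background), and because
CPM normalization is compositional, perturbing a family that carries a
large share of the library shifts all other log ratios by a small constant
— a genuine property of DamID normalization without spike-ins, not a
simulator artifact. Read positions are uniform within the fragment with a
300-bp span (one record stands for a read pair); each genome read
overlapping a TE copy also emits a record in consensus coordinates. Reads
from multi-copy families draw MAPQ 0–3 with probability 0.8 (else 42), so
both MAPQ modes are exercised. Sequencing error and PCR duplicates are not
modelled.

**Determinism.** All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning; identical seeds give byte-identical
FASTA/SAM/TSV outputs. Ground truth (per-TE true effects, per-fragment
sampling probabilities) is written alongside the dataset and never read by
the pipeline.

**What passing tests show — and don't.** The generator reproduces the
*structure* of a DamID study (fragment logic, paired control design,
replicates, repeat multi-mapping, library-composition effects) but not
sequence-level mapping ambiguity, PCR-cycle bias, batch effects between
replicates, or biological variance beyond multinomial sampling. Recovery
results on simulation therefore validate the arithmetic and the inference
chain, not performance on real libraries.

## Problem sizes and numerical choices

Simulation studies use a 400-kb genome, 32 TEs and 50,000 reads per sample
(8–12 samples), a scale at which per-TE standard errors (~0.1 log2) are
several times smaller than the effects studied (|Δ| = 2) — the same
signal-to-noise regime as a full-scale study, at desk-size cost. The
recovery suite runs 20 seeds per study. Tolerances: per-TE delta MAE ≤ 0.3
against truth; Dam-only fold change ±0.2; null calibration of the Z-test
0.05 ± 0.02 over 2000 resamples. Degenerate inputs are defined rather than
exceptional wherever a caller could plausibly hit them (zero-variance
correlation → NaN; all-tied Mann–Whitney → p = 1; TEs with no defined bins
→ missing averages excluded from ranking with a logged count).

## Known limitations

- Consensus-level TE quantification only; per-copy signal is not resolved.
- The compositional shift of CPM normalization (above) biases null deltas
  by a small constant when perturbed families carry a large library share;
  no spike-in or median-centering correction is applied because the
  method under study applies none.
- The two-proportion Z-test is conservative when the selection is a large
  fraction of the TE universe.
- GC bias, quantile/loess normalization and FDR machinery are out of
  scope.
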