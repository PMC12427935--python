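"""Inferential layer: TE-class enrichment Z-test, thresholded set overlap,
Mann–Whitney comparison of region-binned profiles, and RT-qPCR fold-change
testing.

The Mann–Whitney U test is implemented in-package because the variant
needed here — exact two-sided p by enumeration for small samples *including
tied data*, tie- and continuity-corrected normal approximation otherwise —
is not available as one call in the scientific stack.  All other numerics
(ranking, normal and t distributions) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .occupancy import OccupancyProfile


# ---------------------------------------------------------------------------
# TE-class enrichment (two-proportion Z-test)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Class frequency in a selected TE set versus the full TE universe.

    Pooled two-proportion z statistic, two-sided normal p-value; the
    selected set is compared against the whole universe (selection not
    excluded), matching a 'ratio of LTR TEs among all TEs' comparison.
    """

    target_class: str
    n_selected: int
    n_selected_in_class: int
    n_universe: int
    n_universe_in_class: int
    p_selected: float
    p_universe: float
    z: float
    p_value: float


def class_enrichment_ztest(
    selected, universe: pd.DataFrame, target_class: str
) -> EnrichmentResult:
    """Two-proportion Z-test of class frequency in ``selected`` (TE names)
    against the full universe (a table with te_name and family_class)."""
    selected = list(selected)
    if not selected:
        raise ValueError("empty selection")
    names = set(universe["te_name"])
    stray = set(selected) - names
    if stray:
        raise ValueError(f"selected TEs not in universe: {sorted(stray)}")
    in_class = dict(zip(universe["te_name"], universe["family_class"] == target_class))
    n_sel = len(selected)
    x_sel = sum(in_class[t] for t in selected)
    n_uni = len(universe)
    x_uni = int((universe["family_class"] == target_class).sum())
    if x_uni == 0:
        raise ValueError(f"universe has no TEs of class {target_class!r}")
    p_sel = x_sel / n_sel
    p_uni = x_uni / n_uni
    pooled = (x_sel + x_uni) / (n_sel + n_uni)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_sel + 1 / n_uni))
    if se == 0:
        z = 0.0
    else:
        z = (p_sel - p_uni) / se
    p_value = float(2 * sps.norm.sf(abs(z)))
    return EnrichmentResult(
        target_class, n_sel, x_sel, n_uni, x_uni, p_sel, p_uni, float(z),
        min(p_value, 1.0),
    )


# ---------------------------------------------------------------------------
# Thresholded set overlap (Venn-style)
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    set_up: set[str]
    set_down: set[str]
    intersection: set[str]
    jaccard: float
    threshold_up: float
    threshold_down: float


def overlap_sets(
    delta_a: pd.Series,
    delta_b: pd.Series,
    threshold_up: float = 1.0,
    threshold_down: float = -1.0,
) -> OverlapResult:
    """Overlap of {delta_a > threshold_up} with {delta_b < threshold_down}.

    ``delta_a``/``delta_b`` are per-TE delta series indexed by te_name on
    the same TE universe (e.g. the increase under one perturbation and the
    decrease under another).  Jaccard is NaN when both sets are empty.
    """
    if set(delta_a.index) != set(delta_b.index):
        raise ValueError("delta series on different TE universes")
    set_up = set(delta_a.index[delta_a > threshold_up])
    set_down = set(delta_b.index[delta_b < threshold_down])
    inter = set_up & set_down
    union = set_up | set_down
    jaccard = len(inter) / len(union) if union else float("nan")
    return OverlapResult(set_up, set_down, inter, jaccard, threshold_up, threshold_down)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

EXACT_LIMIT = 12  # exact enumeration when n1 + n2 <= this


@dataclass
class MWUResult:
    U: float  # U statistic of the first sample
    n1: int
    n2: int
    p_value: float
    tie_corrected: bool
    method: str  # "exact" | "normal"
    degenerate: bool = False


def mann_whitney_u(x, y, method: str = "auto") -> MWUResult:
    """Two-sided Mann–Whitney U test with midranks for ties.

    Exact p by enumeration of all C(n1+n2, n1) group labelings when
    n1 + n2 <= 12 (valid with ties); otherwise a normal approximation with
    tie correction and continuity correction.  The two-sided p is
    2·min(P(U ≤ u), P(U ≥ u)) capped at 1.  All-identical pooled values are
    degenerate: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if len(tie_counts) == 1:
        return MWUResult(u1, n1, n2, 1.0, has_ties, "degenerate", degenerate=True)
    if method == "exact" or (method == "auto" and n1 + n2 <= EXACT_LIMIT):
        p = _exact_two_sided_p(ranks, n1, u1)
        return MWUResult(u1, n1, n2, p, has_ties, "exact")
    # normal approximation
    n = n1 + n2
    mu = n1 * n2 / 2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MWUResult(u1, n1, n2, 1.0, has_ties, "degenerate", degenerate=True)
    cc = 0.5 * np.sign(u1 - mu)  # continuity correction toward the mean
    z = (u1 - mu - cc) / np.sqrt(sigma2)
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return MWUResult(u1, n1, n2, p, has_ties, "normal")


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Enumerate all assignments of n1 of the pooled ranks to sample 1.

    With midranks the rank sums are multiples of 0.5; comparisons use a
    small tolerance to be safe against float accumulation.
    """
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2
    u_values = np.array(
        [sum(c) - offset for c in combinations(ranks, n1)], dtype=float
    )
    eps = 1e-9
    p_le = float((u_values <= u1 + eps).mean())
    p_ge = float((u_values >= u1 - eps).mean())
    return min(1.0, 2 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# cHet region comparison
# ---------------------------------------------------------------------------

@dataclass
class BoxStats:
    """Box-plot summary: quartiles and whiskers at 1.5 IQR."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "BoxStats":
        values = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        lo = values[values >= q1 - 1.5 * iqr].min()
        hi = values[values <= q3 + 1.5 * iqr].max()
        return cls(len(values), float(med), float(q1), float(q3), float(lo), float(hi))


@dataclass
class ChetComparison:
    bins: pd.DataFrame  # chrom, bin_start, bin_end + one value column per condition
    mwu: MWUResult
    box_a: BoxStats
    box_b: BoxStats
    label_a: str
    label_b: str


def chet_compare(
    profile_a: OccupancyProfile,
    profile_b: OccupancyProfile,
    features: pd.DataFrame,
    chet_regions: pd.DataFrame,
    bin_width: int = 1000,
    label_a: str = "A",
    label_b: str = "B",
) -> ChetComparison:
    """Compare log2(Dam-fusion/Dam) distributions inside constitutive-
    heterochromatin regions between two conditions.

    cHet regions (BED-style chrom/start/end) are tiled into ``bin_width``
    bins; each bin's value per condition is the mean of defined profile
    entries whose feature midpoint falls in the bin.  The two per-bin
    distributions are compared with the Mann–Whitney U test, and box-plot
    summaries are reported.
    """
    if not np.array_equal(profile_a.feature_ids, profile_b.feature_ids):
        raise ValueError("profiles on different feature universes")
    if chet_regions.empty:
        raise ValueError("no cHet regions supplied")
    seq_col = "chrom" if "chrom" in features.columns else "seq_name"
    mids = (
        features["start"].to_numpy(np.int64) + features["end"].to_numpy(np.int64)
    ) // 2
    chroms = features[seq_col].to_numpy()
    rows = []
    vals_a: list[float] = []
    vals_b: list[float] = []
    for region in chet_regions.itertuples(index=False):
        on_chrom = chroms == region.chrom
        for bs in range(int(region.start), int(region.end), bin_width):
            be = min(bs + bin_width, int(region.end))
            in_bin = on_chrom & (mids >= bs) & (mids < be)
            a = profile_a.log2_ratio[in_bin]
            b = profile_b.log2_ratio[in_bin]
            a = a[~np.isnan(a)]
            b = b[~np.isnan(b)]
            if len(a) == 0 or len(b) == 0:
                continue
            va, vb = float(a.mean()), float(b.mean())
            rows.append((region.chrom, bs, be, va, vb))
            vals_a.append(va)
            vals_b.append(vb)
    if not rows:
        raise ValueError("no defined bins inside cHet regions")
    bins = pd.DataFrame(
        rows,
        columns=["chrom", "bin_start", "bin_end", f"value_{label_a}", f"value_{label_b}"],
    )
    mwu = mann_whitney_u(vals_a, vals_b)
    return ChetComparison(
        bins,
        mwu,
        BoxStats.from_values(np.array(vals_a)),
        BoxStats.from_values(np.array(vals_b)),
        label_a,
        label_b,
    )


# ---------------------------------------------------------------------------
# RT-qPCR fold change (ΔΔCt against a reference gene)
# ---------------------------------------------------------------------------

@dataclass
class QpcrResult:
    target: str
    fold_changes: np.ndarray  # per test-condition replicate
    mean_fold_change: float
    t: float
    p_value: float
    n_replicates: int
    tested: bool  # False when <2 replicates or zero variance


def qpcr_foldchange(
    ct_target_test,
    ct_reference_test,
    ct_target_control,
    ct_reference_control,
    target: str = "",
) -> QpcrResult:
    """ΔΔCt fold change of a target transcript, reference-normalized.

    ΔCt = Ct_target − Ct_reference per replicate within each condition;
    fold change per test replicate = 2^−(ΔCt_test − mean ΔCt_control);
    one-sample two-tailed t-test of the log2 fold changes against 0.
    """
    tgt_test = np.asarray(ct_target_test, dtype=float)
    ref_test = np.asarray(ct_reference_test, dtype=float)
    tgt_ctrl = np.asarray(ct_target_control, dtype=float)
    ref_ctrl = np.asarray(ct_reference_control, dtype=float)
    if tgt_test.shape != ref_test.shape or tgt_ctrl.shape != ref_ctrl.shape:
        raise ValueError("mismatched replicate structure")
    dct_test = tgt_test - ref_test
    dct_ctrl = tgt_ctrl - ref_ctrl
    ddct = dct_test - dct_ctrl.mean()
    fc = 2.0 ** (-ddct)
    log2_fc = -ddct
    n = len(fc)
    if n < 2 or np.std(log2_fc, ddof=1) == 0:
        return QpcrResult(
            target, fc, float(fc.mean()), float("nan"), float("nan"), n, False
        )
    t, p = sps.ttest_1samp(log2_fc, 0.0)
    return QpcrResult(target, fc, float(fc.mean()), float(t), float(p), n, True)
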