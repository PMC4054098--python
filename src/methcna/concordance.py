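"""Cross-platform CNA concordance: interval overlap, sensitivity/specificity, binomial CIs.

Two state-called segment sets (e.g. methylation-array calls against SNP-array calls
for the same sample) are compared per alteration state. A truth segment is a true
positive iff it intersects, by at least 1 bp, a same-state test segment, with both
segments carrying at least ``min_markers`` probes; segments below the marker floor
are excluded from every count (they are uncallable on that platform, not wrong).
True negatives are genomic windows with no call of the assessed state on either
side. True-positive counts convert to binomial probabilities with exact
Clopper-Pearson 95% intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import CNAState, DataError, Segment, SegmentSet, chrom_sort_key
from .cna import LogRatioProfile
from .preprocess import BetaMatrix
from .io import ProbeManifest

logger = logging.getLogger(__name__)

GenomicBin = tuple[str, int, int]  # chrom, 1-based inclusive start/end


@dataclass
class OverlapPartition:
    """Matched/unmatched/excluded split of two segment sets for one state."""

    state: CNAState
    matched_a: list[Segment]
    unmatched_a: list[Segment]
    matched_b: list[Segment]
    unmatched_b: list[Segment]
    excluded_a: list[Segment]
    excluded_b: list[Segment]


@dataclass
class ConcordanceResult:
    """Confusion counts and derived rates for one paired comparison at one state."""

    state: CNAState
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    binom_p: float | None
    ci95: tuple[float, float] | None


def _eligible(segs: SegmentSet, state: CNAState, min_markers: int):
    keep, excluded = [], []
    for s in segs:
        if s.state is None:
            raise DataError("segments must be state-called before concordance analysis")
        if s.state != state:
            continue
        (keep if s.n_probes >= min_markers else excluded).append(s)
    return keep, excluded


def _tree_by_chrom(segments: list[Segment]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for s in segments:
        # half-open internally for the tree; 1-bp overlap == interval intersection
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end + 1, s)
    return trees


def overlap_segments(
    a: SegmentSet, b: SegmentSet, state: CNAState, min_markers: int = 3
) -> OverlapPartition:
    """Partition both sets into matched / unmatched / marker-excluded for one state."""
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    a_keep, a_excl = _eligible(a, state, min_markers)
    b_keep, b_excl = _eligible(b, state, min_markers)
    b_trees = _tree_by_chrom(b_keep)
    a_trees = _tree_by_chrom(a_keep)

    def split(keep: list[Segment], trees: dict[str, IntervalTree]):
        matched, unmatched = [], []
        for s in keep:
            tree = trees.get(s.chrom)
            hit = bool(tree and tree.overlap(s.start, s.end + 1))
            (matched if hit else unmatched).append(s)
        return matched, unmatched

    m_a, u_a = split(a_keep, b_trees)
    m_b, u_b = split(b_keep, a_trees)
    return OverlapPartition(
        state=state, matched_a=m_a, unmatched_a=u_a, matched_b=m_b,
        unmatched_b=u_b, excluded_a=a_excl, excluded_b=b_excl,
    )


def make_bins(
    sets: list[SegmentSet], bin_size: int = 1_000_000
) -> list[GenomicBin]:
    """Tile the genome jointly covered by all sets into fixed-size windows."""
    spans: dict[str, tuple[int, int]] = {}
    for segs in sets:
        for chrom, ss in segs.by_chrom().items():
            lo, hi = ss[0].start, ss[-1].end
            if chrom in spans:
                plo, phi = spans[chrom]
                spans[chrom] = (max(lo, plo), min(hi, phi))
            else:
                spans[chrom] = (lo, hi)
    bins: list[GenomicBin] = []
    for chrom in sorted(spans, key=chrom_sort_key):
        lo, hi = spans[chrom]
        start = lo
        while start <= hi:
            bins.append((chrom, start, min(start + bin_size - 1, hi)))
            start += bin_size
    return bins


def sensitivity_specificity(
    truth: SegmentSet,
    test: SegmentSet,
    state: CNAState,
    min_markers: int = 3,
    bins: list[GenomicBin] | None = None,
) -> ConcordanceResult:
    """Confusion table for one state: segment-level TP/FN/FP, window-level TN.

    sensitivity = TP/(TP+FN) over truth segments; specificity = TN/(TN+FP) where TN
    counts windows with no state call on either platform. With no truth segment of
    the state, sensitivity is undefined (None), never 0.
    """
    part = overlap_segments(truth, test, state, min_markers)
    tp, fn, fp = len(part.matched_a), len(part.unmatched_a), len(part.unmatched_b)

    if bins is None:
        bins = make_bins([truth, test])
    truth_trees = _tree_by_chrom([s for s in truth if s.state == state])
    test_trees = _tree_by_chrom([s for s in test if s.state == state])
    tn = 0
    for chrom, lo, hi in bins:
        t1 = truth_trees.get(chrom)
        t2 = test_trees.get(chrom)
        if not (t1 and t1.overlap(lo, hi + 1)) and not (t2 and t2.overlap(lo, hi + 1)):
            tn += 1

    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    if tp + fn > 0:
        p, ci = binom_tp(tp, tp + fn)
    else:
        p, ci = None, None
    return ConcordanceResult(
        state=state, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, binom_p=p, ci95=ci,
    )


def binom_tp(tp: int, n: int) -> tuple[float, tuple[float, float]]:
    """True-positive count as a binomial probability with an exact 95% CI.

    The Clopper-Pearson bounds are the beta quantiles Beta(tp, n-tp+1) at 2.5% and
    Beta(tp+1, n-tp) at 97.5%, with the conventional 0/1 endpoints at tp=0 / tp=n.
    """
    if n < 1:
        raise DataError("binom_tp requires n >= 1")
    if not (0 <= tp <= n):
        raise DataError("need 0 <= tp <= n")
    p = tp / n
    lo = 0.0 if tp == 0 else float(stats.beta.ppf(0.025, tp, n - tp + 1))
    hi = 1.0 if tp == n else float(stats.beta.ppf(0.975, tp + 1, n - tp))
    return p, (lo, hi)


def _bin_values_profile(p: LogRatioProfile, bins: list[GenomicBin]) -> np.ndarray:
    out = np.full(len(bins), np.nan)
    for i, (chrom, lo, hi) in enumerate(bins):
        mask = (p.chrom == chrom) & (p.pos >= lo) & (p.pos <= hi)
        if mask.any():
            out[i] = p.log2r[mask].mean()
    return out


def _bin_values_segments(s: SegmentSet, bins: list[GenomicBin]) -> np.ndarray:
    trees = _tree_by_chrom(list(s))
    out = np.full(len(bins), np.nan)
    for i, (chrom, lo, hi) in enumerate(bins):
        tree = trees.get(chrom)
        if not tree:
            continue
        total_w = 0.0
        acc = 0.0
        for iv in tree.overlap(lo, hi + 1):
            seg: Segment = iv.data
            w = min(seg.end, hi) - max(seg.start, lo) + 1
            acc += w * seg.mean_log2
            total_w += w
        if total_w > 0:
            out[i] = acc / total_w
    return out


def profile_correlation(
    a: LogRatioProfile | SegmentSet,
    b: LogRatioProfile | SegmentSet,
    bins: list[GenomicBin],
) -> tuple[float, float]:
    """Pearson r and r^2 between two platforms' profiles averaged into shared bins."""
    va = _bin_values_profile(a, bins) if isinstance(a, LogRatioProfile) else _bin_values_segments(a, bins)
    vb = _bin_values_profile(b, bins) if isinstance(b, LogRatioProfile) else _bin_values_segments(b, bins)
    ok = ~(np.isnan(va) | np.isnan(vb))
    if ok.sum() < 3:
        raise DataError("need at least 3 shared bins with values on both sides")
    if np.std(va[ok]) == 0 or np.std(vb[ok]) == 0:
        warnings.warn("zero variance on one side; correlation undefined")
        return float("nan"), float("nan")
    r = float(stats.pearsonr(va[ok], vb[ok]).statistic)
    return r, r * r


def associate_beta_with_state(
    beta: BetaMatrix,
    segs: SegmentSet,
    manifest: ProbeManifest,
    by_island: bool = False,
    sample: str | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Summarize methylation beta values by the copy-number state of their segment.

    Probes are assigned to segments by position; per state (optionally split by the
    CpG-island flag) the count, mean, median and quartiles of beta are reported,
    together with a rank-based (Spearman) trend test of beta against the ordered
    state. Returns (summary frame, (rho, p_value)).
    """
    col = beta.samples.index(sample) if sample is not None else 0
    values = beta.beta[:, col]
    trees = _tree_by_chrom([s for s in segs if s.state is not None])
    chroms = manifest.chrom_of()
    pos = manifest.pos_of()
    states = np.full(manifest.n_probes, np.nan)
    for i in range(manifest.n_probes):
        tree = trees.get(chroms[i])
        if not tree:
            continue
        hits = tree.overlap(pos[i], pos[i] + 1)
        if hits:
            states[i] = int(next(iter(hits)).data.state)
    ok = ~np.isnan(states)
    df = pd.DataFrame(
        {
            "state": [CNAState(int(s)).name for s in states[ok]],
            "state_order": states[ok].astype(int),
            "beta": values[ok],
            "cpg_island": manifest.df["cpg_island"].to_numpy()[ok],
        }
    )
    keys = ["state", "state_order"] + (["cpg_island"] if by_island else [])
    summary = (
        df.groupby(keys, sort=True)["beta"]
        .agg(n="size", mean="mean", median="median",
             q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
        .sort_values(["state_order"] + (["cpg_island"] if by_island else []))
        .drop(columns="state_order")
        .reset_index(drop=True)
    )
    if df["state_order"].nunique() > 1:
        res = stats.spearmanr(df["state_order"], df["beta"])
        trend = (float(res.statistic), float(res.pvalue))
    else:
        trend = (float("nan"), float("nan"))
    return summary, trend
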