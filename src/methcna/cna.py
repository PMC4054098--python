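"""Log2-ratio construction, circular binary segmentation and CNA state calling.

A sample's copy-number signal is its GC- and batch-corrected log2 total intensity
minus the per-probe average over normal reference samples, median-centered on the
autosomes. Circular binary segmentation (CBS) recursively finds the arc of the
circularized profile maximizing a pooled two-sample t statistic against its
complement, assesses it by a seeded permutation test, and splits while p <= alpha;
adjacent segments whose mean difference falls below ``undo_sd`` times the profile
noise (median absolute successive difference, scaled to a Gaussian SD) are merged
back ("sdundo"). Segment means are then thresholded into five copy-number states.

The single-copy threshold of 0.33 on the log2 scale is the empirical magnitude of
the X-chromosome difference between male and female reference DNA on these arrays:
a true one-copy change (log2(1/2) = -1) appears compressed to about a third of its
nominal size. Amplification/deletion thresholds are defined incrementally as a
multiple of the single-copy threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cbs_kernels import max_b_with_cuts, permutation_exceedances, t_from_b
from .io import CNAState, DataError, Segment, SegmentSet, chrom_sort_key

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(c) for c in range(1, 23))


@dataclass
class LogRatioProfile:
    """Genome-ordered per-probe log2 ratios for one sample vs the normal reference."""

    sample_id: str
    probes: pd.Index
    chrom: np.ndarray
    pos: np.ndarray
    log2r: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2r).all():
            raise DataError("log2 ratios must be finite")
        if not (len(self.probes) == len(self.chrom) == len(self.pos) == len(self.log2r)):
            raise DataError("profile field lengths differ")

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return sorted(seen, key=chrom_sort_key)

    def autosome_mask(self) -> np.ndarray:
        return np.isin(self.chrom, AUTOSOMES)


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio thresholds for state calling.

    ``single_copy`` is the |log2 ratio| bound for a one-copy change (default 0.33);
    high-level amplification / homozygous deletion sit incrementally further out at
    ``amp_multiplier * single_copy``.
    """

    single_copy: float = 0.33
    amp_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.single_copy <= 0:
            raise ValueError("single_copy must be positive")
        if self.amp_multiplier <= 1:
            raise ValueError("amp_multiplier must exceed 1")


@dataclass(frozen=True)
class CBSParams:
    """Circular binary segmentation settings (permutation test is seeded)."""

    alpha: float = 0.001
    min_width: int = 3
    undo_sd: float = 3.0
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.n_perm < 1 / self.alpha:
            raise ValueError("n_perm must be at least 1/alpha")


def build_reference(normals: np.ndarray, method: str = "mean") -> np.ndarray:
    """Per-probe average of the normal samples' corrected log2 total intensities."""
    normals = np.asarray(normals, dtype=float)
    if normals.ndim == 1:
        normals = normals[:, None]
    if normals.shape[1] == 0:
        raise DataError("at least one normal sample is required for the reference")
    if method == "mean":
        return normals.mean(axis=1)
    if method == "median":
        return np.median(normals, axis=1)
    raise ValueError(f"unknown reference method: {method!r}")


def log2_ratio(
    sample: np.ndarray,
    reference: np.ndarray,
    probes: pd.Index,
    chrom: np.ndarray,
    pos: np.ndarray,
    sample_id: str = "sample",
) -> LogRatioProfile:
    """log2 ratio = corrected log2 intensity minus reference, median-centered.

    Centering uses the autosomal median only, so sex-chromosome dosage does not
    shift the baseline; global intensity shifts are removed entirely.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.shape != reference.shape:
        raise DataError("sample and reference lengths differ")
    log2r = sample - reference
    auto = np.isin(chrom, AUTOSOMES)
    center_mask = auto if auto.any() else np.ones_like(auto)
    log2r = log2r - np.median(log2r[center_mask])
    return LogRatioProfile(
        sample_id=sample_id, probes=probes, chrom=np.asarray(chrom),
        pos=np.asarray(pos), log2r=log2r,
    )


def cbs_statistic(x: np.ndarray, i: int, j: int) -> float:
    """Pooled two-sample t comparing arc ``x[i:j]`` against its complement.

    Signed as mean(arc) - mean(complement); +/-inf when the pooled within-group
    variance vanishes but the means differ, 0 for a constant vector.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not (0 <= i < j <= n) or (j - i) >= n:
        raise ValueError("need 0 <= i < j <= n with a non-empty complement")
    arc = x[i:j]
    comp = np.concatenate([x[:i], x[j:]])
    k, m = arc.size, comp.size
    d = arc.mean() - comp.mean()
    ss_within = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
    if ss_within <= 1e-12 * max(((x - x.mean()) ** 2).sum(), 1.0):
        return 0.0 if d == 0 else math.copysign(math.inf, d)
    sp2 = ss_within / (n - 2)
    return float(d / math.sqrt(sp2 * (1 / k + 1 / m)))


def max_cbs_statistic(x: np.ndarray, min_width: int = 1) -> float:
    """Max |pooled-t| over all circular arcs leaving pieces of >= min_width probes."""
    x = np.asarray(x, dtype=float)
    b, _, _ = max_b_with_cuts(x, min_width)
    if b < 0:
        return 0.0
    ss_tot = float(((x - x.mean()) ** 2).sum())
    return t_from_b(b, ss_tot, x.size)


def estimate_noise(profile: LogRatioProfile | np.ndarray, autosomes_only: bool = True) -> float:
    """Noise level from the median deviance of genome-adjacent probes.

    median |x[k+1] - x[k]| within chromosomes, scaled by 1/(sqrt(2) * 0.6745) so
    that i.i.d. Gaussian noise of SD sigma yields sigma; robust to true
    copy-number steps, which contribute only a handful of large diffs.
    """
    if isinstance(profile, LogRatioProfile):
        mask = profile.autosome_mask() if autosomes_only else np.ones(len(profile.log2r), bool)
        if not mask.any():
            mask = np.ones(len(profile.log2r), bool)
        x = profile.log2r[mask]
        chrom = profile.chrom[mask]
        within = chrom[1:] == chrom[:-1]
        diffs = np.abs(np.diff(x))[within]
    else:
        x = np.asarray(profile, dtype=float)
        diffs = np.abs(np.diff(x))
    if x.size < 2 or diffs.size == 0:
        raise DataError("need at least 2 probes on one chromosome to estimate noise")
    return float(np.median(diffs) / (math.sqrt(2) * 0.6745))


def _segment_chrom(
    x: np.ndarray, params: CBSParams, seeds: "_SeedStream"
) -> list[tuple[int, int]]:
    """Recursive circular splitting of one chromosome; returns [start, end) index pairs."""
    n = x.size
    max_exceed = int(math.floor(params.alpha * params.n_perm))
    out: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(0, n)]
    while stack:
        s, e = stack.pop()
        m = e - s
        if m < 2 * params.min_width:
            out.append((s, e))
            continue
        b_obs, c1, c2 = max_b_with_cuts(x[s:e], params.min_width)
        if b_obs <= 0:
            out.append((s, e))
            continue
        exceed, _ = permutation_exceedances(
            x[s:e], params.min_width, b_obs, params.n_perm, max_exceed, seeds.next()
        )
        if exceed <= max_exceed:
            cuts = [c for c in (c1, c2) if c > 0]
            bounds = [s] + [s + c for c in sorted(cuts)] + [e]
            # deterministic traversal: push right-to-left so left pieces pop first
            for a, b in reversed(list(zip(bounds[:-1], bounds[1:]))):
                stack.append((a, b))
        else:
            out.append((s, e))
    return sorted(out)


class _SeedStream:
    """Deterministic stream of sub-seeds below 2^31 for the permutation kernels."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def next(self) -> int:
        return int(self._rng.integers(0, 2**31 - 1))


def _sdundo(
    bounds: list[tuple[int, int]], x: np.ndarray, undo_sd: float, noise: float
) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means are statistically indistinguishable.

    A split survives only if the two segment means differ by at least ``undo_sd``
    standard errors, SE = noise * sqrt(1/n1 + 1/n2), with ``noise`` the per-probe
    SD from the median successive-difference estimator. Scaling by the SE of the
    mean difference (rather than the raw probe SD) keeps genuine low-amplitude
    events supported by many probes while still undoing chance splits.
    """
    bounds = list(bounds)
    while len(bounds) > 1:
        means = [x[s:e].mean() for s, e in bounds]
        sizes = [e - s for s, e in bounds]
        zs = [
            abs(means[i + 1] - means[i])
            / (noise * math.sqrt(1 / sizes[i] + 1 / sizes[i + 1]))
            for i in range(len(means) - 1)
        ]
        i = int(np.argmin(zs))
        if zs[i] >= undo_sd:
            break
        bounds[i] = (bounds[i][0], bounds[i + 1][1])
        del bounds[i + 1]
    return bounds


def segment(profile: LogRatioProfile, params: CBSParams | None = None) -> SegmentSet:
    """Circular binary segmentation of a log2-ratio profile, per chromosome.

    Splits recursively while the permutation p-value of the max arc statistic is
    <= alpha, then applies sdundo pruning with the profile-level noise estimate.
    The output partitions the retained probes: segment probe counts on a
    chromosome sum to that chromosome's probe count.
    """
    params = params or CBSParams()
    noise = None
    try:
        noise = estimate_noise(profile)
    except DataError:
        pass
    seeds = _SeedStream(params.seed)
    segments: list[Segment] = []
    for chrom in profile.chromosomes():
        mask = profile.chrom == chrom
        x = profile.log2r[mask]
        pos = profile.pos[mask]
        if x.size < params.min_width:
            warnings.warn(
                f"chromosome {chrom} has {x.size} probe(s) < min_width={params.min_width}; "
                "emitting a single segment"
            )
            bounds = [(0, x.size)]
        else:
            bounds = _segment_chrom(x, params, seeds)
            if noise is not None and noise > 0:
                bounds = _sdundo(bounds, x, params.undo_sd, noise)
        for s, e in bounds:
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(pos[s]),
                    end=int(pos[e - 1]),
                    n_probes=e - s,
                    mean_log2=float(x[s:e].mean()),
                )
            )
    return SegmentSet(sample_id=profile.sample_id, segments=segments)


def derive_threshold(
    male_profile: LogRatioProfile,
    female_profile: LogRatioProfile,
    floor: float = 0.1,
    amp_multiplier: float = 2.0,
) -> Thresholds:
    """Single-copy threshold from the male/female X-chromosome log-ratio difference.

    The X chromosome differs by exactly one copy between sexes, so the median
    male-minus-female X log2 ratio measures how far the array compresses a true
    one-copy change. The returned magnitude is floored at ``floor``.
    """
    mx = male_profile.chrom == "X"
    fx = female_profile.chrom == "X"
    if not mx.any() or not fx.any():
        raise DataError("both profiles need X-chromosome probes to derive a threshold")
    shared = male_profile.probes[mx].intersection(female_profile.probes[fx])
    if len(shared) == 0:
        raise DataError("no shared X probes between the two profiles")
    m = pd.Series(male_profile.log2r, index=male_profile.probes)[shared]
    f = pd.Series(female_profile.log2r, index=female_profile.probes)[shared]
    single = abs(float(np.median(m.to_numpy() - f.to_numpy())))
    if single < floor:
        warnings.warn(
            f"derived single-copy magnitude {single:.3f} below floor {floor}; using floor"
        )
        single = floor
    return Thresholds(single_copy=single, amp_multiplier=amp_multiplier)


def thresholds_for_attenuation(attenuation: float, amp_copies: int = 6) -> Thresholds:
    """Midpoint calling thresholds for a linearly attenuated copy-number scale.

    With a linear attenuation ``a``, integer copy numbers land at a*log2(cn/2).
    The neutral/gain boundary is placed midway between 0 and the one-copy-gain
    level, and the incremental amplification/deletion boundary midway between the
    one-copy magnitude and the amplified level — the minimum-error detector for
    equal-noise segments.
    """
    if attenuation <= 0:
        raise ValueError("attenuation must be positive")
    gain = attenuation * math.log2(3 / 2)
    amp = attenuation * math.log2(amp_copies / 2)
    single = gain / 2
    incremental = (attenuation * 1.0 + amp) / 2
    return Thresholds(single_copy=single, amp_multiplier=incremental / single)


def call_states(segs: SegmentSet, th: Thresholds | None = None) -> SegmentSet:
    """Threshold segment means into the five CNA states (ties go to the extreme state)."""
    th = th or Thresholds()
    hi = th.amp_multiplier * th.single_copy
    states: list[CNAState] = []
    for seg in segs:
        m = seg.mean_log2
        if m <= -hi:
            states.append(CNAState.DELETION)
        elif m <= -th.single_copy:
            states.append(CNAState.LOSS)
        elif m >= hi:
            states.append(CNAState.AMPLIFICATION)
        elif m >= th.single_copy:
            states.append(CNAState.GAIN)
        else:
            states.append(CNAState.NEUTRAL)
    return segs.with_states(states)


def probe_type_correlation(
    profile: LogRatioProfile, probe_type: np.ndarray, bin_probes: int = 50
) -> tuple[float, float]:
    """Diagnostic: Pearson r and r^2 between type-I-only and type-II-only profiles.

    Both chemistries are averaged into shared genomic bins of ~``bin_probes``
    probes; high agreement justifies segmenting both designs jointly.
    """
    from scipy.stats import pearsonr

    order = np.arange(len(profile.log2r))
    bins = order // bin_probes
    t1 = pd.Series(profile.log2r[probe_type == "I"], index=bins[probe_type == "I"])
    t2 = pd.Series(profile.log2r[probe_type == "II"], index=bins[probe_type == "II"])
    m1 = t1.groupby(level=0).mean()
    m2 = t2.groupby(level=0).mean()
    shared = m1.index.intersection(m2.index)
    if len(shared) < 3:
        raise DataError("need at least 3 shared bins")
    r = float(pearsonr(m1[shared], m2[shared]).statistic)
    return r, r * r
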