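# Methods

## Copy number from two-channel methylation arrays

Each CpG probe on an Infinium-style methylation array reports two fluorescence
intensities, one for the methylated (M) and one for the unmethylated (U) allele.
Their ratio estimates methylation,

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100),

with the conventional offset of 100 fluorescence units regularizing low-intensity
probes (so beta is in [0, 1)). Their **sum** M + U measures how much template DNA
hybridized and therefore tracks local copy number. The package turns per-sample
M/U matrices into five-state copy-number calls (homozygous DELETION, one-copy
LOSS, NEUTRAL, one-copy GAIN, high-level AMPLIFICATION) and quantifies agreement
with calls from a second platform.

## Pipeline stages

1. **Detection p-values.** Per sample, the total intensities of the negative-control
   probes estimate a normal background (mean, SD); a probe's detection p-value is
   the upper-tail probability of its total intensity under that background. Probes
   failing detection (default p > 0.01) in more than half of the *normal reference*
   samples are dropped as unreliable. The check deliberately ignores tumor samples:
   genuinely deleted tumor regions fail detection for a biological reason and must
   stay in the analysis.
2. **GC wave.** Log2 total intensities show a spatial "wave" correlated with local
   GC content. Cyclic loess (default span 0.3, 2 cycles) of log-intensity on the
   manifest's per-probe GC fraction removes it; the sample's mean log-intensity is
   restored afterwards so the correction is mean-preserving. The GC fraction is a
   manifest input, not computed from genome sequence.
3. **Batch adjustment (optional).** Parametric empirical-Bayes location/scale
   adjustment (the ComBat model): per-probe standardization against the pooled
   batch-mean fit, moment-based normal / inverse-gamma hyperpriors, iterated
   conditional posterior means for the per-batch location and scale, then
   back-transformation. A non-parametric mode (Monte-Carlo integration over the
   empirical prior) is available behind a flag. Applied to log2 total intensities
   before ratio construction; opt-in because single-batch studies must not be
   forced through it.
4. **Log2 ratios.** The reference is the per-probe mean (optionally median) of the
   normal samples' corrected log2 intensities; a sample's profile is its corrected
   log2 intensity minus the reference, median-centered on autosomes only (so sex
   chromosome dosage cannot shift the baseline). Y probes are dropped for female
   samples.
5. **Probe exclusion.** Probes in the polymorphic MHC window (default
   chr6:28,477,797–33,448,354, configurable to any exclusion BED) and probes in
   the top 0.1% of across-sample log-ratio variance are removed. Ties at the
   variance cutoff are kept.
6. **Segmentation.** Circular binary segmentation, described below.
7. **State calling.** Segment means are thresholded: |mean| ≥ single_copy calls a
   one-copy change, |mean| ≥ amp_multiplier × single_copy an amplification or
   homozygous deletion. Boundary ties resolve to the more extreme state for
   determinism. The default single_copy = 0.33 is the empirical magnitude of the
   X-chromosome log2-ratio difference between male and female reference DNA: a
   true one-copy change (nominally log2(1/2) = −1) appears compressed to roughly
   a third of its size on these arrays. `derive_threshold` re-measures this
   compression from any male/female profile pair (|median X difference|, floored
   at 0.1).

## Circular binary segmentation

Per chromosome, the profile is treated as circular and every arc is compared with
its complement by the pooled two-sample t statistic. Writing B for the
between-group sum of squares of a split and SS_tot for the chromosome's total sum
of squares, t² = (n−2)·B/(SS_tot − B), and B needs only partial sums, so the
search is a partial-sum scan; by arc/complement symmetry only arc lengths
k ≤ n/2 are needed. Candidate arcs are restricted so every resulting piece keeps
at least `min_width` probes (default 3).

Significance of the maximal arc is assessed by permutation: the profile values
are shuffled `n_perm` times (default 10,000, seeded) and p is the fraction of
permuted maxima at or above the observed one. Because SS_tot is
permutation-invariant and t² is monotone in B, permuted maxima are compared on
the B scale directly. The permutation loop stops early as soon as the exceedance
count passes floor(alpha × n_perm) — at that point p > alpha is certain, so the
early stop is exact, not an approximation. If p ≤ alpha (default 0.001) the
chromosome splits at the arc's one or two changepoints and the procedure recurses
on each piece.

**Noise estimate.** The profile noise SD is the median absolute difference of
genome-adjacent probes within autosomes, scaled by 1/(√2 · 0.6745) so that
i.i.d. Gaussian noise of SD σ yields σ. The median makes it insensitive to true
copy-number steps, which contribute only a handful of large differences.

**Undo step.** After recursion, adjacent segments are merged while the smallest
standardized mean gap |Δmean| / (noise · √(1/n₁ + 1/n₂)) falls below `undo_sd`
(default 3). The gap is scaled by the standard error of the mean difference, not
by the per-probe SD: a low-amplitude event supported by many probes (the typical
attenuated CNA, |shift| ≤ 0.5) is statistically unambiguous even though its
amplitude is below the probe-level noise, and a probe-SD rule would erase it.

**Numerics.** Degenerate splits with zero pooled within-group variance give
t = ±∞ (0 for a constant vector); comparisons on the B scale avoid the infinity
in the permutation loop. The scan kernels are JIT-compiled (numba, fastmath);
exactness of the fast search is gated on an exhaustive O(n²) brute-force oracle
in the test suite.

## Concordance evaluation

Two state-called segment sets are compared per state. A truth segment is a true
positive iff it intersects ≥ 1 bp of a same-state test segment and both carry at
least `min_markers` probes (default 3); sub-threshold segments are excluded from
all counts — they are uncallable on that platform, not wrong. Sensitivity is
TP/(TP+FN) over truth segments; specificity is TN/(TN+FP) with true negatives
counted as genomic windows (default 1-Mb tiles of the jointly covered genome)
carrying no call of the assessed state on either side. True-positive counts
convert to binomial probabilities with exact Clopper–Pearson 95% intervals
(beta-quantile form). A reciprocal-overlap requirement and the large/focal split
(>10 Mb / <1 Mb) are available as options. `associate_beta_with_state` summarizes
methylation beta by the copy-number state of the enclosing segment, optionally
split by CpG-island membership, with a Spearman trend test across the state order.

## Synthetic data generator

The generator emulates the full data path with known truth. Per probe,

    log2(M+U) = log2(base) + a·log2(cn/2) + g·(gc − 0.5)
                + batch_offset + s·1[type II] + N(0, noise_sd),

with copy number cn piecewise constant over truth segments (lengths: minimum 20
probes plus a geometric excess, mean ≈ 120; i.i.d. states with adjacent
same-state runs merged so every truth boundary is real). Defaults: base 5000,
attenuation a = 0.33 (the empirically observed compression of a one-copy change),
noise SD 0.25 on the log2 scale, GC amplitude 1.0, type-II shift 0.5, 20,000
probes on 20 autosomes at ~10 kb spacing, state mix 70% neutral / 12% loss /
12% gain / 3% deletion / 3% amplification, amplification at 6 copies. Zero-copy
probes have no amplifiable template and draw from the same log-normal background
as the negative controls, so they fail detection exactly like real homozygous
deletions. The M/U split applies beta-distributed jitter around the true
methylation fraction (islands drawn mostly unmethylated, non-islands mostly
methylated), keeping both channels nonnegative. A sparser "second platform"
rendering thins probes to a marker grid, perturbs segment means on the
unattenuated scale and re-thresholds — small events can surface with one or two
markers only, reproducing the sparse-platform false-negative scenario. A
male/female reference cohort (males one X copy) supports threshold derivation.

**What the generator does not model:** nonlinear attenuation (real compression
saturates; the linear factor suffices to exercise threshold derivation), tumor
purity and subclonality, probe-specific affinity differences beyond the type-II
shift, and spatially autocorrelated GC. Passing tests therefore demonstrate the
machinery's correctness under a clean generative model, not performance on real
arrays.

## Calling thresholds on an attenuated scale

With linear attenuation a, integer copy numbers land at a·log2(cn/2): −a for one
copy, +0.585a for three, +1.585a for six. The published single-copy threshold
(±0.33 with a 2× incremental multiplier) describes real-array behavior and is the
package default. For recovery of *simulated* truth, `thresholds_for_attenuation`
places the neutral/gain boundary midway between 0 and the one-copy-gain level
(sc = a·log2(3/2)/2) and the incremental boundary midway between the one-copy
magnitude and the amplified level — the minimum-error detector for equal-noise
segments on this scale. The symmetric threshold interface cannot be optimal on
both sides simultaneously (the deletion level sits far below −a), so small
segments near a boundary carry an irreducible misclassification probability of a
few percent.

## Resolution limits and expected recovery

With noise SD 0.25 and a 4-sample reference (effective SD 0.28), the max-arc t of
a k-probe event with shift Δ is ≈ (Δ/σ)·√k, against a permutation-null maximum
around 4.5–5 at alpha = 0.001. One-copy losses (Δ = 0.33) reach that bar from
k ≈ 20; one-copy gains (Δ = 0.19) only from k ≈ 50. Events below these sizes are
undetectable *by construction* for any test controlling the false-split rate at
alpha — the synthetic analogue of the reduced focal-alteration concordance seen
on real platform comparisons. End-to-end recovery on the default preset is
therefore essentially perfect for deletions, amplifications and losses of ≥ 30
probes, while 20–40-probe gains (and occasional unlucky small losses whose sample
mean lands 2 SE inside a threshold) are missed; aggregate sensitivities hover
near 0.9 for the affected states, varying with the seed.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the default
20,000-probe preset (one tumor vs four normals), the CBS error-rate checks at 100
(suite) / 50 (script) replicates of 200-probe chromosomes, the artifact-removal
checks at 1,500–5,000 probes, and threshold/sex-call checks at 3,000 probes per
cohort — sizes at which every reported rate is stable to a few percent.
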