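"""Intensity preprocessing: beta values, detection p-values, GC-wave and batch correction.

The methylation fraction at a CpG is estimated as

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100)

with the conventional offset of 100 fluorescence units stabilizing low-intensity
probes. Copy number rides on the total intensity M + U, which carries two array
artifacts this module removes before ratio construction: a genomic "wave" correlated
with local GC content (removed by cyclic loess on the log2 total intensity) and
between-chip batch effects (removed by parametric empirical-Bayes location/scale
adjustment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import DataError, IntensityMatrix, ProbeManifest

logger = logging.getLogger(__name__)

BETA_OFFSET = 100.0

#: default MHC exclusion window on chr6p (hg19-scale coordinates; configurable)
MHC_REGION: tuple[str, int, int] = ("6", 28_477_797, 33_448_354)


@dataclass
class BetaMatrix:
    """Methylation beta values in [0, 1), probes x samples."""

    probes: pd.Index
    samples: list[str]
    beta: np.ndarray


@dataclass
class DetectionPValues:
    """Per-probe, per-sample probability that the signal arises from background."""

    probes: pd.Index
    samples: list[str]
    p: np.ndarray


@dataclass
class ProbeFilter:
    """Boolean keep-mask over probes with a drop reason for every excluded probe."""

    keep: np.ndarray
    reasons: dict[str, str]  # probe_id -> mhc | high_variance | detection | user

    def __post_init__(self) -> None:
        n_dropped = int((~self.keep).sum())
        if n_dropped != len(self.reasons):
            raise DataError("every dropped probe needs exactly one reason")


def compute_beta(x: IntensityMatrix) -> BetaMatrix:
    """Elementwise beta = max(M,0)/(max(M,0)+max(U,0)+100); total on nonnegative reals."""
    M = np.maximum(x.M, 0.0)
    U = np.maximum(x.U, 0.0)
    beta = M / (M + U + BETA_OFFSET)
    return BetaMatrix(probes=x.probes, samples=list(x.samples), beta=beta)


def detection_pvalues(
    x: IntensityMatrix, negctl_M: np.ndarray, negctl_U: np.ndarray
) -> DetectionPValues:
    """Detection p-values from a per-sample normal background model.

    For each sample the background mean and SD are estimated from the total (M+U)
    intensity of the negative-control probes; a probe's p-value is the upper-tail
    probability of its total intensity under that Normal. Probes indistinguishable
    from background (large p) sit in regions with no amplifiable template, e.g.
    homozygous deletions.
    """
    negctl_M = np.asarray(negctl_M, dtype=float)
    negctl_U = np.asarray(negctl_U, dtype=float)
    if negctl_M.shape[0] < 2:
        raise DataError("need at least 2 negative-control probes to estimate background")
    if negctl_M.shape[1] != len(x.samples):
        raise DataError("negative-control samples do not match the signal matrix")
    bg = negctl_M + negctl_U
    mu = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    sd = np.where(sd <= 0, 1e-12, sd)
    p = stats.norm.sf(x.total, loc=mu, scale=sd)
    return DetectionPValues(probes=x.probes, samples=list(x.samples), p=p)


def gc_correct(
    log_intensity: np.ndarray,
    manifest: ProbeManifest,
    span: float = 0.3,
    cycles: int = 2,
) -> np.ndarray:
    """Remove the GC genomic wave from log2 total intensities by cyclic loess.

    Per sample and per cycle, a loess curve of log-intensity on the probe's local GC
    fraction is fitted and subtracted; after the final cycle the sample's original
    mean log-intensity is restored, so the correction is mean-preserving.
    """
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    log_intensity = np.asarray(log_intensity, dtype=float)
    one_d = log_intensity.ndim == 1
    y = log_intensity[:, None].copy() if one_d else log_intensity.copy()
    gc = manifest.df["gc_fraction"].to_numpy(dtype=float)
    if y.shape[0] != gc.shape[0]:
        raise DataError("log_intensity rows do not match the manifest")
    if np.ptp(gc) == 0:
        warnings.warn("all gc_fraction values identical; GC correction is a no-op")
        return log_intensity

    delta = 0.005 * np.ptp(gc)  # interpolation shortcut; gc has heavy ties
    orig_mean = y.mean(axis=0)
    for j in range(y.shape[1]):
        for _ in range(cycles):
            fit = lowess(
                y[:, j], gc, frac=span, it=1, delta=delta, return_sorted=False
            )
            y[:, j] -= fit
        y[:, j] += orig_mean[j] - y[:, j].mean()
    return y[:, 0] if one_d else y


def combat_adjust(
    m: np.ndarray, batch: list[str] | np.ndarray, parametric: bool = True
) -> np.ndarray:
    """Empirical-Bayes location/scale batch adjustment (ComBat).

    Each probe is standardized against the pooled batch-mean model; per-batch
    location (gamma) and scale (delta^2) estimates are shrunk toward batch-level
    hyperpriors — normal / inverse-gamma moment estimates in parametric mode,
    Monte-Carlo posterior means from the empirical prior otherwise — then the data
    are back-transformed. Constant (zero-variance) probes pass through unchanged.
    """
    m = np.asarray(m, dtype=float)
    batch = np.asarray(batch)
    levels = pd.unique(batch)
    if len(levels) < 2:
        raise DataError("combat_adjust needs at least 2 batches")
    groups = [np.flatnonzero(batch == b) for b in levels]
    for b, idx in zip(levels, groups):
        if len(idx) < 2:
            raise DataError(f"batch {b!r} has a single sample")
    n_array = m.shape[1]
    n_batches = np.array([len(g) for g in groups])

    batch_means = np.column_stack([m[:, g].mean(axis=1) for g in groups])
    grand_mean = batch_means @ (n_batches / n_array)
    resid = m.copy()
    for j, g in enumerate(groups):
        resid[:, g] -= batch_means[:, [j]]
    var_pooled = (resid**2).sum(axis=1) / n_array

    keep = var_pooled > 0
    if not keep.any():
        return m.copy()
    sd = np.sqrt(var_pooled[keep])
    s_data = (m[keep] - grand_mean[keep, None]) / sd[:, None]

    adjusted = m.copy()
    bayes = s_data.copy()
    for j, g in enumerate(groups):
        sub = s_data[:, g]
        n_b = len(g)
        gamma_hat = sub.mean(axis=1)
        delta_hat = sub.var(axis=1, ddof=1)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        if parametric:
            g_star, d_star = _it_solve(sub, gamma_hat, delta_hat, gamma_bar, tau2)
        else:
            g_star, d_star = _int_eprior(sub, gamma_hat, delta_hat)
        bayes[:, g] = (sub - g_star[:, None]) / np.sqrt(d_star)[:, None]
    adjusted[keep] = bayes * sd[:, None] + grand_mean[keep, None]
    return adjusted


def _moments_inverse_gamma(delta_hat: np.ndarray) -> tuple[float, float]:
    mean, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    a = (2 * s2 + mean**2) / s2
    b = (mean * s2 + mean**3) / s2
    return a, b


def _it_solve(
    sub: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated conditional posterior means for the parametric EB model."""
    a_prior, b_prior = _moments_inverse_gamma(delta_hat)
    n = sub.shape[1]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        ss = ((sub - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ss + b_prior) / (n / 2 + a_prior - 1)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _int_eprior(
    sub: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Non-parametric posterior means: integrate over the empirical prior."""
    n = sub.shape[1]
    g_star = np.empty_like(gamma_hat)
    d_star = np.empty_like(delta_hat)
    for i in range(sub.shape[0]):
        g = np.delete(gamma_hat, i)
        d = np.delete(delta_hat, i)
        x = sub[i]
        sum2 = ((x[None, :] - g[:, None]) ** 2).sum(axis=1)
        lik = (2 * np.pi * d) ** (-n / 2) * np.exp(-sum2 / (2 * d))
        lik = lik / max(lik.sum(), 1e-300)
        g_star[i] = (g * lik).sum()
        d_star[i] = (d * lik).sum()
    return g_star, d_star


def filter_probes(
    manifest: ProbeManifest,
    profiles: np.ndarray,
    mhc_region: tuple[str, int, int] = MHC_REGION,
    variance_quantile: float = 0.999,
) -> ProbeFilter:
    """Drop probes in the polymorphic MHC window and hyper-variable probes.

    ``profiles`` is the probes x samples log-ratio matrix; probes whose
    across-sample variance strictly exceeds the ``variance_quantile`` quantile are
    dropped (ties at the threshold are kept).
    """
    if not (0 <= variance_quantile < 1):
        raise ValueError("variance_quantile must lie in [0, 1)")
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim == 1:
        profiles = profiles[:, None]
    if profiles.shape[0] != manifest.n_probes:
        raise DataError("profiles rows do not match the manifest")
    keep = np.ones(manifest.n_probes, dtype=bool)
    reasons: dict[str, str] = {}

    chrom, start, end = mhc_region
    in_mhc = (
        (manifest.chrom_of() == chrom)
        & (manifest.pos_of() >= start)
        & (manifest.pos_of() <= end)
    )
    for pid in manifest.probe_ids[in_mhc]:
        reasons[pid] = "mhc"
    keep &= ~in_mhc

    if profiles.shape[1] >= 2:
        var = profiles.var(axis=1, ddof=1)
        cutoff = np.quantile(var, variance_quantile)
        noisy = var > cutoff
        for pid in manifest.probe_ids[noisy & keep]:
            reasons[pid] = "high_variance"
        keep &= ~noisy
    return ProbeFilter(keep=keep, reasons=reasons)


def detection_filter(
    pvals: DetectionPValues,
    samples: list[str] | None = None,
    cutoff: float = 0.01,
    max_failed_fraction: float = 0.5,
) -> np.ndarray:
    """Keep-mask for probes that pass detection (p <= cutoff) in most reference samples.

    Restricting the check to normal reference samples keeps genuinely deleted tumor
    regions (which legitimately fail detection) in the analysis.
    """
    cols = (
        [pvals.samples.index(s) for s in samples] if samples is not None
        else list(range(len(pvals.samples)))
    )
    failed = (pvals.p[:, cols] > cutoff).mean(axis=1)
    return failed <= max_failed_fraction
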