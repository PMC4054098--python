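"""Synthetic two-channel methylation-array data with known copy-number truth.

The generative model for a probe's log2 total intensity is

    log2(M+U) = log2(base) + a * log2(cn/2) + g * (gc - 0.5)
                + batch_offset + type_shift * 1[type II] + Normal(0, noise_sd)

where ``a`` is a linear attenuation mapping the true log2 copy-number ratio to the
observed one (real arrays compress a one-copy change to roughly a third of its
nominal size; the linear factor is a deliberate simplification), ``g`` scales the
GC genomic wave, and type-II probes carry a systematic intensity shift. Probes with
zero copies carry no amplifiable template and draw from the same log-normal
background as the negative-control probes, so they fail signal detection. The
methylated/unmethylated split follows the probe's true methylation fraction with
beta-distributed jitter, keeping both channels nonnegative by construction.

CpG-island probes are drawn mostly unmethylated and non-island probes mostly
methylated (a bimodal mixture), with island probes slightly GC-richer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CNAState, DataError, IntensityMatrix, ProbeManifest, Segment, SegmentSet
from .cna import thresholds_for_attenuation

_CN_OF_STATE = {
    CNAState.DELETION: 0,
    CNAState.LOSS: 1,
    CNAState.NEUTRAL: 2,
    CNAState.GAIN: 3,
}

#: nominal log2 ratio reported for zero-copy truth segments (template-free probes
#: land near background, several log2 units below neutral)
DELETION_LOG2 = -3.0


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulator; the defaults are the tested conditions."""

    seed: int
    n_probes: int = 20_000
    n_chrom: int = 20
    intensity_base: float = 5000.0
    attenuation: float = 0.33
    noise_sd: float = 0.25
    gc_amplitude: float = 1.0
    batch_offsets: tuple[float, ...] | None = None
    island_fraction: float = 0.3
    probe_type_shift: float = 0.5
    seg_min_probes: int = 20
    seg_mean_probes: int = 120
    state_freqs: tuple[tuple[CNAState, float], ...] = (
        (CNAState.NEUTRAL, 0.70),
        (CNAState.LOSS, 0.12),
        (CNAState.GAIN, 0.12),
        (CNAState.DELETION, 0.03),
        (CNAState.AMPLIFICATION, 0.03),
    )
    amp_copies: int = 6
    background_log2_mean: float = 8.2
    background_log2_sd: float = 0.6
    n_controls: int = 600
    gap_mean_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.n_probes < 10 * self.seg_min_probes:
            raise DataError("n_probes must be at least 10x the minimum segment length")
        freqs = dict(self.state_freqs)
        if abs(sum(freqs.values()) - 1) > 1e-9 or any(f < 0 for f in freqs.values()):
            raise ValueError("state frequencies must be nonnegative and sum to 1")


@dataclass
class SimulationTruth:
    """Known per-probe copy number, methylation, and the truth segment set."""

    manifest: ProbeManifest
    cn: np.ndarray
    methylation: np.ndarray
    segments: SegmentSet
    params: SimParams


def _state_to_cn(state: CNAState, amp_copies: int) -> int:
    return _CN_OF_STATE.get(state, amp_copies)


def _truth_log2(cn: int, attenuation: float) -> float:
    return DELETION_LOG2 if cn == 0 else attenuation * math.log2(cn / 2)


def simulate_truth(params: SimParams) -> SimulationTruth:
    """Draw piecewise-constant copy-number truth plus manifest annotation.

    Segment lengths are ``seg_min_probes`` plus a geometric excess; states are
    drawn i.i.d. from ``state_freqs`` and adjacent same-state runs are merged, so
    every truth boundary is a real copy-number change.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    states_pool = [s for s, _ in params.state_freqs]
    probs = np.array([f for _, f in params.state_freqs])

    per_chrom = np.full(params.n_chrom, params.n_probes // params.n_chrom)
    per_chrom[: params.n_probes % params.n_chrom] += 1

    chroms: list[str] = []
    pos: list[int] = []
    cn = np.empty(params.n_probes, dtype=np.int64)
    seg_records: list[Segment] = []
    offset = 0
    excess_mean = max(params.seg_mean_probes - params.seg_min_probes, 1)
    for ci in range(params.n_chrom):
        n_c = int(per_chrom[ci])
        chrom = str(ci + 1)
        gaps = rng.integers(params.gap_mean_bp // 5, params.gap_mean_bp * 9 // 5, size=n_c)
        p = np.cumsum(gaps) + 1000
        chroms.extend([chrom] * n_c)
        pos.extend(p.tolist())

        # segment lengths then i.i.d. states; same-state neighbors merge below
        lengths: list[int] = []
        while sum(lengths) < n_c:
            lengths.append(
                params.seg_min_probes + int(rng.geometric(1.0 / excess_mean)) - 1
            )
        remainder = n_c - sum(lengths[:-1])
        lengths = lengths[:-1]
        if not lengths or remainder >= params.seg_min_probes:
            lengths.append(remainder)
        else:
            lengths[-1] += remainder
        seg_states = [states_pool[i] for i in rng.choice(len(states_pool), size=len(lengths), p=probs)]

        merged: list[tuple[int, CNAState]] = []
        for ln, st in zip(lengths, seg_states):
            if merged and merged[-1][1] == st:
                merged[-1] = (merged[-1][0] + ln, st)
            else:
                merged.append((ln, st))

        start_idx = 0
        for ln, st in merged:
            c = _state_to_cn(st, params.amp_copies)
            cn[offset + start_idx : offset + start_idx + ln] = c
            seg_records.append(
                Segment(
                    chrom=chrom,
                    start=int(p[start_idx]),
                    end=int(p[start_idx + ln - 1]),
                    n_probes=ln,
                    mean_log2=_truth_log2(c, params.attenuation),
                    state=st,
                )
            )
            start_idx += ln
        offset += n_c

    island = rng.random(params.n_probes) < params.island_fraction
    gc = np.where(
        island,
        rng.normal(0.55, 0.10, params.n_probes),
        rng.normal(0.40, 0.10, params.n_probes),
    ).clip(0.2, 0.8)
    probe_type = np.where(rng.random(params.n_probes) < 0.7, "II", "I")
    methylation = np.where(
        island,
        rng.beta(2.0, 10.0, params.n_probes),
        rng.beta(10.0, 2.5, params.n_probes),
    )
    mdf = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(pos, dtype=np.int64),
            "probe_type": probe_type,
            "gc_fraction": gc,
            "cpg_island": island,
        },
        index=pd.Index([f"cg{i:07d}" for i in range(params.n_probes)], name="probe_id"),
    )
    manifest = ProbeManifest(mdf)
    return SimulationTruth(
        manifest=manifest,
        cn=cn,
        methylation=methylation,
        segments=SegmentSet(sample_id="truth", segments=seg_records),
        params=params,
    )


def _log2_totals(
    rng: np.random.Generator,
    params: SimParams,
    cn: np.ndarray,
    gc: np.ndarray,
    type2: np.ndarray,
    batch_offset: float,
) -> np.ndarray:
    base = math.log2(params.intensity_base)
    ratio = np.where(cn > 0, params.attenuation * np.log2(np.maximum(cn, 1) / 2.0), 0.0)
    y = (
        base
        + ratio
        + params.gc_amplitude * (gc - 0.5)
        + batch_offset
        + params.probe_type_shift * type2
        + rng.normal(0.0, params.noise_sd, size=cn.size)
    )
    bg = rng.normal(params.background_log2_mean, params.background_log2_sd, size=cn.size)
    return np.where(cn == 0, bg, y)


def _split_channels(
    rng: np.random.Generator, total: np.ndarray, beta_true: np.ndarray, kappa: float = 200.0
) -> tuple[np.ndarray, np.ndarray]:
    b = np.clip(beta_true, 0.01, 0.99)
    beta_obs = rng.beta(kappa * b, kappa * (1 - b))
    M = total * beta_obs
    return M, np.maximum(total - M, 0.0)


def simulate_intensities(
    truth: SimulationTruth, n_normals: int = 4, n_tumors: int = 1
) -> tuple[IntensityMatrix, np.ndarray, np.ndarray]:
    """Emit M/U matrices for normal (CN=2) and aberrant samples plus negative controls.

    Samples are named ``normal_1..k`` then ``tumor_1..m``; tumors carry the truth
    copy-number vector. Returns ``(intensities, negctl_M, negctl_U)``.
    """
    params = truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n_probes = truth.manifest.n_probes
    gc = truth.manifest.df["gc_fraction"].to_numpy()
    type2 = (truth.manifest.df["probe_type"] == "II").to_numpy().astype(float)

    names = [f"normal_{i+1}" for i in range(n_normals)] + [
        f"tumor_{i+1}" for i in range(n_tumors)
    ]
    offsets = params.batch_offsets or (0.0,)
    batch = [f"batch_{(i % len(offsets)) + 1}" for i in range(len(names))]

    M = np.empty((n_probes, len(names)))
    U = np.empty_like(M)
    neutral = np.full(n_probes, 2, dtype=np.int64)
    for j, name in enumerate(names):
        cn = truth.cn if name.startswith("tumor") else neutral
        total = 2.0 ** _log2_totals(rng, params, cn, gc, type2, offsets[j % len(offsets)])
        M[:, j], U[:, j] = _split_channels(rng, total, truth.methylation)

    bg = 2.0 ** rng.normal(
        params.background_log2_mean, params.background_log2_sd,
        size=(params.n_controls, len(names)),
    )
    frac = rng.beta(2.0, 2.0, size=bg.shape)
    negctl_M, negctl_U = bg * frac, bg * (1 - frac)
    x = IntensityMatrix(
        probes=truth.manifest.probe_ids, samples=names, M=M, U=U,
        batch=batch if params.batch_offsets else None,
    )
    return x, negctl_M, negctl_U


def simulate_second_platform(
    truth: SimulationTruth,
    marker_density: float = 0.15,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SegmentSet:
    """Render the truth as a sparser second platform (SNP-array stand-in).

    Each truth probe position becomes a marker with probability ``marker_density``;
    segment means are the unattenuated log2 copy ratios perturbed by noise and
    re-thresholded. Segments keep their truth coordinates but carry the reduced
    marker counts, so low-coverage events surface with 1-2 markers only (the
    false-negative scenario for sparse platforms).
    """
    if marker_density <= 0:
        raise ValueError("marker_density must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    pos = truth.manifest.pos_of()
    chroms = truth.manifest.chrom_of()
    is_marker = (
        rng.random(truth.manifest.n_probes) < marker_density
        if marker_density < 1
        else np.ones(truth.manifest.n_probes, dtype=bool)
    )
    th = thresholds_for_attenuation(1.0, truth.params.amp_copies)
    hi = th.amp_multiplier * th.single_copy
    out: list[Segment] = []
    for seg in truth.segments:
        in_seg = (chroms == seg.chrom) & (pos >= seg.start) & (pos <= seg.end) & is_marker
        n_mark = int(in_seg.sum())
        if n_mark == 0:
            continue
        cn = _state_to_cn(seg.state, truth.params.amp_copies)
        level = DELETION_LOG2 if cn == 0 else math.log2(cn / 2)
        mean = level + (rng.normal(0.0, noise_sd / math.sqrt(n_mark)) if noise_sd > 0 else 0.0)
        if mean <= -hi:
            st = CNAState.DELETION
        elif mean <= -th.single_copy:
            st = CNAState.LOSS
        elif mean >= hi:
            st = CNAState.AMPLIFICATION
        elif mean >= th.single_copy:
            st = CNAState.GAIN
        else:
            st = CNAState.NEUTRAL
        out.append(
            Segment(
                chrom=seg.chrom, start=seg.start, end=seg.end,
                n_probes=n_mark, mean_log2=float(mean), state=st,
            )
        )
    return SegmentSet(sample_id="platform2", segments=out)


def simulate_sex_cohort(
    params: SimParams, n_female: int = 2, n_male: int = 2, x_fraction: float = 0.2
) -> tuple[ProbeManifest, IntensityMatrix, np.ndarray, np.ndarray]:
    """Normal reference cohort with an X chromosome: females CN=2, males CN=1 on X.

    All autosomes are copy-neutral; this is the calibration construction behind the
    single-copy threshold. Returns (manifest, intensities, negctl_M, negctl_U).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    n_x = int(params.n_probes * x_fraction)
    n_auto = params.n_probes - n_x
    auto_truth = simulate_truth(
        replace(
            params,
            n_probes=n_auto,
            state_freqs=((CNAState.NEUTRAL, 1.0),),
        )
    )
    mdf = auto_truth.manifest.df.copy()
    gaps = rng.integers(params.gap_mean_bp // 5, params.gap_mean_bp * 9 // 5, size=n_x)
    island = rng.random(n_x) < params.island_fraction
    xdf = pd.DataFrame(
        {
            "chrom": ["X"] * n_x,
            "pos": np.cumsum(gaps) + 1000,
            "probe_type": np.where(rng.random(n_x) < 0.7, "II", "I"),
            "gc_fraction": np.where(
                island, rng.normal(0.55, 0.1, n_x), rng.normal(0.40, 0.1, n_x)
            ).clip(0.2, 0.8),
            "cpg_island": island,
        },
        index=pd.Index([f"cgX{i:06d}" for i in range(n_x)], name="probe_id"),
    )
    mdf = pd.concat([mdf, xdf])
    manifest = ProbeManifest(mdf)
    gc = manifest.df["gc_fraction"].to_numpy()
    type2 = (manifest.df["probe_type"] == "II").to_numpy().astype(float)
    is_x = manifest.chrom_of() == "X"
    meth = np.concatenate(
        [auto_truth.methylation, np.where(island, rng.beta(2, 10, n_x), rng.beta(10, 2.5, n_x))]
    )

    names = [f"female_{i+1}" for i in range(n_female)] + [
        f"male_{i+1}" for i in range(n_male)
    ]
    M = np.empty((manifest.n_probes, len(names)))
    U = np.empty_like(M)
    for j, name in enumerate(names):
        cn = np.full(manifest.n_probes, 2, dtype=np.int64)
        if name.startswith("male"):
            cn[is_x] = 1
        total = 2.0 ** _log2_totals(rng, params, cn, gc, type2, 0.0)
        M[:, j], U[:, j] = _split_channels(rng, total, meth)
    bg = 2.0 ** rng.normal(
        params.background_log2_mean, params.background_log2_sd,
        size=(params.n_controls, len(names)),
    )
    frac = rng.beta(2.0, 2.0, size=bg.shape)
    x = IntensityMatrix(
        probes=manifest.probe_ids, samples=names, M=M, U=U,
        sex=["F"] * n_female + ["M"] * n_male,
    )
    return manifest, x, bg * frac, bg * (1 - frac)


def default_preset(seed: int) -> SimParams:
    """The default study conditions: 20,000 probes, attenuation 0.33, noise SD 0.25."""
    return SimParams(seed=seed)
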