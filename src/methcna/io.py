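"""Readers and writers for probe manifests, two-channel signal matrices and segment files.

Internal coordinates are 1-based inclusive throughout (matching manifest positions);
the BED half-open convention is applied only at the file boundary. Chromosome labels
are normalized by stripping a leading ``chr`` prefix; ``X`` and ``Y`` stay letters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DataError(ValueError):
    """A file parsed but its contents violate an invariant."""


def normalize_chrom(label: object) -> str | None:
    """Map a chromosome label to the canonical '1'..'22', 'X', 'Y' set, else None."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in ("23",):
        s = "X"
    elif s in ("24",):
        s = "Y"
    s = s.upper() if s in ("x", "y") else s
    return s if s in _CHROM_RANK else None


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_RANK[chrom]


class CNAState(IntEnum):
    """Copy-number call for a segment, ordered from loss to gain of material."""

    DELETION = -2   # homozygous deletion, ~0 copies
    LOSS = -1       # heterozygous loss, 1 copy
    NEUTRAL = 0     # 2 copies
    GAIN = 1        # single-copy gain, 3 copies
    AMPLIFICATION = 2  # high-level amplification


@dataclass(frozen=True)
class ProbeManifest:
    """Genomic and design annotation for every probe; the coordinate backbone.

    ``df`` is indexed by probe_id with columns chrom, pos (1-based), probe_type
    ('I'|'II'), gc_fraction in [0,1], cpg_island (bool), sorted by (chrom, pos).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe_id(s): {dupes[:5]}")
        if (df["pos"] < 1).any():
            raise DataError("manifest positions must be >= 1")
        if ((df["gc_fraction"] < 0) | (df["gc_fraction"] > 1)).any():
            raise DataError("gc_fraction must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def n_probes(self) -> int:
        return len(self.df)

    def chrom_of(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def pos_of(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def subset(self, keep: np.ndarray | pd.Index) -> "ProbeManifest":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            return ProbeManifest(self.df.loc[keep])
        return ProbeManifest(self.df.loc[keep])

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ProbeManifest":
        """Build from a raw frame, normalizing chromosomes and sort order."""
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df = df[df["chrom"].notna()]
        df = df.sort_values(
            by=["chrom", "pos"], key=lambda s: s.map(_CHROM_RANK) if s.name == "chrom" else s
        )
        return ProbeManifest(df)


@dataclass
class IntensityMatrix:
    """Paired methylated/unmethylated channel intensities, probes x samples."""

    probes: pd.Index
    samples: list[str]
    M: np.ndarray
    U: np.ndarray
    batch: list[str] | None = None
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        shape = (len(self.probes), len(self.samples))
        if self.M.shape != shape or self.U.shape != shape:
            raise DataError(
                f"M/U shape {self.M.shape}/{self.U.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        if not (np.isfinite(self.M).all() and np.isfinite(self.U).all()):
            raise DataError("intensities must be finite")
        if (self.M < 0).any() or (self.U < 0).any():
            raise DataError("intensities must be >= 0 after clamping")

    @property
    def total(self) -> np.ndarray:
        """Copy-number-informative total intensity M + U."""
        return self.M + self.U


@dataclass(frozen=True)
class Segment:
    """One chromosomal segment, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    state: CNAState | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"segment start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise DataError("segment must contain at least one probe")


@dataclass
class SegmentSet:
    """Ordered, per-chromosome non-overlapping segments for one sample."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start)
        )
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
                raise DataError(
                    f"overlapping segments on chrom {seg.chrom}: "
                    f"{prev.start}-{prev.end} and {seg.start}-{seg.end}"
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def with_states(self, states: Sequence[CNAState]) -> "SegmentSet":
        if len(states) != len(self.segments):
            raise DataError("state list length mismatch")
        return SegmentSet(
            self.sample_id,
            [replace(s, state=st) for s, st in zip(self.segments, states)],
        )


# ---------------------------------------------------------------------------
# manifest / signal readers

_MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "probe_type", "gc_fraction", "cpg_island")

_TRUE_STRINGS = {"true", "1", "yes", "t", "island"}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """TSV by default; comma autodetected from the header line."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_manifest(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ProbeManifest:
    """Read a probe manifest from delimited text.

    ``dialect`` maps the canonical column names (probe_id, chrom, pos, probe_type,
    gc_fraction, cpg_island) to the file's header names. Rows whose chromosome label
    cannot be normalized, or whose numeric cells do not parse, are dropped with a
    logged count; probes are returned sorted by (chrom, pos).
    """
    raw = _read_delimited(path)
    dialect = dict(dialect or {})
    cols = {name: dialect.get(name, name) for name in _MANIFEST_COLUMNS}
    missing = [file_col for file_col in cols.values() if file_col not in raw.columns]
    if missing:
        raise FormatError(f"manifest missing required column(s): {missing}")

    df = pd.DataFrame(
        {
            "probe_id": raw[cols["probe_id"]],
            "chrom": raw[cols["chrom"]].map(normalize_chrom),
            "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
            "probe_type": raw[cols["probe_type"]].str.strip().str.upper(),
            "gc_fraction": pd.to_numeric(raw[cols["gc_fraction"]], errors="coerce"),
            "cpg_island": raw[cols["cpg_island"]]
            .str.strip()
            .str.lower()
            .isin(_TRUE_STRINGS),
        }
    )
    n_raw = len(df)
    ok = df["chrom"].notna() & df["pos"].notna() & df["gc_fraction"].notna()
    n_dropped = int(n_raw - ok.sum())
    if n_dropped:
        logger.info("read_manifest: dropped %d unparseable row(s) of %d", n_dropped, n_raw)
    df = df[ok]
    if df["probe_id"].duplicated().any():
        raise DataError("manifest contains duplicate probe_id values")
    df["pos"] = df["pos"].astype(np.int64)
    df = df.set_index("probe_id")
    df = df.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(_CHROM_RANK) if s.name == "chrom" else s
    )
    return ProbeManifest(df)


def _read_signal_file(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    return df.apply(pd.to_numeric, errors="coerce")


def read_signal_matrix(
    path_M: str | Path, path_U: str | Path, manifest: ProbeManifest
) -> IntensityMatrix:
    """Read a GenomeStudio-style M/U signal export pair.

    Probes are restricted to the manifest intersection (manifest order); negative raw
    values are clamped to 0 and rows with unparseable cells are dropped, both with
    logged counts.
    """
    m = _read_signal_file(path_M)
    u = _read_signal_file(path_U)
    if list(m.columns) != list(u.columns):
        raise FormatError(
            f"sample columns differ between M ({list(m.columns)}) and U ({list(u.columns)})"
        )
    bad = m.isna().any(axis=1) | u.isna().any(axis=1).reindex(m.index, fill_value=True)
    if bad.any():
        logger.info("read_signal_matrix: dropped %d row(s) with unparseable cells", int(bad.sum()))
        m, u = m[~bad], u.loc[m.index]

    shared = manifest.probe_ids.intersection(m.index)
    n_extra = len(m.index.difference(manifest.probe_ids))
    if n_extra:
        logger.info("read_signal_matrix: %d probe(s) absent from manifest excluded", n_extra)
    order = manifest.probe_ids[manifest.probe_ids.isin(shared)]
    M = m.loc[order].to_numpy(dtype=float)
    U = u.loc[order].to_numpy(dtype=float)
    n_clamped = int((M < 0).sum() + (U < 0).sum())
    if n_clamped:
        logger.info("read_signal_matrix: clamped %d negative value(s) to 0", n_clamped)
    return IntensityMatrix(
        probes=pd.Index(order), samples=list(m.columns),
        M=np.clip(M, 0, None), U=np.clip(U, 0, None),
    )


# ---------------------------------------------------------------------------
# segment writers / readers

_SEG_HEADER = ["sample", "chrom", "start", "end", "n_probes", "mean_log2", "state"]


def _fmt_state(state: CNAState | None) -> str:
    return state.name if state is not None else "NA"


def _parse_state(token: str) -> CNAState | None:
    token = token.strip()
    if token in ("", "NA", ".", "nan"):
        return None
    return CNAState[token]


def write_segments(segs: SegmentSet, path: str | Path, format: str = "seg") -> None:
    """Write a SegmentSet as SEG (tab, 1-based inclusive) or BED (0-based half-open).

    The BED dialect carries the state in the name field, mean_log2 in the score
    field, and n_probes in column 7; the sample id travels in a ``#sample=`` header
    comment so the round trip is lossless.
    """
    path = Path(path)
    lines: list[str] = []
    if format == "seg":
        lines.append("\t".join(_SEG_HEADER))
        for s in segs:
            lines.append(
                f"{segs.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_probes}"
                f"\t{s.mean_log2:.6f}\t{_fmt_state(s.state)}"
            )
    elif format == "bed":
        lines.append(f"#sample={segs.sample_id}")
        for s in segs:
            lines.append(
                f"{s.chrom}\t{s.start - 1}\t{s.end}\t{_fmt_state(s.state)}"
                f"\t{s.mean_log2:.6f}\t.\t{s.n_probes}"
            )
    else:
        raise ValueError(f"unknown segment format: {format!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_segments(path: str | Path, format: str = "seg") -> SegmentSet:
    """Read SEG/BED segments back into 1-based inclusive coordinates.

    Accepts the dialects written by :func:`write_segments` as well as minimal
    (chrom, start, end[, mean_log2[, n_probes]]) files. Overlapping segments on one
    chromosome raise :class:`DataError`.
    """
    path = Path(path)
    sample_id = path.stem
    segments: list[Segment] = []
    with open(path, "r", encoding="utf-8") as fh:
        rows = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if format == "seg":
        header = rows[0].split("\t")
        idx = {name: header.index(name) for name in header}
        for row in rows[1:]:
            f = row.split("\t")
            sample_id = f[idx["sample"]] if "sample" in idx else sample_id
            chrom = normalize_chrom(f[idx["chrom"]])
            if chrom is None:
                raise FormatError(f"unmappable chromosome in segment row: {row!r}")
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    n_probes=int(f[idx["n_probes"]]) if "n_probes" in idx else 1,
                    mean_log2=float(f[idx["mean_log2"]]) if "mean_log2" in idx else 0.0,
                    state=_parse_state(f[idx["state"]]) if "state" in idx else None,
                )
            )
    elif format == "bed":
        for row in rows:
            if row.startswith("#sample="):
                sample_id = row.split("=", 1)[1]
                continue
            if row.startswith(("#", "track", "browser")):
                continue
            f = row.split("\t")
            chrom = normalize_chrom(f[0])
            if chrom is None:
                raise FormatError(f"unmappable chromosome in BED row: {row!r}")
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    state=_parse_state(f[3]) if len(f) > 3 else None,
                    mean_log2=float(f[4]) if len(f) > 4 else 0.0,
                    n_probes=int(f[6]) if len(f) > 6 else 1,
                )
            )
    else:
        raise ValueError(f"unknown segment format: {format!r}")
    return SegmentSet(sample_id=sample_id, segments=segments)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    """Write a manifest in the canonical TSV dialect (round-trips read_manifest)."""
    df = manifest.df.reset_index()
    df["cpg_island"] = df["cpg_island"].map({True: "TRUE", False: "FALSE"})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_signal_matrix(x: IntensityMatrix, path_M: str | Path, path_U: str | Path) -> None:
    """Write the M/U channel pair as TSV (round-trips read_signal_matrix)."""
    for arr, path in ((x.M, path_M), (x.U, path_U)):
        pd.DataFrame(arr, index=x.probes, columns=x.samples).rename_axis("probe_id").to_csv(
            path, sep="\t", lineterminator="\n", float_format="%.4f"
        )
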