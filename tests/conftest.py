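import numpy as np
import pandas as pd
import pytest

from methcna.cna import LogRatioProfile
from methcna.io import ProbeManifest


def make_manifest(
    chroms, positions, probe_type=None, gc=None, island=None, prefix="cg"
) -> ProbeManifest:
    n = len(positions)
    df = pd.DataFrame(
        {
            "chrom": list(chroms),
            "pos": np.asarray(positions, dtype=np.int64),
            "probe_type": probe_type if probe_type is not None else ["II"] * n,
            "gc_fraction": gc if gc is not None else np.full(n, 0.45),
            "cpg_island": island if island is not None else [False] * n,
        },
        index=pd.Index([f"{prefix}{i:05d}" for i in range(n)], name="probe_id"),
    )
    return ProbeManifest.from_frame(df)


def make_profile(values, chrom="1", sample_id="s1", spacing=1000) -> LogRatioProfile:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if isinstance(chrom, str):
        chroms = np.array([chrom] * n)
    else:
        chroms = np.asarray(chrom)
    return LogRatioProfile(
        sample_id=sample_id,
        probes=pd.Index([f"p{i:05d}" for i in range(n)]),
        chrom=chroms,
        pos=np.arange(1, n + 1, dtype=np.int64) * spacing,
        log2r=values,
    )


@pytest.fixture
def small_manifest() -> ProbeManifest:
    return make_manifest(
        chroms=["1", "1", "1", "2", "2", "X"],
        positions=[100, 200, 300, 100, 200, 500],
    )
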