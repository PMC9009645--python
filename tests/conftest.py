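"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import pytest

from hopfinger.io import (
    GenotypeTable,
    MarkerDef,
    MarkerKind,
    Population,
    SampleMeta,
    Sex,
    SNPCall,
    SSRCall,
)


def make_ssr_table(rows, marker_names=None, metas=None):
    """Build an SSR GenotypeTable from {sample_id: [allele-tuple, ...]}.

    An empty tuple or None is a missing call.  ``metas`` optionally maps
    sample_id -> SampleMeta.
    """
    rows = dict(rows)
    n_markers = len(next(iter(rows.values())))
    names = marker_names or [f"L{j + 1}" for j in range(n_markers)]
    markers = [MarkerDef(n, MarkerKind.SSR, motif_length=2) for n in names]
    samples, calls = [], []
    for sid, row in rows.items():
        meta = (metas or {}).get(sid, SampleMeta(sid, ploidy=2))
        samples.append(meta)
        calls.append([SSRCall(tuple(cell or ())) for cell in row])
    return GenotypeTable(markers=markers, samples=samples, calls=calls)


def make_snp_table(rows, marker_names=None, metas=None):
    """Build a SNP GenotypeTable from {sample_id: "XX XY YY -"-style list}."""
    rows = dict(rows)
    n_markers = len(next(iter(rows.values())))
    names = marker_names or [f"S{j + 1}" for j in range(n_markers)]
    markers = [MarkerDef(n, MarkerKind.SNP) for n in names]
    token = {"XX": SNPCall.XX, "XY": SNPCall.XY, "YY": SNPCall.YY,
             "-": SNPCall.MISSING, "": SNPCall.MISSING}
    samples, calls = [], []
    for sid, row in rows.items():
        meta = (metas or {}).get(sid, SampleMeta(sid, ploidy=2))
        samples.append(meta)
        calls.append([token[c] if isinstance(c, str) else c for c in row])
    return GenotypeTable(markers=markers, samples=samples, calls=calls)


@pytest.fixture
def two_pool_table():
    """10 samples in two pools sharing no alleles across pools at any of 8
    loci: a planted two-clade structure with maximal divergence."""
    import numpy as np

    rng = np.random.default_rng(42)
    pool_alleles = {"A": [100, 102, 104, 106], "B": [200, 202, 204, 206]}
    rows = {}
    metas = {}
    for pool in ("A", "B"):
        for i in range(5):
            sid = f"{pool}{i + 1}"
            rows[sid] = [
                tuple(sorted(rng.choice(pool_alleles[pool], size=2, replace=False)))
                for _ in range(8)
            ]
            metas[sid] = SampleMeta(
                sid,
                Population.CULT if pool == "A" else Population.WNA,
                Sex.UNKNOWN,
                2,
            )
    return make_ssr_table(rows, metas=metas)
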