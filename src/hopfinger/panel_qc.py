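"""SNP panel construction, KASP QC, cross-platform concordance, sex scan.

The panel-building path mirrors how a genotyping service panel is derived
from discovery data: depth/presence/frequency filters on the discovery SNP
matrix, per-marker quality indices (HWE probability index, PIC, observed
heterozygosity, minor allele frequency) screened on their four-index
average, and finally a minimal discriminating subset (see
:mod:`hopfinger.identity`).

Validation utilities compare the production assay back to the discovery
calls: cluster-quality QC (three well-defined genotype classes, bounded
missingness), a mismatch classification between the two platforms
(het->hom, hom->opposite-hom, hom->het), and a scan for sex-specific
alleles at a sex-linked SSR in a dioecious crop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from . import diversity
from .io import GenotypeTable, MarkerKind, Population, SNPCall, SSRCall, Sex

__all__ = [
    "SnpFilterConfig",
    "FilterStep",
    "filter_snps",
    "MarkerIndices",
    "marker_indices",
    "select_candidates",
    "KaspQCResult",
    "kasp_qc",
    "ConcordanceReport",
    "concordance",
    "SexAlleleReport",
    "sex_specific_alleles",
]


@dataclass(frozen=True)
class SnpFilterConfig:
    """Discovery-data SNP filter thresholds.

    Defaults follow common panel-development practice for a reduced-
    representation discovery set: calls below 2x depth masked, sites kept at
    >= 90% genotype presence, samples kept at >= 75% call rate, then sites
    kept at minor allele frequency >= 0.20 and missingness <= 10%.
    """

    maf_min: float = 0.20
    site_missing_max: float = 0.10
    genotype_presence_min: float = 0.90
    taxa_presence_min: float = 0.75
    min_depth: int = 2

    def __post_init__(self) -> None:
        for name in ("maf_min", "site_missing_max", "genotype_presence_min", "taxa_presence_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class FilterStep:
    step: str
    n_sites: int
    n_samples: int


def _site_stats(calls: list[SNPCall]) -> tuple[float, float]:
    """(minor allele frequency, missing fraction) of one site."""
    x = y = present = 0
    for c in calls:
        d = c.dosage()
        if d is None:
            continue
        present += 1
        x += 2 * d[0]
        y += 2 * d[1]
    missing = 1.0 - present / len(calls) if calls else 1.0
    if x + y == 0:
        return 0.0, missing
    p = x / (x + y)
    return min(p, 1.0 - p), missing


def filter_snps(table: GenotypeTable, cfg: SnpFilterConfig | None = None,
                depth: np.ndarray | None = None,
                require_complete: bool = False) -> tuple[GenotypeTable, list[FilterStep]]:
    """Apply the discovery-panel filters in order, reporting retention.

    Order: (1) mask calls with depth < ``min_depth`` (only when a per-call
    ``depth`` grid is supplied); (2) drop sites below the genotype-presence
    floor; (3) drop samples below the taxa-presence floor; (4) keep sites
    with MAF >= ``maf_min`` and missingness <= ``site_missing_max``;
    (5, optional) keep only sites with no missing data at all.  An empty
    result is legal and simply reported.
    """
    cfg = cfg or SnpFilterConfig()
    if any(m.kind is not MarkerKind.SNP for m in table.markers):
        raise ValueError("filter_snps expects a SNP table")
    work = table
    steps = [FilterStep("input", work.n_markers, work.n_samples)]

    if depth is not None:
        depth = np.asarray(depth)
        if depth.shape != (table.n_samples, table.n_markers):
            raise ValueError("depth grid shape must match the call grid")
        calls = [
            [
                SNPCall.MISSING if depth[i, j] < cfg.min_depth else work.calls[i][j]
                for j in range(work.n_markers)
            ]
            for i in range(work.n_samples)
        ]
        work = GenotypeTable(markers=list(work.markers), samples=list(work.samples), calls=calls)
        steps.append(FilterStep("depth_mask", work.n_markers, work.n_samples))

    keep = [
        m.name
        for m in work.markers
        if (1.0 - _site_stats(work.column(m.name))[1]) >= cfg.genotype_presence_min
    ]
    work = work.subset_markers(keep)
    steps.append(FilterStep("site_presence", work.n_markers, work.n_samples))

    if work.n_markers:
        keep_samples = []
        for sid in work.sample_ids:
            row = work.row(sid)
            rate = sum(1 for c in row if not c.missing) / len(row)
            if rate >= cfg.taxa_presence_min:
                keep_samples.append(sid)
        work = work.subset_samples(keep_samples)
    steps.append(FilterStep("taxa_presence", work.n_markers, work.n_samples))

    keep = []
    for m in work.markers:
        maf, miss = _site_stats(work.column(m.name))
        if maf >= cfg.maf_min and miss <= cfg.site_missing_max:
            keep.append(m.name)
    work = work.subset_markers(keep)
    steps.append(FilterStep("maf_and_missing", work.n_markers, work.n_samples))

    if require_complete:
        keep = [
            m.name for m in work.markers
            if _site_stats(work.column(m.name))[1] == 0.0
        ]
        work = work.subset_markers(keep)
        steps.append(FilterStep("no_missing", work.n_markers, work.n_samples))
    return work, steps


@dataclass(frozen=True)
class MarkerIndices:
    """Per-site screen indices and their mean.

    ``hwe_index`` is the chi-square goodness-of-fit p-value of observed
    genotype counts against Hardy-Weinberg expectations (1 df, no continuity
    correction); ``mean4`` averages hwe_index, pic, het_obs and maf."""

    marker: str
    hwe_index: float
    pic: float
    het_obs: float
    maf: float

    @property
    def mean4(self) -> float:
        return (self.hwe_index + self.pic + self.het_obs + self.maf) / 4.0


def _hwe_pvalue(n_xx: int, n_xy: int, n_yy: int) -> float:
    n = n_xx + n_xy + n_yy
    if n == 0:
        return 1.0
    p = (2 * n_xx + n_xy) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0  # monomorphic: trivially at equilibrium
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_xx, n_xy, n_yy], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def marker_indices(table: GenotypeTable, min_calls: int = 10) -> list[MarkerIndices]:
    """HWE index, PIC, observed heterozygosity and MAF per SNP site."""
    out = []
    for m in table.markers:
        counts = Counter(c for c in table.column(m.name) if not c.missing)
        n = sum(counts.values())
        if n < min_calls:
            raise ValueError(f"marker {m.name}: only {n} calls (< {min_calls})")
        n_xx, n_xy, n_yy = counts[SNPCall.XX], counts[SNPCall.XY], counts[SNPCall.YY]
        p = (2 * n_xx + n_xy) / (2 * n)
        maf = min(p, 1.0 - p)
        out.append(
            MarkerIndices(
                marker=m.name,
                hwe_index=_hwe_pvalue(n_xx, n_xy, n_yy),
                pic=diversity.pic([p, 1.0 - p]),
                het_obs=n_xy / n,
                maf=maf,
            )
        )
    return out


def select_candidates(indices: list[MarkerIndices], threshold: float = 0.50) -> list[str]:
    """Markers whose four-index mean meets the threshold (>=, so a marker
    sitting exactly at the boundary is kept)."""
    return [ix.marker for ix in indices if ix.mean4 >= threshold]


# ---------------------------------------------------------------------------
# KASP QC


@dataclass(frozen=True)
class KaspQCResult:
    retained: tuple[str, ...]
    removed: dict[str, str]          # marker -> reason
    flagged_samples: tuple[str, ...]  # > missing_max missing across retained


def kasp_qc(table: GenotypeTable, missing_max: float = 0.20) -> KaspQCResult:
    """Assay-level QC of a production SNP panel.

    A marker is removed when it is monomorphic (a single genotype cluster),
    lacks one of the three genotype classes (only two clusters), or exceeds
    the missing-data ceiling.  Samples missing more than the same ceiling
    across the retained markers are flagged (low-quality DNA).
    """
    if not table.n_markers:
        raise ValueError("empty panel")
    removed: dict[str, str] = {}
    retained: list[str] = []
    for m in table.markers:
        calls = table.column(m.name)
        present = [c for c in calls if not c.missing]
        miss_frac = 1.0 - len(present) / len(calls)
        classes = set(present)
        if len(classes) <= 1:
            removed[m.name] = "monomorphic"
        elif len(classes) < 3:
            removed[m.name] = "fewer than three genotype clusters"
        elif miss_frac > missing_max:
            removed[m.name] = f"missing fraction {miss_frac:.2f} > {missing_max:.2f}"
        else:
            retained.append(m.name)
    flagged = []
    if retained:
        sub = table.subset_markers(retained)
        for sid in sub.sample_ids:
            row = sub.row(sid)
            miss = sum(1 for c in row if c.missing) / len(row)
            if miss > missing_max:
                flagged.append(sid)
    return KaspQCResult(tuple(retained), removed, tuple(flagged))


# ---------------------------------------------------------------------------
# GBS vs KASP concordance


MISMATCH_GROUPS = ("het_to_hom", "hom_to_opposite_hom", "hom_to_het")


def classify_mismatch(g: SNPCall, k: SNPCall) -> str | None:
    """Classify a discovery-vs-assay disagreement; None when calls agree.

    Group 1 (het_to_hom): discovery heterozygote called homozygous by the
    assay; group 2 (hom_to_opposite_hom): opposite homozygotes (the
    signature of a sample swap); group 3 (hom_to_het): discovery homozygote
    called heterozygous.
    """
    if g.missing or k.missing:
        raise ValueError("cannot classify a missing call")
    if g is k:
        return None
    if g.het and k.hom:
        return "het_to_hom"
    if g.hom and k.hom:
        return "hom_to_opposite_hom"
    return "hom_to_het"


def _largest_remainder_shares(counts: dict[str, int]) -> dict[str, float]:
    """Percent shares rounded to 2 dp, corrected to sum to exactly 100.00."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    raw = {k: 100.0 * v / total for k, v in counts.items()}
    floored = {k: float(np.floor(v * 100)) / 100 for k, v in raw.items()}
    deficit = int(round((100.0 - sum(floored.values())) * 100))
    order = sorted(counts, key=lambda k: (-(raw[k] - floored[k]), k))
    shares = dict(floored)
    for k in order[:deficit]:
        shares[k] = round(shares[k] + 0.01, 2)
    return {k: round(v, 2) for k, v in shares.items()}


@dataclass(frozen=True)
class ConcordanceReport:
    """Cross-platform concordance summary.

    ``agreement_pct_all`` counts matches over all compared (non-missing on
    both sides) calls; ``group_shares`` are percentages of all mismatches
    before any sample exclusion; samples whose own mismatch fraction exceeds
    the incongruity threshold are listed in ``excluded_samples`` and removed
    for ``agreement_pct_after_exclusion``."""

    n_samples: int
    n_markers: int
    counts: dict[str, int]                 # match + the three mismatch groups
    skipped_missing: int
    per_sample_incongruity: dict[str, float]
    per_locus_mismatches: dict[str, int]
    excluded_samples: tuple[str, ...]
    agreement_pct_all: float
    agreement_pct_after_exclusion: float
    group_shares: dict[str, float]
    mismatch_cells: tuple[tuple[str, str, str], ...] = field(repr=False, default=())


def concordance(gbs: GenotypeTable, kasp: GenotypeTable,
                sample_incongruity_max: float = 0.20) -> ConcordanceReport:
    """Compare discovery (GBS) and assay (KASP) calls on shared samples/markers."""
    shared_samples = [s for s in gbs.sample_ids if s in set(kasp.sample_ids)]
    shared_markers = [m for m in gbs.marker_names if m in set(kasp.marker_names)]
    if not shared_samples or not shared_markers:
        raise ValueError("no shared (sample, marker) cells between the tables")
    g = gbs.subset_samples(shared_samples).subset_markers(shared_markers)
    k = kasp.subset_samples(shared_samples).subset_markers(shared_markers)

    counts = {"match": 0, **{grp: 0 for grp in MISMATCH_GROUPS}}
    skipped = 0
    per_sample_cmp: Counter = Counter()
    per_sample_mm: Counter = Counter()
    per_locus_mm: Counter = Counter()
    cells = []
    for i, sid in enumerate(g.sample_ids):
        for j, mname in enumerate(g.marker_names):
            cg, ck = g.calls[i][j], k.calls[i][j]
            if cg.missing or ck.missing:
                skipped += 1
                continue
            per_sample_cmp[sid] += 1
            grp = classify_mismatch(cg, ck)
            if grp is None:
                counts["match"] += 1
            else:
                counts[grp] += 1
                per_sample_mm[sid] += 1
                per_locus_mm[mname] += 1
                cells.append((sid, mname, grp))

    incong = {
        sid: (per_sample_mm[sid] / per_sample_cmp[sid]) if per_sample_cmp[sid] else 0.0
        for sid in g.sample_ids
    }
    excluded = tuple(s for s in g.sample_ids if incong[s] > sample_incongruity_max)
    total_cmp = sum(per_sample_cmp.values())
    mism_all = sum(counts[grp] for grp in MISMATCH_GROUPS)
    agree_all = 100.0 * counts["match"] / total_cmp if total_cmp else float("nan")
    kept = [s for s in g.sample_ids if s not in excluded]
    kept_cmp = sum(per_sample_cmp[s] for s in kept)
    kept_mm = sum(per_sample_mm[s] for s in kept)
    agree_excl = 100.0 * (kept_cmp - kept_mm) / kept_cmp if kept_cmp else float("nan")
    shares = _largest_remainder_shares({grp: counts[grp] for grp in MISMATCH_GROUPS})
    return ConcordanceReport(
        n_samples=len(shared_samples),
        n_markers=len(shared_markers),
        counts=counts,
        skipped_missing=skipped,
        per_sample_incongruity=incong,
        per_locus_mismatches=dict(per_locus_mm),
        excluded_samples=excluded,
        agreement_pct_all=agree_all,
        agreement_pct_after_exclusion=agree_excl,
        group_shares=shares,
        mismatch_cells=tuple(cells),
    )


# ---------------------------------------------------------------------------
# sex-linked allele scan


@dataclass(frozen=True)
class SexAlleleReport:
    """Sex-specific alleles at one (sex-linked) SSR marker.

    An allele is male-specific iff carried by at least one male and by no
    female (and symmetrically).  ``pools`` classifies each reported allele by
    the gene pools of its carriers (CULT / WNA / BOTH)."""

    marker: str
    male_specific: dict[int, int]    # allele -> carrier count
    female_specific: dict[int, int]
    pools: dict[int, str]


def sex_specific_alleles(table: GenotypeTable, marker: str) -> SexAlleleReport:
    """Scan one SSR marker for alleles confined to a single sex."""
    j = table.marker_index(marker)
    carriers_by_sex: dict[Sex, Counter] = {Sex.F: Counter(), Sex.M: Counter()}
    pools: dict[int, set[str]] = {}
    seen = {Sex.F: 0, Sex.M: 0}
    for meta, row in zip(table.samples, table.calls):
        call = row[j]
        if not isinstance(call, SSRCall):
            raise ValueError("sex-allele scan is defined for SSR markers")
        if call.missing or meta.sex is Sex.UNKNOWN:
            continue
        seen[meta.sex] += 1
        for allele in call.distinct:
            carriers_by_sex[meta.sex][allele] += 1
            if meta.population in (Population.CULT, Population.WNA):
                pools.setdefault(allele, set()).add(meta.population.value)
    if seen[Sex.F] == 0 or seen[Sex.M] == 0:
        raise ValueError(
            f"marker {marker}: need scored calls from both sexes "
            f"(F={seen[Sex.F]}, M={seen[Sex.M]})"
        )
    male = {
        a: c for a, c in sorted(carriers_by_sex[Sex.M].items())
        if carriers_by_sex[Sex.F][a] == 0
    }
    female = {
        a: c for a, c in sorted(carriers_by_sex[Sex.F].items())
        if carriers_by_sex[Sex.M][a] == 0
    }
    pool_class = {}
    for a in list(male) + list(female):
        ps = pools.get(a, set())
        pool_class[a] = "BOTH" if len(ps) == 2 else (next(iter(ps)) if ps else "UNKNOWN")
    return SexAlleleReport(
        marker=marker,
        male_specific=male,
        female_specific=female,
        pools=pool_class,
    )
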