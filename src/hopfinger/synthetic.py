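"""Synthetic mixed-ploidy germplasm datasets with exact ground truth.

The generator emulates the statistical structure of a clonally maintained
hop collection genotyped with a 9-SSR multiplex and a small bi-allelic SNP
panel:

* two diverged gene pools — cultivated (CULT) and wild North American (WNA)
  accessions — with per-locus allele frequencies perturbed between pools by
  a divergence parameter;
* diploid, triploid and tetraploid individuals (triploids arise from 4x x 2x
  crosses, which :func:`simulate_cross` models by random chromosome
  segregation);
* clonal duplicate groups, optionally mislabeled, which downstream synonym
  detection must recover;
* per-locus null alleles, modeled as a distinguished allele size present in
  the gene pool but invisible on the platform, so the true null frequency is
  known exactly;
* a sex-linked SSR carrying a planted male-specific allele in a dioecious
  population;
* a paired discovery/assay (GBS/KASP) SNP table with injected heterozygote
  dropout, false heterozygotes and whole-row sample swaps, each logged per
  cell with the mismatch class it realizes.

Default parameters reproduce the scale of the motivating collection:
629 accessions = 425 unique founders (331 CULT + 94 WNA) plus 89 clone
groups; 9 SSRs with null-allele frequencies (0.26, 0.12, 0.08, 0.02, 0...);
25 SNPs; 18% males.  Everything derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    GenotypeTable,
    MarkerDef,
    MarkerKind,
    Population,
    SampleMeta,
    Sex,
    SNPCall,
    SSRCall,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FounderSet",
    "SimulatedDataset",
    "default_clone_groups",
    "simulate_pools",
    "simulate_cross",
    "inject_artifacts",
    "simulate_dataset",
]

SEX_MARKER = "HI-AGA7"
SSR_NAMES = (
    SEX_MARKER,
    "K10315842",
    "K10315910",
    "K10316016",
    "K10316221",
    "K10315931",
    "ACA1-K9-3",
    "Primer1",
    "Primer6",
)
DEFAULT_NULL_FREQS = (0.0, 0.02, 0.26, 0.08, 0.0, 0.0, 0.0, 0.0, 0.12)


def default_clone_groups() -> tuple[tuple[int, bool], ...]:
    """89 clone groups (63 triples + 26 quadruples) expanding 425 unique
    founders to 629 accessions; every tenth group is mislabeled."""
    sizes = [3] * 63 + [4] * 26
    return tuple((s, i % 10 == 9) for i, s in enumerate(sizes))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated world.

    ``fst_like_divergence`` mixes a shared base allele-frequency vector with
    a pool-private one (0 = panmictic, 1 = fully private frequencies).
    ``ploidy_mix`` applies to cultivated founders; wild founders are diploid.
    ``error_rates`` are per-eligible-cell (het_dropout, false_het) and
    per-sample (sample_swap) probabilities for the paired SNP tables.
    """

    seed: int = 0
    n_cult: int = 331
    n_wna: int = 94
    n_ssr: int = 9
    n_snp: int = 25
    fst_like_divergence: float = 0.4
    ploidy_mix: tuple[float, float, float] = (0.85, 0.10, 0.05)  # 2x, 3x, 4x
    clone_groups: tuple[tuple[int, bool], ...] = field(default_factory=default_clone_groups)
    null_freqs: tuple[float, ...] = DEFAULT_NULL_FREQS
    het_dropout: float = 0.02
    false_het: float = 0.02
    sample_swap: float = 0.19
    sex_ratio: float = 115 / 628
    sex_marker: str = SEX_MARKER
    alleles_per_locus: tuple[int, int] = (6, 20)
    motif_length: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.ploidy_mix) - 1.0) > 1e-9:
            raise ValueError("ploidy_mix must sum to 1")
        for r in (self.fst_like_divergence, self.het_dropout, self.false_het,
                  self.sample_swap, self.sex_ratio):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages without re-simulation."""

    true_ssr: dict[str, dict[str, tuple[int, ...]]]  # sid -> marker -> dosage genotype
    null_allele_size: dict[str, int | None]
    null_freqs: dict[str, float]
    sex_allele: tuple[str, int]                      # (marker, male-specific size)
    clone_map: dict[str, str]                        # duplicate sid -> founder sid
    mislabels: tuple[str, ...] = ()
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    platform_errors: list[tuple[str, str, str, str]] = field(default_factory=list)
    swapped_samples: tuple[str, ...] = ()


@dataclass
class FounderSet:
    ssr: GenotypeTable
    snp: GenotypeTable
    truth: GroundTruth


@dataclass
class SimulatedDataset:
    """Final emitted tables: the SSR fingerprint table (nulls masked, clones
    included) and the paired discovery/assay SNP tables."""

    ssr: GenotypeTable
    gbs: GenotypeTable
    kasp: GenotypeTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# founders


def _pool_freqs(base: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    private = rng.dirichlet(np.ones(base.size))
    mixed = (1.0 - divergence) * base + divergence * private
    return mixed / mixed.sum()


def _visible_ssr(genotype: tuple[int, ...], null_size: int | None) -> SSRCall:
    vis = tuple(sorted({a for a in genotype if a != null_size}))
    return SSRCall(vis)


def simulate_pools(cfg: SimConfig) -> FounderSet:
    """Draw founder genotypes for two diverged gene pools.

    SSR allele ladders sit on the repeat-motif grid; per-pool frequencies
    derive from a common base perturbed by the divergence parameter.  Null
    alleles are a designated ladder step recorded in the ground truth.  The
    emitted founder table shows the *true* genotypes (null allele included
    as an ordinary size); :func:`inject_artifacts` applies platform
    visibility.  SNP calls are drawn as two allele copies per sample from
    the pool frequency of the site.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(SSR_NAMES[: cfg.n_ssr])
    while len(names) < cfg.n_ssr:
        names.append(f"SSR{len(names) + 1:02d}")
    null_freqs = list(cfg.null_freqs)[: cfg.n_ssr]
    null_freqs += [0.0] * (cfg.n_ssr - len(null_freqs))

    markers = []
    ladders: dict[str, np.ndarray] = {}
    freqs: dict[str, dict[str, np.ndarray]] = {}
    null_size: dict[str, int | None] = {}
    sex_allele_size: int | None = None
    for name, nf in zip(names, null_freqs):
        k = int(rng.integers(cfg.alleles_per_locus[0], cfg.alleles_per_locus[1] + 1))
        base_size = int(rng.integers(90, 260))
        ladder = base_size + cfg.motif_length * np.arange(k)
        base = rng.dirichlet(np.ones(k))
        per_pool = {
            "CULT": _pool_freqs(base, cfg.fst_like_divergence, rng),
            "WNA": _pool_freqs(base, cfg.fst_like_divergence, rng),
        }
        nsize = None
        if nf > 0:
            # the null allele is one extra ladder step, invisible on-platform
            nsize = int(ladder[-1] + cfg.motif_length)
            ladder = np.append(ladder, nsize)
            per_pool = {
                pool: np.append(p * (1.0 - nf), nf) for pool, p in per_pool.items()
            }
        if name == cfg.sex_marker:
            # reserve one more step as the planted male-specific allele;
            # it is transmitted outside the autosomal frequency pool
            sex_allele_size = int(ladder[-1] + cfg.motif_length)
        ladders[name] = ladder
        freqs[name] = per_pool
        null_size[name] = nsize
        markers.append(
            MarkerDef(
                name,
                MarkerKind.SSR,
                motif_length=cfg.motif_length,
                expected_range=(int(ladder[0]), int(ladder[-1]) + cfg.motif_length),
            )
        )
    if cfg.sex_marker not in names:
        raise ValueError(f"sex marker {cfg.sex_marker} not among the SSR names")

    snp_markers = [MarkerDef(f"SNP{j + 1:02d}", MarkerKind.SNP) for j in range(cfg.n_snp)]
    snp_freq: dict[str, dict[str, float]] = {}
    for m in snp_markers:
        base_q = rng.uniform(0.15, 0.85)
        snp_freq[m.name] = {
            "CULT": float(np.clip(base_q + cfg.fst_like_divergence * rng.uniform(-0.4, 0.4), 0.02, 0.98)),
            "WNA": float(np.clip(base_q + cfg.fst_like_divergence * rng.uniform(-0.4, 0.4), 0.02, 0.98)),
        }

    samples: list[SampleMeta] = []
    ssr_calls: list[list[SSRCall]] = []
    snp_calls: list[list[SNPCall]] = []
    true_ssr: dict[str, dict[str, tuple[int, ...]]] = {}
    specs = [("CULT", cfg.n_cult, Population.CULT), ("WNA", cfg.n_wna, Population.WNA)]
    for pool, count, pop in specs:
        for i in range(count):
            sid = f"{pool}-{i + 1:04d}"
            if pool == "CULT":
                ploidy = int(rng.choice((2, 3, 4), p=cfg.ploidy_mix))
            else:
                ploidy = 2
            sex = Sex.M if rng.random() < cfg.sex_ratio else Sex.F
            samples.append(SampleMeta(sid, pop, sex, ploidy))
            geno: dict[str, tuple[int, ...]] = {}
            row: list[SSRCall] = []
            for name in names:
                draws = rng.choice(ladders[name], size=ploidy, p=freqs[name][pool])
                alleles = [int(a) for a in draws]
                if name == cfg.sex_marker and sex is Sex.M:
                    alleles[0] = sex_allele_size  # one male-transmitted copy
                geno[name] = tuple(sorted(alleles))
                row.append(SSRCall(tuple(sorted(set(alleles)))))
            true_ssr[sid] = geno
            ssr_calls.append(row)
            snp_row = []
            for m in snp_markers:
                q = snp_freq[m.name][pool]
                copies = int(rng.binomial(2, q))
                snp_row.append((SNPCall.XX, SNPCall.XY, SNPCall.YY)[copies])
            snp_calls.append(snp_row)

    truth = GroundTruth(
        true_ssr=true_ssr,
        null_allele_size=null_size,
        null_freqs=dict(zip(names, null_freqs)),
        sex_allele=(cfg.sex_marker, int(sex_allele_size)),
        clone_map={},
    )
    return FounderSet(
        ssr=GenotypeTable(markers=markers, samples=samples, calls=ssr_calls),
        snp=GenotypeTable(markers=snp_markers, samples=list(samples), calls=snp_calls),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# crosses


def simulate_cross(founders: FounderSet, mother: str, father: str,
                   n_offspring: int, seed: int = 0,
                   prefix: str | None = None) -> FounderSet:
    """Append offspring of a bi-parental cross to a founder set.

    Gametes follow random chromosome segregation: a diploid parent
    contributes one uniformly drawn allele per locus, a tetraploid two drawn
    without replacement; offspring ploidy is the gamete-size sum (so a
    4x x 2x cross yields triploids).  No mutation: every offspring allele is
    one of the parents' alleles.  Returns a new FounderSet with offspring
    rows and pedigree entries added.
    """
    rng = np.random.default_rng(seed)
    table = founders.ssr
    truth = founders.truth
    metas = {s.sample_id: s for s in table.samples}
    for pid in (mother, father):
        if pid not in metas:
            raise KeyError(f"unknown parent: {pid}")
        if metas[pid].ploidy not in (2, 4):
            raise ValueError(
                f"parent {pid} has ploidy {metas[pid].ploidy}; gamete model "
                "supports 2x and 4x parents only"
            )

    def gamete(pid: str, marker: str) -> list[int]:
        geno = list(truth.true_ssr[pid][marker])
        k = metas[pid].ploidy // 2
        idx = rng.choice(len(geno), size=k, replace=False)
        return [geno[i] for i in sorted(idx)]

    prefix = prefix or f"{mother}x{father}"
    new_samples = list(table.samples)
    new_calls = [list(r) for r in table.calls]
    new_truth = dict(truth.true_ssr)
    pedigree = dict(truth.pedigree)
    for i in range(n_offspring):
        sid = f"{prefix}-{i + 1:03d}"
        sex = Sex.M if rng.random() < 0.5 else Sex.F
        geno_row: list[SSRCall] = []
        genod: dict[str, tuple[int, ...]] = {}
        for m in table.markers:
            alleles = gamete(mother, m.name) + gamete(father, m.name)
            genod[m.name] = tuple(sorted(alleles))
            geno_row.append(SSRCall(tuple(sorted(set(alleles)))))
        new_samples.append(
            SampleMeta(sid, Population.CULT, sex, ploidy=len(genod[table.markers[0].name]))
        )
        new_calls.append(geno_row)
        new_truth[sid] = genod
        pedigree[sid] = (mother, father)
    new_table = GenotypeTable(markers=list(table.markers), samples=new_samples, calls=new_calls)
    new_gt = replace_truth(truth, true_ssr=new_truth, pedigree=pedigree)
    return FounderSet(ssr=new_table, snp=founders.snp, truth=new_gt)


def replace_truth(truth: GroundTruth, **kw) -> GroundTruth:
    data = {
        "true_ssr": truth.true_ssr,
        "null_allele_size": truth.null_allele_size,
        "null_freqs": truth.null_freqs,
        "sex_allele": truth.sex_allele,
        "clone_map": truth.clone_map,
        "mislabels": truth.mislabels,
        "pedigree": truth.pedigree,
        "platform_errors": truth.platform_errors,
        "swapped_samples": truth.swapped_samples,
    }
    data.update(kw)
    return GroundTruth(**data)


# ---------------------------------------------------------------------------
# artifacts


def _mask_nulls(table: GenotypeTable, truth: GroundTruth) -> GenotypeTable:
    calls = []
    for sid, row in zip(table.sample_ids, table.calls):
        new_row = []
        for m, call in zip(table.markers, row):
            nsize = truth.null_allele_size.get(m.name)
            if nsize is None or call.missing:
                new_row.append(call)
            else:
                new_row.append(SSRCall(tuple(a for a in call.distinct if a != nsize)))
        calls.append(new_row)
    return GenotypeTable(markers=list(table.markers), samples=list(table.samples), calls=calls)


def inject_artifacts(founders: FounderSet, cfg: SimConfig) -> SimulatedDataset:
    """Turn the founder truth into the observed dataset.

    (1) Clone groups: each group copies one founder's rows ``size - 1``
    times under new accession ids (a mislabeled group gets ids that carry no
    trace of the founder), recorded in the clone map.  (2) Null alleles:
    the designated null size is removed from every visible SSR call; a
    diploid null homozygote becomes a missing call.  (3) Platform pair: the
    assay (KASP) table carries the true calls; the discovery (GBS) table
    receives heterozygote-dropout and false-heterozygote cell errors at the
    configured rates plus whole-row sample swaps, every alteration logged
    with the mismatch class it realizes against the assay calls.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ssr, snp, truth = founders.ssr, founders.snp, founders.truth

    founder_ids = list(ssr.sample_ids)
    if len(cfg.clone_groups) > len(founder_ids):
        raise ValueError("more clone groups than founders")
    donors = rng.choice(len(founder_ids), size=len(cfg.clone_groups), replace=False)

    samples = list(ssr.samples)
    ssr_calls = [list(r) for r in ssr.calls]
    snp_samples = list(snp.samples)
    snp_calls = [list(r) for r in snp.calls]
    clone_map = dict(truth.clone_map)
    mislabels: list[str] = []
    true_ssr = dict(truth.true_ssr)
    for g, ((size, mislabel), di) in enumerate(zip(cfg.clone_groups, donors)):
        donor_id = founder_ids[di]
        donor_meta = ssr.samples[di]
        for c in range(size - 1):
            sid = f"MIX-{g + 1:03d}{chr(ord('a') + c)}" if mislabel else f"{donor_id}-dup{c + 1}"
            meta = SampleMeta(sid, donor_meta.population, donor_meta.sex, donor_meta.ploidy)
            samples.append(meta)
            ssr_calls.append(list(ssr.calls[di]))
            snp_samples.append(meta)
            snp_calls.append(list(snp.calls[di]))
            clone_map[sid] = donor_id
            true_ssr[sid] = dict(truth.true_ssr[donor_id])
            if mislabel:
                mislabels.append(sid)

    full_ssr = GenotypeTable(markers=list(ssr.markers), samples=samples, calls=ssr_calls)
    masked_ssr = _mask_nulls(full_ssr, truth)

    kasp = GenotypeTable(markers=list(snp.markers), samples=snp_samples, calls=snp_calls)
    gbs_calls = [list(r) for r in snp_calls]
    errors: list[tuple[str, str, str, str]] = []
    sids = [s.sample_id for s in snp_samples]

    # whole-row swaps first, then cell errors on unswapped rows
    n_swap_pairs = min(int(round(cfg.sample_swap * len(sids) / 2.0)), len(sids) // 2)
    swapped: list[str] = []
    if n_swap_pairs:
        pick = rng.choice(len(sids), size=2 * n_swap_pairs, replace=False)
        for a, b in zip(pick[::2], pick[1::2]):
            gbs_calls[a], gbs_calls[b] = gbs_calls[b], gbs_calls[a]
            swapped += [sids[a], sids[b]]
    swapped_set = set(swapped)
    for i, sid in enumerate(sids):
        if sid in swapped_set:
            continue
        for j, m in enumerate(snp.markers):
            call = gbs_calls[i][j]
            if call.missing:
                continue
            if call.het and rng.random() < cfg.het_dropout:
                gbs_calls[i][j] = SNPCall.XX if rng.random() < 0.5 else SNPCall.YY
                errors.append((sid, m.name, "het_dropout", "hom_to_het"))
            elif call.hom and rng.random() < cfg.false_het:
                gbs_calls[i][j] = SNPCall.XY
                errors.append((sid, m.name, "false_het", "het_to_hom"))
    # log realized mismatch classes for swapped rows
    from .panel_qc import classify_mismatch

    for i, sid in enumerate(sids):
        if sid not in swapped_set:
            continue
        for j, m in enumerate(snp.markers):
            g, k = gbs_calls[i][j], snp_calls[i][j]
            if g.missing or k.missing:
                continue
            cls = classify_mismatch(g, k)
            if cls is not None:
                errors.append((sid, m.name, "sample_swap", cls))

    gbs = GenotypeTable(markers=list(snp.markers), samples=list(snp_samples), calls=gbs_calls)
    new_truth = replace_truth(
        truth,
        true_ssr=true_ssr,
        clone_map=clone_map,
        mislabels=tuple(mislabels),
        platform_errors=errors,
        swapped_samples=tuple(sorted(set(swapped))),
    )
    return SimulatedDataset(ssr=masked_ssr, gbs=gbs, kasp=kasp, truth=new_truth)


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Founders plus artifacts in one call (the default simulated world)."""
    cfg = cfg or SimConfig()
    return inject_artifacts(simulate_pools(cfg), cfg)
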