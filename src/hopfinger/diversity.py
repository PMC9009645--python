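"""Diversity statistics and null-allele frequency estimation.

Implements the genotype-richness and diversity summaries used to describe a
clonal germplasm collection — Simpson's index over multilocus-genotype (MLG)
counts, Nei's (1978) unbiased gene diversity, E5 evenness, Hurlbert
rarefaction of the expected MLG count — plus per-locus allelic/genotypic
tables, polymorphism information content, and an EM estimator of null-allele
frequency in diploids under Hardy-Weinberg equilibrium.

Conventions that matter downstream:

* Simpson's index is the *uncorrected* ``1 - sum(p_i**2)``: a group of N
  all-distinct genotypes scores ``1 - 1/N``, matching how such collections
  are conventionally reported.
* Genotypic statistics treat the unordered allele multiset at a locus as the
  category; missing calls are excluded from that locus's genotype counts.
* Rarefaction size defaults to the smallest group's sample count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .io import GenotypeTable, MarkerKind, SNPCall, SSRCall, allele_catalog

__all__ = [
    "simpson_index",
    "nei_gene_diversity",
    "evenness_e5",
    "shannon",
    "rarefied_emlg",
    "pic",
    "LocusStats",
    "locus_table",
    "PopSummary",
    "pop_summary",
    "NullAlleleEstimate",
    "null_allele_em",
]


def _freqs(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("counts must be non-empty with positive total")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr / arr.sum()


def simpson_index(counts: Sequence[float]) -> float:
    """Uncorrected Simpson diversity ``lambda = 1 - sum((n_i/N)**2)``.

    The probability that two genotypes drawn at random (with replacement)
    are different.
    """
    p = _freqs(counts)
    return 1.0 - float(np.sum(p**2))


def nei_gene_diversity(allele_counts: Sequence[float]) -> float:
    """Nei's 1978 unbiased gene diversity from allele *copy* counts.

    ``h = n/(n-1) * (1 - sum(p_i**2))`` with ``n`` the total number of allele
    copies sampled.
    """
    arr = np.asarray(list(allele_counts), dtype=float)
    n = arr.sum()
    if n < 2:
        raise ValueError("need at least 2 allele copies")
    p = arr / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def shannon(counts: Sequence[float]) -> float:
    p = _freqs(counts)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def evenness_e5(counts: Sequence[float]) -> float:
    """E5 evenness ``(G - 1)/(e**H - 1)`` (G = inverse Simpson, H = Shannon).

    Defined as 1 for a single category (the 0/0 degenerate case): a
    distribution with one class is trivially even.
    """
    p = _freqs(counts)
    if np.count_nonzero(p) <= 1:
        return 1.0
    g = 1.0 / float(np.sum(p**2))
    h = shannon(counts)
    return (g - 1.0) / (math.expm1(h))


def _log_comb(n: float, k: float) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def rarefied_emlg(mlg_counts: Sequence[int], n: int) -> float:
    """Hurlbert-rarefied expected number of distinct MLGs in a subsample.

    ``E[MLG] = sum_g [1 - C(N - N_g, n) / C(N, n)]`` for a subsample of size
    ``n`` drawn without replacement from ``N = sum(N_g)`` samples.  Binomials
    are evaluated in log space.
    """
    counts = [int(c) for c in mlg_counts if c > 0]
    big_n = sum(counts)
    if not 1 <= n <= big_n:
        raise ValueError(f"rarefaction size must be in [1, {big_n}]")
    total = 0.0
    log_denom = _log_comb(big_n, n)
    for c in counts:
        if big_n - c < n:
            total += 1.0
        else:
            total += 1.0 - math.exp(_log_comb(big_n - c, n) - log_denom)
    return total


def pic(freqs: Sequence[float]) -> float:
    """Polymorphism information content of a marker.

    ``PIC = 1 - sum(p_i**2) - sum_{i<j} 2 p_i**2 p_j**2``.
    """
    p = np.asarray(list(freqs), dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("allele frequencies must be a simplex")
    sum_sq = float(np.sum(p**2))
    sum_4 = float(np.sum(p**4))
    cross = (sum_sq**2 - sum_4)  # = sum_{i != j} p_i^2 p_j^2
    return 1.0 - sum_sq - cross


# ---------------------------------------------------------------------------
# per-locus table


@dataclass(frozen=True)
class LocusStats:
    """Allelic and genotypic summary for one marker (one row of a per-locus
    table): counts, Simpson's lambda, Nei's unbiased diversity, E5 evenness,
    and the observed allele size range for SSRs."""

    marker: str
    n_alleles: int
    n_genotypes: int
    simpson_allelic: float
    simpson_genotypic: float
    nei_allelic: float
    nei_genotypic: float
    evenness_allelic: float
    evenness_genotypic: float
    allele_range: tuple[int, int] | None
    defined: bool = True


def _genotype_counts(table: GenotypeTable, marker: str) -> Counter:
    counts: Counter = Counter()
    for call in table.column(marker):
        if isinstance(call, SSRCall):
            if not call.missing:
                counts[call.alleles] += 1
        elif not call.missing:
            counts[call.value] += 1
    return counts


def locus_table(table: GenotypeTable) -> list[LocusStats]:
    """Per-marker allelic and genotypic diversity statistics.

    Allelic statistics use allele copy counts over non-missing calls;
    genotypic statistics use counts of distinct genotype states (the allele
    multiset as the category).  An all-missing marker is emitted flagged
    undefined with zeroed statistics.
    """
    out = []
    for m in table.markers:
        cat = allele_catalog(table, m.name)
        geno = _genotype_counts(table, m.name)
        if not cat:
            out.append(LocusStats(m.name, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, None, defined=False))
            continue
        allele_counts = [c for _, c in cat]
        sizes = [a for a, _ in cat if isinstance(a, int)]
        rng = (min(sizes), max(sizes)) if sizes else None
        nei_a = nei_gene_diversity(allele_counts) if sum(allele_counts) >= 2 else 0.0
        nei_g = (
            nei_gene_diversity(list(geno.values())) if sum(geno.values()) >= 2 else 0.0
        )
        out.append(
            LocusStats(
                marker=m.name,
                n_alleles=len(cat),
                n_genotypes=len(geno),
                simpson_allelic=simpson_index(allele_counts),
                simpson_genotypic=simpson_index(list(geno.values())),
                nei_allelic=nei_a,
                nei_genotypic=nei_g,
                evenness_allelic=evenness_e5(allele_counts),
                evenness_genotypic=evenness_e5(list(geno.values())),
                allele_range=rng,
            )
        )
    return out


# ---------------------------------------------------------------------------
# population summary


@dataclass(frozen=True)
class PopSummary:
    """Group-level richness/diversity row: sample count, MLG count, rarefied
    expected MLG count, Simpson's lambda over MLG frequencies, mean Nei
    diversity over loci, and E5 evenness over MLG frequencies."""

    population: str
    n: int
    mlg: int
    emlg: float
    simpson: float
    nei: float
    evenness: float


def mlg_counts(table: GenotypeTable) -> list[int]:
    """Multiplicities of exact-match multilocus genotypes in a table."""
    from .identity import assign_mlg

    assignment = assign_mlg(table)
    return sorted(Counter(assignment.mapping.values()).values(), reverse=True)


def pop_summary(table: GenotypeTable, grouping: dict[str, str] | None = None,
                rarefaction_n: int | None = None,
                include_total: bool = True) -> list[PopSummary]:
    """Per-population richness and diversity summary.

    ``grouping`` maps sample_id -> group label; by default the sample
    metadata's population is used.  eMLG is rarefied to ``rarefaction_n``
    (default: the smallest group's n).  Nei's diversity is the mean of the
    per-locus unbiased allelic diversities within the group.
    """
    if grouping is None:
        grouping = {s.sample_id: s.population.value for s in table.samples}
    groups: dict[str, list[str]] = {}
    for sid in table.sample_ids:
        groups.setdefault(grouping[sid], []).append(sid)
    if not groups:
        raise ValueError("no groups")
    smallest = min(len(v) for v in groups.values())
    rare_n = rarefaction_n if rarefaction_n is not None else smallest

    def summarize(label: str, ids: list[str]) -> PopSummary:
        sub = table.subset_samples(ids)
        counts = mlg_counts(sub)
        neis = [
            row.nei_allelic for row in locus_table(sub) if row.defined
        ]
        return PopSummary(
            population=label,
            n=len(ids),
            mlg=len(counts),
            emlg=rarefied_emlg(counts, min(rare_n, len(ids))),
            simpson=simpson_index(counts),
            nei=float(np.mean(neis)) if neis else 0.0,
            evenness=evenness_e5(counts),
        )

    out = [summarize(label, ids) for label, ids in sorted(groups.items())]
    if include_total and len(groups) > 1:
        out.append(summarize("Total", table.sample_ids))
    return out


# ---------------------------------------------------------------------------
# null-allele EM


@dataclass(frozen=True)
class NullAlleleEstimate:
    """EM estimate of the null-allele frequency at one marker, with a
    bootstrap-percentile confidence interval."""

    marker: str
    freq: float
    ci: tuple[float, float]
    n: int
    converged: bool


def _em_categories(calls: Iterable[SSRCall], include_blanks: bool):
    """Collapse diploid calls into het pairs, apparent-homozygote counts and
    blank count for the EM."""
    hets: Counter = Counter()
    homs: Counter = Counter()
    blanks = 0
    for call in calls:
        if call.missing:
            blanks += 1
            continue
        alleles = call.distinct
        if len(alleles) == 1:
            homs[alleles[0]] += 1
        elif len(alleles) == 2:
            hets[alleles] += 1
        else:
            raise ValueError("null-allele EM expects diploid calls (<= 2 alleles)")
    if not include_blanks:
        blanks = 0
    return hets, homs, blanks


def _em_fit(hets: Counter, homs: Counter, blanks: int,
            tol: float = 1e-8, max_iter: int = 10_000):
    alleles = sorted(set(a for pair in hets for a in pair) | set(homs))
    n_ind = sum(hets.values()) + sum(homs.values()) + blanks
    if n_ind == 0 or not alleles:
        return 0.0, {}, True
    if not hets and not blanks and len(homs) == 1:
        # monomorphic, no blanks: the null frequency is not identifiable away
        # from zero; the EM fixed point is r = 0
        return 0.0, {next(iter(homs)): 1.0}, True
    # initialize from visible copy counts, a pinch of null mass
    copies = Counter()
    for (a, b), c in hets.items():
        copies[a] += c
        copies[b] += c
    for a, c in homs.items():
        copies[a] += 2 * c
    total0 = sum(copies.values())
    r = 0.1 if (blanks or homs) else 0.0
    p = {a: (1.0 - r) * copies[a] / total0 for a in alleles}
    converged = False
    for _ in range(max_iter):
        new_copies = {a: 0.0 for a in alleles}
        null_copies = 2.0 * blanks
        for (a, b), c in hets.items():
            new_copies[a] += c
            new_copies[b] += c
        for a, c in homs.items():
            denom = p[a] ** 2 + 2.0 * p[a] * r
            w = 1.0 if denom <= 0 else p[a] ** 2 / denom  # P(true hom | apparent hom)
            new_copies[a] += c * (1.0 + w)
            null_copies += c * (1.0 - w)
        total = 2.0 * n_ind
        new_p = {a: v / total for a, v in new_copies.items()}
        new_r = null_copies / total
        delta = abs(new_r - r) + sum(abs(new_p[a] - p[a]) for a in alleles)
        p, r = new_p, new_r
        if delta < tol:
            converged = True
            break
    return r, p, converged


def null_em_loglik(hets: Counter, homs: Counter, blanks: int,
                   p: dict, r: float) -> float:
    """Multinomial log-likelihood of the observed phenotype classes under
    HWE with a null allele (used to check EM monotonicity)."""
    ll = 0.0
    for (a, b), c in hets.items():
        ll += c * math.log(max(2.0 * p[a] * p[b], 1e-300))
    for a, c in homs.items():
        ll += c * math.log(max(p[a] ** 2 + 2.0 * p[a] * r, 1e-300))
    if blanks:
        ll += blanks * math.log(max(r**2, 1e-300))
    return ll


def null_allele_em(table: GenotypeTable, marker: str, *,
                   include_blanks: bool = True, min_n: int = 20,
                   ci_reps: int = 1000, ci_level: float = 0.95,
                   seed: int = 0) -> NullAlleleEstimate:
    """EM null-allele frequency at one SSR marker, diploid samples only.

    Under HWE with a null allele of frequency ``r``, an apparent homozygote
    ``A/A`` is a mixture of true homozygotes and ``A/null`` heterozygotes,
    and (optionally) a blank call is a null homozygote.  The E-step
    apportions apparent homozygotes by the current frequencies; the M-step
    re-estimates allele frequencies from expected copy counts; iteration
    stops when the total frequency change falls below 1e-8 (or at 10^4
    iterations).  The CI is a nonparametric bootstrap (percentile) over
    individuals.
    """
    if marker not in table.marker_names:
        raise KeyError(f"unknown marker: {marker}")
    sub = table.diploid_subset()
    calls = [c for c in sub.column(marker)]
    used = [c for c in calls if include_blanks or not c.missing]
    if len(used) < min_n:
        raise ValueError(
            f"marker {marker}: {len(used)} diploid samples < required {min_n}"
        )
    hets, homs, blanks = _em_categories(calls, include_blanks)
    r, _, converged = _em_fit(hets, homs, blanks)

    if ci_reps > 0:
        rng = np.random.default_rng(seed)
        cats: list[SSRCall] = [c for c in calls if include_blanks or not c.missing]
        boots = np.empty(ci_reps)
        for k in range(ci_reps):
            idx = rng.integers(0, len(cats), size=len(cats))
            h, ho, bl = _em_categories([cats[i] for i in idx], include_blanks)
            boots[k] = _em_fit(h, ho, bl)[0]
        alpha = (1.0 - ci_level) / 2.0
        ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1.0 - alpha)))
        ci = (min(ci[0], r), max(ci[1], r))
    else:
        ci = (r, r)
    return NullAlleleEstimate(marker=marker, freq=float(r), ci=ci,
                              n=len(used), converged=converged)
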