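"""Allele-sharing parentage exclusion and the dominant pseudo-locus export.

A candidate parent is excluded when it shares no allele with the putative
offspring at some locus where both are scored — the Mendelian requirement
that an offspring inherit at least one allele per locus from each true
parent, which holds at any ploidy under bivalent or random-chromosome
segregation.  Null alleles violate the assumption (a heterozygote carrying a
null looks homozygous), so a nulls-aware mode can discount mismatches at
loci with an appreciable estimated null frequency.

For external likelihood software built around dominant diploid markers, a
polyploid codominant table can be recoded as presence/absence at one
pseudo-locus per (marker, allele): 1 = allele present, 2 = absent, 0 =
missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeTable, MarkerKind, SSRCall, allele_catalog

__all__ = [
    "DominantMatrix",
    "rodzen_transform",
    "CompatibilityReport",
    "parent_offspring_compatibility",
    "exclusion_scan",
    "export_dominant",
    "read_dominant",
]

PRESENT, ABSENT, MISSING = 1, 2, 0


@dataclass(frozen=True)
class DominantMatrix:
    """Samples x pseudo-loci presence/absence grid (1 present / 2 absent /
    0 missing); pseudo-locus names are ``<marker>.<allele>``."""

    sample_ids: tuple[str, ...]
    locus_names: tuple[str, ...]
    codes: np.ndarray  # int8, shape (samples, pseudo-loci)


def rodzen_transform(table: GenotypeTable) -> DominantMatrix:
    """Recode a (possibly polyploid) codominant SSR table as dominant loci.

    Each catalog allele of each marker becomes one pseudo-locus; a sample
    scores 1 there if its call carries the allele, 2 if its call is present
    but lacks it, and 0 at all of a marker's pseudo-loci when the call is
    missing.
    """
    names: list[str] = []
    columns: list[np.ndarray] = []
    n = table.n_samples
    for m in table.markers:
        if m.kind is not MarkerKind.SSR:
            raise ValueError("dominant transform is defined for SSR tables")
        catalog = [a for a, _ in allele_catalog(table, m.name)]
        col_calls = table.column(m.name)
        for allele in catalog:
            names.append(f"{m.name}.{allele}")
            col = np.zeros(n, dtype=np.int8)
            for i, call in enumerate(col_calls):
                if call.missing:
                    col[i] = MISSING
                else:
                    col[i] = PRESENT if allele in call.alleles else ABSENT
            columns.append(col)
    codes = np.column_stack(columns) if columns else np.zeros((n, 0), dtype=np.int8)
    return DominantMatrix(
        sample_ids=tuple(table.sample_ids),
        locus_names=tuple(names),
        codes=codes,
    )


@dataclass(frozen=True)
class CompatibilityReport:
    """Allele-sharing check of one candidate parent against one offspring.

    ``mismatch_loci`` lists markers where both are scored yet share no
    allele; the pair is compatible when that count is within the tolerance.
    ``shared_total`` sums distinct shared alleles over informative loci
    (used to rank equally-compatible candidates)."""

    offspring: str
    candidate: str
    mismatch_loci: tuple[str, ...]
    n_informative: int
    shared_total: int
    compatible: bool
    is_clone: bool = False
    ignored_null_loci: tuple[str, ...] = ()


def parent_offspring_compatibility(table: GenotypeTable, offspring: str,
                                   candidate: str, tolerance: int = 0,
                                   null_loci: set[str] | None = None) -> CompatibilityReport:
    """Score a candidate parent by per-locus allele sharing.

    A locus is informative when both calls are non-missing; it mismatches
    when the allele-set intersection there is empty.  Loci named in
    ``null_loci`` are excluded from the mismatch list (but still counted as
    informative) to absorb suspected null-allele artifacts.
    """
    off_row = table.row(offspring)
    cand_row = table.row(candidate)
    null_loci = null_loci or set()
    mismatches: list[str] = []
    ignored: list[str] = []
    informative = 0
    shared_total = 0
    identical = True
    for m, oc, cc in zip(table.markers, off_row, cand_row):
        if not isinstance(oc, SSRCall):
            raise ValueError("parentage exclusion is defined for SSR tables")
        if oc.missing or cc.missing:
            if not (oc.missing and cc.missing):
                identical = False
            continue
        informative += 1
        shared = set(oc.alleles) & set(cc.alleles)
        shared_total += len(shared)
        if oc.distinct != cc.distinct:
            identical = False
        if not shared:
            if m.name in null_loci:
                ignored.append(m.name)
            else:
                mismatches.append(m.name)
    if informative == 0:
        raise ValueError(
            f"no informative loci between {offspring} and {candidate}"
        )
    return CompatibilityReport(
        offspring=offspring,
        candidate=candidate,
        mismatch_loci=tuple(mismatches),
        n_informative=informative,
        shared_total=shared_total,
        compatible=len(mismatches) <= tolerance,
        is_clone=identical,
        ignored_null_loci=tuple(ignored),
    )


def exclusion_scan(table: GenotypeTable, offspring: str,
                   candidates: list[str] | None = None, tolerance: int = 0,
                   null_freqs: dict[str, float] | None = None,
                   null_threshold: float = 0.05) -> list[CompatibilityReport]:
    """Score every candidate parent for one offspring, best first.

    Candidates default to all other samples.  With ``null_freqs`` (marker ->
    estimated null-allele frequency, e.g. from the diversity module's EM),
    mismatches at loci whose estimate exceeds ``null_threshold`` are ignored.
    Sorted by (mismatch count, shared alleles descending, candidate id).
    """
    if candidates is None:
        candidates = [s for s in table.sample_ids if s != offspring]
    if not candidates:
        raise ValueError("no candidates")
    null_loci = (
        {m for m, f in (null_freqs or {}).items() if f > null_threshold}
        if null_freqs
        else set()
    )
    reports = [
        parent_offspring_compatibility(table, offspring, c, tolerance, null_loci)
        for c in candidates
    ]
    reports.sort(key=lambda r: (len(r.mismatch_loci), -r.shared_total, r.candidate))
    return reports


def export_dominant(matrix: DominantMatrix, path) -> None:
    """Write the dominant matrix as whitespace-delimited text.

    First line: pseudo-locus names; then one row per sample, sample id first,
    codes in {0, 1, 2}.
    """
    with open(path, "w") as fh:
        fh.write("sample_id " + " ".join(matrix.locus_names) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.codes):
            fh.write(sid + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_dominant(path) -> DominantMatrix:
    """Read a file written by :func:`export_dominant` (round-trip helper)."""
    with open(path) as fh:
        header = fh.readline().split()
        locus_names = tuple(header[1:])
        sample_ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sample_ids.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    codes = np.asarray(rows, dtype=np.int8) if rows else np.zeros((0, len(locus_names)), dtype=np.int8)
    return DominantMatrix(tuple(sample_ids), locus_names, codes)
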