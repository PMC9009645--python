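"""Genotype tables for mixed-ploidy SSR and bi-allelic SNP data.

The central container is :class:`GenotypeTable`: an ordered samples x markers
grid of calls, homogeneous in marker kind per table.  SSR calls are multisets
of fragment sizes in bp (1-4 alleles; allele dosage in polyploids is usually
unknown, so the distinct-set representation is the default).  SNP calls are
the four KASP/GBS cluster states ``X:X`` / ``X:Y`` / ``Y:Y`` / missing.

Readers and writers cover the plain-CSV dialect used throughout the package
and the diploid Genepop export consumed by null-allele estimation tools.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MarkerKind",
    "MarkerDef",
    "Population",
    "Sex",
    "SampleMeta",
    "SSRCall",
    "SNPCall",
    "GenotypeTable",
    "GenotypeParseError",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_defs",
    "write_genepop",
    "allele_catalog",
]

MAX_PLOIDY = 4


class GenotypeParseError(ValueError):
    """Malformed genotype input, reported with row/column context."""


class MarkerKind(str, enum.Enum):
    SSR = "SSR"
    SNP = "SNP"


class Population(str, enum.Enum):
    CULT = "CULT"
    WNA = "WNA"
    UNKNOWN = "UNKNOWN"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class MarkerDef:
    """A marker definition: an SSR primer pair or a bi-allelic SNP assay.

    ``motif_length`` is the repeat-unit length in bp (SSR only; it is the
    Bruvo-distance ``replen``).  ``expected_range`` is the expected fragment
    size window in bp.  ``alleles`` holds the two nucleotide labels of a SNP.
    """

    name: str
    kind: MarkerKind = MarkerKind.SSR
    motif_length: float | None = None
    expected_range: tuple[int, int] | None = None
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind is MarkerKind.SSR and self.motif_length is not None:
            if self.motif_length <= 0:
                raise ValueError(f"marker {self.name}: motif_length must be > 0")
        if self.expected_range is not None:
            lo, hi = self.expected_range
            if not lo < hi:
                raise ValueError(f"marker {self.name}: expected_range min must be < max")


@dataclass(frozen=True)
class SampleMeta:
    """Per-accession metadata: repository id, gene pool, sex, ploidy."""

    sample_id: str
    population: Population = Population.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    ploidy: int | None = None

    def __post_init__(self) -> None:
        if self.ploidy is not None and self.ploidy not in (2, 3, 4):
            raise ValueError(f"sample {self.sample_id}: ploidy must be 2, 3 or 4")


@dataclass(frozen=True)
class SSRCall:
    """A microsatellite call: a sorted multiset of 1-4 fragment sizes (bp).

    An empty allele tuple is the missing call.  Duplicate sizes are legal
    (known dosage, e.g. from a simulator); scoring software normally reports
    the distinct set only.
    """

    alleles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.alleles) > MAX_PLOIDY:
            raise ValueError(f"SSR call with {len(self.alleles)} alleles (max {MAX_PLOIDY})")
        if any(a <= 0 for a in self.alleles):
            raise ValueError("SSR allele sizes must be positive integers")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def missing(self) -> bool:
        return not self.alleles

    @property
    def distinct(self) -> tuple[int, ...]:
        """The distinct-set view (unknown-dosage representation)."""
        return tuple(sorted(set(self.alleles)))

    def __str__(self) -> str:
        return ":".join(str(a) for a in self.alleles)


class SNPCall(str, enum.Enum):
    """Bi-allelic cluster call (X = reference-style allele, Y = alternate)."""

    XX = "XX"
    XY = "XY"
    YY = "YY"
    MISSING = ""

    @property
    def missing(self) -> bool:
        return self is SNPCall.MISSING

    @property
    def het(self) -> bool:
        return self is SNPCall.XY

    @property
    def hom(self) -> bool:
        return self in (SNPCall.XX, SNPCall.YY)

    def dosage(self) -> tuple[float, float] | None:
        """Within-individual allele frequency vector (X, Y), or None if missing."""
        return _SNP_DOSAGE.get(self)


_SNP_DOSAGE = {
    SNPCall.XX: (1.0, 0.0),
    SNPCall.XY: (0.5, 0.5),
    SNPCall.YY: (0.0, 1.0),
}

_SNP_TOKENS = {
    "XX": SNPCall.XX,
    "XY": SNPCall.XY,
    "YX": SNPCall.XY,
    "YY": SNPCall.YY,
    "X:X": SNPCall.XX,
    "X:Y": SNPCall.XY,
    "Y:X": SNPCall.XY,
    "Y:Y": SNPCall.YY,
    "": SNPCall.MISSING,
    "NA": SNPCall.MISSING,
}


@dataclass
class GenotypeTable:
    """Samples x markers genotype grid with metadata.

    ``calls[i][j]`` is the call of sample ``i`` at marker ``j``; the call type
    (:class:`SSRCall` or :class:`SNPCall`) must match ``markers[j].kind``.
    """

    markers: list[MarkerDef]
    samples: list[SampleMeta]
    calls: list[list[object]] = field(repr=False)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(self.calls) != len(self.samples):
            raise ValueError("call grid row count != sample count")
        for i, row in enumerate(self.calls):
            if len(row) != len(self.markers):
                raise ValueError(f"row {i} has {len(row)} calls for {len(self.markers)} markers")
            for j, call in enumerate(row):
                kind = self.markers[j].kind
                ok = isinstance(call, SSRCall) if kind is MarkerKind.SSR else isinstance(call, SNPCall)
                if not ok:
                    raise ValueError(
                        f"call at sample {self.samples[i].sample_id}, marker "
                        f"{self.markers[j].name} does not match marker kind {kind.value}"
                    )

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample: {sample_id}") from None

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker: {name}") from None

    def call(self, sample_id: str, marker: str):
        return self.calls[self.sample_index(sample_id)][self.marker_index(marker)]

    def column(self, marker: str) -> list:
        j = self.marker_index(marker)
        return [row[j] for row in self.calls]

    def row(self, sample_id: str) -> list:
        return list(self.calls[self.sample_index(sample_id)])

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeTable(
            markers=list(self.markers),
            samples=[self.samples[i] for i in idx],
            calls=[list(self.calls[i]) for i in idx],
        )

    def subset_markers(self, names: Sequence[str]) -> "GenotypeTable":
        idx = [self.marker_index(m) for m in names]
        return GenotypeTable(
            markers=[self.markers[j] for j in idx],
            samples=list(self.samples),
            calls=[[row[j] for j in idx] for row in self.calls],
        )

    def diploid_subset(self, unknown_as_diploid: bool = True) -> "GenotypeTable":
        keep = [
            s.sample_id
            for s in self.samples
            if s.ploidy == 2 or (unknown_as_diploid and s.ploidy is None)
        ]
        return self.subset_samples(keep)

    def to_dataframe(self) -> pd.DataFrame:
        """Render as the genotype CSV dialect (strings, '' for missing)."""
        recs = []
        for meta, row in zip(self.samples, self.calls):
            rec = {
                "sample_id": meta.sample_id,
                "population": meta.population.value,
                "sex": meta.sex.value,
                "ploidy": "" if meta.ploidy is None else str(meta.ploidy),
            }
            for m, call in zip(self.markers, row):
                rec[m.name] = call.value if isinstance(call, SNPCall) else str(call)
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# parsing


def parse_ssr_cell(text: str, where: str = "") -> SSRCall:
    text = text.strip()
    if text in ("", "NA"):
        return SSRCall(())
    parts = text.split(":")
    if len(parts) > MAX_PLOIDY:
        raise GenotypeParseError(f"{where}: {len(parts)} alleles in one call (max {MAX_PLOIDY})")
    try:
        alleles = tuple(int(p) for p in parts)
    except ValueError:
        raise GenotypeParseError(f"{where}: non-integer SSR allele in {text!r}") from None
    if any(a <= 0 for a in alleles):
        raise GenotypeParseError(f"{where}: non-positive allele size in {text!r}")
    return SSRCall(alleles)


def parse_snp_cell(text: str, where: str = "") -> SNPCall:
    token = text.strip().upper()
    try:
        return _SNP_TOKENS[token]
    except KeyError:
        raise GenotypeParseError(f"{where}: unknown SNP token {text!r}") from None


_META_COLUMNS = ("sample_id", "population", "sex", "ploidy")


def read_genotype_table(path, kind: MarkerKind | str = MarkerKind.SSR,
                        markers: Sequence[MarkerDef] | None = None,
                        collapse_dosage: bool = False) -> GenotypeTable:
    """Read the genotype CSV dialect.

    Header: ``sample_id,population,sex,ploidy,<marker1>,...``.  SSR cells are
    colon-separated integer fragment sizes; SNP cells one of XX/XY/YY/'' (NA
    also accepted as missing).  Unknown population/sex values map to UNKNOWN.
    With ``collapse_dosage`` SSR multisets are reduced to their distinct set.
    """
    kind = MarkerKind(kind)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise GenotypeParseError(f"missing metadata columns: {missing_meta}")
    marker_names = [c for c in df.columns if c not in _META_COLUMNS]
    if markers is not None:
        by_name = {m.name: m for m in markers}
        marker_defs = [by_name.get(n, MarkerDef(n, kind)) for n in marker_names]
    else:
        marker_defs = [MarkerDef(n, kind) for n in marker_names]

    samples: list[SampleMeta] = []
    calls: list[list[object]] = []
    for _, rec in df.iterrows():
        sid = str(rec["sample_id"]).strip()
        try:
            pop = Population(str(rec["population"]).strip().upper() or "UNKNOWN")
        except ValueError:
            pop = Population.UNKNOWN
        try:
            sex = Sex(str(rec["sex"]).strip().upper() or "UNKNOWN")
        except ValueError:
            sex = Sex.UNKNOWN
        ploidy_text = str(rec["ploidy"]).strip()
        ploidy = int(ploidy_text) if ploidy_text else None
        samples.append(SampleMeta(sid, pop, sex, ploidy))

        row: list[object] = []
        for name in marker_names:
            where = f"sample {sid}, marker {name}"
            if kind is MarkerKind.SSR:
                call = parse_ssr_cell(str(rec[name]), where)
                if collapse_dosage and not call.missing:
                    call = SSRCall(call.distinct)
            else:
                call = parse_snp_cell(str(rec[name]), where)
            row.append(call)
        calls.append(row)
    return GenotypeTable(markers=marker_defs, samples=samples, calls=calls)


def write_genotype_table(table: GenotypeTable, path) -> None:
    """Write the genotype CSV dialect (inverse of :func:`read_genotype_table`)."""
    table.to_dataframe().to_csv(path, index=False)


def read_marker_defs(path, kind: MarkerKind | str | None = None) -> list[MarkerDef]:
    """Read a marker-definition CSV: ``name,kind,motif_length,range_min,range_max``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, rec in df.iterrows():
        k = MarkerKind(str(rec.get("kind", "") or (kind or "SSR")).upper())
        motif = rec.get("motif_length", "")
        lo, hi = rec.get("range_min", ""), rec.get("range_max", "")
        out.append(
            MarkerDef(
                name=str(rec["name"]).strip(),
                kind=k,
                motif_length=float(motif) if str(motif).strip() else None,
                expected_range=(int(lo), int(hi)) if str(lo).strip() and str(hi).strip() else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genepop export (diploid SSR subset)


def write_genepop(table: GenotypeTable, path, title: str = "hopfinger export") -> None:
    """Write a diploid-only Genepop file with 6-digit allele tokens.

    Cell coding: two alleles concatenate (120:130 -> ``120130``); a single
    visible allele is zero-padded on the left (120 -> ``000120``, the unknown
    second allele); a missing call becomes ``000000``.  Only diploid samples
    (unknown ploidy treated as diploid) are emitted; allele sizes must fit in
    three digits.
    """
    if any(m.kind is not MarkerKind.SSR for m in table.markers):
        raise ValueError("Genepop export is defined for SSR tables only")
    sub = table.diploid_subset()
    lines = [title]
    lines.extend(m.name for m in sub.markers)
    lines.append("Pop")
    for meta, row in zip(sub.samples, sub.calls):
        tokens = []
        for m, call in zip(sub.markers, row):
            alleles = call.distinct
            if len(alleles) > 2:
                raise ValueError(
                    f"sample {meta.sample_id}, marker {m.name}: "
                    f"{len(alleles)} alleles cannot be coded in diploid Genepop"
                )
            if any(a > 999 for a in alleles):
                raise ValueError(
                    f"sample {meta.sample_id}, marker {m.name}: allele > 999 bp "
                    "is unrepresentable in 3-digit Genepop tokens"
                )
            if not alleles:
                tokens.append("000000")
            elif len(alleles) == 1:
                tokens.append(f"000{alleles[0]:03d}")
            else:
                tokens.append(f"{alleles[0]:03d}{alleles[1]:03d}")
        lines.append(f"{meta.sample_id} , " + " ".join(tokens))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# allele catalog


def allele_catalog(table: GenotypeTable, marker: str) -> list[tuple[object, int]]:
    """Distinct alleles at a marker with occurrence counts, sorted ascending.

    Counts are over non-missing calls; each allele copy in a multiset counts
    once per appearance (so a known-dosage duplicate counts twice).  For SNP
    markers the alleles are "X" and "Y" with copy counts.
    """
    j = table.marker_index(marker)
    counter: Counter = Counter()
    for row in table.calls:
        call = row[j]
        if isinstance(call, SSRCall):
            if not call.missing:
                counter.update(call.alleles)
        else:
            d = call.dosage()
            if d is not None:
                for label, dose in zip(("X", "Y"), d):
                    copies = int(round(2 * dose))
                    if copies:
                        counter[label] += copies
    return sorted(counter.items())
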