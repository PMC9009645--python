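"""Multilocus-genotype identity: duplicate detection and marker-set selection.

A multilocus genotype (MLG) is the joint call across the whole marker panel;
accessions sharing an MLG are putative clones, duplicates or mislabels
("synonyms").  This module assigns MLG ids, extracts synonym groups, compares
how two genotyping systems partition the same samples, and selects a minimal
subset of markers that still distinguishes every pair of distinct MLGs (the
set-cover problem behind reduced fingerprinting panels).
"""

from __future__ import annotations

import enum
import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .io import GenotypeTable, SNPCall, SSRCall

__all__ = [
    "MLGPolicy",
    "MLGAssignment",
    "assign_mlg",
    "SynonymGroup",
    "synonym_groups",
    "PanelComparison",
    "compare_panels",
    "MarkerPanelSelection",
    "minimal_marker_set",
]


class MLGPolicy(str, enum.Enum):
    EXACT = "exact"
    MISSING_COMPATIBLE = "missing_compatible"


@dataclass(frozen=True)
class MLGAssignment:
    """sample_id -> mlg_id mapping under a stated missing-data policy.

    mlg ids are deterministic: ``MLG-<k>`` numbered by the lexicographically
    smallest member of each genotype class.  ``flagged`` lists ids of
    MISSING_COMPATIBLE groups whose transitive closure contains two mutually
    incompatible members (identity inferred through an intermediate)."""

    mapping: dict[str, str]
    policy: MLGPolicy
    flagged: frozenset[str] = frozenset()


def _call_key(call) -> tuple:
    if isinstance(call, SSRCall):
        return ("SSR", call.distinct)
    return ("SNP", call.value)


def _compatible(a, b) -> bool:
    if isinstance(a, SSRCall):
        return a.missing or b.missing or a.distinct == b.distinct
    return a.missing or b.missing or a is b


def assign_mlg(table: GenotypeTable, policy: MLGPolicy = MLGPolicy.EXACT) -> MLGAssignment:
    """Group samples into multilocus genotypes.

    EXACT: two samples share an MLG iff every marker call, including missing
    status, is identical (SSR calls compared as distinct allele sets).
    MISSING_COMPATIBLE: a missing call is compatible with anything; groups
    are connected components of the pairwise-compatibility graph, and a
    component containing two mutually incompatible members is flagged.
    """
    ids = table.sample_ids
    if policy is MLGPolicy.EXACT:
        by_key: dict[tuple, list[str]] = defaultdict(list)
        for sid, row in zip(ids, table.calls):
            by_key[tuple(_call_key(c) for c in row)].append(sid)
        classes = sorted(by_key.values(), key=lambda members: min(members))
        mapping = {}
        for k, members in enumerate(classes, start=1):
            for sid in members:
                mapping[sid] = f"MLG-{k}"
        return MLGAssignment(mapping=mapping, policy=policy)

    # MISSING_COMPATIBLE: union-find over compatible pairs
    parent = {sid: sid for sid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = dict(zip(ids, table.calls))
    for a, b in itertools.combinations(ids, 2):
        if all(_compatible(ca, cb) for ca, cb in zip(rows[a], rows[b])):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    components: dict[str, list[str]] = defaultdict(list)
    for sid in ids:
        components[find(sid)].append(sid)
    classes = sorted(components.values(), key=lambda members: min(members))
    mapping, flagged = {}, set()
    for k, members in enumerate(classes, start=1):
        mlg = f"MLG-{k}"
        for sid in members:
            mapping[sid] = mlg
        for a, b in itertools.combinations(members, 2):
            if not all(_compatible(ca, cb) for ca, cb in zip(rows[a], rows[b])):
                flagged.add(mlg)
                break
    return MLGAssignment(mapping=mapping, policy=policy, flagged=frozenset(flagged))


@dataclass(frozen=True)
class SynonymGroup:
    """A set of >= 2 accessions sharing one multilocus genotype."""

    group_name: str
    members: frozenset[str]


def synonym_groups(assignment: MLGAssignment) -> list[SynonymGroup]:
    """All MLGs with >= 2 members, deterministically named.

    The group name is ``<smallest member>_syn<k>`` with groups ordered by
    their lexicographically smallest member.
    """
    by_mlg: dict[str, set[str]] = defaultdict(set)
    for sid, mlg in assignment.mapping.items():
        by_mlg[mlg].add(sid)
    multi = sorted(
        (members for members in by_mlg.values() if len(members) >= 2),
        key=lambda m: min(m),
    )
    return [
        SynonymGroup(group_name=f"{min(members)}_syn{k}", members=frozenset(members))
        for k, members in enumerate(multi, start=1)
    ]


@dataclass(frozen=True)
class PanelComparison:
    """How two genotyping systems partition the same samples.

    ``merged_only_in_b``: sample pairs one MLG in panel B but distinguished
    by panel A (B under-splits, e.g. a SNP panel collapsing wild accessions);
    ``split_only_in_b`` is the converse."""

    groups_a: tuple[SynonymGroup, ...]
    groups_b: tuple[SynonymGroup, ...]
    merged_only_in_b: tuple[tuple[str, str], ...]
    split_only_in_b: tuple[tuple[str, str], ...]
    shared_samples: tuple[str, ...]


def compare_panels(table_a: GenotypeTable, table_b: GenotypeTable,
                   policy: MLGPolicy = MLGPolicy.EXACT) -> PanelComparison:
    """Compare synonym structure of two panels over their shared samples."""
    shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    only_a = sorted(set(table_a.sample_ids) - set(shared))
    only_b = sorted(set(table_b.sample_ids) - set(shared))
    if only_a or only_b:
        warnings.warn(
            f"samples present in one panel only are excluded "
            f"(A-only: {len(only_a)}, B-only: {len(only_b)})",
            stacklevel=2,
        )
    if len(shared) < 2:
        raise ValueError("need at least 2 shared samples to compare panels")
    sub_a, sub_b = table_a.subset_samples(shared), table_b.subset_samples(shared)
    asg_a, asg_b = assign_mlg(sub_a, policy), assign_mlg(sub_b, policy)
    merged_b, split_b = [], []
    for x, y in itertools.combinations(sorted(shared), 2):
        same_a = asg_a.mapping[x] == asg_a.mapping[y]
        same_b = asg_b.mapping[x] == asg_b.mapping[y]
        if same_b and not same_a:
            merged_b.append((x, y))
        elif same_a and not same_b:
            split_b.append((x, y))
    return PanelComparison(
        groups_a=tuple(synonym_groups(asg_a)),
        groups_b=tuple(synonym_groups(asg_b)),
        merged_only_in_b=tuple(merged_b),
        split_only_in_b=tuple(split_b),
        shared_samples=tuple(shared),
    )


# ---------------------------------------------------------------------------
# minimal discriminating marker set


class SelectionMode(str, enum.Enum):
    EXACT = "exact"
    GREEDY = "greedy"


@dataclass(frozen=True)
class MarkerPanelSelection:
    """A marker subset that distinguishes every pair of samples, with a
    certificate naming, for each pair, one selected marker where the two
    calls are non-missing and different."""

    selected: tuple[str, ...]
    certificate: dict[tuple[str, str], str] = field(hash=False)
    exact: bool = True


def _pair_masks(table: GenotypeTable) -> tuple[list[int], list[tuple[str, str]]]:
    """Per-marker bitmask of which sample pairs the marker distinguishes.

    A marker distinguishes a pair only when both calls are non-missing and
    unequal (missing data cannot certify a difference)."""
    ids = table.sample_ids
    pairs = list(itertools.combinations(range(len(ids)), 2))
    pair_ids = [(ids[i], ids[j]) for i, j in pairs]
    masks = []
    for j in range(table.n_markers):
        col = [row[j] for row in table.calls]
        mask = 0
        for bit, (a, b) in enumerate(pairs):
            ca, cb = col[a], col[b]
            if ca.missing or cb.missing:
                continue
            if _call_key(ca) != _call_key(cb):
                mask |= 1 << bit
        masks.append(mask)
    return masks, pair_ids


def minimal_marker_set(table: GenotypeTable,
                       mode: SelectionMode = SelectionMode.EXACT,
                       max_exact_markers: int = 20) -> MarkerPanelSelection:
    """Select a marker subset that distinguishes every pair of samples.

    EXACT performs iterative deepening over subset sizes (a minimum-size set
    cover; feasible for panels of a few dozen markers), trying combinations
    of the most-discriminating markers first.  GREEDY repeatedly adds the
    marker covering the most not-yet-distinguished pairs, breaking ties by
    panel order.  Raises if the full panel itself leaves some pair
    indistinguishable.
    """
    masks, pair_ids = _pair_masks(table)
    n_pairs = len(pair_ids)
    full = (1 << n_pairs) - 1
    union = 0
    for m in masks:
        union |= m
    if union != full:
        uncovered = [pair_ids[b] for b in range(n_pairs) if not (union >> b) & 1]
        raise ValueError(
            f"full panel cannot distinguish {len(uncovered)} pair(s), "
            f"e.g. {uncovered[:5]}"
        )
    names = table.marker_names
    mode = SelectionMode(mode)

    if mode is SelectionMode.GREEDY:
        chosen: list[int] = []
        covered = 0
        while covered != full:
            best_j, best_gain = None, -1
            for j, m in enumerate(masks):
                gain = _popcount(m & ~covered)
                if gain > best_gain:
                    best_j, best_gain = j, gain
            chosen.append(best_j)
            covered |= masks[best_j]
        selected = [names[j] for j in chosen]
        return MarkerPanelSelection(
            selected=tuple(selected),
            certificate=_certificate(table, selected),
            exact=False,
        )

    # EXACT: iterative deepening, markers ordered by coverage descending
    order = sorted(range(len(masks)), key=lambda j: (-_popcount(masks[j]), j))
    for k in range(1, min(max_exact_markers, len(masks)) + 1):
        hit = _cover_search(masks, order, full, k)
        if hit is not None:
            selected = [names[j] for j in sorted(hit)]
            return MarkerPanelSelection(
                selected=tuple(selected),
                certificate=_certificate(table, selected),
                exact=True,
            )
    raise ValueError(f"no covering subset of size <= {max_exact_markers} found")


def _popcount(x: int) -> int:
    return x.bit_count() if hasattr(int, "bit_count") else bin(x).count("1")


def _cover_search(masks, order, full, k):
    """Depth-first search for a size-k subset whose masks OR to `full`."""
    n = len(order)

    def rec(start: int, covered: int, picked: tuple[int, ...]):
        if covered == full:
            return picked
        remaining = k - len(picked)
        if remaining == 0:
            return None
        # bound: even taking the best `remaining` masks cannot help if their
        # union with `covered` misses a pair covered by no remaining marker
        possible = covered
        for idx in range(start, n):
            possible |= masks[order[idx]]
        if possible != full:
            return None
        for idx in range(start, n - remaining + 1):
            j = order[idx]
            if masks[j] & ~covered == 0:
                continue
            got = rec(idx + 1, covered | masks[j], picked + (j,))
            if got is not None:
                return got
        return None

    return rec(0, 0, ())


def _certificate(table: GenotypeTable, selected: list[str]) -> dict[tuple[str, str], str]:
    sub = table.subset_markers(selected)
    ids = sub.sample_ids
    cert: dict[tuple[str, str], str] = {}
    for i, j in itertools.combinations(range(len(ids)), 2):
        for name, ca, cb in zip(selected, sub.calls[i], sub.calls[j]):
            if not ca.missing and not cb.missing and _call_key(ca) != _call_key(cb):
                cert[(ids[i], ids[j])] = name
                break
    return cert
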