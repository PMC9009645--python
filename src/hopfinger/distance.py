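"""Pairwise genetic distances for mixed-ploidy genotypes, NJ trees, bootstrap.

Bruvo's distance handles microsatellite genotypes of unequal ploidy by
padding the smaller allele set with virtual alleles and minimizing the mean
per-allele distance over all one-to-one matchings.  The per-allele distance
is ``1 - 2**(-|x - y| / replen)`` with ``replen`` the repeat-unit length in
bp.  Setting ``replen`` to a value far below one nucleotide (0.001) turns the
measure into an allele-sharing (band-sharing) model: any size difference
scores 1, so it behaves like an infinite-allele model that tolerates mixed
ploidy — the configuration used for fingerprinting clonal collections.

Prevosti's distance is half the L1 distance between within-individual allele
frequency vectors, averaged over loci where both calls are present; it is the
natural companion metric for bi-allelic SNP calls.

Both matrices use pairwise deletion over loci, so the resulting matrix is
complete whenever every sample pair shares at least one scored locus; the
neighbor-joining implementation therefore requires a complete matrix (no
"njs" missing-distance variant is needed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .io import GenotypeTable, MarkerKind, SNPCall, SSRCall

__all__ = [
    "PloidyModel",
    "BruvoConfig",
    "ALLELE_SHARING_REPLEN",
    "bruvo_allele_distance",
    "bruvo_locus_distance",
    "bruvo_matrix",
    "prevosti_locus_distance",
    "prevosti_matrix",
    "per_locus_distances",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "write_distance_tsv",
    "bipartitions",
]

ALLELE_SHARING_REPLEN = 0.001

# enum values mirror the genome addition/loss variants of the Bruvo model
from enum import Enum


class PloidyModel(str, Enum):
    INFINITE = "infinite"            # virtual alleles at distance 1 to everything
    ADDITION = "addition"            # virtual alleles drawn from the smaller genotype
    LOSS = "loss"                    # virtual alleles drawn from the larger genotype
    ADDITION_LOSS_MEAN = "addition_loss_mean"


@dataclass(frozen=True)
class BruvoConfig:
    """Bruvo distance configuration.

    ``replen`` may be a single number applied to all markers or a mapping
    marker name -> repeat length.  The default 0.001 is the allele-sharing
    mode.  ``ploidy_model`` selects how allele sets of unequal size are
    padded.
    """

    replen: float | dict[str, float] = ALLELE_SHARING_REPLEN
    ploidy_model: PloidyModel = PloidyModel.INFINITE

    def replen_for(self, marker: str) -> float:
        r = self.replen[marker] if isinstance(self.replen, dict) else self.replen
        if r <= 0:
            raise ValueError(f"replen must be > 0 (marker {marker})")
        return float(r)


def bruvo_allele_distance(x: float, y: float, replen: float) -> float:
    """Distance between two allele sizes: ``1 - 2**(-|x - y|/replen)``."""
    if x <= 0 or y <= 0:
        raise ValueError("allele sizes must be positive")
    if replen <= 0:
        raise ValueError("replen must be positive")
    steps = abs(x - y) / replen
    return 1.0 - 2.0 ** (-steps)


_VIRTUAL = None  # sentinel for an infinite-model virtual allele


def _matching_mean(a: Sequence, b: Sequence, replen: float) -> float:
    """Minimum over one-to-one matchings of the mean per-pair distance.

    ``a`` and ``b`` have equal length <= 4; ``None`` entries are virtual
    alleles at distance 1 to everything.
    """
    k = len(a)
    cost = [
        [1.0 if ai is _VIRTUAL else bruvo_allele_distance(ai, bi, replen) for bi in b]
        for ai in a
    ]
    best = math.inf
    for perm in itertools.permutations(range(k)):
        total = 0.0
        for i, j in enumerate(perm):
            total += cost[i][j]
            if total >= best:
                break
        else:
            best = total
    return best / k


def bruvo_locus_distance(a: SSRCall, b: SSRCall, replen: float,
                         model: PloidyModel = PloidyModel.INFINITE) -> float:
    """Bruvo distance between two single-locus genotypes.

    Allele sets of unequal size are padded to the larger size with virtual
    alleles according to ``model``; under ADDITION/LOSS the distance is
    averaged over every possible assignment of donor alleles to the virtual
    slots (combinations with replacement), each evaluated at its own optimal
    matching, following the genome addition/loss treatment of the model.
    """
    if a.missing or b.missing:
        raise ValueError("bruvo_locus_distance is undefined for missing calls")
    small, large = sorted((a.distinct, b.distinct), key=len)
    if len(large) > 4:
        raise ValueError("allele sets larger than 4 are not supported")
    deficit = len(large) - len(small)
    if deficit == 0:
        return _matching_mean(small, large, replen)

    if model is PloidyModel.INFINITE:
        padded = tuple(small) + (_VIRTUAL,) * deficit
        return _matching_mean(padded, large, replen)
    if model is PloidyModel.ADDITION_LOSS_MEAN:
        add = bruvo_locus_distance(a, b, replen, PloidyModel.ADDITION)
        loss = bruvo_locus_distance(a, b, replen, PloidyModel.LOSS)
        return 0.5 * (add + loss)
    donor = small if model is PloidyModel.ADDITION else large
    values = [
        _matching_mean(tuple(small) + fill, large, replen)
        for fill in itertools.combinations_with_replacement(donor, deficit)
    ]
    return float(np.mean(values))


def _ssr_locus_layer(calls: Sequence[SSRCall], replen: float, model: PloidyModel) -> np.ndarray:
    """Pairwise per-locus Bruvo distances with NaN where either call is missing."""
    n = len(calls)
    out = np.full((n, n), np.nan)
    cache: dict[tuple, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        a, b = calls[i], calls[j]
        if a.missing or b.missing:
            continue
        key = (a.distinct, b.distinct) if a.distinct <= b.distinct else (b.distinct, a.distinct)
        d = cache.get(key)
        if d is None:
            d = bruvo_locus_distance(a, b, replen, model)
            cache[key] = d
        out[i, j] = out[j, i] = d
    for i in range(n):
        out[i, i] = np.nan if calls[i].missing else 0.0
    return out


def _freq_vector(call, alleles: Sequence) -> np.ndarray | None:
    if isinstance(call, SSRCall):
        if call.missing:
            return None
        vec = np.zeros(len(alleles))
        idx = {a: k for k, a in enumerate(alleles)}
        for a in call.alleles:
            vec[idx[a]] += 1
        return vec / vec.sum()
    d = call.dosage()
    return None if d is None else np.asarray(d)


def prevosti_locus_distance(a, b, alleles: Sequence | None = None) -> float:
    """Half the L1 distance between within-individual allele frequency vectors."""
    if alleles is None:
        pool = set()
        for c in (a, b):
            if isinstance(c, SSRCall):
                pool.update(c.alleles)
            else:
                pool.update(("X", "Y"))
        alleles = sorted(pool)
    p, q = _freq_vector(a, alleles), _freq_vector(b, alleles)
    if p is None or q is None:
        raise ValueError("prevosti_locus_distance is undefined for missing calls")
    return 0.5 * float(np.abs(p - q).sum())


def _prevosti_locus_layer(calls: Sequence) -> np.ndarray:
    n = len(calls)
    out = np.full((n, n), np.nan)
    if isinstance(calls[0], SSRCall):
        alleles = sorted({a for c in calls for a in c.alleles})
    else:
        alleles = ["X", "Y"]
    vecs = [_freq_vector(c, alleles) for c in calls]
    for i in range(n):
        if vecs[i] is not None:
            out[i, i] = 0.0
    for i, j in itertools.combinations(range(n), 2):
        if vecs[i] is None or vecs[j] is None:
            continue
        out[i, j] = out[j, i] = 0.5 * float(np.abs(vecs[i] - vecs[j]).sum())
    return out


def per_locus_distances(table: GenotypeTable, metric: str = "bruvo",
                        cfg: BruvoConfig | None = None) -> np.ndarray:
    """(loci, n, n) stack of per-locus pairwise distances (NaN = undefined).

    The mean over axis 0, ignoring NaN, is the pairwise-deletion distance
    matrix; locus-bootstrap resampling reuses the same stack.
    """
    cfg = cfg or BruvoConfig()
    layers = []
    for m in table.markers:
        calls = table.column(m.name)
        if metric == "bruvo":
            if m.kind is not MarkerKind.SSR:
                raise ValueError("Bruvo distance is defined for SSR markers only")
            layers.append(_ssr_locus_layer(calls, cfg.replen_for(m.name), cfg.ploidy_model))
        elif metric == "prevosti":
            layers.append(_prevosti_locus_layer(calls))
        else:
            raise ValueError(f"unknown metric: {metric}")
    return np.stack(layers)


def _mean_matrix(stack: np.ndarray, table: GenotypeTable) -> DistanceMatrix:
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(stack), axis=0)
        mean = np.where(counts > 0, np.nansum(np.nan_to_num(stack), axis=0), np.nan)
        mean = np.divide(mean, counts, out=np.full(counts.shape, np.nan), where=counts > 0)
    ids = table.sample_ids
    all_missing = [ids[i] for i in range(len(ids)) if counts[i, i] == 0]
    if all_missing:
        raise ValueError(f"samples missing at every locus: {all_missing}")
    bad = np.argwhere(np.isnan(mean))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"samples {ids[i]} and {ids[j]} share no scored locus")
    np.fill_diagonal(mean, 0.0)
    return DistanceMatrix((mean + mean.T) / 2.0, ids)


def bruvo_matrix(table: GenotypeTable, cfg: BruvoConfig | None = None) -> DistanceMatrix:
    """Pairwise Bruvo distances: mean of defined per-locus distances."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    return _mean_matrix(per_locus_distances(table, "bruvo", cfg), table)


def prevosti_matrix(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise Prevosti distances with missing calls ignored per pair."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    return _mean_matrix(per_locus_distances(table, "prevosti"), table)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is chosen; ties resolve to the
    smallest (row, column) index pair.  A negative estimated branch length is
    clamped to zero with the deficit moved to the sibling branch so the
    joined path length is preserved.  Returns an unrooted tree (trifurcating
    root) of :class:`skbio.TreeNode`.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (row, col) among minima, scanning the upper triangle in order
        besti = bestj = None
        qmin = q.min()
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    besti, bestj = a, b
                    break
            if besti is not None:
                break
        i, j = besti, bestj
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i], active[j]
        child_i, child_j = nodes[gi], nodes[gj]
        child_i.length, child_j.length = float(li), float(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        g_new = d.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [g_new]

    # closed-form star resolution of the last three nodes
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for g, length in zip((a, b, c), (la, lb, lc)):
        nodes[g].length = float(max(length, 0.0))
        root.append(nodes[g])
    return root


# ---------------------------------------------------------------------------
# bootstrap support


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, canonicalized.

    Each internal edge splits the leaf set in two; the side not containing
    the lexicographically smallest leaf is the canonical representative.
    """
    tips = frozenset(t.name for t in tree.tips())
    anchor = min(tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        out.add(side if anchor not in side else tips - side)
    return out


def bootstrap_support(table: GenotypeTable, metric: str = "bruvo",
                      cfg: BruvoConfig | None = None, reps: int = 2000,
                      seed: int = 0) -> TreeNode:
    """NJ tree with locus-bootstrap support percentages on internal nodes.

    Loci are resampled with replacement ``reps`` times; the support of an
    internal edge of the full-data tree is the percentage of replicate trees
    containing the same bipartition.  Support values are stored as the
    ``name`` of internal nodes (integer percent), the convention Newick
    readers expect.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if table.n_markers < 2:
        raise ValueError("locus bootstrap needs at least 2 loci")
    stack = per_locus_distances(table, metric, cfg)
    ref = neighbor_joining(_mean_matrix(stack, table))
    ref_bips = {bip: 0 for bip in bipartitions(ref)}
    rng = np.random.default_rng(seed)
    L = stack.shape[0]
    for _ in range(reps):
        idx = rng.integers(0, L, size=L)
        try:
            rep_dm = _mean_matrix(stack[idx], table)
        except ValueError:
            continue  # replicate dropped a pair's only shared locus
        for bip in bipartitions(neighbor_joining(rep_dm)):
            if bip in ref_bips:
                ref_bips[bip] += 1
    tips = frozenset(t.name for t in ref.tips())
    anchor = min(tips)
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        key = side if anchor not in side else tips - side
        node.name = str(int(round(100.0 * ref_bips[key] / reps)))
    return ref


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree as Newick with branch lengths and support labels."""
    tree.write(str(path), format="newick")


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Write a labeled square distance matrix as TSV."""
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
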