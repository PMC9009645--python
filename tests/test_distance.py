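"""Bruvo/Prevosti distances, neighbor joining, bootstrap support.

The Bruvo implementation is checked against an independent brute-force
oracle that enumerates every padding configuration and every one-to-one
matching directly from the definition.
"""

import io as _io
import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from conftest import make_ssr_table, make_snp_table
from hopfinger.distance import (
    ALLELE_SHARING_REPLEN,
    BruvoConfig,
    PloidyModel,
    bipartitions,
    bootstrap_support,
    bruvo_allele_distance,
    bruvo_locus_distance,
    bruvo_matrix,
    neighbor_joining,
    prevosti_locus_distance,
    prevosti_matrix,
    write_newick,
)
from hopfinger.io import SNPCall, SSRCall


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate paddings and matchings from the definition


def oracle_allele_d(x, y, replen):
    if x is None or y is None:
        return 1.0
    return 1.0 - 2.0 ** (-abs(x - y) / replen)


def oracle_bruvo(a, b, replen, model="infinite"):
    small, large = sorted((tuple(sorted(set(a))), tuple(sorted(set(b)))), key=len)
    deficit = len(large) - len(small)

    def best_matching(padded):
        return min(
            sum(oracle_allele_d(x, y, replen) for x, y in zip(padded, perm)) / len(large)
            for perm in itertools.permutations(large)
        )

    if deficit == 0:
        return best_matching(small)
    if model == "infinite":
        return best_matching(small + (None,) * deficit)
    if model == "addition_loss_mean":
        return 0.5 * (
            oracle_bruvo(a, b, replen, "addition") + oracle_bruvo(a, b, replen, "loss")
        )
    donor = small if model == "addition" else large
    vals = [
        best_matching(small + fill)
        for fill in itertools.combinations_with_replacement(donor, deficit)
    ]
    return sum(vals) / len(vals)


def test_bruvo_allele_distance_closed_form():
    assert bruvo_allele_distance(100, 100, 2) == 0.0
    assert bruvo_allele_distance(100, 104, 2) == pytest.approx(0.75)
    # allele-sharing limit: any difference saturates to 1
    assert bruvo_allele_distance(100, 101, ALLELE_SHARING_REPLEN) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bruvo_allele_distance(-1, 100, 2)
    with pytest.raises(ValueError):
        bruvo_allele_distance(100, 100, 0)


@pytest.mark.parametrize(
    "a,b,replen,model,expected",
    [
        ((100, 102), (100, 104), 2, PloidyModel.INFINITE, 0.25),
        ((100, 102), (100, 104), ALLELE_SHARING_REPLEN, PloidyModel.INFINITE, 0.5),
        ((100, 102), (100, 102, 104), 2, PloidyModel.INFINITE, 1.0 / 3.0),
    ],
)
def test_bruvo_locus_distance_worked_examples(a, b, replen, model, expected):
    d = bruvo_locus_distance(SSRCall(a), SSRCall(b), replen, model)
    assert d == pytest.approx(expected)
    assert d == pytest.approx(oracle_bruvo(a, b, replen, model.value))


@pytest.mark.parametrize("model", list(PloidyModel))
def test_bruvo_equals_bruteforce_oracle(model):
    """Property: for allele sets of size <= 4, the implementation equals the
    exhaustive pad-and-match enumeration under every ploidy model."""
    rng = np.random.default_rng(7)
    n_cases = 10_000 if model is PloidyModel.INFINITE else 1_000
    for _ in range(n_cases):
        ka, kb = rng.integers(1, 5, size=2)
        a = tuple(sorted(set(100 + 2 * rng.integers(0, 8, size=ka))))
        b = tuple(sorted(set(100 + 2 * rng.integers(0, 8, size=kb))))
        replen = float(rng.choice([0.001, 1.0, 2.0, 3.5]))
        got = bruvo_locus_distance(SSRCall(a), SSRCall(b), replen, model)
        want = oracle_bruvo(a, b, replen, model.value)
        assert got == pytest.approx(want, abs=1e-12), (a, b, replen, model)
        assert 0.0 <= got <= 1.0


def test_allele_sharing_identity():
    """At replen 0.001 the Bruvo locus distance equals 1 - shared/matched,
    the band-sharing identity."""
    rng = np.random.default_rng(11)
    for _ in range(2_000):
        ka, kb = rng.integers(1, 5, size=2)
        a = tuple(sorted(set(100 + rng.integers(0, 6, size=ka))))
        b = tuple(sorted(set(100 + rng.integers(0, 6, size=kb))))
        d = bruvo_locus_distance(SSRCall(a), SSRCall(b), ALLELE_SHARING_REPLEN)
        shared = len(set(a) & set(b))
        assert d == pytest.approx(1.0 - shared / max(len(set(a)), len(set(b))), abs=1e-9)


def test_bruvo_locus_distance_rejects_missing():
    with pytest.raises(ValueError):
        bruvo_locus_distance(SSRCall(()), SSRCall((100,)), 2)


def test_bruvo_matrix_pairwise_deletion():
    table = make_ssr_table(
        {
            "a": [(100, 102), (200, 202)],
            "b": [(100, 102), ()],
        },
        marker_names=["m1", "m2"],
    )
    dm = bruvo_matrix(table, BruvoConfig(replen=2.0))
    # only m1 is defined for the pair; identical there
    assert dm["a", "b"] == 0.0

    identical = make_ssr_table({"a": [(100, 102)], "b": [(100, 102)]})
    assert bruvo_matrix(identical)["a", "b"] == 0.0

    disjoint = make_ssr_table(
        {"a": [(100, 102), (104,)], "b": [(200, 202), (204,)]}
    )
    assert bruvo_matrix(disjoint)["a", "b"] == pytest.approx(1.0)


def test_bruvo_matrix_errors():
    all_missing = make_ssr_table({"a": [(100,)], "b": [()]})
    with pytest.raises(ValueError, match="missing at every locus"):
        bruvo_matrix(all_missing)
    no_overlap = make_ssr_table(
        {"a": [(100,), ()], "b": [(), (104,)], "c": [(100,), (104,)]}
    )
    with pytest.raises(ValueError, match="share no scored locus"):
        bruvo_matrix(no_overlap)


def test_prevosti_worked_examples():
    assert prevosti_locus_distance(SSRCall((100, 102)), SSRCall((100, 104))) == 0.5
    assert prevosti_locus_distance(SNPCall.XX, SNPCall.XY) == 0.5
    assert prevosti_locus_distance(SNPCall.XX, SNPCall.YY) == 1.0
    assert prevosti_locus_distance(SNPCall.XY, SNPCall.XY) == 0.0


def test_prevosti_snp_equals_half_scaled_manhattan_on_dosage():
    """Property: on bi-allelic data the per-pair Prevosti distance is half
    the Manhattan distance between the (X, Y) allele-dosage vectors scaled
    by ploidy, averaged over loci."""
    rng = np.random.default_rng(3)
    calls = [SNPCall.XX, SNPCall.XY, SNPCall.YY]
    dose = {SNPCall.XX: (2, 0), SNPCall.XY: (1, 1), SNPCall.YY: (0, 2)}
    for _ in range(200):
        row_a = [calls[i] for i in rng.integers(0, 3, size=6)]
        row_b = [calls[i] for i in rng.integers(0, 3, size=6)]
        table = make_snp_table({"a": row_a, "b": row_b})
        d = prevosti_matrix(table)["a", "b"]
        manhattan = sum(
            abs(dose[x][0] - dose[y][0]) + abs(dose[x][1] - dose[y][1])
            for x, y in zip(row_a, row_b)
        )
        assert d == pytest.approx(0.5 * manhattan / 2 / 6, abs=1e-12)


def test_matrix_invariants(two_pool_table):
    for dm in (bruvo_matrix(two_pool_table), prevosti_matrix(two_pool_table)):
        data = dm.data
        assert np.allclose(data, data.T)
        assert np.allclose(np.diag(data), 0.0)
        assert data.min() >= 0.0 and data.max() <= 1.0


# ---------------------------------------------------------------------------
# neighbor joining


def _tip_distances(tree):
    td = tree.tip_tip_distances()
    return {frozenset((a, b)): td[a, b] for a, b in itertools.combinations(td.ids, 2)}


def test_nj_recovers_additive_four_taxon_tree():
    """On a matrix satisfying the four-point condition, NJ reproduces the
    generating tree's path lengths exactly."""
    ids = ["A", "B", "C", "D"]
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    d = {
        ("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 5,
        ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7,
    }
    mat = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = ids.index(x), ids.index(y)
        mat[i, j] = mat[j, i] = v
    # four-point condition sanity: two of the three pair sums are equal max
    sums = sorted([d[("A", "B")] + d[("C", "D")],
                   d[("A", "C")] + d[("B", "D")],
                   d[("A", "D")] + d[("B", "C")]])
    assert sums[1] == sums[2]
    tree = neighbor_joining(DistanceMatrix(mat, ids))
    got = _tip_distances(tree)
    for (x, y), v in d.items():
        assert got[frozenset((x, y))] == pytest.approx(v, abs=1e-9)
    assert bipartitions(tree) == {frozenset({"C", "D"})} or bipartitions(tree) == {
        frozenset({"A", "B"})
    }


def test_nj_three_taxon_closed_form():
    d = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ["a", "b", "c"])
    tree = neighbor_joining(d)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})


def test_nj_equidistant_matrix():
    d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
    tree = neighbor_joining(d)
    internal = [n.length for n in tree.non_tips(include_self=False)]
    assert all(abs(l) < 1e-12 for l in internal)


def test_nj_matches_skbio_on_random_additive_matrices():
    """Independent cross-check: on random additive matrices, our NJ and
    scikit-bio's NJ recover the same (true) topology."""
    rng = np.random.default_rng(19)
    for rep in range(10):
        n = int(rng.integers(5, 9))
        ids = [f"t{i}" for i in range(n)]
        # random bifurcating tree via random joins with positive lengths
        nodes = [TreeNode(name=i) for i in ids]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[j], nodes[i]
            a.length = float(rng.uniform(0.5, 2.0))
            b.length = float(rng.uniform(0.5, 2.0))
            parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
            nodes.append(parent)
        true_tree = nodes[0]
        td = true_tree.tip_tip_distances()
        dm = DistanceMatrix(td.data, list(td.ids))
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert bipartitions(ours) == bipartitions(theirs)
        got = _tip_distances(ours)
        want = {frozenset((a, b)): td[a, b] for a, b in itertools.combinations(td.ids, 2)}
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_two_clade_support(two_pool_table):
    """All loci carry the same pool split, so the pool bipartition must get
    (near) 100% support."""
    tree = bootstrap_support(two_pool_table, reps=200, seed=5)
    pool_a = frozenset(s for s in two_pool_table.sample_ids if s.startswith("A"))
    tips = frozenset(two_pool_table.sample_ids)
    anchor = min(tips)
    target = pool_a if anchor not in pool_a else tips - pool_a
    supports = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = side if anchor not in side else tips - side
        if node.name is not None:
            supports[key] = int(node.name)
    assert supports[target] >= 95


def test_bootstrap_single_locus_supports_binary():
    table = make_ssr_table(
        {
            "a": [(100, 102)],
            "b": [(100, 102)],
            "c": [(200, 202)],
            "d": [(200, 204)],
        }
    )
    with pytest.raises(ValueError):
        bootstrap_support(table, reps=10)  # needs >= 2 loci
    two = make_ssr_table(
        {
            "a": [(100, 102), (100, 102)],
            "b": [(100, 102), (100, 102)],
            "c": [(200, 202), (200, 202)],
            "d": [(200, 204), (200, 204)],
        }
    )
    tree = bootstrap_support(two, reps=50, seed=1)
    sup = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
    assert all(s in (0, 100) for s in sup)
    with pytest.raises(ValueError):
        bootstrap_support(two, reps=0)


def test_newick_round_trip(tmp_path, two_pool_table):
    tree = bootstrap_support(two_pool_table, reps=20, seed=2)
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    back = TreeNode.read(str(path), format="newick")
    assert bipartitions(back) == bipartitions(tree)
    assert {t.name for t in back.tips()} == set(two_pool_table.sample_ids)
    # support labels sit on internal nodes only
    for tip in back.tips():
        assert tip.name in two_pool_table.sample_ids
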