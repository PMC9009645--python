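"""SNP filters, marker indices, assay QC, concordance, sex-allele scan."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_snp_table, make_ssr_table
from hopfinger.io import Population, SampleMeta, Sex, SNPCall
from hopfinger.panel_qc import (
    SnpFilterConfig,
    classify_mismatch,
    concordance,
    filter_snps,
    kasp_qc,
    marker_indices,
    select_candidates,
    sex_specific_alleles,
)


def _snp_counts_table(n_xx, n_xy, n_yy, name="m"):
    rows = {}
    i = 0
    for call, n in (("XX", n_xx), ("XY", n_xy), ("YY", n_yy)):
        for _ in range(n):
            rows[f"s{i}"] = [call]
            i += 1
    return make_snp_table(rows, marker_names=[name])


# ---------------------------------------------------------------------------
# filters


def test_filter_snps_maf_and_missing_rules():
    # m_lowmaf: MAF 0.10 in 20 samples; m_miss: 15% missing; two clean sites
    # (the extra clean site keeps the samples with a gap above the 75% taxa
    # presence floor, so the site-level missingness rule does the removal)
    rows = {}
    for i in range(20):
        clean = "XX" if i < 5 else ("YY" if i < 10 else "XY")
        rows[f"s{i}"] = [
            "XY" if i < 4 else "XX",              # m_lowmaf: p(Y) = 0.10
            "-" if i < 3 else "XY",               # m_miss: 15% missing
            clean,
            clean,
        ]
    table = make_snp_table(
        rows, marker_names=["m_lowmaf", "m_miss", "m_clean1", "m_clean2"]
    )
    cfg = SnpFilterConfig(genotype_presence_min=0.80)
    out, steps = filter_snps(table, cfg)
    assert out.marker_names == ["m_clean1", "m_clean2"]
    names = [s.step for s in steps]
    assert names == ["input", "site_presence", "taxa_presence", "maf_and_missing"]
    counts = [s.n_sites for s in steps]
    assert counts == sorted(counts, reverse=True)  # non-increasing


def test_filter_snps_presence_depth_and_idempotence():
    rows = {f"s{i}": ["XY", "XX" if i % 2 else "YY"] for i in range(10)}
    table = make_snp_table(rows, marker_names=["a", "b"])
    depth = np.full((10, 2), 2, dtype=int)
    depth[:9, 0] = 1  # below the 2x floor -> site a loses 90% of calls
    out, steps = filter_snps(table, depth=depth)
    assert out.marker_names == ["b"]
    assert steps[1].step == "depth_mask"
    # idempotence: filtering the filtered table changes nothing
    out2, _ = filter_snps(out)
    assert out2.marker_names == out.marker_names
    assert out2.sample_ids == out.sample_ids


def test_filter_snps_taxa_presence_drops_samples():
    rows = {f"s{i}": ["XY", "XY", "XX", "YY"] for i in range(8)}
    rows["bad"] = ["-", "-", "-", "XY"]  # 25% presence < 75% floor
    table = make_snp_table(rows)
    cfg = SnpFilterConfig(genotype_presence_min=0.5, site_missing_max=0.2)
    out, _ = filter_snps(table, cfg)
    assert "bad" not in out.sample_ids


def test_filter_snps_empty_output_is_reported_not_raised():
    table = make_snp_table({f"s{i}": ["XX"] for i in range(10)})
    out, steps = filter_snps(table)  # monomorphic: MAF 0 < 0.20
    assert out.n_markers == 0
    assert steps[-1].n_sites == 0


# ---------------------------------------------------------------------------
# marker indices and candidate selection


def test_marker_indices_hwe_equilibrium_site():
    table = _snp_counts_table(25, 50, 25)
    (ix,) = marker_indices(table)
    assert ix.maf == 0.5 and ix.het_obs == 0.5
    assert ix.pic == pytest.approx(0.375)
    assert ix.hwe_index == pytest.approx(1.0)
    assert ix.mean4 == pytest.approx(0.59375)
    assert select_candidates([ix]) == ["m"]


def test_marker_indices_het_deficit_site():
    table = _snp_counts_table(50, 0, 50)
    (ix,) = marker_indices(table)
    assert ix.het_obs == 0.0 and ix.maf == 0.5
    assert ix.hwe_index == pytest.approx(0.0, abs=1e-12)
    assert ix.mean4 == pytest.approx(0.21875)
    assert select_candidates([ix]) == []


def test_marker_indices_monomorphic():
    table = _snp_counts_table(40, 0, 0)
    (ix,) = marker_indices(table)
    assert ix.maf == 0.0 and ix.pic == 0.0 and ix.hwe_index == 1.0
    assert ix.mean4 == pytest.approx(0.25)


def test_select_candidates_boundary_inclusive():
    table = _snp_counts_table(25, 50, 25)
    (ix,) = marker_indices(table)
    assert select_candidates([ix], threshold=ix.mean4) == ["m"]


# ---------------------------------------------------------------------------
# KASP QC


def test_kasp_qc_28_to_25_fixture():
    """A 28-marker panel with 2 monomorphic assays and 1 two-cluster assay
    retains 25 markers, mirroring production-assay attrition."""
    rng = np.random.default_rng(55)
    n = 40
    rows = {f"s{i}": [] for i in range(n)}
    names = [f"K{j + 1:02d}" for j in range(28)]
    for j in range(28):
        if j < 2:
            col = ["XX"] * n                       # monomorphic
        elif j == 2:
            col = ["XX"] * 20 + ["YY"] * 20        # two clusters only
        else:
            col = [("XX", "XY", "YY")[k] for k in rng.integers(0, 3, size=n)]
        for i in range(n):
            rows[f"s{i}"].append(col[i])
    table = make_snp_table(rows, marker_names=names)
    res = kasp_qc(table)
    assert len(res.retained) == 25
    assert res.removed["K01"] == "monomorphic"
    assert res.removed["K02"] == "monomorphic"
    assert "clusters" in res.removed["K03"]


def test_kasp_qc_missing_rules_and_sample_flag():
    rows = {f"s{i}": ["XX" if i < 4 else ("XY" if i < 8 else "YY"),
                      "-" if i < 3 else ("XX", "XY", "YY")[i % 3]]
            for i in range(12)}
    rows["lowdna"] = ["-", "-"]
    table = make_snp_table(rows, marker_names=["good", "gappy"])
    res = kasp_qc(table, missing_max=0.20)
    assert "good" in res.retained
    assert "gappy" in res.removed  # 4/13 missing > 20%
    assert "lowdna" in res.flagged_samples


# ---------------------------------------------------------------------------
# concordance


@pytest.mark.parametrize(
    "g,k,expected",
    [
        (SNPCall.XY, SNPCall.XX, "het_to_hom"),
        (SNPCall.XY, SNPCall.YY, "het_to_hom"),
        (SNPCall.XX, SNPCall.YY, "hom_to_opposite_hom"),
        (SNPCall.YY, SNPCall.XX, "hom_to_opposite_hom"),
        (SNPCall.XX, SNPCall.XY, "hom_to_het"),
        (SNPCall.YY, SNPCall.XY, "hom_to_het"),
        (SNPCall.XX, SNPCall.XX, None),
    ],
)
def test_classify_mismatch(g, k, expected):
    assert classify_mismatch(g, k) == expected


def test_concordance_counts_shares_and_exclusion():
    gbs = make_snp_table(
        {
            "a": ["XY", "XX", "XX", "YY", "XX"],
            "b": ["XX", "XX", "XY", "-", "XX"],
            "swapped": ["XX", "YY", "XX", "YY", "XX"],
        }
    )
    kasp = make_snp_table(
        {
            "a": ["XX", "XX", "XX", "YY", "XX"],       # one g1 mismatch (1/5)
            "b": ["XX", "XX", "XY", "XY", "XX"],       # missing cell skipped
            "swapped": ["YY", "XX", "XX", "XX", "XX"],  # three g2 mismatches
        }
    )
    rep = concordance(gbs, kasp)
    assert rep.counts["het_to_hom"] == 1
    assert rep.counts["hom_to_opposite_hom"] == 3
    assert rep.skipped_missing == 1
    assert sum(rep.group_shares.values()) == pytest.approx(100.0)
    # a sits exactly at 20% incongruity: not excluded (> threshold required)
    assert rep.excluded_samples == ("swapped",)
    assert rep.per_sample_incongruity["swapped"] == pytest.approx(0.6)
    assert rep.agreement_pct_after_exclusion >= rep.agreement_pct_all
    # agreement accounting: matches / compared
    compared = rep.counts["match"] + 4
    assert rep.agreement_pct_all == pytest.approx(100 * rep.counts["match"] / compared)


def test_concordance_recovers_injected_errors_exactly():
    """The classifier reproduces the generator's per-class injection log on
    a 100-sample, 25-locus platform pair with all three error modes."""
    from hopfinger.synthetic import SimConfig, simulate_dataset

    cfg = SimConfig(
        seed=29,
        n_cult=70,
        n_wna=30,
        clone_groups=(),
        null_freqs=(0.0,) * 9,
        het_dropout=0.04,
        false_het=0.03,
        sample_swap=0.02,
    )
    ds = simulate_dataset(cfg)
    rep = concordance(ds.gbs, ds.kasp)
    logged = Counter(cls for *_, cls in ds.truth.platform_errors)
    for grp in ("het_to_hom", "hom_to_opposite_hom", "hom_to_het"):
        assert rep.counts[grp] == logged[grp], grp
    # swapped samples exceed the incongruity threshold and classify to g2
    for sid in ds.truth.swapped_samples:
        assert rep.per_sample_incongruity[sid] > 0.20
        assert sid in rep.excluded_samples


def test_concordance_requires_overlap():
    a = make_snp_table({"a": ["XX"]})
    b = make_snp_table({"b": ["XX"]})
    with pytest.raises(ValueError, match="no shared"):
        concordance(a, b)


# ---------------------------------------------------------------------------
# sex-specific alleles


def test_sex_specific_alleles_planted():
    metas = {
        "m1": SampleMeta("m1", Population.CULT, Sex.M, 2),
        "m2": SampleMeta("m2", Population.WNA, Sex.M, 2),
        "f1": SampleMeta("f1", Population.CULT, Sex.F, 2),
        "f2": SampleMeta("f2", Population.CULT, Sex.F, 2),
    }
    table = make_ssr_table(
        {
            "m1": [(163, 180)],
            "m2": [(163, 184)],
            "f1": [(157, 180)],
            "f2": [(180, 184)],
        },
        marker_names=["sexloc"],
        metas=metas,
    )
    rep = sex_specific_alleles(table, "sexloc")
    assert rep.male_specific == {163: 2}
    assert rep.female_specific == {157: 1}
    assert rep.pools[163] == "BOTH" and rep.pools[157] == "CULT"
    # shared allele 180 reported in neither list
    assert 180 not in rep.male_specific and 180 not in rep.female_specific


def test_sex_specific_alleles_errors():
    metas = {"m1": SampleMeta("m1", Population.CULT, Sex.M, 2),
             "f1": SampleMeta("f1", Population.CULT, Sex.F, 2)}
    all_missing = make_ssr_table(
        {"m1": [()], "f1": [()]}, marker_names=["x"], metas=metas
    )
    with pytest.raises(ValueError, match="both sexes"):
        sex_specific_alleles(all_missing, "x")
    males_only = make_ssr_table(
        {"m1": [(100,)]}, marker_names=["x"],
        metas={"m1": SampleMeta("m1", Population.CULT, Sex.M, 2)},
    )
    with pytest.raises(ValueError, match="both sexes"):
        sex_specific_alleles(males_only, "x")
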