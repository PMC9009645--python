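"""Pipeline orchestration: the fingerprinting and SNP-panel analysis runs.

These functions wire the library modules together in the order the analyses
are normally performed on a germplasm collection:

``run_fingerprint``
    SSR table -> Bruvo allele-sharing distances -> NJ tree with locus
    bootstrap -> synonym (duplicate) groups -> per-population and per-locus
    diversity tables -> null-allele estimates -> PCoA + PAM structure,
    optionally a parentage exclusion scan.

``run_panel``
    discovery SNP table -> presence/MAF filters -> four-index marker screen
    -> minimal discriminating subset -> assay QC -> discovery-vs-assay
    concordance.

Every stage's effective parameters land in the returned report (JSON
serializable), and with ``out_dir`` set the standard TSV/Newick/JSON files
are written.  There is no command-line wrapper: these functions plus the
example scripts are the interface.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diversity, identity, panel_qc, parentage, structure
from .distance import (
    ALLELE_SHARING_REPLEN,
    BruvoConfig,
    bootstrap_support,
    bruvo_matrix,
    write_distance_tsv,
    write_newick,
)
from .io import GenotypeTable, MarkerKind

__all__ = ["run_fingerprint", "run_panel"]


def _tree_to_newick(tree) -> str:
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _locus_table_frame(stats) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in stats])


def run_fingerprint(
    table: GenotypeTable,
    *,
    replen: float | dict[str, float] = ALLELE_SHARING_REPLEN,
    bootstrap_reps: int = 2000,
    k_range: tuple[int, int] = (2, 8),
    pcoa_variance: float = 0.90,
    null_ci_reps: int = 1000,
    offspring: list[str] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the SSR fingerprinting analysis end to end.

    ``replen`` defaults to the allele-sharing setting (0.001 bp per repeat
    unit); pass a marker->motif-length mapping for the mutation-model
    distance instead.  ``pcoa_variance`` sets how much positive-eigenvalue
    variance the coordinates fed to PAM must cover.  ``offspring`` names
    samples to run a parentage exclusion scan for (all other samples are
    candidates).  Stage failures raise with the stage name attached.
    """
    report: dict[str, Any] = {
        "params": {
            "replen": replen,
            "bootstrap_reps": bootstrap_reps,
            "k_range": list(k_range),
            "pcoa_variance": pcoa_variance,
            "seed": seed,
        }
    }
    cfg = BruvoConfig(replen=replen)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    dm = stage("bruvo_matrix", lambda: bruvo_matrix(table, cfg))
    tree = stage(
        "bootstrap_nj",
        lambda: bootstrap_support(table, "bruvo", cfg, reps=bootstrap_reps, seed=seed),
    )
    assignment = stage("assign_mlg", lambda: identity.assign_mlg(table))
    groups = identity.synonym_groups(assignment)
    pops = stage("pop_summary", lambda: diversity.pop_summary(table))
    loci = stage("locus_table", lambda: diversity.locus_table(table))

    nulls = {}
    diploids = table.diploid_subset()
    for m in table.marker_names:
        try:
            est = diversity.null_allele_em(
                diploids, m, ci_reps=null_ci_reps, seed=seed
            )
            nulls[m] = {"freq": est.freq, "ci": list(est.ci), "n": est.n}
        except ValueError as exc:
            nulls[m] = {"error": str(exc)}

    ord_res = stage("pcoa", lambda: structure.pcoa(dm))
    cum = np.cumsum(ord_res.explained)
    n_axes = int(np.searchsorted(cum, pcoa_variance) + 1)
    coords = ord_res.coordinates[:, :n_axes]
    diag = stage(
        "choose_k",
        lambda: structure.choose_k(coords, k_range, labels=list(ord_res.labels), seed=seed),
    )
    best = diag.results[diag.ks.index(diag.recommended)]

    report.update(
        {
            "n_samples": table.n_samples,
            "n_markers": table.n_markers,
            "tree_newick": _tree_to_newick(tree),
            "synonym_groups": {
                g.group_name: sorted(g.members) for g in groups
            },
            "n_mlg": len(set(assignment.mapping.values())),
            "pop_summary": [dataclasses.asdict(p) for p in pops],
            "locus_table": [dataclasses.asdict(s) for s in loci],
            "null_alleles": nulls,
            "pcoa_explained": [float(x) for x in ord_res.explained[:5]],
            "pcoa_axes_used": n_axes,
            "k_recommended": diag.recommended,
            "k_diagnostics": {
                "ks": list(diag.ks),
                "wss": list(diag.wss),
                "silhouette": list(diag.silhouette),
            },
            "clusters": best.labels,
        }
    )

    if offspring:
        scans = {}
        for off in offspring:
            reports = stage(
                f"exclusion_scan:{off}",
                lambda off=off: parentage.exclusion_scan(table, off),
            )
            scans[off] = [
                {
                    "candidate": r.candidate,
                    "mismatches": list(r.mismatch_loci),
                    "n_informative": r.n_informative,
                    "compatible": r.compatible,
                }
                for r in reports[:10]
            ]
        report["parentage"] = scans

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_distance_tsv(dm, out / "bruvo_distances.tsv")
        write_newick(tree, out / "nj_bootstrap.nwk")
        pd.DataFrame(
            [
                {"group_name": g.group_name, "member": m, "n": len(g.members)}
                for g in groups
                for m in sorted(g.members)
            ]
        ).to_csv(out / "synonym_groups.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(p) for p in pops]).to_csv(
            out / "pop_summary.tsv", sep="\t", index=False
        )
        _locus_table_frame(loci).to_csv(out / "locus_table.tsv", sep="\t", index=False)
        with open(out / "fingerprint_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def run_panel(
    gbs: GenotypeTable,
    kasp: GenotypeTable | None = None,
    *,
    filter_cfg: panel_qc.SnpFilterConfig | None = None,
    index_threshold: float = 0.50,
    kasp_missing_max: float = 0.20,
    incongruity_max: float = 0.20,
    selection_mode: identity.SelectionMode = identity.SelectionMode.GREEDY,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the SNP panel construction and validation analysis.

    Filters the discovery table, screens markers on the four-index average,
    picks a minimal discriminating subset among the candidates, and — when
    an assay table is supplied — applies assay QC and the discovery-vs-assay
    concordance classification.  An empty post-filter panel stops gracefully
    with a warning recorded in the report.
    """
    if any(m.kind is not MarkerKind.SNP for m in gbs.markers):
        raise ValueError("run_panel expects SNP tables")
    report: dict[str, Any] = {
        "params": {
            "index_threshold": index_threshold,
            "kasp_missing_max": kasp_missing_max,
            "incongruity_max": incongruity_max,
            "selection_mode": identity.SelectionMode(selection_mode).value,
            "seed": seed,
        }
    }
    filtered, steps = panel_qc.filter_snps(gbs, filter_cfg)
    report["filter_steps"] = [dataclasses.asdict(s) for s in steps]
    if filtered.n_markers == 0:
        warnings.warn("no SNP sites survived filtering; stopping", stacklevel=2)
        report["warning"] = "no SNP sites survived filtering"
        return report

    indices = panel_qc.marker_indices(filtered)
    candidates = panel_qc.select_candidates(indices, index_threshold)
    report["marker_indices"] = [
        {**dataclasses.asdict(ix), "mean4": ix.mean4} for ix in indices
    ]
    report["candidates"] = candidates

    selection_report: dict[str, Any] = {}
    if candidates:
        cand_table = filtered.subset_markers(candidates)
        try:
            sel = identity.minimal_marker_set(cand_table, mode=selection_mode)
            selection_report = {
                "selected": list(sel.selected),
                "exact": sel.exact,
                "n_selected": len(sel.selected),
            }
        except ValueError as exc:
            selection_report = {"infeasible": str(exc)}
    report["minimal_marker_set"] = selection_report

    if kasp is not None:
        qc = panel_qc.kasp_qc(kasp, kasp_missing_max)
        report["kasp_qc"] = {
            "retained": list(qc.retained),
            "removed": qc.removed,
            "flagged_samples": list(qc.flagged_samples),
        }
        conc = panel_qc.concordance(gbs, kasp, incongruity_max)
        report["concordance"] = {
            "counts": conc.counts,
            "group_shares": conc.group_shares,
            "agreement_pct_all": conc.agreement_pct_all,
            "agreement_pct_after_exclusion": conc.agreement_pct_after_exclusion,
            "excluded_samples": list(conc.excluded_samples),
            "skipped_missing": conc.skipped_missing,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(s) for s in steps]).to_csv(
            out / "filter_steps.tsv", sep="\t", index=False
        )
        with open(out / "panel_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
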