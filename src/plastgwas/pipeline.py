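"""End-to-end case study on synthetic data with planted truth.

`run_case_study` wires every stage together at a desk-scale design: a
multi-family inbred panel, one focal trait carrying a main-effect, a
plastic (environment-specific) and an antagonistic QTL, the five-estimator
battery, the four scan families, the two-stage consensus rule, QTL variance
accounting, and allele-direction analysis against the planted registry.
The analysis drivers and the acceptance script are thin wrappers over it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotate, consensus, plasticity, popgen, scans, simdata

__all__ = ["run_case_study", "scan_suite", "CASE_STUDY_QTLS"]

#: Planted architecture of the focal trait: a main-effect locus, a
#: WW-specific plastic locus, and an antagonistic locus.
CASE_STUDY_QTLS = (
    simdata.QTLSpec(kind="main", trait="GY", var_frac=0.10),
    simdata.QTLSpec(kind="plastic", trait="GY", var_frac=0.20, env="WW"),
    simdata.QTLSpec(kind="antagonistic", trait="GY", var_frac=0.15),
)


def scan_suite(
    panel,
    plast_table: pd.DataFrame,
    K,
    trait: str,
    seed: int,
    methods=("MLM", "MULTILOCUS", "RF", "GB"),
    estimators=("WW", "WL", "Ratio", "RDPI", "Linear"),
    n_permutations: int = 100,
    n_estimators: int = 100,
    alpha: float = 0.05,
) -> tuple[dict, dict]:
    """Run every (method, estimator) scan for one trait.

    Model-based scans are called at BH FDR ``alpha``; ML importance scans at
    empirical ``alpha``.  Returns (calls, results) where ``calls`` maps
    (method, trait, estimator) -> significant marker set and ``results``
    keeps the full ScanResult objects.
    """
    responses = {
        est: plast_table.xs(trait, level="trait")[est] for est in estimators
    }
    calls, results = {}, {}
    for mi, method in enumerate(methods):
        for ei, est in enumerate(estimators):
            y = responses[est]
            if method == "MLM":
                res = scans.mlm_scan(panel, y, K, trait=trait, estimator=est)
                res = scans.call_significant(res, "bh_fdr", alpha)
            elif method == "MULTILOCUS":
                res = scans.multilocus_scan(panel, y, K, trait=trait, estimator=est)
                res = scans.call_significant(res, "bh_fdr", alpha)
            else:
                res = scans.ml_importance_scan(
                    panel,
                    y,
                    learner=method,
                    n_permutations=n_permutations,
                    seed=seed + 1000 * mi + ei,
                    trait=trait,
                    estimator=est,
                    n_estimators=n_estimators,
                )
                res = scans.call_significant(res, "empirical", alpha)
            calls[(method, trait, est)] = res.significant_markers()
            results[(method, est)] = res
    return calls, results


def run_case_study(
    seed: int = 1,
    n_families: int = 5,
    lines_per_family: int = 60,
    markers_per_chromosome: int = 40,
    n_permutations: int = 100,
    n_estimators: int = 100,
    methods=("MLM", "MULTILOCUS", "RF", "GB"),
    with_annotation: bool = True,
) -> dict:
    """Simulate, analyse, and score one full pipeline run.

    Returns a dict of all intermediate artifacts plus recovery summaries
    against the planted truth (see keys ``consensus``, ``qtl_variance``,
    ``allele_direction``, ``recovery``).
    """
    trait = "GY"
    config = simdata.SimConfig(
        n_families=n_families,
        lines_per_family=lines_per_family,
        markers_per_chromosome=markers_per_chromosome,
        missing_rate=0.02,
        n_replicates=2,
        env_effect=5.0,
        sigma2_poly=1.0,
        sigma2_resid=1.0,
        seed=seed,
    )
    panel = simdata.simulate_genotypes(config)
    registry = simdata.plant_qtls(
        panel,
        CASE_STUDY_QTLS,
        seed=seed + 7,
        sigma2_poly=config.sigma2_poly,
        sigma2_resid=config.sigma2_resid,
    )
    phenotypes = simdata.simulate_phenotypes(panel, registry, config)

    qc_panel, qc_report = popgen.marker_qc(panel)
    K = popgen.kinship(qc_panel)
    pcs, pct = popgen.pca(qc_panel, n_components=4)
    ld = popgen.ld_decay(qc_panel, max_distance=2e8, bin_width=2e7)

    means = plasticity.env_means(phenotypes)
    plast = plasticity.plasticity_table(means)
    retained_estimators, est_corr = plasticity.estimator_screen(
        plast.xs(trait, level="trait").dropna()
    )
    wilcoxon = plasticity.wilcoxon_env(means, trait)

    from .varcomp import fit_variance_components

    decomp = fit_variance_components(phenotypes, trait)

    calls, scan_results = scan_suite(
        qc_panel,
        plast,
        K,
        trait,
        seed=seed,
        methods=methods,
        n_permutations=n_permutations,
        n_estimators=n_estimators,
    )
    cons = consensus.consensus_pipeline(calls, trait)
    counts = consensus.intersection_counts(calls, trait)

    # truth markers may have been pruned by QC; map to the retained panel
    truth = registry.entries.copy()
    retained_ids = set(qc_panel.markers["marker_id"])
    truth["in_qc_panel"] = truth["marker_id"].isin(retained_ids)
    high_conf = set(cons.loc[cons["high_confidence"], "marker_id"])
    consensus_markers = sorted(set(cons["marker_id"]))

    qtl_var = consensus.qtl_variance_explained(
        qc_panel,
        plast.xs(trait, level="trait")["WW"],
        consensus_markers,
        seed=seed,
    ) if consensus_markers else None

    # per-environment effect estimates for direction analysis
    eff_ww = scans.mlm_scan(qc_panel, plast.xs(trait, level="trait")["WW"], K).table
    eff_wl = scans.mlm_scan(qc_panel, plast.xs(trait, level="trait")["WL"], K).table
    direction = annotate.allele_direction(
        qc_panel, plast, eff_ww, eff_wl, consensus_markers, trait
    ) if consensus_markers else pd.DataFrame()

    out = {
        "config": config,
        "panel": panel,
        "qc_panel": qc_panel,
        "qc_report": qc_report,
        "kinship": K,
        "pca_scores": pcs,
        "pca_pct": pct,
        "ld_curve": ld,
        "registry": registry,
        "phenotypes": phenotypes,
        "env_means": means,
        "plasticity": plast,
        "retained_estimators": retained_estimators,
        "estimator_corr": est_corr,
        "wilcoxon": wilcoxon,
        "varcomp": decomp,
        "calls": calls,
        "scan_results": scan_results,
        "consensus": cons,
        "intersection_counts": counts,
        "qtl_variance": qtl_var,
        "allele_direction": direction,
    }

    truth_set = set(truth.loc[truth["in_qc_panel"], "marker_id"])
    out["recovery"] = {
        "n_truth_in_panel": len(truth_set),
        "n_consensus": len(consensus_markers),
        "n_high_confidence": len(high_conf),
        "truth_in_consensus": len(truth_set & set(consensus_markers)),
        "truth_in_high_confidence": len(truth_set & high_conf),
    }

    if with_annotation:
        gff_text, gene2go = annotate.synthetic_annotation(qc_panel, seed=seed + 13)
        import os
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
            fh.write(gff_text)
            gff_path = fh.name
        try:
            regions = annotate.classify_region(qc_panel.markers, gff_path)
        finally:
            os.unlink(gff_path)
        ann = regions.set_index("marker_id")
        study_genes = set(
            ann.loc[[m for m in consensus_markers if m in ann.index], "gene_id"].dropna()
        )
        population_genes = set(ann["gene_id"].dropna())
        enrichment = (
            annotate.go_enrichment(study_genes, population_genes, gene2go)
            if study_genes
            else pd.DataFrame()
        )
        sig_map = cons.merge(qc_panel.markers, on="marker_id")
        chrom_lengths = {
            c: int(sub["pos"].max()) + 1000
            for c, sub in qc_panel.markers.groupby("chrom")
        }
        karyogram = annotate.karyogram_export(
            sig_map[["marker_id", "chrom", "pos", "trait"]], chrom_lengths
        ) if len(sig_map) else pd.DataFrame()
        out.update(
            {
                "regions": regions,
                "gene2go": gene2go,
                "enrichment": enrichment,
                "karyogram": karyogram,
            }
        )
    return out
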