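"""End-to-end orchestration: filter -> burden -> signatures -> hypoxia ->
associations -> prediction, with tidy TSV outputs per stage.

This is the library behind ``pgin all``; each stage function takes and
returns plain containers so stages can also be run in isolation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import (
    genomic_instability,
    hypoxia,
    outcome_stats,
    predictive_models,
    signatures as sigmod,
    variant_filtering,
)
from .io_formats import (
    RunConfig,
    read_coverage,
    read_expression,
    read_gene_signatures,
    read_metadata,
    read_variant_table,
    write_variant_table,
)

logger = logging.getLogger("pgin")

#: per-outcome KNN feature sets; maternal age joins for SGA
OUTCOME_FEATURES: dict[str, list[str]] = {
    "pe": ["burden", "hypoxia", "fetal_sex"],
    "mvm": ["burden", "hypoxia", "fetal_sex"],
    "sga": ["burden", "hypoxia", "fetal_sex", "maternal_age"],
}


def load_inputs(in_dir: str | Path) -> dict:
    """Read a simulated-bundle-layout input directory."""
    in_dir = Path(in_dir)
    variants = read_variant_table(in_dir / "variants.tsv")
    coverage = {
        p.stem: read_coverage(p) for p in sorted((in_dir / "coverage").glob("*.tsv"))
    }
    expression = read_expression(in_dir / "expression.tsv")
    metadata = read_metadata(in_dir / "metadata.csv")
    gene_sigs = read_gene_signatures(in_dir / "hypoxia_signatures.tsv")
    return {
        "variants": variants,
        "coverage": coverage,
        "expression": expression,
        "metadata": metadata,
        "hypoxia_signatures": gene_sigs,
    }


def run_all(inputs: dict, config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on in-memory inputs; optionally write stage TSVs.

    Returns a dict with the cascade result, instability table, signature
    set and matches, hypoxia scores, cohort table, group comparisons, Cox
    fits, and cross-validated classifier metrics.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- filter cascade ---------------------------------------------------
    cascade = variant_filtering.run_cascade(inputs["variants"], config)
    results["cascade"] = cascade
    logger.info(
        "filter: %(n_input)d in -> %(n_rare)d rare (%(n_rare_genes)d genes), "
        "%(n_rare_damaging)d rare damaging (%(n_rare_damaging_genes)d genes)",
        cascade.summary,
    )
    if out is not None:
        write_variant_table(cascade.rare, out / "rare_variants.tsv")
        write_variant_table(cascade.rare_damaging, out / "rare_damaging_variants.tsv")
        pd.DataFrame([cascade.summary]).to_csv(out / "filter_summary.tsv", sep="\t", index=False)

    # --- genomic instability ----------------------------------------------
    burden = genomic_instability.cohort_instability(cascade.rare, inputs["coverage"], config)
    results["instability"] = burden
    logger.info("burden: scored %d samples", len(burden))
    if out is not None:
        burden.to_csv(out / "instability.tsv", sep="\t")

    # --- mutational signatures --------------------------------------------
    # signatures are characterized on the full somatic SNV set; the
    # rare-variant subset is too sparse per sample for a stable factorization
    sample_ids = list(burden.index)
    catalog = sigmod.build_catalog(cascade.somatic, sample_ids=sample_ids)
    reference = sigmod.read_reference_signatures(config.reference_signature_path)
    sigset = sigmod.extract_signatures(
        catalog, rank=config.signature_rank, n_restarts=config.nmf_restarts, seed=config.seed
    )
    matches = sigmod.match_to_reference(sigset, reference)
    results["catalog"] = catalog
    results["signatures"] = sigset
    results["signature_matches"] = matches
    logger.info(
        "signatures: K=%d, matches: %s",
        config.signature_rank,
        "; ".join(f"{l}->{m} (cos {c:.3f})" for l, (m, c) in zip(sigset.labels, matches)),
    )
    if out is not None:
        catalog.to_frame().to_csv(out / "catalog.tsv", sep="\t", index_label="channel")
        sigmod.write_signature_set(sigset, out / "signatures.tsv")
        sigmod.write_exposures(sigset, out / "exposures.tsv")

    # --- hypoxia ----------------------------------------------------------
    hyp = hypoxia.hypoxia_score(
        inputs["expression"], inputs["hypoxia_signatures"], tie_score=config.hypoxia_tie_score
    )
    results["hypoxia"] = hyp
    if out is not None:
        hyp.to_csv(out / "hypoxia_scores.tsv", sep="\t")

    # --- cohort table -----------------------------------------------------
    meta = inputs["metadata"]
    cohort = outcome_stats.derive_groups(meta)
    cohort = cohort.join(burden[["burden"]], how="inner")
    cohort["hypoxia"] = hyp["combined"].reindex(cohort.index)
    results["cohort"] = cohort
    if out is not None:
        cohort.to_csv(out / "cohort.tsv", sep="\t")

    # --- associations -----------------------------------------------------
    comparisons = outcome_stats.compare_groups(cohort["burden"], cohort["group"])
    hyp_comp = outcome_stats.compare_groups(cohort["hypoxia"], cohort["group"])
    results["burden_comparisons"] = comparisons
    results["hypoxia_comparisons"] = hyp_comp
    contrib = sigmod.group_contributions(sigset, cohort, "group")
    results["group_contributions"] = contrib
    try:
        # correlate the clock-like component (best match to the SBS1 analog)
        # with burden; fall back to the largest-exposure signature
        clock_label = None
        clock_cos = -1.0
        for lab, (ref_name, cos) in zip(sigset.labels, matches):
            is_clock = ref_name == "SBS1" or ref_name.startswith("SBS1_")
            if is_clock and cos > clock_cos:
                clock_label, clock_cos = lab, cos
        rho, p = sigmod.correlate_contribution_burden(sigset, cohort["burden"], label=clock_label)
        results["contribution_burden_spearman"] = {"rho": rho, "p": p, "signature": clock_label or sigset.labels[0]}
    except Exception as exc:  # degenerate small cohorts
        logger.warning("contribution-burden correlation unavailable: %s", exc)
        results["contribution_burden_spearman"] = None
    cox_fits = {}
    for outcome in ("pe", "mvm", "sga"):
        try:
            cox_fits[outcome] = outcome_stats.fit_cox(
                cohort,
                features=["burden", "hypoxia"],
                duration_col="ga_weeks",
                event_col=outcome,
                seed=config.seed,
            )
        except Exception as exc:
            logger.warning("Cox fit for %s failed: %s", outcome, exc)
    results["cox"] = cox_fits
    if out is not None:
        comparisons.to_csv(out / "burden_group_tests.tsv", sep="\t", index=False)
        hyp_comp.to_csv(out / "hypoxia_group_tests.tsv", sep="\t", index=False)
        contrib.to_csv(out / "group_contributions.tsv", sep="\t", index_label="group")
        rows = []
        for outcome, fit in cox_fits.items():
            for feat in fit.coefficients.index:
                rows.append(
                    {
                        "outcome": outcome,
                        "feature": feat,
                        "coef": fit.coefficients[feat],
                        "hr": fit.hazard_ratios[feat],
                        "ci_low": fit.ci_low[feat],
                        "ci_high": fit.ci_high[feat],
                        "p": fit.p_values[feat],
                        "penalizer": fit.penalizer,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "cox_fits.tsv", sep="\t", index=False)

    # --- prediction -------------------------------------------------------
    predictions = {}
    for outcome, feats in OUTCOME_FEATURES.items():
        labels = cohort[outcome].astype(bool)
        if labels.nunique() < 2 or labels.value_counts().min() < 2:
            logger.warning("predict: outcome %s lacks both classes; skipped", outcome)
            continue
        res = predictive_models.cross_validate(
            cohort,
            outcome,
            {outcome: feats},
            k_neighbors=config.knn_neighbors,
            seed=config.seed,
            standardize=config.standardize_features,
        )[outcome]
        predictions[outcome] = res
        logger.info("predict %s: AUC %.3f, accuracy %.3f", outcome, res.auc, res.accuracy)
    results["predictions"] = predictions
    if out is not None:
        pd.DataFrame(
            [
                {"outcome": o, "features": "+".join(r.features), "auc": round(r.auc, 10), "accuracy": round(r.accuracy, 10)}
                for o, r in predictions.items()
            ]
        ).to_csv(out / "prediction_metrics.tsv", sep="\t", index=False)
        for o, r in predictions.items():
            pd.DataFrame(r.roc_points, columns=["fpr", "tpr"]).to_csv(
                out / f"roc_{o}.tsv", sep="\t", index=False
            )
    return results
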