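"""End-to-end helpers: cohort -> feature space -> protocol -> recovery score.

These glue the modules together the way the analysis is meant to be run:
label-conditional imputation of every view (methylation platforms fused
first), assembly into one matrix, the repeated-holdout protocol, and —
for synthetic cohorts with planted signals — scoring how well the
feature-count table recovers the planted genes and their directions of
regulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, LabeledCohort, generate_cohort
from .experiment import (
    RepeatConfig,
    count_features,
    gene_count_table,
    run_experiment,
    select_best_models,
)
from .views import FeatureSpace, assemble_feature_space, fuse_methylation, impute_label_conditional

__all__ = ["build_feature_space", "desk_scale_config", "evaluate_recovery"]


def build_feature_space(cohort: LabeledCohort) -> FeatureSpace:
    """Impute every view label-conditionally and concatenate.

    The two methylation platforms, when both are present, are fused into
    ``methyl_fusion`` before imputation. View order: all non-methylation
    views in cohort order, then the fused methylation view.
    """
    labels = cohort.labels
    views = dict(cohort.views)
    ordered = []
    methyl_pair = [views.pop(n) for n in ("methyl_450", "methyl_27") if n in views]
    for view in views.values():
        ordered.append(impute_label_conditional(view, labels))
    if len(methyl_pair) == 2:
        ordered.append(impute_label_conditional(fuse_methylation(*methyl_pair), labels))
    else:
        ordered.extend(impute_label_conditional(v, labels) for v in methyl_pair)
    return assemble_feature_space(ordered)


def desk_scale_config(seed: int = 0, n_samples: int = 400) -> CohortConfig:
    """A cohort config with the full-scale statistical shape at desk scale.

    Keeps the published class structure (16% TNBC / 63% Luminal A /
    16% Luminal B / 5% HER2), the 15-down/5-up planted-gene split and the
    standardized effect size delta = 2, but shrinks the attribute space to
    ~2,000 columns (1,800 isoforms in 600 genes, 100 miRNAs, 120 methylation
    probes fusing to 100) so the repeated protocol runs in minutes.
    """
    return CohortConfig(
        n_samples=n_samples,
        view_widths={"isoform": 1800, "mirna": 100, "methyl_450": 80, "methyl_27": 40},
        shared_methyl_probes=20,
        isoforms_per_gene=3,
        n_planted_down=15,
        n_planted_up=5,
        effect_size=2.0,
        noise_sd=1.0,
        missing_rate=0.1,
        seed=seed,
    )


def evaluate_recovery(
    cohort_config: CohortConfig,
    repeat_config: RepeatConfig,
    top_n: int = 20,
) -> dict:
    """Run the full protocol on a synthetic cohort and score recovery.

    Returns a dict with the gene-level count table, the fraction of planted
    genes found among its ``top_n`` rows, the fraction of recovered planted
    genes whose direction call matches the planted direction, and the mean
    held-out F1 of the SCM models.
    """
    cohort, planted = generate_cohort(cohort_config)
    fs = build_feature_space(cohort)
    labels = cohort.labels
    results = run_experiment(fs, labels, repeat_config)
    selected = select_best_models(results, repeat_config.k_best, repeat_config.selection_metric)
    attr_table = count_features(selected, fs, labels)
    genes = gene_count_table(attr_table)

    planted_by_gene = {p.gene_symbol: p for p in planted}
    top = genes.head(top_n)
    recovered = [g for g in top.gene_symbol if g in planted_by_gene]
    recovery_fraction = len(recovered) / len(planted_by_gene) if planted_by_gene else float("nan")
    if recovered:
        ok = sum(
            1
            for g in recovered
            if top.loc[top.gene_symbol == g, "direction"].iloc[0]
            == planted_by_gene[g].direction
        )
        direction_accuracy = ok / len(recovered)
    else:
        direction_accuracy = float("nan")
    scm_f1 = [r.test_metrics.f1 for r in results if r.algorithm == "scm"]
    return {
        "gene_counts": genes,
        "attribute_counts": attr_table,
        "planted_genes": sorted(planted_by_gene),
        "recovered_genes": recovered,
        "recovery_fraction": recovery_fraction,
        "direction_accuracy": direction_accuracy,
        "mean_scm_test_f1": float(np.mean(scm_f1)) if scm_f1 else float("nan"),
        "n_samples": cohort_config.n_samples,
        "n_attributes": fs.width,
    }
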