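"""End-to-end orchestration: simulate -> discover -> filter -> DE ->
methylation -> network -> panel -> subtype evaluation with survival.

Each step delegates to the corresponding library module; the analysis
drivers and the acceptance script both run through these functions so that
every reported number comes from the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import annotation, codepot, coexnet, expression, linctype, methlink, subtype_eval
from .syndata import (
    SimulatedStudy,
    SimulationDesign,
    generate_expression,
    generate_survival,
    generate_training_sequences,
    simulate,
)

__all__ = ["PipelineResult", "run_discovery", "run_de_classes", "run_network",
           "run_panel", "run_validation", "run_all"]


def run_discovery(
    study: SimulatedStudy, n_train_per_class: int = 500
) -> tuple[annotation.DiscoveryResult, codepot.ConsensusScorer]:
    """Train the coding-potential consensus on generator sequences and run
    the lincRNA filter cascade over the candidate catalog."""
    seqs, labels = generate_training_sequences(study.design, n_train_per_class)
    scorer = codepot.train_scorers(seqs, labels)
    result = annotation.filter_novel_lincrnas(
        study.novel, study.known, study.sequences, scorer
    )
    return result, scorer


def run_de_classes(
    study: SimulatedStudy, alpha: float = 0.05, fc_min: float = 1.0
) -> tuple[dict, pd.Series]:
    """Tumor-vs-control DE for every (subtype, control-pool) comparison and
    the Class I/II/III assignment.

    Matched-adjacent groups are pooled as the ``adjacent`` control and the
    normal-breast group is the second control, giving the ten comparisons
    the class rules quantify over.
    """
    filtered = expression.low_expression_filter(study.fpkm)
    meta = study.meta.copy()
    meta["group"] = meta["group"].where(
        ~meta["group"].str.startswith("adjacent"), "adjacent"
    )
    tables = {}
    for subtype in expression.TUMOR_GROUPS:
        for control in ("adjacent", "normal"):
            tables[(subtype, control)] = expression.differential_expression(
                filtered, meta, control, subtype, alpha=alpha, fc_min=fc_min
            )
    classes = expression.assign_expression_class(tables)
    return tables, classes


def run_methylation(study: SimulatedStudy, p_max: float = 0.01) -> pd.DataFrame:
    transcripts = list(study.known) + list(study.novel)
    sites = study.cpg.rename(columns={"start": "position"})
    return methlink.significant_meth_regulators(
        transcripts, sites, study.beta, study.fpkm, p_max=p_max
    )


def run_network(
    study: SimulatedStudy,
    lincrna_ids: list[str],
    extra_null_pairs: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation edges for planted cis pairs, planted coding-coding pairs
    and (optionally) random null pairs."""
    catalog = {t.id: t for t in list(study.known) + list(study.novel)}
    pairs = [(l, g, "lincRNA-coding") for l, g, _ in study.truth.cis_pairs]
    pairs += [(a, b, "coding-coding") for a, b, _ in study.truth.coding_coexpressed_pairs]
    for members in study.truth.coexpressed_modules:
        pairs += [
            (a, b, "coding-coding")
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        ]
    if extra_null_pairs:
        rng = np.random.default_rng(seed)
        planted = {frozenset(p[:2]) for p in pairs}
        coding = [t.id for t in study.known if t.biotype == "coding"]
        added = 0
        while added < extra_null_pairs:
            linc = lincrna_ids[rng.integers(len(lincrna_ids))]
            gene = coding[rng.integers(len(coding))]
            if frozenset((linc, gene)) in planted:
                continue
            pairs.append((linc, gene, "lincRNA-coding"))
            added += 1
    return coexnet.build_edges(
        study.fpkm, pairs, ppi=study.ppi_set, catalog=catalog
    )


def run_panel(study: SimulatedStudy) -> linctype.LinctypePanel:
    filtered = expression.low_expression_filter(study.fpkm)
    return linctype.select_linctype(filtered, study.meta)


@dataclass
class ValidationResult:
    clusters: subtype_eval.ClusterAssignment
    ari: float
    logrank: subtype_eval.LogrankResult
    survival: pd.DataFrame = field(repr=False)


def run_validation(
    study: SimulatedStudy,
    panel: linctype.LinctypePanel,
    k: int = 5,
    seed: int = 0,
) -> ValidationResult:
    """Evaluate the panel on an independent simulated tumor cohort.

    Generates a validation cohort (``n_validation_per_subtype`` per
    subtype), k-means-clusters it on the row-centered log2 panel expression,
    scores agreement with the true subtypes (adjusted Rand index), then
    simulates subtype-hazard survival and tests the clusters by log-rank.
    """
    design = study.design
    groups = [(s, design.n_validation_per_subtype) for s in design.subtypes]
    fpkm, meta = generate_expression(
        design, study.truth, study.known, study.novel, groups=groups, cohort="validation"
    )
    members = [m for m in panel.members if m in fpkm.index]
    log_expr = subtype_eval.row_center(np.log2(fpkm.loc[members] + 1.0))
    clusters = subtype_eval.kmeans_cluster(log_expr, k=k, seed=seed)
    truth_labels = meta["group"]
    ari = float(adjusted_rand_score(truth_labels, clusters.labels))
    surv = generate_survival(design, truth_labels, study.truth)
    grouped = [
        (surv.loc[clusters.labels == c, "time"].to_numpy(),
         surv.loc[clusters.labels == c, "event"].to_numpy())
        for c in sorted(pd.unique(clusters.labels))
    ]
    logrank = subtype_eval.logrank_test(grouped)
    return ValidationResult(clusters, ari, logrank, surv)


@dataclass
class PipelineResult:
    study: SimulatedStudy
    discovery: annotation.DiscoveryResult
    de_tables: dict
    classes: pd.Series
    meth: pd.DataFrame
    edges: pd.DataFrame
    panel: linctype.LinctypePanel
    validation: ValidationResult


def run_all(design: SimulationDesign | None = None, seed: int | None = None) -> PipelineResult:
    """The full pipeline from one design/seed."""
    if design is None:
        design = SimulationDesign()
    if seed is not None:
        design = SimulationDesign(**{**design.__dict__, "seed": seed})
    study = simulate(design)
    discovery, _ = run_discovery(study)
    de_tables, classes = run_de_classes(study)
    meth = run_methylation(study)
    edges = run_network(study, discovery.accepted or study.truth.novel_lincrna_ids)
    panel = run_panel(study)
    validation = run_validation(study, panel, seed=design.seed)
    return PipelineResult(study, discovery, de_tables, classes, meth, edges, panel, validation)
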