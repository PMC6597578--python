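"""End-to-end pipeline: simulate -> gene-level CN -> integration ->
prognostic filtering + boosting -> signature -> scoring -> evaluation.

Each stage is a thin call into the corresponding module; this file owns
only the plumbing (which cohorts feed which stage, where thresholds and
seeds travel) and the structured result object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cna, integration, signature as sig, survival as surv
from .simulate import Cohort, GroundTruth, SimulationConfig, simulate_cohorts

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rho_cut: float = 0.6
    p_cut: float = 1e-5
    split: str = "tertile"
    filter_p: float = 0.01
    cv_folds: int = 5
    boost_cv_folds: int = 10
    boost_max_steps: int = 200
    combine: str = "union"
    # univariate screening pool: "candidates" restricts the survival filter
    # to the integration hits; "all" screens every gene (stands in for the
    # study's additional expression-based gene lists)
    screen: str = "candidates"
    seed: int = 0


@dataclass
class PipelineResult:
    cohorts: list[Cohort]
    truth: GroundTruth
    meta: pd.DataFrame
    candidates: dict[str, set]
    filter_records: list
    boost_fit: surv.BoostFit | None
    model: sig.SignatureModel
    training_scores: pd.Series
    cv: sig.CVClassification


def load_cohort(directory, index: int, dialect: str) -> Cohort:
    """Read one cohort from disk (the layout ``write_cohort`` produces:
    segments.seg, genes.bed, expression.tsv, probe_map.tsv, clinical.tsv)."""
    from pathlib import Path

    import pandas as pd

    from .survival import read_clinical

    d = Path(directory)
    segments = cna.read_seg(d / "segments.seg")
    annotation = cna.read_gene_annotation(d / "genes.bed")
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    probe_map = pd.read_csv(d / "probe_map.tsv", sep="\t")
    clinical = read_clinical(d / "clinical.tsv")
    return Cohort(index, dialect, segments, expression, probe_map, clinical, annotation)


def gene_cn_for_cohort(cohort: Cohort) -> cna.GeneCNMatrix:
    called = cna.call_states(cohort.segments, cohort.dialect)
    ann = cohort.annotation
    return cna.assign_gene_cn(called, ann)


def integrate_cohorts(
    cohorts: list[Cohort], rho_cut: float, p_cut: float
) -> tuple[pd.DataFrame, dict[str, set]]:
    sp_stats, an_stats = [], []
    for c in cohorts:
        gm = gene_cn_for_cohort(c)
        expr = cna.collapse_probes(c.expression, c.probe_map)
        name = f"cohort{c.index}"
        if gm.L.notna().any().any():
            sp_stats.append(integration.spearman_per_cohort(expr, gm, name))
        an_stats.append(integration.anova_per_cohort(expr, gm, name))
    sp = pd.concat(sp_stats) if sp_stats else pd.DataFrame(columns=["gene", "cohort", "n", "rho"])
    an = pd.concat(an_stats)
    meta = integration.meta_table(sp, an, rho_cut=rho_cut, p_cut=p_cut)
    return meta, meta.attrs["selection"]


def derive_signature(
    cohorts: list[Cohort],
    candidates: list[str],
    config: PipelineConfig,
    training_cohort: int = 0,
    screen_genes: list[str] | None = None,
) -> tuple[list, surv.BoostFit | None, sig.SignatureModel]:
    """Univariate filter (over ``screen_genes``, default the candidates)
    + boosting over the integration candidates, on the training cohort."""
    train = cohorts[training_cohort]
    records = sig.filter_prognostic(
        screen_genes if screen_genes is not None else candidates,
        train.expression, train.probe_map, train.clinical,
        split=config.split, p_thresh=config.filter_p,
    )
    boost_fit = None
    expr_genes = cna.collapse_probes(train.expression, train.probe_map)
    cand_present = [g for g in candidates if g in expr_genes.index]
    if len(cand_present) >= 2:
        clin = train.clinical.set_index("sample")
        X = expr_genes.loc[cand_present, clin.index].T
        boost_fit = surv.coxboost_select(
            clin["time_months"].to_numpy(), clin["event"].to_numpy(), X,
            max_steps=config.boost_max_steps, cv_folds=config.boost_cv_folds,
            seed=config.seed,
        )
    model = sig.build_signature(
        records,
        boost_fit.coef if boost_fit is not None else None,
        combine=config.combine,
        provenance={
            "split": config.split, "filter_p": config.filter_p,
            "rho_cut": config.rho_cut, "p_cut": config.p_cut,
            "combine": config.combine, "seed": config.seed,
        },
    )
    return records, boost_fit, model


def run_pipeline(config: PipelineConfig, training_cohort: int = 0) -> PipelineResult:
    cohorts, truth = simulate_cohorts(config.simulation)
    meta, selection = integrate_cohorts(cohorts, config.rho_cut, config.p_cut)
    candidates = sorted(selection["union"])
    screen_genes = candidates
    if config.screen == "all" or not candidates:
        screen_genes = sorted(cohorts[0].annotation["gene"])
    if not candidates:
        log.warning("integration selected no candidates; screening all genes")
        candidates = screen_genes
    records, boost_fit, model = derive_signature(
        cohorts, candidates, config, training_cohort, screen_genes=screen_genes
    )
    train = cohorts[training_cohort]
    scores = sig.compute_score(model, train.expression, train.probe_map)
    dec = sig.deceased_label(train.clinical)
    cv = sig.cv_train_classify(scores, dec, k=config.cv_folds, seed=config.seed)
    model.cutoff = cv.cutoff
    return PipelineResult(
        cohorts=cohorts, truth=truth, meta=meta, candidates=selection,
        filter_records=records, boost_fit=boost_fit, model=model,
        training_scores=scores, cv=cv,
    )
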