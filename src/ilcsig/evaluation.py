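"""Assessment of risk stratifications: KM/log-rank by class, adjusted Cox,
ROC/AUC, chi-square enrichment, the Nottingham Prognostic Index, and the
expression clustering recipe (median/MAD standardization, Spearman sample
distance, Pearson gene distance)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score

from .survival import CoxFit, cox_fit, km_estimate, logrank_test

log = logging.getLogger(__name__)


@dataclass
class StrataReport:
    per_class: pd.DataFrame          # n, events, median survival per class
    logrank_chi2: float
    logrank_df: int
    logrank_p: float
    cox: CoxFit | None = None
    hazard_ratio: float = np.nan     # High vs Low, covariate-adjusted
    auc: float = np.nan
    outcome_label: str = "deceased (event at any observed time)"
    km: dict = field(default_factory=dict)


def evaluate_strata(
    classes: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
    scores: pd.Series | None = None,
    deceased: pd.Series | None = None,
) -> StrataReport:
    """KM + log-rank between classes, Cox hazard ratio of the class label
    adjusted for clinical covariates, and AUC of the continuous score
    against the deceased label."""
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    samples = classes.index.intersection(clin.index)
    cls = classes.loc[samples]
    if cls.nunique() < 2:
        raise ValueError("stratification has a single class")
    time = clin.loc[samples, "time_months"].to_numpy(float)
    event = clin.loc[samples, "event"].to_numpy(int)

    km = km_estimate(time, event, cls.to_numpy())
    chi2, df, p = logrank_test(time, event, cls.to_numpy())
    rows = {
        g: {"n": km[g]["n"], "events": km[g]["events"], "median_months": km[g]["median"]}
        for g in km
    }

    fit, hr = None, np.nan
    design = pd.DataFrame(index=samples)
    design["class_high"] = (cls == "High").astype(float)
    if cls.isin(["High", "Low"]).all():
        pass
    else:  # generic 2+ level stratification: indicator per non-reference level
        design = pd.get_dummies(cls, drop_first=True).astype(float)
    for c in covariates or []:
        if c in clin.columns:
            design[c] = clin.loc[samples, c].astype(float)
        else:
            log.warning("covariate %s absent from clinical table; skipped", c)
    design = design.loc[:, design.std(axis=0) > 0]
    if design.shape[1]:
        fit = cox_fit(time, event, design)
        hr = float(np.exp(fit.coef[0]))

    auc = np.nan
    if scores is not None:
        y = (deceased if deceased is not None else clin.loc[samples, "event"]).loc[samples]
        if y.nunique() == 2:
            auc = float(roc_auc_score(y.astype(int), scores.loc[samples]))
    return StrataReport(
        per_class=pd.DataFrame(rows).T,
        logrank_chi2=chi2, logrank_df=df, logrank_p=p,
        cox=fit, hazard_ratio=hr, auc=auc, km=km,
    )


def chi_square_enrichment(classes: pd.Series, annotation: pd.Series) -> dict:
    """Pearson chi-square on the classes x annotation contingency table.

    No continuity correction (plain Pearson statistic); a warning is
    attached when any expected count is below 5, and a degenerate table
    (zero margin) is an error.
    """
    shared = classes.index.intersection(annotation.index)
    table = pd.crosstab(classes.loc[shared], annotation.loc[shared])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any() or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (a margin is zero)")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    low_expected = bool((expected < 5).any())
    if low_expected:
        log.warning("chi-square expected count < 5; test may be unreliable")
    return {
        "table": table,
        "expected": pd.DataFrame(expected, index=table.index, columns=table.columns),
        "chi2": float(chi2),
        "df": int(df),
        "p": float(p),
        "low_expected_warning": low_expected,
    }


def npi(size_cm: float, grade: int, node_stage: int,
        bands: tuple[float, float] = (3.4, 5.4)) -> tuple[float, str]:
    """Nottingham Prognostic Index: 0.2 x size(cm) + grade + nodal stage;
    bands good < 3.4, moderate 3.4-5.4, poor > 5.4 (boundaries inclusive
    into the moderate band, configurable)."""
    if grade not in (1, 2, 3):
        raise ValueError(f"grade must be 1, 2 or 3 (got {grade})")
    if node_stage not in (1, 2, 3):
        raise ValueError(f"node stage must be 1, 2 or 3 (got {node_stage})")
    if size_cm <= 0:
        raise ValueError("tumor size must be positive")
    value = 0.2 * size_cm + grade + node_stage
    lo, hi = bands
    band = "good" if value < lo else ("moderate" if value <= hi else "poor")
    return float(value), band


def npi_table(clinical: pd.DataFrame) -> pd.DataFrame:
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    vals, bands = zip(
        *(
            npi(r.size_cm, int(r.grade), int(r.nodes_positive))
            for r in clin.itertuples()
        )
    )
    return pd.DataFrame({"npi": vals, "npi_band": bands}, index=clin.index)


def _mad(x: np.ndarray) -> np.ndarray:
    return np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)


def standardize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Median-center each gene and divide by its median absolute deviation;
    zero-MAD genes are dropped with a log entry."""
    X = expr.to_numpy(float)
    med = np.median(X, axis=1, keepdims=True)
    mad = _mad(X)
    keep = mad > 0
    if (~keep).any():
        log.info("dropping %d zero-MAD genes before clustering", int((~keep).sum()))
    out = (X[keep] - med[keep]) / mad[keep, None]
    return pd.DataFrame(out, index=expr.index[keep], columns=expr.columns)


def cluster_expression(
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    n_clusters: int = 2,
    method: str = "average",
) -> dict:
    """Hierarchical clustering of samples and genes.

    Genes are standardized (median-center / MAD); sample distance is
    1 - Spearman correlation, gene distance is 1 - Pearson correlation;
    agglomerative clustering (average linkage default) with a k-cluster
    tree cut for sample labels.
    """
    sub = expr.loc[genes] if genes is not None else expr
    if sub.shape[0] < 3 or sub.shape[1] < 3:
        raise ValueError("clustering needs at least 3 genes and 3 samples")
    std = standardize_expression(sub)
    sample_corr = stats.spearmanr(std.to_numpy()).statistic
    if np.isscalar(sample_corr):   # 2 samples edge case
        sample_corr = np.array([[1.0, sample_corr], [sample_corr, 1.0]])
    d_samples = np.clip(1.0 - sample_corr, 0.0, 2.0)
    np.fill_diagonal(d_samples, 0.0)
    d_genes = np.clip(1.0 - np.corrcoef(std.to_numpy()), 0.0, 2.0)
    np.fill_diagonal(d_genes, 0.0)
    link_s = linkage(squareform(d_samples, checks=False), method=method)
    link_g = linkage(squareform(d_genes, checks=False), method=method)
    labels = fcluster(link_s, t=n_clusters, criterion="maxclust")
    return {
        "sample_linkage": link_s,
        "gene_linkage": link_g,
        "sample_labels": pd.Series(labels, index=std.columns, name="cluster"),
        "standardized": std,
    }


def stepwise_cox(
    clinical: pd.DataFrame,
    candidates: list[str],
    entry_p: float = 0.05,
) -> tuple[list[str], CoxFit | None]:
    """Forward-selection Cox model: at each round the candidate whose
    likelihood-ratio test against the current model has the smallest
    p < ``entry_p`` enters; stops when none qualifies."""
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    time = clin["time_months"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    chosen: list[str] = []
    current_ll = None
    fit = None
    remaining = [c for c in candidates if c in clin.columns]
    while remaining:
        best = None
        for c in remaining:
            cols = chosen + [c]
            X = clin[cols].astype(float)
            if (X[c].std() == 0):
                continue
            try:
                cand_fit = cox_fit(time, event, X)
            except Exception:
                continue
            if current_ll is None:
                from .survival import cox_partial_loglik

                null_ll = cox_partial_loglik(time, event, np.zeros(len(time)))
                lr = 2 * (cand_fit.loglik - null_ll)
            else:
                lr = 2 * (cand_fit.loglik - current_ll)
            p = stats.chi2.sf(lr, df=1)
            if best is None or p < best[0]:
                best = (p, c, cand_fit)
        if best is None or best[0] >= entry_p:
            break
        p, c, fit = best
        chosen.append(c)
        remaining.remove(c)
        current_ll = fit.loglik
    return chosen, fit
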