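"""Copy-number-driven expression: per-cohort statistics and meta-analysis.

Two complementary routes identify genes whose expression tracks DNA dosage:

* **Spearman route** — per cohort, the rank correlation between a gene's
  log expression and its gene-level copy-number log-ratio; cohort
  correlations are pooled with a DerSimonian–Laird random-effects model on
  the Fisher-z scale (within-study variance 1/(n-3), inverse-variance
  weights), and the pooled z is back-transformed.  Genes with combined
  effect > 0.6 are retained.

* **ANOVA route** — per cohort, a one-way ANOVA of expression across the
  discrete copy-number states, Benjamini–Hochberg adjusted within cohort;
  p-values are combined across cohorts with Stouffer's weighted Z
  (weights = sample size):  Z = sum(n_i * z_i) / sqrt(sum(n_i^2)) with
  z_i = Phi^{-1}(1 - p_i).  Genes with combined p < 1e-5 are retained.

Cohorts that deliver only discrete states (no log-ratio) contribute to
the ANOVA route only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cna import GeneCNMatrix

log = logging.getLogger(__name__)

MIN_SAMPLES_RHO = 4


@dataclass
class MetaResult:
    """Pooled per-gene result of one meta-analytic route."""

    gene: str
    combined_effect: float = np.nan   # back-transformed pooled correlation
    tau2: float = np.nan              # between-study variance (DL)
    combined_p: float = np.nan
    n_cohorts_used: int = 0


def spearman_per_cohort(
    expr: pd.DataFrame, cn: GeneCNMatrix, cohort: str
) -> pd.DataFrame:
    """Per-gene Spearman rho between expression and copy-number log-ratio.

    ``expr`` is gene-level (genes x samples).  Genes with fewer than 4
    paired samples, or constant expression / log-ratio, get a missing rho.
    Vectorized: Pearson correlation of midranks computed column-wise.
    """
    shared = expr.columns.intersection(cn.L.columns)
    genes = expr.index.intersection(cn.L.index)
    E = expr.loc[genes, shared]
    L = cn.L.loc[genes, shared]
    valid = E.notna() & L.notna()
    # rank within each gene over its valid samples
    Er = E.where(valid).rank(axis=1)
    Lr = L.where(valid).rank(axis=1)
    n = valid.sum(axis=1)
    Ec = Er.sub(Er.mean(axis=1), axis=0)
    Lc = Lr.sub(Lr.mean(axis=1), axis=0)
    num = (Ec * Lc).sum(axis=1)
    den = np.sqrt((Ec**2).sum(axis=1) * (Lc**2).sum(axis=1))
    rho = num / den.replace(0, np.nan)
    rho[n < MIN_SAMPLES_RHO] = np.nan
    dropped = int((n < MIN_SAMPLES_RHO).sum())
    if dropped:
        log.info("%s: %d genes with <%d paired samples, rho missing",
                 cohort, dropped, MIN_SAMPLES_RHO)
    return pd.DataFrame(
        {"gene": genes, "cohort": cohort, "n": n.astype(int).to_numpy(), "rho": rho.to_numpy()}
    )


def anova_per_cohort(
    expr: pd.DataFrame, cn: GeneCNMatrix, cohort: str
) -> pd.DataFrame:
    """One-way ANOVA of expression across discrete copy-number states,
    BH-adjusted across the genes tested within the cohort.

    A gene needs >=2 distinct states, each with >=2 samples; otherwise its
    p is missing (not 1)."""
    shared = expr.columns.intersection(cn.C.columns)
    genes = expr.index.intersection(cn.C.index)
    E = expr.loc[genes, shared].to_numpy(dtype=float)
    C = cn.C.loc[genes, shared].to_numpy(dtype=object)
    valid = ~pd.isna(C) & ~np.isnan(E)
    # per-state sufficient statistics, vectorized over genes
    n_tot = np.zeros(len(genes))
    k_grp = np.zeros(len(genes))
    s_tot = np.zeros(len(genes))
    ssw = np.zeros(len(genes))
    group_stats = []
    from .cna import STATES

    for s in STATES:
        m = (C == s) & valid
        n_s = m.sum(axis=1)
        sum_s = np.where(m, E, 0.0).sum(axis=1)
        sumsq_s = np.where(m, E**2, 0.0).sum(axis=1)
        elig = n_s >= 2
        group_stats.append((elig, n_s, sum_s))
        n_tot += np.where(elig, n_s, 0)
        k_grp += elig
        s_tot += np.where(elig, sum_s, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ssw += np.where(elig, sumsq_s - sum_s**2 / np.maximum(n_s, 1), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = s_tot / n_tot
        ssb = np.zeros(len(genes))
        for elig, n_s, sum_s in group_stats:
            mean_s = sum_s / np.maximum(n_s, 1)
            ssb += np.where(elig, n_s * (mean_s - grand) ** 2, 0.0)
        f_stat = (ssb / np.maximum(k_grp - 1, 1)) / (ssw / np.maximum(n_tot - k_grp, 1))
        pvals = stats.f.sf(f_stat, np.maximum(k_grp - 1, 1), np.maximum(n_tot - k_grp, 1))
    pvals = np.where(ssw <= 0, np.where(ssb <= 0, 1.0, 0.0), pvals)
    pvals = np.where(k_grp >= 2, pvals, np.nan)
    out = pd.DataFrame(
        {"gene": genes, "cohort": cohort, "n": valid.sum(axis=1), "anova_p": pvals}
    )
    tested = out["anova_p"].notna()
    adj = np.full(len(out), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            out.loc[tested, "anova_p"], method="fdr_bh"
        )[1]
    out["anova_p_adj"] = adj
    return out


def fisher_z(rho: np.ndarray) -> np.ndarray:
    return np.arctanh(rho)


def dl_meta_correlation(stats_df: pd.DataFrame) -> dict[str, MetaResult]:
    """DerSimonian–Laird random-effects pooling of per-cohort correlations.

    For each gene with >=2 cohorts reporting (rho, n): Fisher-z transform,
    within-study variance v_i = 1/(n_i - 3); Q = sum(w_i (z_i - z_fixed)^2)
    with w_i = 1/v_i; tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w));
    pooled z = sum(z_i / (v_i + tau^2)) / sum(1 / (v_i + tau^2)), back-
    transformed with tanh.  Cohorts with n <= 3 are excluded.
    """
    results: dict[str, MetaResult] = {}
    use = stats_df.dropna(subset=["rho"])
    use = use[use["n"] > 3]
    for g, sub in use.groupby("gene"):
        if len(sub) < 2:
            if len(sub) == 1:
                r = float(sub["rho"].iloc[0])
                results[g] = MetaResult(g, combined_effect=r, tau2=0.0, n_cohorts_used=1)
            continue
        z = fisher_z(sub["rho"].to_numpy(dtype=float))
        v = 1.0 / (sub["n"].to_numpy(dtype=float) - 3.0)
        w = 1.0 / v
        z_fixed = np.sum(w * z) / np.sum(w)
        q = np.sum(w * (z - z_fixed) ** 2)
        k = len(z)
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (v + tau2)
        z_pooled = np.sum(w_re * z) / np.sum(w_re)
        se = np.sqrt(1.0 / np.sum(w_re))
        p = 2.0 * stats.norm.sf(abs(z_pooled) / se)
        results[g] = MetaResult(
            g, combined_effect=float(np.tanh(z_pooled)), tau2=float(tau2),
            combined_p=float(p), n_cohorts_used=k,
        )
    return results


def stouffer_meta(
    stats_df: pd.DataFrame, use_adjusted: bool = True
) -> dict[str, MetaResult]:
    """Stouffer's sample-size-weighted Z combination of per-cohort ANOVA p.

    z_i = Phi^{-1}(1 - p_i); Z = sum(n_i z_i) / sqrt(sum(n_i^2));
    combined p = 1 - Phi(Z).  BH-adjusted per-cohort p-values are combined
    by default (set ``use_adjusted=False`` for raw p).  Zero p-values are
    clipped to the smallest positive float and logged.
    """
    col = "anova_p_adj" if use_adjusted else "anova_p"
    results: dict[str, MetaResult] = {}
    use = stats_df.dropna(subset=[col])
    tiny = np.finfo(float).tiny
    if (use[col] <= 0).any():
        log.warning("%d p-values at 0 clipped to %g", int((use[col] <= 0).sum()), tiny)
    for g, sub in use.groupby("gene"):
        if len(sub) < 2:
            continue
        p = np.clip(sub[col].to_numpy(dtype=float), tiny, 1.0)
        n = sub["n"].to_numpy(dtype=float)
        z = stats.norm.isf(p)      # Phi^{-1}(1 - p)
        zc = np.sum(n * z) / np.sqrt(np.sum(n**2))
        results[g] = MetaResult(
            g, combined_p=float(stats.norm.sf(zc)), n_cohorts_used=len(sub)
        )
    return results


def select_candidates(
    spearman_meta: dict[str, MetaResult],
    anova_meta: dict[str, MetaResult],
    rho_cut: float = 0.6,
    p_cut: float = 1e-5,
) -> dict[str, set[str]]:
    """Retention by strict thresholds: combined effect > rho_cut (Spearman
    route), combined p < p_cut (ANOVA route).  Returns the disjoint sets
    ``spearman_only``, ``anova_only``, ``both`` and their ``union``."""
    by_rho = {g for g, m in spearman_meta.items() if m.combined_effect > rho_cut}
    by_p = {g for g, m in anova_meta.items() if m.combined_p < p_cut}
    return {
        "spearman_only": by_rho - by_p,
        "anova_only": by_p - by_rho,
        "both": by_rho & by_p,
        "union": by_rho | by_p,
    }


def meta_table(
    spearman_stats: pd.DataFrame,
    anova_stats: pd.DataFrame,
    rho_cut: float = 0.6,
    p_cut: float = 1e-5,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Full per-gene meta table: pooled effect, tau2, combined p, selection."""
    dl = dl_meta_correlation(spearman_stats)
    st = stouffer_meta(anova_stats, use_adjusted=use_adjusted)
    sel = select_candidates(dl, st, rho_cut, p_cut)
    genes = sorted(set(dl) | set(st))
    rows = []
    for g in genes:
        d = dl.get(g)
        s = st.get(g)
        which = []
        if d is not None and d.combined_effect > rho_cut:
            which.append("spearman")
        if s is not None and s.combined_p < p_cut:
            which.append("anova")
        rows.append(
            {
                "gene": g,
                "combined_effect": d.combined_effect if d else np.nan,
                "tau2": d.tau2 if d else np.nan,
                "combined_p": s.combined_p if s else np.nan,
                "n_cohorts_spearman": d.n_cohorts_used if d else 0,
                "n_cohorts_anova": s.n_cohorts_used if s else 0,
                "selected_by": "+".join(which),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["selection"] = sel
    return out
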