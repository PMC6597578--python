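"""Prognostic metagene construction, scoring and High/Low classification.

A candidate gene enters the signature when (i) the Kaplan–Meier curves of
its expression tertiles (or quartiles) spread monotonically, (ii) all of
its probes agree in direction, and (iii) the k-group log-rank test is
significant.  Member genes carry a coefficient of +1 when high expression
is associated with poor outcome and -1 otherwise, and the per-sample score
is the signed combination

    score = (sum over +1 genes of expression)/N - (sum over -1 genes)/N

i.e. the mean of each arm scaled by the arm's share of the N signature
genes.  Before scoring, each sample's signature-gene expression vector is
rescaled to [0, 100] to widen the dynamic range.  The High/Low cutoff is
trained by five-fold cross-validation: on each training split the ROC
cutoff maximizing sensitivity + specificity for predicting deceased cases
is chosen, and the held-out fold is classified with it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import fast_km_rmst, fast_logrank

log = logging.getLogger(__name__)


@dataclass
class GeneFilterRecord:
    gene: str
    probe_p: dict[str, float]
    monotonic: bool
    probes_consistent: bool
    direction: int | None      # +1 high-expression-bad, -1 low-expression-bad
    passed: bool


def _bin_labels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Ordered expression bins (0 = lowest) by quantile cut; ties keep
    bins as balanced as the data allow."""
    ranks = pd.Series(values).rank(method="first").to_numpy()
    return np.minimum((ranks - 1) * n_bins // len(values), n_bins - 1).astype(int)


def _probe_assessment(expr_row, time, event, n_bins, horizon):
    """Per-probe: k-group log-rank p, monotonicity of per-bin restricted
    mean survival, and direction (+1 when the top bin does worst)."""
    bins = _bin_labels(np.asarray(expr_row, float), n_bins)
    chi2, df, p = fast_logrank(time, event, bins)
    means = [fast_km_rmst(time[bins == b], event[bins == b], horizon) for b in range(n_bins)]
    diffs = np.diff(means)
    if np.all(diffs < 0):
        return p, True, +1        # survival shrinks as expression rises
    if np.all(diffs > 0):
        return p, True, -1
    return p, False, 0


def filter_prognostic(
    candidates: list[str],
    expression: pd.DataFrame,
    probe_map: pd.DataFrame,
    clinical: pd.DataFrame,
    split: str = "tertile",
    p_thresh: float = 0.01,
) -> list[GeneFilterRecord]:
    """Univariate prognostic filter over candidate genes.

    ``expression`` is probe-level (probes x samples); every probe of a gene
    must pass the log-rank threshold with monotone restricted-mean-survival
    ordering and the same direction for the gene to pass.  The restricted
    mean is computed to the maximum observed follow-up.
    """
    if split not in ("tertile", "quartile"):
        raise ValueError("split must be 'tertile' or 'quartile'")
    n_bins = 3 if split == "tertile" else 4
    clin = clinical.set_index("sample")
    samples = expression.columns.intersection(clin.index)
    time = clin.loc[samples, "time_months"].to_numpy(float)
    event = clin.loc[samples, "event"].to_numpy(int)
    horizon = float(time.max())
    probes_by_gene = probe_map.groupby("gene")["probe"].apply(list)

    records = []
    for g in candidates:
        if g not in probes_by_gene.index:
            log.info("gene %s has no probes in the expression matrix; skipped", g)
            continue
        probes = [p for p in probes_by_gene[g] if p in expression.index]
        if not probes:
            log.info("gene %s probes absent from expression matrix; skipped", g)
            continue
        pvals, monos, dirs = {}, [], []
        for p in probes:
            pv, mono, d = _probe_assessment(
                expression.loc[p, samples].to_numpy(), time, event, n_bins, horizon
            )
            pvals[p] = pv
            monos.append(mono)
            dirs.append(d)
        all_pass = all(pv < p_thresh for pv in pvals.values()) and all(monos)
        consistent = all(monos) and len(set(dirs)) == 1
        passed = all_pass and consistent
        direction = dirs[0] if passed else None
        records.append(
            GeneFilterRecord(g, pvals, all(monos), consistent, direction, passed)
        )
    return records


@dataclass
class SignatureModel:
    """Deployable prognostic metagene: gene list, signed unit coefficients,
    and the trained score cutoff."""

    genes: list[str]
    coefficients: list[int]
    cutoff: float = np.nan
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients must align")
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if any(c not in (1, -1) for c in self.coefficients):
            raise ValueError("coefficients must be +1 or -1")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_positive(self) -> int:
        return sum(1 for c in self.coefficients if c == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for c in self.coefficients if c == -1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(d["genes"], [int(c) for c in d["coefficients"]],
                   float(d.get("cutoff", np.nan)), d.get("provenance", {}))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene": self.genes, "coefficient": self.coefficients}).to_csv(
            path, sep="\t", index=False
        )


def build_signature(
    filter_records: list[GeneFilterRecord],
    boost_coef: pd.Series | None = None,
    combine: str = "union",
    provenance: dict | None = None,
) -> SignatureModel:
    """Combine univariate-filtered genes with boosting-selected genes.

    Directions come from the filter records where available; a gene picked
    only by boosting takes the sign of its boosted coefficient.  ``combine``
    is ``union`` (default) or ``intersection``.
    """
    filtered = {r.gene: r.direction for r in filter_records if r.passed}
    boosted = {}
    if boost_coef is not None:
        boosted = {g: int(np.sign(v)) for g, v in boost_coef.items() if v != 0}
    if combine == "union":
        genes = sorted(set(filtered) | set(boosted))
    elif combine == "intersection":
        genes = sorted(set(filtered) & set(boosted))
    else:
        raise ValueError("combine must be 'union' or 'intersection'")
    if not genes:
        raise ValueError("no genes survive signature construction")
    coefs = [filtered.get(g, boosted.get(g)) for g in genes]
    return SignatureModel(genes, coefs, provenance=provenance or {})


def rescale_0_100(submatrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample affine rescale of the signature-gene expression to
    [0, 100]:  A -> (A - min(A)) / (max(A) - min(A)) * 100.

    ``submatrix`` is genes x samples; each sample (column) is rescaled on
    its own min/max over the signature genes.
    """
    mins = submatrix.min(axis=0)
    maxs = submatrix.max(axis=0)
    span = maxs - mins
    flat = span[span == 0]
    if len(flat):
        raise ValueError(
            f"constant signature-gene expression in sample(s) {list(flat.index)}; "
            "cannot rescale to 0-100"
        )
    return (submatrix - mins) / span * 100.0


def compute_score(
    model: SignatureModel,
    expression: pd.DataFrame,
    probe_map: pd.DataFrame | None = None,
    rescale: bool = True,
    max_missing: float = 0.10,
) -> pd.Series:
    """Signed metagene score per sample.

    Probe-level input is collapsed to genes by averaging when a probe map
    is given.  More than ``max_missing`` of the model genes absent is an
    error; otherwise N, Np, Nn are renormalized to the present genes with
    a warning.  With ``rescale`` the signature-gene submatrix is first
    mapped to [0, 100] per sample.
    """
    if probe_map is not None:
        from .cna import collapse_probes

        expression = collapse_probes(expression, probe_map)
    present = [g for g in model.genes if g in expression.index]
    missing = model.n - len(present)
    if missing > max_missing * model.n:
        raise ValueError(
            f"{missing}/{model.n} signature genes missing from the expression matrix"
        )
    if missing:
        log.warning("%d signature genes missing; renormalizing N", missing)
    coefs = pd.Series(model.coefficients, index=model.genes).loc[present]
    sub = expression.loc[present]
    if rescale:
        sub = rescale_0_100(sub)
    n = len(present)
    score = sub.mul(coefs, axis=0).sum(axis=0) / n
    score.name = "score"
    return score


def roc_optimal_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff maximizing sensitivity + specificity of ``score > cutoff``
    for the positive (deceased) label; candidates are the midpoints of
    consecutive sorted unique scores plus open ends, lowest-winning ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        if sens + spec > best_j + 1e-12:
            best_j, best_c = sens + spec, c
    return float(best_c)


@dataclass
class CVClassification:
    classes: pd.Series                   # per-sample "High"/"Low"
    fold_of: pd.Series                   # per-sample held-out fold id
    fold_cutoffs: list[float]
    cutoff: float                        # deployable: median of fold cutoffs
    seed: int


def cv_train_classify(
    scores: pd.Series,
    deceased: pd.Series,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> CVClassification:
    """Five-fold cross-validated High/Low classification.

    For each fold the ROC-optimal cutoff is chosen on the other k-1 folds
    and applied to the held-out fold, so every sample is classified exactly
    once; the deployable cutoff is the median of the fold cutoffs.
    """
    scores = scores.astype(float)
    y = deceased.loc[scores.index].astype(int)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(scores))
    if stratify:
        pos = idx[y.to_numpy() == 1]
        neg = idx[y.to_numpy() == 0]
        rng.shuffle(pos)
        rng.shuffle(neg)
        folds = [np.sort(np.concatenate([pos[i::k], neg[i::k]])) for i in range(k)]
    else:
        perm = rng.permutation(idx)
        folds = [np.sort(perm[i::k]) for i in range(k)]

    classes = pd.Series(index=scores.index, dtype=object)
    fold_of = pd.Series(index=scores.index, dtype=int)
    cutoffs = []
    for fi, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        ytr = y.iloc[train]
        if ytr.nunique() < 2:
            raise ValueError(
                "a training split contains a single outcome class; "
                "use stratified folds (stratify=True)"
            )
        c = roc_optimal_cutoff(scores.iloc[train].to_numpy(), ytr.to_numpy())
        cutoffs.append(c)
        held = scores.index[test]
        classes.loc[held] = np.where(scores.loc[held] > c, "High", "Low")
        fold_of.loc[held] = fi
    return CVClassification(
        classes=classes, fold_of=fold_of, fold_cutoffs=cutoffs,
        cutoff=float(np.median(cutoffs)), seed=seed,
    )


def deceased_label(clinical: pd.DataFrame, horizon_months: float | None = None) -> pd.Series:
    """Binary deceased label: event observed (optionally within a follow-up
    horizon, e.g. 120 months for a 10-year endpoint)."""
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    ev = clin["event"].astype(int)
    if horizon_months is not None:
        ev = ((clin["event"] == 1) & (clin["time_months"] <= horizon_months)).astype(int)
    ev.name = "deceased"
    return ev


def classify(model: SignatureModel, scores: pd.Series) -> pd.Series:
    """Apply the deployable cutoff: High when score > cutoff."""
    if not np.isfinite(model.cutoff):
        raise ValueError("model has no trained cutoff")
    out = pd.Series(np.where(scores > model.cutoff, "High", "Low"), index=scores.index)
    out.name = "class"
    return out
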