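# ilcsig

Derivation and application of prognostic metagenes for invasive lobular
breast carcinoma (ILC) from integrated DNA copy-number, expression and
survival data — with a synthetic multi-cohort generator standing in for
controlled-access patient cohorts.

## Who this is for

Computational biologists who want a tested, reusable implementation of the
integrative signature-building procedure used in ILC genomics: gene-level
copy-number calling from heterogeneous segment formats, meta-analytic
detection of dosage-driven expression, survival-based gene filtering,
boosted Cox variable selection, signed metagene scoring and cross-validated
High/Low risk classification.

## The method

**Gene-level copy number.** Per-cohort segments (absolute copies,
CBS-smoothed log-ratios, or pre-called states) are mapped to the five-state
vocabulary HOMD/HETD/NEUT/GAIN/AMP (absolute dialect: 0 / 1 / 2 / 3–5 / ≥6
copies; log-ratio dialect: ±0.3 gain/loss cutoffs). A gene inside one
segment inherits its state C(s,g) and log-ratio L(s,g); a gene broken by
segments takes the overlapping segment maximizing |severity| with the
severity map {NEUT: 0, GAIN: +1, HETD: −1, AMP: +2, HOMD: −2}.

**Dosage-driven expression.** Per cohort, Spearman ρ between expression and
L(s,g), pooled across cohorts by a DerSimonian–Laird random-effects model
on the Fisher-z scale (within-study variance 1/(n−3)); and a one-way ANOVA
of expression across C(s,g) states, BH-adjusted per cohort and combined by
Stouffer's weighted Z,

    Z = Σᵢ nᵢ zᵢ / √(Σᵢ nᵢ²),   zᵢ = Φ⁻¹(1 − pᵢ).

Genes with combined effect > 0.6 or combined P < 10⁻⁵ are candidates.

**Prognostic filtering.** A candidate gene enters the signature when its
expression tertiles (or quartiles) yield Kaplan–Meier curves with a
monotone spread (computable proxy: strictly ordered restricted mean
survival), all probes agree in direction, and the k-group log-rank test has
P < 0.01. In parallel, component-wise likelihood-based boosting of a Cox
model (penalized univariate updates, 10-fold cross-validated step count,
penalty = 9 × events) selects a multivariate gene set; the union forms the
signature.

**Scoring and classification.** Member genes carry coefficients cᵢ ∈ {+1, −1}
(+1 when high expression is adverse). Per sample, the signature-gene vector
A is rescaled to (A − min A)/(max A − min A) × 100 and scored as

    score = (Σ₊ expr / Np)(Np/N) − (Σ₋ expr / Nn)(Nn/N),

the signed arm means weighted by arm share. Five-fold cross-validation picks
each fold's ROC-optimal cutoff (max sensitivity + specificity for predicting
deceased cases) on the training folds and classifies the held-out fold;
the deployable cutoff is the median of fold cutoffs.

## Worked example

```python
from ilcsig import SimulationConfig, PipelineConfig, run_pipeline
from ilcsig.signature import compute_score, classify
from ilcsig.survival import logrank_test

sim = SimulationConfig(
    n_cohorts=2, cohort_sizes=(150, 100), n_genes=300,
    n_cn_driven=20, n_prognostic=30, hazard_ratio=2.5,
    dialects=("absolute", "logratio"), seed=7, two_probes_per_gene=True,
)
config = PipelineConfig(simulation=sim, screen="all", boost_max_steps=50, seed=7)
result = run_pipeline(config, training_cohort=0)

model = result.model
print(f"signature: {model.n} genes ({model.n_positive} risk, {model.n_negative} protective)")
print(f"trained High/Low cutoff: {model.cutoff:.2f}")

holdout = result.cohorts[1]
scores = compute_score(model, holdout.expression, holdout.probe_map)
classes = classify(model, scores)
clin = holdout.clinical.set_index("sample")
chi2, df, p = logrank_test(
    clin["time_months"].to_numpy(), clin["event"].to_numpy(),
    classes.loc[clin.index].to_numpy(),
)
print(f"held-out cohort: {(classes == 'High').sum()} High / {(classes == 'Low').sum()} Low")
print(f"log-rank chi2 = {chi2:.1f} (df {df}), p = {p:.2e}")
```

Output:

```
signature: 30 genes (13 risk, 17 protective)
trained High/Low cutoff: 1.49
held-out cohort: 40 High / 60 Low
log-rank chi2 = 19.7 (df 1), p = 9.05e-06
```

The generator planted a 30-gene prognostic program with a hazard ratio of
2.5 per standard deviation of the latent risk; the pipeline re-derives a
signature from the training cohort alone, and its High/Low split separates
survival in the held-out cohort far below the P < 0.01 bar.

The same pipeline is scriptable from the shell:

```
ilcsig run-all --seed 7 --config config.yaml --out results/
ilcsig simulate --seed 1 --out data/
ilcsig cn-genes --seg data/cohort0/segments.seg --genes data/cohort0/genes.bed \
    --dialect absolute --out results/cohort0
ilcsig score --model results/signature.json --expr new_expression.tsv \
    --probe-map probe_map.tsv --out scores.tsv
```

## Layout

- `src/ilcsig/simulate.py` — synthetic multi-cohort generator with planted truth
- `src/ilcsig/cna.py` — segment reading, state calling, gene-level C/L matrices
- `src/ilcsig/integration.py` — Spearman/ANOVA statistics, DL and Stouffer meta-analysis
- `src/ilcsig/survival.py` — KM, log-rank, Cox Newton–Raphson, boosting
- `src/ilcsig/signature.py` — prognostic filter, scoring, CV classification
- `src/ilcsig/evaluation.py` — strata reports, enrichment, NPI, clustering
- `src/ilcsig/pipeline.py`, `src/ilcsig/cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
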