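# Methods

## Scope and design

`ilcsig` implements the full derivation chain of a copy-number-aware
prognostic metagene for invasive lobular breast carcinoma: gene-level
copy-number calling, two-route meta-analytic integration with expression,
survival-based gene selection, signed scoring and cross-validated risk
classification. Real ILC cohorts are controlled-access; the package
therefore ships a first-class synthetic generator whose planted structure
lets every stage be validated against ground truth.

## Synthetic data model

**Genome and cohorts.** A toy genome of 3 chromosomes × 100 Mb carries
`n_genes` evenly spaced 50-kb genes (default 2,000). Three cohorts of
differing size (default 30/60/80) deliver copy number in different
dialects — absolute integer copies, CBS-style log-ratios, or pre-called
discrete states — mirroring the heterogeneity of real multi-cohort
copy-number data. Coordinates are 0-based half-open in memory; SEG files
are written/read as 1-based inclusive.

**Copy-number events.** Four recurrent events emulate the ILC landscape's
mix of arm-level gains/losses and focal high-level amplification: a 1q-like
arm gain (3 copies), a 2q-like arm loss (1 copy), a focal amplification
(7 copies) and a focal homozygous deletion (0 copies). Each sample carries
each event independently with probability `alteration_fraction` (default
0.4 for arm events; half/quarter that for the focal amp/deletion). Segments
tile each chromosome at event boundaries.

**Dosage-driven expression.** `n_cn_driven` genes (default 40) are drawn
round-robin from the altered regions; their log-scale expression is
`baseline + cn_expr_slope × (copies − 2) + N(0, expr_noise_sd²)`. The
defaults `cn_expr_slope = 2.75`, `expr_noise_sd = 1.0` put the within-cohort
Spearman correlation for a gain-region gene near 0.8 (point-biserial
algebra: r² = s²pq / (s²pq + σ²) with carrier fraction p = 0.4), the regime
in which strongly dosage-driven genes live in real tumors. Gene baselines
are N(7, 1), shared across cohorts. An optional two-probe mode duplicates
each gene's signal with independent noise to exercise the multi-probe
consistency filter.

**Prognostic program and survival.** `n_prognostic` genes (default 30) are
drawn from copy-number-neutral genes, each with a random direction ±1; a
per-sample latent factor u ~ N(0,1) shifts each member by
`direction × prognostic_effect × u` (default loading 1.0, i.e. unit
signal-to-noise per gene). The recorded latent risk is the standardized,
sign-corrected mean of the realized member-gene expression — exactly the
quantity a signed metagene estimates — and survival times are exponential
with hazard `baseline_hazard × hazard_ratio^risk` (defaults 0.01/month and
2.5). Censoring is uniform on [0, T], with T solved by root finding so that
the expected censoring fraction E[(1 − e^{−λT})/(λT)] equals `censor_rate`
(default 0.3); simpler fixed-horizon schemes bias early follow-up.
Grade, tumor size and nodal stage are emitted with a mild dependence on the
latent risk so multivariate adjustment has something to adjust for. A
`binary_risk` switch makes the latent factor two-group, giving closed-form
expectations for Kaplan–Meier medians in tests.

**Randomness.** All draws go through `numpy.random.default_rng` (PCG64)
seeded with `(seed, cohort, stream)` tuples, one fixed stream id per
generation stage, so outputs are bit-identical across runs and platforms
and independent of call order.

**What the generator does not emulate.** Allele-specific copy number,
tumor purity and ploidy artifacts, microarray noise spectra and batch
effects, correlated gene-gene expression beyond the planted program, and
non-exponential hazards. Passing tests therefore demonstrate correctness
of the algorithms under the stated generative assumptions, not performance
on real tumors.

## Copy-number processing

State calling per dialect: absolute copies 0 → HOMD, 1 → HETD, 2 → NEUT,
3–5 → GAIN, ≥6 → AMP; log-ratios ±0.3 for gain/loss with amplification and
homozygous-deletion cutoffs defaulting to ±1.0 (real pipelines take these
from sample-specific GISTIC output, which is out of scope; the cutoffs are
configurable); discrete labels are alias-normalized (LOSS→HETD, HD→HOMD, …).
Discrete-only cohorts have no log-ratio and participate in the ANOVA route
only.

Gene assignment follows maximal severity. Tie-breaks, which the severity
rule leaves open, are deterministic: larger overlap first, then the
positive-severity state (AMP over HOMD), then the leftmost segment. A gene
partially overlapped by a single segment goes through the same rule rather
than the containment shortcut. Strand is ignored.

## Integration statistics

The Spearman route computes rank correlations as Pearson correlations of
midranks (vectorized over genes, identical to `scipy.stats.spearmanr`,
verified in tests), requires ≥4 paired samples, and pools per-cohort
correlations with DerSimonian–Laird: Fisher z, within-study variance
1/(n−3), moment estimator of τ² truncated at zero, inverse-variance
weights 1/(vᵢ + τ²), pooled z back-transformed with tanh. The ANOVA route
runs a one-way F test across states with ≥2 states of ≥2 samples each
(single-state genes are missing, not P = 1), adjusts per cohort with
Benjamini–Hochberg, and combines with sample-size-weighted Stouffer Z.
Adjusted p-values are combined by default — the procedure applies BH per
dataset *before* meta-analysis — with a `use_adjusted=False` switch since
combining adjusted p-values is statistically unconventional; both modes are
tested. The one-sided conversion Φ⁻¹(1 − p) matches the inherently
one-sided F-test p-value. Retention is strict: combined effect > 0.6,
combined P < 10⁻⁵, over ≥2 contributing cohorts. The combined-effect
threshold is applied on the correlation scale (back-transformed), not the
Fisher-z scale.

## Survival machinery

Kaplan–Meier and the unweighted k-group log-rank test delegate to
lifelines; `fast_logrank` / `fast_km_rmst` are numpy re-implementations of
the same statistics for per-gene screening loops, with equality to
lifelines asserted across random datasets in the test suite.

The Cox fit is a Newton–Raphson maximizer of the partial likelihood with
the Efron tie correction (Breslow available as an option), convergence at
gradient norm < 1e-8, at most 100 iterations with step halving; failure
raises an error carrying the last iterate. Standard errors come from the
inverse observed information.

Component-wise likelihood-based boosting updates one coefficient per step
by the penalized univariate Newton step Δⱼ = Uⱼ/(Iⱼ + λ) against the
current linear predictor, choosing the candidate with the largest
penalized-likelihood gain U²/(2(I + λ)). Candidates are standardized to
mean 0, unit variance; the penalty defaults to 9 × (number of events), the
convention of likelihood-based boosting for Cox models, and the step count
maximizes the mean event-stratified 10-fold cross-validated validation
partial likelihood (full-minus-train formulation), searched to
`max_steps = 200` with early stop after 20 non-improving steps. The
boosting penalty and step budget are conventions, not values fixed by the
original procedure, and are exposed as configuration.

## Signature construction and deployment

The univariate filter splits samples into expression tertiles by default
(quartiles available: both conventions are in circulation and the choice is
recorded in the model provenance). "Monotone spread" of the KM curves is
operationalized as strictly ordered per-bin restricted mean survival with
horizon at maximum follow-up, since visual monotonicity needs a computable
proxy. A gene passes when all probes pass the log-rank threshold
(P < 0.01), are monotone, and agree in direction; direction +1 means the
high-expression bin does worst. Filtered and boosting-selected genes are
combined by union (intersection available for sensitivity analysis);
directions from the filter take precedence, boosting-only genes use the
sign of the boosted coefficient.

Scoring renormalizes N, Np, Nn when ≤10% of model genes are absent from an
expression matrix and errors beyond that. Per-sample 0–100 rescaling is
applied to the signature-gene submatrix (rescaling before subsetting would
let non-signature genes shift the score's dynamic range). Classification
trains one ROC-optimal cutoff per cross-validation fold — candidates are
midpoints of consecutive sorted unique training scores plus open ends, ties
resolved toward the lowest cutoff — and the deployable cutoff is the median
of fold cutoffs, a choice the within-CV-only training procedure leaves
open. The deceased label is the observed event flag, optionally restricted
to a follow-up horizon (e.g. 120 months).

## Evaluation

Strata reports combine KM/log-rank, a Cox model of the High/Low indicator
adjusted for requested clinical covariates, and the AUC of the continuous
score against the deceased label. "Stepwise" multivariate modeling is
forward selection by likelihood-ratio entry P < 0.05, one reading of a
procedure whose criterion is not pinned down. Chi-square enrichment uses
the plain Pearson statistic (no continuity correction) and flags expected
counts < 5. NPI = 0.2 × size(cm) + grade + nodal stage with bands
good < 3.4 ≤ moderate ≤ 5.4 < poor. Expression clustering median-centers
each gene, divides by MAD (zero-MAD genes dropped), and clusters with
average linkage on 1 − Spearman (samples) and 1 − Pearson (genes)
distances.

## Problem sizes in tests

The acceptance-style properties run at desk scale chosen once as the study
conditions: integration recovery uses the generator defaults (3 cohorts of
30/60/80, 40 planted dosage genes among 2,000, 20 seeds); the end-to-end
property uses a 150-sample training cohort and 100-sample held-out cohort
with 300 genes, 30 planted prognostic genes (HR 2.5) and a boosting step
budget of 50; null calibrations use 200–500 replicates. The full suite
completes in a few minutes on one CPU.

## Known limitations

- The log-ratio AMP/HOMD cutoffs are global per run, not sample-specific.
- The boosting CV curve uses the full-minus-train partial-likelihood
  contribution; alternatives (verweij–van houwelingen variants) differ
  slightly in small samples.
- Monotonicity via restricted-mean ordering is stricter than visual
  inspection for noisy middle bins.
- No batch correction, purity adjustment or probe re-annotation; inputs
  are assumed pre-normalized and mapped.
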