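"""Multi-cohort synthetic data with planted copy-number and survival structure.

Emulates the inputs of an integrative copy-number / expression / survival
study of invasive lobular breast carcinoma: several cohorts of different
size, each delivering DNA copy number in a different encoding dialect
(absolute integer copies, CBS-style log-ratios, or pre-called discrete
states), together with log-scale expression matrices and clinical tables
with a breast-cancer-specific-survival endpoint.

Planted structure, recorded in :class:`GroundTruth`:

* recurrent arm-level gains/losses and a focal amplification on a toy
  genome of three 100-Mb chromosomes;
* a set of dosage-driven genes whose expression is a linear function of
  copy number plus Gaussian noise;
* a prognostic gene program: each member gene is shifted by a per-sample
  latent factor with a planted direction (+1 = high expression is bad),
  and survival times are exponential with hazard
  ``baseline_hazard * hazard_ratio ** risk``.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``(seed, cohort, stream)`` tuples, so every artifact is bit-identical
across runs and platforms for a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

CHROM_LENGTH = 100_000_000
N_CHROMS = 3
GENE_LENGTH = 50_000

# rng stream ids; keep stable so outputs do not depend on call order
_STREAM_TRUTH = 99
_STREAM_BASELINE = 98
_STREAM_CARRIERS = 0
_STREAM_EXPR = 1
_STREAM_SURV = 2

VALID_DIALECTS = ("absolute", "logratio", "discrete")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class AlterationEvent:
    """A recurrent copy-number event present in a fraction of samples."""

    name: str
    chrom: str
    start: int
    end: int
    copies: int          # absolute copy number in carrier samples
    fraction: float      # fraction of samples carrying the event


@dataclass
class SimulationConfig:
    n_cohorts: int = 3
    cohort_sizes: Sequence[int] = (30, 60, 80)
    n_genes: int = 2000
    n_cn_driven: int = 40
    cn_expr_slope: float = 2.75
    expr_noise_sd: float = 1.0
    n_prognostic: int = 30
    prognostic_effect: float = 1.0
    hazard_ratio: float = 2.5
    censor_rate: float = 0.3
    baseline_hazard: float = 0.01     # events per month
    seed: int = 0
    dialects: Sequence[str] = ("absolute", "logratio", "discrete")
    alteration_fraction: float = 0.4
    two_probes_per_gene: bool = False
    binary_risk: bool = False
    allow_overlap: bool = False       # let planted gene sets overlap

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ConfigurationError("cohort_sizes length must equal n_cohorts")
        if len(self.dialects) != self.n_cohorts:
            raise ConfigurationError("dialects length must equal n_cohorts")
        for d in self.dialects:
            if d not in VALID_DIALECTS:
                raise ConfigurationError(f"unknown copy-number dialect {d!r}")
        if any(n < 10 for n in self.cohort_sizes):
            raise ConfigurationError("every cohort must have >= 10 samples")
        if self.n_cn_driven + self.n_prognostic > self.n_genes and not self.allow_overlap:
            raise ConfigurationError("planted gene sets exceed n_genes")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard_ratio must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of one simulation run."""

    cn_driven_genes: list[str]
    prognostic_genes: dict[str, int]          # gene -> direction (+1 / -1)
    latent_risk: dict[int, pd.Series] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cn_driven_genes": self.cn_driven_genes,
            "prognostic_genes": self.prognostic_genes,
            "latent_risk": {str(c): s.round(10).to_dict() for c, s in self.latent_risk.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls(
            cn_driven_genes=list(payload["cn_driven_genes"]),
            prognostic_genes={g: int(d) for g, d in payload["prognostic_genes"].items()},
        )
        for c, d in payload["latent_risk"].items():
            truth.latent_risk[int(c)] = pd.Series(d).sort_index()
        return truth


def toy_annotation(n_genes: int = 2000) -> pd.DataFrame:
    """Evenly spaced genes on a 3 x 100 Mb toy genome (0-based half-open)."""
    per_chrom = int(np.ceil(n_genes / N_CHROMS))
    rows = []
    g = 0
    for c in range(N_CHROMS):
        spacing = CHROM_LENGTH // (per_chrom + 1)
        for i in range(per_chrom):
            if g >= n_genes:
                break
            start = (i + 1) * spacing
            rows.append((f"G{g:04d}", f"chr{c + 1}", start, start + GENE_LENGTH, "+"))
            g += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def default_events(alteration_fraction: float = 0.4) -> list[AlterationEvent]:
    """Recurrent alteration layout: two arm-level events, one focal amp,
    one focal homozygous deletion."""
    f = alteration_fraction
    return [
        AlterationEvent("gain_1q", "chr1", 50_000_000, CHROM_LENGTH, 3, f),
        AlterationEvent("loss_2q", "chr2", 50_000_000, CHROM_LENGTH, 1, f),
        AlterationEvent("amp_3p", "chr3", 20_000_000, 30_000_000, 7, f / 2),
        AlterationEvent("homd_3q", "chr3", 70_000_000, 75_000_000, 0, f / 4),
    ]


def _genes_in_region(annotation: pd.DataFrame, ev: AlterationEvent) -> list[str]:
    m = (
        (annotation["chrom"] == ev.chrom)
        & (annotation["start"] >= ev.start)
        & (annotation["end"] <= ev.end)
    )
    return annotation.loc[m, "gene"].tolist()


def plant_truth(
    config: SimulationConfig,
    annotation: pd.DataFrame | None = None,
    events: list[AlterationEvent] | None = None,
) -> GroundTruth:
    """Choose planted dosage-driven and prognostic gene sets.

    Dosage-driven genes are drawn round-robin from the recurrently altered
    regions (their copy number must vary across samples for a dosage effect
    to exist); prognostic genes are drawn from copy-number-neutral genes so
    the two planted mechanisms stay disjoint unless ``allow_overlap``.
    """
    if annotation is None:
        annotation = toy_annotation(config.n_genes)
    if events is None:
        events = default_events(config.alteration_fraction)
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])

    per_event = [_genes_in_region(annotation, ev) for ev in events]
    for genes in per_event:
        rng.shuffle(genes)
    cn_driven: list[str] = []
    k = 0
    while len(cn_driven) < config.n_cn_driven:
        pool = per_event[k % len(per_event)]
        if pool:
            cn_driven.append(pool.pop())
        elif not any(per_event):
            raise ConfigurationError("not enough genes in altered regions")
        k += 1

    altered = set().union(*(_genes_in_region(annotation, ev) for ev in events))
    neutral = [g for g in annotation["gene"] if g not in altered]
    if config.allow_overlap:
        neutral = annotation["gene"].tolist()
    if len(neutral) < config.n_prognostic:
        raise ConfigurationError("not enough neutral genes for the prognostic program")
    prog = list(rng.choice(neutral, size=config.n_prognostic, replace=False))
    directions = rng.choice([1, -1], size=config.n_prognostic)
    return GroundTruth(
        cn_driven_genes=sorted(cn_driven),
        prognostic_genes={g: int(d) for g, d in zip(prog, directions)},
    )


def _sample_ids(config: SimulationConfig, cohort: int) -> list[str]:
    return [f"C{cohort}_S{i:03d}" for i in range(config.cohort_sizes[cohort])]


def _copies_to_logratio(copies: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(copies.astype(float), 0.1) / 2.0)


def _copies_to_state(copies: int) -> str:
    if copies == 0:
        return "HOMD"
    if copies == 1:
        return "HETD"
    if copies == 2:
        return "NEUT"
    if copies <= 5:
        return "GAIN"
    return "AMP"


def simulate_segments(
    config: SimulationConfig,
    cohort: int,
    events: list[AlterationEvent] | None = None,
) -> pd.DataFrame:
    """Per-sample copy-number segments tiling the toy genome.

    Returns a segment table with 0-based half-open coordinates and columns
    ``sample, chrom, start, end, n_markers, value, copies``; ``value`` is
    encoded in the cohort's dialect while ``copies`` keeps the generating
    absolute copy number (a ground-truth side channel dropped on SEG write).
    """
    if cohort >= config.n_cohorts:
        raise ConfigurationError(f"cohort index {cohort} out of range")
    dialect = config.dialects[cohort]
    if events is None:
        events = default_events(config.alteration_fraction)
    rng = np.random.default_rng([config.seed, cohort, _STREAM_CARRIERS])
    samples = _sample_ids(config, cohort)
    carrier = {ev.name: rng.random(len(samples)) < ev.fraction for ev in events}

    # breakpoints per chromosome from event boundaries
    bounds: dict[str, list[int]] = {f"chr{c + 1}": [0, CHROM_LENGTH] for c in range(N_CHROMS)}
    for ev in events:
        bounds[ev.chrom].extend([ev.start, ev.end])
    for c in bounds:
        bounds[c] = sorted(set(bounds[c]))

    rows = []
    for si, s in enumerate(samples):
        for chrom, bps in bounds.items():
            for a, b in zip(bps[:-1], bps[1:]):
                copies = 2
                for ev in events:
                    if ev.chrom == chrom and ev.start <= a and b <= ev.end and carrier[ev.name][si]:
                        copies = ev.copies
                if dialect == "absolute":
                    value: object = copies
                elif dialect == "logratio":
                    value = round(float(_copies_to_logratio(np.array([copies]))[0]), 4)
                else:
                    value = _copies_to_state(copies)
                rows.append((s, chrom, a, b, max((b - a) // 50_000, 1), value, copies))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_markers", "value", "copies"]
    )


def _gene_copies(segments: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """genes x samples absolute copies, by containment in the tiling segments."""
    samples = segments["sample"].unique()
    out = pd.DataFrame(2, index=annotation["gene"], columns=samples, dtype=int)
    for (s, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        genes = annotation[annotation["chrom"] == chrom]
        starts = seg["start"].to_numpy()
        idx = np.searchsorted(starts, genes["start"].to_numpy(), side="right") - 1
        out.loc[genes["gene"], s] = seg["copies"].to_numpy()[idx]
    return out


def simulate_expression(
    segments: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    cohort: int,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-scale expression (probes x samples) plus the probe->gene map.

    Dosage-driven genes: baseline + slope * (copies - 2) + noise.
    Prognostic genes: baseline + direction * effect * latent + noise.
    Other genes: baseline + noise.  The realized latent risk (standardized,
    sign-corrected mean of the prognostic program) is recorded in ``truth``.
    """
    if annotation is None:
        annotation = toy_annotation(config.n_genes)
    rng = np.random.default_rng([config.seed, cohort, _STREAM_EXPR])
    base_rng = np.random.default_rng([config.seed, _STREAM_BASELINE])
    baselines = pd.Series(
        base_rng.normal(7.0, 1.0, size=len(annotation)), index=annotation["gene"]
    )
    copies = _gene_copies(segments, annotation)
    samples = list(copies.columns)
    n = len(samples)

    if config.binary_risk:
        latent = (np.arange(n) < n // 2).astype(float) - 0.5
        rng.shuffle(latent)
    else:
        latent = rng.normal(0.0, 1.0, size=n)

    signal = pd.DataFrame(
        np.tile(baselines.to_numpy()[:, None], (1, n)),
        index=annotation["gene"], columns=samples,
    )
    for g in truth.cn_driven_genes:
        signal.loc[g] += config.cn_expr_slope * (copies.loc[g].to_numpy() - 2.0)
    for g, d in truth.prognostic_genes.items():
        signal.loc[g] += d * config.prognostic_effect * latent

    n_probes = 2 if config.two_probes_per_gene else 1
    frames, map_rows = [], []
    for p in range(n_probes):
        noise = rng.normal(0.0, config.expr_noise_sd, size=signal.shape)
        block = signal + noise
        block.index = [f"{g}_p{p + 1}" for g in signal.index]
        frames.append(block)
        map_rows.extend((f"{g}_p{p + 1}", g) for g in signal.index)
    expr = pd.concat(frames).sort_index()
    probe_map = pd.DataFrame(map_rows, columns=["probe", "gene"]).sort_values("probe")

    # realized latent risk: standardized sign-corrected program mean
    prog = pd.DataFrame(
        {g: d * expr.loc[[p for p, gg in map_rows if gg == g]].mean(axis=0)
         for g, d in truth.prognostic_genes.items()}
    )
    risk = prog.mean(axis=1)
    risk = (risk - risk.mean()) / risk.std(ddof=0)
    truth.latent_risk[cohort] = risk
    return expr, probe_map.reset_index(drop=True)


def _expected_censor_fraction(tmax: float, hazards: np.ndarray) -> float:
    x = hazards * tmax
    return float(np.mean((1.0 - np.exp(-x)) / x))


def solve_censoring_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Horizon T of U(0, T) censoring achieving the target expected
    censoring fraction, by root finding on the exact closed form."""
    f = lambda t: _expected_censor_fraction(t, hazards) - censor_rate
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 10
        if hi > 1e12:
            break
    return brentq(f, lo, hi)


def simulate_survival(
    truth: GroundTruth, config: SimulationConfig, cohort: int
) -> pd.DataFrame:
    """Clinical table: exponential survival driven by the latent risk,
    independent uniform censoring, plus grade and NPI component covariates."""
    if cohort not in truth.latent_risk:
        raise ConfigurationError(
            "latent risk undefined; run simulate_expression for this cohort first"
        )
    rng = np.random.default_rng([config.seed, cohort, _STREAM_SURV])
    risk = truth.latent_risk[cohort]
    hazards = config.baseline_hazard * config.hazard_ratio ** risk.to_numpy()
    t_event = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        tmax = solve_censoring_horizon(hazards, config.censor_rate)
        t_cens = rng.uniform(0.0, tmax, size=len(risk))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(risk), dtype=int)

    z = risk.to_numpy()
    grade = np.clip(np.rint(2.0 + 0.5 * z + rng.normal(0, 0.7, len(z))), 1, 3).astype(int)
    size_cm = np.round(np.exp(rng.normal(0.8 + 0.15 * z, 0.4)), 1).clip(0.5, 10.0)
    nodes = np.clip(1 + rng.poisson(0.4 * np.exp(0.3 * z)), 1, 3).astype(int)
    return pd.DataFrame(
        {
            "sample": risk.index,
            "time_months": np.round(time, 4),
            "event": event,
            "grade": grade,
            "size_cm": size_cm,
            "nodes_positive": nodes,
            "cohort": f"cohort{cohort}",
        }
    ).reset_index(drop=True)


@dataclass
class Cohort:
    """One simulated cohort: all inputs a downstream stage consumes."""

    index: int
    dialect: str
    segments: pd.DataFrame
    expression: pd.DataFrame
    probe_map: pd.DataFrame
    clinical: pd.DataFrame
    annotation: pd.DataFrame


def simulate_cohorts(
    config: SimulationConfig,
    events: list[AlterationEvent] | None = None,
) -> tuple[list[Cohort], GroundTruth]:
    """Run the full generator for every cohort in the configuration."""
    annotation = toy_annotation(config.n_genes)
    if events is None:
        events = default_events(config.alteration_fraction)
    truth = plant_truth(config, annotation, events)
    cohorts = []
    for c in range(config.n_cohorts):
        segs = simulate_segments(config, c, events)
        expr, pmap = simulate_expression(segs, truth, config, c, annotation)
        clin = simulate_survival(truth, config, c)
        cohorts.append(Cohort(c, config.dialects[c], segs, expr, pmap, clin, annotation))
    return cohorts, truth


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write SEG (1-based inclusive), expression, probe map and clinical TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seg = cohort.segments.copy()
    seg["start"] = seg["start"] + 1      # 0-based half-open -> 1-based inclusive
    seg = seg[["sample", "chrom", "start", "end", "n_markers", "value"]]
    seg.to_csv(out / "segments.seg", sep="\t", index=False)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t", index_label="probe")
    cohort.probe_map.to_csv(out / "probe_map.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    ann = cohort.annotation[["chrom", "start", "end", "gene", "strand"]].copy()
    ann.insert(4, "score", 0)
    ann.to_csv(out / "genes.bed", sep="\t", index=False, header=False)


def write_simulation(
    cohorts: list[Cohort], truth: GroundTruth, outdir: str | Path
) -> None:
    out = Path(outdir)
    for c in cohorts:
        write_cohort(c, out / f"cohort{c.index}")
    truth.to_json(out / "ground_truth.json")
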