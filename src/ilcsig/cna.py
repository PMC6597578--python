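"""Gene-level copy-number calls from per-cohort segment data.

Cohorts deliver copy number in different dialects — absolute integer
copies, CBS-smoothed log-ratios, or pre-called discrete states — so
segments are first mapped onto a common five-state vocabulary
(HOMD, HETD, NEUT, GAIN, AMP) with cohort-appropriate thresholds, and
then projected onto genes.  A gene falling completely within one segment
inherits that segment's state and log-ratio; a gene broken by several
segments takes the state (and its log-ratio) of the overlapping segment
whose severity is maximal in absolute value:

    C(s,g) = CNstate(argmax |severity(CNstates)|)
    L(s,g) = LogR(argmax |severity(CNstates)|)

with the fixed severity map NEUT:0, GAIN:+1, HETD:-1, AMP:+2, HOMD:-2.

Coordinates are 0-based half-open internally; SEG files are read as
1-based inclusive and converted.  Strand is ignored (copy number is
strand-agnostic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATES = ("HOMD", "HETD", "NEUT", "GAIN", "AMP")
SEVERITY = {"NEUT": 0, "HOMD": -2, "AMP": 2, "HETD": -1, "GAIN": 1}

# common aliases seen in pre-called (discrete dialect) inputs
_STATE_ALIASES = {
    "HOMD": "HOMD", "HD": "HOMD", "HOMDEL": "HOMD", "-2": "HOMD",
    "HETD": "HETD", "LOSS": "HETD", "DEL": "HETD", "HETLOSS": "HETD", "-1": "HETD",
    "NEUT": "NEUT", "NEUTRAL": "NEUT", "DIPLOID": "NEUT", "0": "NEUT",
    "GAIN": "GAIN", "1": "GAIN",
    "AMP": "AMP", "AMPLIFICATION": "AMP", "2": "AMP",
}


class InputError(ValueError):
    """Raised for malformed segment or annotation inputs."""


@dataclass
class CallThresholds:
    """State-calling thresholds.

    Absolute dialect (integer copies): 0 HOMD, 1 HETD, 2 NEUT, 3-5 GAIN,
    >=6 AMP.  Log-ratio dialect: gain above +0.3, loss below -0.3; the
    amplification / homozygous-deletion cutoffs are not universal (real
    pipelines take them from sample-specific GISTIC output) and default
    to +/-1.0 here.
    """

    logratio_gain: float = 0.3
    logratio_loss: float = -0.3
    logratio_amp: float = 1.0
    logratio_homd: float = -1.0


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG-style TSV (sample, chrom, start, end, n_markers, value);
    1-based inclusive coordinates are converted to 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["sample", "chrom", "start", "end", "n_markers", "value"][: len(df.columns)]
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise InputError(f"{len(bad)} segments with start >= end in {path}")
    return df


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED6-style gene annotation (chrom, start, end, gene, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene", "score", "strand"]
    if df["gene"].duplicated().any():
        raise InputError("duplicate gene ids in annotation")
    return df[["gene", "chrom", "start", "end", "strand"]]


def call_states(
    segments: pd.DataFrame,
    dialect: str,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Label each segment with a discrete state and a log-ratio.

    Absolute copies are also converted to log2(copies/2) log-ratios
    (floored at 0.1 copies) so downstream rank statistics have a
    continuous substrate; discrete inputs keep their state only
    (log-ratio missing), which restricts those cohorts to ANOVA-based
    integration.
    """
    thresholds = thresholds or CallThresholds()
    seg = segments.copy()
    v = seg["value"]
    if dialect == "absolute":
        copies = v.astype(float)
        state = np.select(
            [copies < 1, copies < 2, copies <= 2.5, copies <= 5],
            ["HOMD", "HETD", "NEUT", "GAIN"],
            default="AMP",
        )
        logratio = np.log2(np.maximum(copies, 0.1) / 2.0)
    elif dialect == "logratio":
        lr = v.astype(float)
        t = thresholds
        state = np.select(
            [lr <= t.logratio_homd, lr < t.logratio_loss, lr >= t.logratio_amp, lr > t.logratio_gain],
            ["HOMD", "HETD", "AMP", "GAIN"],
            default="NEUT",
        )
        logratio = lr.to_numpy()
    elif dialect == "discrete":
        labels = v.astype(str).str.upper().str.strip()
        unknown = ~labels.isin(_STATE_ALIASES)
        if unknown.any():
            first = seg[unknown].iloc[0]
            raise InputError(
                f"unmappable copy-number state {first['value']!r} "
                f"(sample {first['sample']}, {first['chrom']}:{first['start']}-{first['end']})"
            )
        state = labels.map(_STATE_ALIASES).to_numpy()
        logratio = np.full(len(seg), np.nan)
    else:
        raise InputError(f"unknown copy-number dialect {dialect!r}")
    seg["state"] = state
    seg["logratio"] = logratio
    seg["severity"] = seg["state"].map(SEVERITY)
    return seg


@dataclass
class GeneCNMatrix:
    """Gene-level copy number: discrete states C and log-ratios L."""

    C: pd.DataFrame            # genes x samples, state labels (object, NaN = missing)
    L: pd.DataFrame            # genes x samples, float log-ratios
    severity_map: dict = field(default_factory=lambda: dict(SEVERITY))


def assign_gene_cn(segments: pd.DataFrame, genes: pd.DataFrame) -> GeneCNMatrix:
    """Project called segments onto genes by the maximal-severity rule.

    Requires ``call_states`` output (state/logratio/severity columns).
    Genes covered by no segment are missing; a chromosome absent from a
    sample's segments is logged once per chromosome.
    """
    for col in ("state", "severity"):
        if col not in segments.columns:
            raise InputError("segments must be passed through call_states first")
    samples = sorted(pd.unique(segments["sample"]))   # order-independent output
    gene_ids = genes["gene"].tolist()
    C = pd.DataFrame(np.nan, index=gene_ids, columns=samples, dtype=object)
    L = pd.DataFrame(np.nan, index=gene_ids, columns=samples, dtype=float)

    seg_chroms = set(segments["chrom"])
    for chrom in sorted(set(genes["chrom"]) - seg_chroms):
        log.warning("no segments on %s; genes there left missing", chrom)

    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        seg = seg.sort_values("start")
        s0 = seg["start"].to_numpy()
        s1 = seg["end"].to_numpy()
        sev = seg["severity"].to_numpy()
        st = seg["state"].to_numpy()
        lr = seg["logratio"].to_numpy()
        g0 = sub["start"].to_numpy()
        g1 = sub["end"].to_numpy()
        # overlapping segment window per gene (segments are sorted, disjoint)
        lo = np.searchsorted(s1, g0, side="right")
        hi = np.searchsorted(s0, g1, side="left")
        best_state = np.full(len(sub), None, dtype=object)
        best_lr = np.full(len(sub), np.nan)
        for gi in range(len(sub)):
            if lo[gi] >= hi[gi]:
                continue     # no overlap
            idx = np.arange(lo[gi], hi[gi])
            if len(idx) == 1 and s0[idx[0]] <= g0[gi] and g1[gi] <= s1[idx[0]]:
                j = idx[0]   # gene fully inside one segment
            else:
                overlap = np.minimum(s1[idx], g1[gi]) - np.maximum(s0[idx], g0[gi])
                # argmax |severity|; ties -> larger overlap; then prefer the
                # positive-severity state (AMP over HOMD); then leftmost
                j = max(idx, key=lambda jj, gi=gi: (
                    abs(sev[jj]),
                    min(s1[jj], g1[gi]) - max(s0[jj], g0[gi]),
                    sev[jj],
                    -s0[jj],
                ))
            best_state[gi] = st[j]
            best_lr[gi] = lr[j]
        C.loc[sub["gene"], sample] = best_state
        L.loc[sub["gene"], sample] = best_lr
    return GeneCNMatrix(C=C, L=L)


def alteration_frequency(matrix: GeneCNMatrix) -> pd.DataFrame:
    """Per-gene fraction of samples in each non-neutral state (missing
    samples excluded from the denominator)."""
    C = matrix.C
    present = C.notna().sum(axis=1)
    out = {}
    for state, col in [("AMP", "amp"), ("GAIN", "gain"), ("HETD", "loss"), ("HOMD", "homd")]:
        out[col] = (C == state).sum(axis=1) / present.replace(0, np.nan)
    freq = pd.DataFrame(out).fillna(0.0)
    freq.index.name = "gene"
    return freq


def coamplification(
    matrix: GeneCNMatrix, region_a: list[str], region_b: list[str]
) -> dict:
    """Co-occurrence of amplification between two gene regions.

    A sample is amplified for a region when any of the region's genes is
    AMP.  Returns carrier counts and the conditional co-amplification
    fractions in both directions.
    """
    for name, region in [("region_a", region_a), ("region_b", region_b)]:
        if not set(region) & set(matrix.C.index):
            raise InputError(f"{name}: no genes present in the copy-number matrix")
    amp_a = (matrix.C.loc[[g for g in region_a if g in matrix.C.index]] == "AMP").any(axis=0)
    amp_b = (matrix.C.loc[[g for g in region_b if g in matrix.C.index]] == "AMP").any(axis=0)
    n_a, n_b = int(amp_a.sum()), int(amp_b.sum())
    n_ab = int((amp_a & amp_b).sum())
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_ab": n_ab,
        "frac_b_given_a": n_ab / n_a if n_a else np.nan,
        "frac_a_given_b": n_ab / n_b if n_b else np.nan,
        "carriers": pd.DataFrame({"region_a": amp_a, "region_b": amp_b}),
    }


def collapse_probes(expression: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Probe-level -> gene-level expression by averaging a gene's probes."""
    m = probe_map.set_index("probe")["gene"]
    genes = expression.index.map(m)
    if genes.isna().any():
        raise InputError("expression contains probes absent from the probe map")
    out = expression.groupby(genes.to_numpy()).mean()
    out.index.name = "gene"
    return out
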