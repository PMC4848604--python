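"""Threshold-based differential-expression calls for the host response.

A host gene is called differentially expressed between an infection phase
and the uninfected control when BOTH gates pass:

* ``|log2FC| > 1.5`` where ``log2FC = log2((group mean + c)/(control + c))``
  with pseudocount ``c`` (default 1); and
* the single control value lies outside the test group's
  ``mean +/- 2 * SD`` band (sample SD, n-1 denominator).

Between the early and late phases the second gate is instead a two-sided
two-sample Student t-test (pooled variance) at ``p < 0.01``.

These are the historical rules of the source analysis, kept deliberately:
there is no dispersion modelling, no shrinkage and no multiple-testing
correction by default (a Benjamini-Hochberg option exists, off by default).
Modern count-model DE tools (DESeq2/edgeR-style NB GLMs) differ exactly
where these rules are weakest: a single unreplicated control and a raw
p-value threshold.  Comparisons against the 0-min control rest on one
replicate and are susceptible to culture bias; output headers carry this
caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTROL_CAVEAT = (
    "comparisons against the 0-min control use a single unreplicated control "
    "sample and are susceptible to culture bias"
)


@dataclass(frozen=True)
class DEThresholds:
    """Gates for the compound DE rule; all strictly positive except pseudocount>=0."""

    log2fc_threshold: float = 1.5
    sd_multiplier: float = 2.0
    alpha: float = 0.01
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0 or self.sd_multiplier <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def log2_fold_change(
    group_mean: float, reference_value: float, pseudocount: float = 1.0
) -> float:
    """log2((group_mean + c) / (reference_value + c)).

    With the default pseudocount the ratio is always finite; with
    ``pseudocount=0`` zero numerators/denominators yield signed infinities
    (and 0/0 -> 0 by convention).
    """
    num = group_mean + pseudocount
    den = reference_value + pseudocount
    if num == 0 and den == 0:
        return 0.0
    if den == 0:
        return math.inf
    if num == 0:
        return -math.inf
    return math.log2(num / den)


def _status(log2fc: float, second_gate: bool, thr: DEThresholds) -> str:
    if not second_gate:
        return "ns"
    if log2fc > thr.log2fc_threshold:
        return "up"
    if log2fc < -thr.log2fc_threshold:
        return "down"
    return "ns"


def de_call_vs_control(
    norm_counts,
    group_sample_ids: list[str],
    control_sample_id: str,
    thresholds: DEThresholds = DEThresholds(),
    comparison: str = "vs_control",
    organism: str = "host",
) -> pd.DataFrame:
    """Call genes DE between a phase group and the single uninfected control.

    Per gene: ``log2fc`` of the group mean against the control value, and the
    2-SD control gate (control outside group mean +/- k*SD, sample SD with
    n-1 denominator).  Status is up/down only when both the log2FC gate and
    the control gate pass.

    Raises
    ------
    ValueError
        if the group has fewer than 2 samples (SD undefined).
    """
    if len(group_sample_ids) < 2:
        raise ValueError("group must have >=2 samples for an SD to exist")
    values = norm_counts.values
    if organism is not None and norm_counts.features:
        mask = norm_counts.gene_mask(organism)
        values = values.loc[mask]
    group = values[group_sample_ids].to_numpy(dtype=float)
    control = values[control_sample_id].to_numpy(dtype=float)
    mean = group.mean(axis=1)
    sd = group.std(axis=1, ddof=1)
    k = thresholds.sd_multiplier
    outside = (control < mean - k * sd) | (control > mean + k * sd)
    rows = []
    for i, gene in enumerate(values.index):
        lfc = log2_fold_change(mean[i], control[i], thresholds.pseudocount)
        rows.append(
            {
                "gene_id": gene,
                "comparison": comparison,
                "log2fc": lfc,
                "group_mean": mean[i],
                "group_sd": sd[i],
                "control_value": control[i],
                "control_outside_2sd": bool(outside[i]),
                "status": _status(lfc, bool(outside[i]), thresholds),
            }
        )
    return pd.DataFrame(rows)


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided pooled-variance Student t-test p-value with degenerate-case
    conventions: zero pooled variance gives p=1 for equal means, p=0 otherwise."""
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def de_call_late_vs_early(
    norm_counts,
    early_sample_ids: list[str],
    late_sample_ids: list[str],
    thresholds: DEThresholds = DEThresholds(),
    welch: bool = False,
    bh_correct: bool = False,
    organism: str = "host",
) -> pd.DataFrame:
    """Call genes DE between the late and early phases (late vs early).

    ``log2fc`` is the late group mean against the early group mean; the
    second gate is a two-sided two-sample Student t-test (pooled variance;
    Welch optionally) at ``p < alpha``.  ``bh_correct=True`` applies a
    Benjamini-Hochberg adjustment to the p-values before gating (off by
    default, matching the raw-threshold rule).
    """
    if len(early_sample_ids) < 2 or len(late_sample_ids) < 2:
        raise ValueError("both groups need >=2 samples for a t-test")
    values = norm_counts.values
    if organism is not None and norm_counts.features:
        mask = norm_counts.gene_mask(organism)
        values = values.loc[mask]
    early = values[early_sample_ids].to_numpy(dtype=float)
    late = values[late_sample_ids].to_numpy(dtype=float)
    e_mean, l_mean = early.mean(axis=1), late.mean(axis=1)
    if welch:
        pvals = np.array(
            [
                float(stats.ttest_ind(late[i], early[i], equal_var=False).pvalue)
                for i in range(len(values.index))
            ]
        )
    else:
        pvals = np.array(
            [_pooled_t(late[i], early[i]) for i in range(len(values.index))]
        )
    gate_p = pvals
    if bh_correct:
        gate_p = _benjamini_hochberg(pvals)
    rows = []
    for i, gene in enumerate(values.index):
        lfc = log2_fold_change(l_mean[i], e_mean[i], thresholds.pseudocount)
        sig = gate_p[i] < thresholds.alpha
        rows.append(
            {
                "gene_id": gene,
                "comparison": "late_vs_early",
                "log2fc": lfc,
                "group_mean": l_mean[i],
                "group_sd": late[i].std(ddof=1),
                "p_value": pvals[i],
                "status": _status(lfc, bool(sig), thresholds),
            }
        )
    return pd.DataFrame(rows)


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def tally_de(calls: pd.DataFrame, n_total_genes: int) -> dict:
    """Summarize one comparison's calls against the genome-wide gene count.

    Returns integer tallies and full-precision percentages; formatting to the
    report's printed precision (2 dp for genome fractions, 1 dp for the
    up-among-DE fraction) happens only in :func:`format_tally`.
    """
    n_up = int((calls["status"] == "up").sum())
    n_down = int((calls["status"] == "down").sum())
    n_de = n_up + n_down
    pct = lambda k: 100.0 * k / n_total_genes if n_total_genes else 0.0
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_de": n_de,
        "n_total_genes": int(n_total_genes),
        "genome_pct_de": pct(n_de),
        "genome_pct_up": pct(n_up),
        "genome_pct_down": pct(n_down),
        "up_of_de_pct": 100.0 * n_up / n_de if n_de else 0.0,
        "down_of_de_pct": 100.0 * n_down / n_de if n_de else 0.0,
    }


def format_tally(tally: dict) -> dict:
    """Printed-precision view: genome fractions to 2 dp, DE fractions to 1 dp."""
    return {
        "n_up": tally["n_up"],
        "n_down": tally["n_down"],
        "n_de": tally["n_de"],
        "genome_pct_de": round(tally["genome_pct_de"], 2),
        "genome_pct_up": round(tally["genome_pct_up"], 2),
        "genome_pct_down": round(tally["genome_pct_down"], 2),
        "up_of_de_pct": round(tally["up_of_de_pct"], 1),
        "down_of_de_pct": round(tally["down_of_de_pct"], 1),
    }
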