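"""Total-Count normalization and the per-sample phage-read-fraction statistic.

Total Count (TC) normalization rescales each sample so that per-sample read
totals within a chosen *scope* are equal across samples.  The reference total
is the mean of per-sample scope totals, which keeps normalized values close
to the raw count scale.  Three scopes are supported:

``all_reads``
    totals over every gene (host differential expression context);
``phage_only`` / ``host_only``
    totals over one organism's genes (used e.g. to normalize phage coverage
    or phage temporal profiles "against each other").

Normalization always returns a new matrix flagged ``normalized=True``; raw
integer matrices are never modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from phagetime.io import TimeCourseCounts

SCOPES = ("all_reads", "phage_only", "host_only")


@dataclass
class NormalizedCounts(TimeCourseCounts):
    """Total-Count-normalized matrix plus the per-sample scale factors."""

    scale_factors: pd.Series | None = None
    scope: str = "all_reads"


def _scope_totals(counts: TimeCourseCounts, scope: str) -> pd.Series:
    if scope == "all_reads":
        return counts.values.sum(axis=0)
    organism = {"phage_only": "phage", "host_only": "host"}[scope]
    mask = counts.gene_mask(organism)
    return counts.values.loc[mask].sum(axis=0)


def total_count_normalize(
    counts: TimeCourseCounts, scope: str = "all_reads"
) -> NormalizedCounts:
    """Scale each sample by (mean scope total) / (its scope total).

    After scaling, per-sample totals within the scope are equal (to floating
    precision).  The operation is idempotent: normalizing an already
    normalized matrix with the same scope changes nothing.

    Raises
    ------
    ValueError
        if ``scope`` is unknown or any sample has a zero scope total
        (the error names the sample).
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    totals = _scope_totals(counts, scope)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample {zero[0]!r} has zero total within scope {scope!r}; "
            "cannot normalize"
        )
    reference = float(totals.mean())
    factors = reference / totals.astype(float)
    values = counts.values.astype(float).mul(factors, axis=1)
    return NormalizedCounts(
        values=values,
        samples=list(counts.samples),
        features=counts.features,
        normalized=True,
        scale_factors=factors,
        scope=scope,
    )


def phage_read_fraction(counts: TimeCourseCounts) -> pd.DataFrame:
    """Per-sample percentage of mapped gene reads assigned to phage genes.

    Computed on the *raw* count matrix (pre-normalization).  Returns a
    DataFrame with columns ``sample_id, time_min, phage_reads, host_reads,
    phage_fraction_pct``.

    Raises
    ------
    ValueError
        if any sample has zero total mapped gene reads.
    """
    phage_mask = counts.gene_mask("phage")
    phage = counts.values.loc[phage_mask].sum(axis=0)
    host = counts.values.loc[~phage_mask].sum(axis=0)
    total = phage + host
    if (total <= 0).any():
        bad = total.index[total <= 0][0]
        raise ValueError(f"sample {bad!r} has zero mapped gene reads")
    frac = 100.0 * phage / total
    return pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "time_min": [s.time_min for s in counts.samples],
            "phage_reads": phage.to_numpy(),
            "host_reads": host.to_numpy(),
            "phage_fraction_pct": frac.to_numpy(),
        }
    )
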