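"""Temporal classification of phage genes from phase-averaged expression.

Each phage gene's normalized TGR values are averaged within the early
(2-5 min), middle (10-21 min) and late (28-49 min) phase groups; the three
averages are rescaled to percent with the highest set to 100.  The gene is
assigned to the phase holding the maximum, unless the runner-up percentage is
within ``margin_threshold`` (default 40) of the top — in which case the gene
is *constitutive* (not regulated).  Genes whose mean normalized TGR over all
infected samples falls below ``min_tgr`` (default 10) are *excluded* before
any profile is computed.  The uninfected control sample plays no role.

The classification is a total, deterministic function of the three phase
averages: exact ties at the top give margin 0 and are always constitutive;
no random tie-breaking occurs anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phagetime.io import DEFAULT_PHASE_GROUPING, PHASES, TimeCourseCounts

CLASSES = ("early", "middle", "late", "constitutive", "excluded")

DEFAULT_MIN_TGR = 10.0
DEFAULT_MARGIN = 40.0


@dataclass(frozen=True)
class PhaseProfile:
    """Per-gene phase averages and their percent-scaled values (max = 100)."""

    gene_id: str
    avg_early: float
    avg_middle: float
    avg_late: float
    mean_infected: float

    @property
    def averages(self) -> np.ndarray:
        return np.array([self.avg_early, self.avg_middle, self.avg_late])

    @property
    def pct(self) -> np.ndarray:
        """Percent-scaled phase averages; all-zero profiles stay at zero."""
        avgs = self.averages
        top = avgs.max()
        if top <= 0:
            return np.zeros(3)
        # divide first: x/x is exactly 1.0 in IEEE, so the peak is exactly 100
        return (avgs / top) * 100.0


@dataclass(frozen=True)
class TemporalCall:
    gene_id: str
    temporal_class: str
    margin: float
    profile: PhaseProfile | None


def phase_averages(
    norm_counts: TimeCourseCounts,
    grouping: Mapping[str, Sequence[float]] = DEFAULT_PHASE_GROUPING,
) -> list[PhaseProfile]:
    """Arithmetic mean of normalized TGR per phase per gene.

    The control group (time 0) is excluded from every phase average and from
    the overall infected-sample mean used by the exclusion rule.

    Raises
    ------
    ValueError
        if a phase group matches no sample (empty phase).
    """
    cols: dict[str, list[str]] = {p: [] for p in PHASES}
    infected: list[str] = []
    for s in norm_counts.samples:
        for phase in PHASES:
            if s.time_min in grouping[phase]:
                cols[phase].append(s.sample_id)
                infected.append(s.sample_id)
    for phase in PHASES:
        if not cols[phase]:
            raise ValueError(f"phase group {phase!r} matches no sample")
    values = norm_counts.values
    means = {p: values[cols[p]].mean(axis=1) for p in PHASES}
    overall = values[infected].mean(axis=1)
    return [
        PhaseProfile(
            gene_id=g,
            avg_early=float(means["early"][g]),
            avg_middle=float(means["middle"][g]),
            avg_late=float(means["late"][g]),
            mean_infected=float(overall[g]),
        )
        for g in values.index
    ]


def classify_temporal(
    profile: PhaseProfile,
    min_tgr: float = DEFAULT_MIN_TGR,
    margin_threshold: float = DEFAULT_MARGIN,
) -> TemporalCall:
    """Assign one gene to early/middle/late/constitutive/excluded.

    Rules, in order:

    1. mean normalized TGR over all infected samples < ``min_tgr`` ->
       *excluded* (no profile reported);
    2. otherwise let ``margin = 100 - second-highest percent value``; if
       ``margin >= margin_threshold`` the gene takes the arg-max phase,
       else it is *constitutive*.
    """
    if profile.mean_infected < min_tgr:
        return TemporalCall(profile.gene_id, "excluded", margin=0.0, profile=None)
    pct = profile.pct
    order = np.argsort(pct)  # stable; ties resolved by the margin rule anyway
    margin = float(pct[order[-1]] - pct[order[-2]])
    if margin >= margin_threshold:
        cls = PHASES[int(np.argmax(pct))]
    else:
        cls = "constitutive"
    return TemporalCall(profile.gene_id, cls, margin=margin, profile=profile)


def classify_all(
    norm_counts: TimeCourseCounts,
    grouping: Mapping[str, Sequence[float]] = DEFAULT_PHASE_GROUPING,
    min_tgr: float = DEFAULT_MIN_TGR,
    margin_threshold: float = DEFAULT_MARGIN,
) -> tuple[pd.DataFrame, dict]:
    """Classify every gene of the matrix; return the call table and a summary.

    The summary maps each class to its size and lists genes with zero reads
    in every sample separately (they are necessarily excluded, but deserve a
    distinct report, being candidates for annotation errors).
    """
    profiles = phase_averages(norm_counts, grouping)
    rows = []
    zero_genes: list[str] = []
    totals = norm_counts.values.sum(axis=1)
    for prof in profiles:
        call = classify_temporal(prof, min_tgr, margin_threshold)
        pct = prof.pct
        rows.append(
            {
                "gene_id": prof.gene_id,
                "avg_early": prof.avg_early,
                "avg_middle": prof.avg_middle,
                "avg_late": prof.avg_late,
                "pct_early": pct[0],
                "pct_middle": pct[1],
                "pct_late": pct[2],
                "mean_infected": prof.mean_infected,
                "margin": call.margin,
                "temporal_class": call.temporal_class,
            }
        )
        if totals[prof.gene_id] == 0:
            zero_genes.append(prof.gene_id)
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "avg_early", "avg_middle", "avg_late",
            "pct_early", "pct_middle", "pct_late",
            "mean_infected", "margin", "temporal_class",
        ],
    )
    summary = {
        "class_sizes": {
            c: int((table["temporal_class"] == c).sum()) for c in CLASSES
        },
        "n_genes": int(len(table)),
        "zero_read_genes": zero_genes,
    }
    return table, summary
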