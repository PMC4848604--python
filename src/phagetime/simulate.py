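"""Ground-truth synthetic data emulating a phage-host dual RNA-seq time course.

The generator emulates the design of the study this package reanalyzes: nine
post-infection sampling times (2, 5, 10, 15, 21, 28, 35, 42, 49 min) plus an
uninfected 0-min control; a phage read fraction ramping from ~3% at 2 min to
~16% at the last time point; phage genes drawn from four temporal classes
(early / middle / late / constitutive, proportions 92:8:94:147) plus a
low-expression excluded class (26); host genes with planted early
down-regulation and late up-regulation; and planted antisense and intergenic
transcripts on the phage genome.

Count model
-----------
Per sample, the number of phage-gene reads is drawn binomially from the
configured phage-fraction curve, and reads are then distributed over genes
multinomially with per-gene gamma-perturbed weights (gamma shape = the
negative-binomial size parameter ``dispersion``).  Marginally this is a
gamma-Poisson (negative-binomial-like) count model; conditioning on totals
makes count conservation exact and keeps the realized phage fraction within
binomial sampling error of the configured curve.  ``dispersion=None`` (or
``inf``) gives the Poisson limit.

Temporal profiles are piecewise-constant over the three phase groups, with
the peak phase ``peak_fold`` (default 5) above the off-phases.  Per-class
total activity is balanced so that the summed phage expression is flat
across phases: only then can the configured uptake curve and the planted
block profiles coexist (an unbalanced mix would distort every gene's
Total-Count share in the phase where few genes peak, moving planted
constitutive genes over the classification margin).

All randomness flows from ``SimConfig.seed`` through one generator;
identical configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phagetime.coverage import _third_label
from phagetime.io import (
    DEFAULT_PHASE_GROUPING,
    GeneFeature,
    SampleMeta,
    TimeCourseCounts,
    phase_of,
    write_counts,
    write_coverage_bedgraph,
    write_gff3,
    write_intervals,
)

DEFAULT_TIME_POINTS = (0, 2, 5, 10, 15, 21, 28, 35, 42, 49)

#: Temporal-class mix used as the simulation default, proportional to the
#: published class sizes 92 early : 8 middle : 94 late : 147 constitutive :
#: 26 excluded (of 367 protein-coding phage genes).
DEFAULT_CLASS_WEIGHTS = {
    "early": 92,
    "middle": 8,
    "late": 94,
    "constitutive": 147,
    "excluded": 26,
}


def default_fraction_curve(time_points=DEFAULT_TIME_POINTS) -> dict[float, float]:
    """Phage read fraction ramping linearly from 3% at 2 min to 16% at the
    final time point; 0 at the uninfected control."""
    tp = [t for t in time_points if t > 0]
    t0, t1 = tp[0], tp[-1]
    curve = {0.0: 0.0}
    for t in tp:
        curve[float(t)] = 0.03 + (0.16 - 0.03) * (t - t0) / (t1 - t0)
    return curve


@dataclass(frozen=True)
class HostDEConfig:
    """Planted host effects; counts default to the published DE proportions
    scaled to the simulated host-genome size, with |log2FC| = 2."""

    n_early_down: int = 13
    n_early_up: int = 2
    n_late_up: int = 15
    n_late_down: int = 12
    effect_log2fc: float = 2.0


@dataclass
class SimConfig:
    seed: int
    phage_genome_len: int = 50_000
    n_phage_genes: int = 120
    n_host_genes: int = 500
    time_points_min: tuple = DEFAULT_TIME_POINTS
    class_proportions: dict = field(default_factory=dict)
    phage_fraction_curve: dict = field(default_factory=dict)
    host_de: HostDEConfig = field(default_factory=HostDEConfig)
    dispersion: float | None = 100.0
    n_asrna: int = 9
    n_intergenic_rna: int = 1
    library_size: int = 500_000
    # layout / shape parameters
    gene_length_mean: int = 300
    gene_length_sd: int = 80
    min_gene_length: int = 150
    max_gene_length: int = 600
    read_length: int = 90
    assigned_fraction: float = 0.95
    peak_fold: float = 5.0
    weight_sigma: float = 0.6
    ncrna_target_depth: float = 60.0
    grouping: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_GROUPING))
    emit_coverage: bool = True

    def __post_init__(self) -> None:
        if not self.class_proportions:
            total = sum(DEFAULT_CLASS_WEIGHTS.values())
            self.class_proportions = {
                k: v / total for k, v in DEFAULT_CLASS_WEIGHTS.items()
            }
        if not self.phage_fraction_curve:
            self.phage_fraction_curve = default_fraction_curve(self.time_points_min)
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        tp = list(self.time_points_min)
        if tp[0] != 0:
            raise ValueError("first time point must be the 0-min control")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points_min must be strictly increasing")
        for t in tp:
            f = self.phage_fraction_curve[float(t)]
            if not (0.0 <= f < 1.0):
                raise ValueError("phage fractions must lie in [0, 1)")
        if self.phage_fraction_curve[0.0] != 0.0:
            raise ValueError("phage fraction at the 0-min control must be 0")
        if self.n_phage_genes * self.gene_length_mean > self.phage_genome_len:
            raise ValueError(
                "cannot place genes without overlap: gene count x mean length "
                "exceeds the genome length"
            )


@dataclass
class SimTruth:
    """Ground truth: planted phage classes, host effects and ncRNA intervals."""

    phage_gene_class: dict[str, str]
    host_gene_effect: dict[str, dict[str, float]]
    planted_ncrnas: list[tuple[str, int, int, str, str]]


def _largest_remainder(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: p * n for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _place_genes(
    rng: np.random.Generator,
    cfg: SimConfig,
    forced_gap_sizes: list[int],
) -> tuple[list[tuple[int, int, str]], list[int]]:
    """Lay out non-overlapping genes on both strands; returns (genes, gap list)
    where gaps[i] precedes gene i (gaps[n] trails the last gene)."""
    n = cfg.n_phage_genes
    lengths = np.clip(
        np.round(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, n)),
        cfg.min_gene_length,
        cfg.max_gene_length,
    ).astype(int)
    free = cfg.phage_genome_len - int(lengths.sum())
    min_gap = 20
    if free < min_gap * (n + 1) + sum(forced_gap_sizes):
        raise ValueError("cannot place genes without overlap: genome too crowded")
    gaps = np.full(n + 1, min_gap, dtype=int)
    # reserve interior gaps for planted intergenic transcripts
    forced_idx = rng.choice(np.arange(1, n), size=len(forced_gap_sizes), replace=False)
    for idx, size in zip(forced_idx, forced_gap_sizes):
        gaps[idx] = size
    remaining = free - int(gaps.sum())
    extra = rng.multinomial(remaining, rng.dirichlet(np.ones(n + 1)))
    gaps += extra
    strands = rng.choice(np.array(["+", "-"]), size=n)
    genes = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        genes.append((pos + 1, pos + int(lengths[i]), str(strands[i])))
        pos += int(lengths[i])
    return genes, [int(g) for g in gaps]


def _oriented_third_zone(
    start: int, end: int, strand: str, third: str
) -> tuple[int, int]:
    """Absolute coordinate window whose midpoints fall in the gene's 5'/middle/
    3' third (in the gene's own orientation)."""
    length = end - start + 1
    b1 = start + length // 3
    b2 = start + (2 * length) // 3
    zones = {"left": (start, b1 - 1), "middle": (b1, b2 - 1), "right": (b2, end)}
    if strand == "+":
        key = {"5prime": "left", "middle": "middle", "3prime": "right"}[third]
    else:
        key = {"5prime": "right", "middle": "middle", "3prime": "left"}[third]
    return zones[key]


def simulate_infection(
    config: SimConfig,
) -> tuple[list[GeneFeature], TimeCourseCounts, pd.DataFrame, SimTruth]:
    """Generate annotation, count matrix, read intervals and ground truth.

    Returns ``(features, counts, read_intervals, truth)`` where
    ``read_intervals`` covers the phage contig only (columns ``contig, start,
    end, strand, sample_id``; empty when ``emit_coverage=False``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    times = [float(t) for t in cfg.time_points_min]
    infected = [t for t in times if t > 0]
    sample_ids = [f"t{int(t):02d}" for t in times]
    samples = [
        SampleMeta(sid, t, phase_of(t, cfg.grouping))
        for sid, t in zip(sample_ids, times)
    ]

    # ---- planted intergenic transcript sizes (gaps reserved during layout)
    intergenic_lengths = [
        int(rng.integers(150, 251)) for _ in range(cfg.n_intergenic_rna)
    ]
    forced_gaps = [L + 2 * 31 for L in intergenic_lengths]

    phage_layout, gaps = _place_genes(rng, cfg, forced_gaps)
    phage_ids = [f"g{i + 1:03d}" for i in range(cfg.n_phage_genes)]
    features: list[GeneFeature] = [
        GeneFeature(gid, "phage", s, e, strand, organism="phage")
        for gid, (s, e, strand) in zip(phage_ids, phage_layout)
    ]

    # ---- host genes: layout is nominal (no host coverage is simulated)
    host_ids = [f"h{i + 1:04d}" for i in range(cfg.n_host_genes)]
    host_lengths = np.clip(
        np.round(rng.normal(900, 200, cfg.n_host_genes)), 300, 2000
    ).astype(int)
    pos = 0
    for hid, L in zip(host_ids, host_lengths):
        strand = str(rng.choice(np.array(["+", "-"])))
        features.append(
            GeneFeature(hid, "host", pos + 101, pos + 100 + int(L), strand,
                        organism="host")
        )
        pos += 100 + int(L)

    # ---- temporal classes and per-gene activity weights
    class_counts = _largest_remainder(cfg.class_proportions, cfg.n_phage_genes)
    labels = np.repeat(
        [c for c in class_counts], [class_counts[c] for c in class_counts]
    )
    labels = labels[rng.permutation(cfg.n_phage_genes)]
    phage_class = dict(zip(phage_ids, labels))

    weights = np.clip(rng.lognormal(0.0, cfg.weight_sigma, cfg.n_phage_genes), 0.05, None)
    phases_of_samples = [phase_of(t, cfg.grouping) for t in infected]
    profile = np.ones((cfg.n_phage_genes, len(infected)))
    for i, lab in enumerate(labels):
        if lab in ("early", "middle", "late"):
            for j, ph in enumerate(phases_of_samples):
                if ph == lab:
                    profile[i, j] = cfg.peak_fold
    # balance per-class activity so phase-summed phage expression is flat and
    # Total-Count shares reproduce the planted block profiles
    class_w = {
        c: weights[labels == c].sum() for c in ("early", "middle", "late")
    }
    target_w = np.mean([v for v in class_w.values() if v > 0]) if any(
        v > 0 for v in class_w.values()
    ) else 0.0
    for c, w in class_w.items():
        if w > 0:
            weights[labels == c] *= target_w / w
    # excluded genes: flat, scaled to a normalized mean well below the
    # exclusion threshold of 10 (target mean ~1.5-6)
    excl = labels == "excluded"
    if excl.any():
        s_t = (weights[~excl, None] * profile[~excl]).sum(axis=0)
        fracs = np.array([cfg.phage_fraction_curve[t] for t in infected])
        budget = round(cfg.assigned_fraction * cfg.library_size)
        m_bar = float((fracs * budget).mean())
        inv_s = float((1.0 / s_t).mean())
        targets = rng.uniform(1.5, 6.0, int(excl.sum()))
        weights[excl] = targets / (m_bar * inv_s)

    # ---- host planted effects
    de = cfg.host_de
    n_planted = de.n_early_down + de.n_early_up + de.n_late_up + de.n_late_down
    planted = rng.choice(cfg.n_host_genes, size=n_planted, replace=False)
    cursor = 0
    host_effect: dict[str, dict[str, float]] = {}
    host_mult = np.ones((cfg.n_host_genes, len(times)))
    phase_cols = {
        ph: [k for k, t in enumerate(times) if phase_of(t, cfg.grouping) == ph]
        for ph in ("early", "late")
    }
    for group, phase, sign in (
        ("n_early_down", "early", -1),
        ("n_early_up", "early", +1),
        ("n_late_up", "late", +1),
        ("n_late_down", "late", -1),
    ):
        k = getattr(de, group)
        for idx in planted[cursor : cursor + k]:
            gid = host_ids[idx]
            eff = sign * de.effect_log2fc
            host_effect.setdefault(gid, {})[f"{phase}_vs_control"] = eff
            host_mult[idx, phase_cols[phase]] = 2.0 ** eff
        cursor += k
    for gid, effs in host_effect.items():
        late = effs.get("late_vs_control", 0.0)
        early = effs.get("early_vs_control", 0.0)
        if late - early:
            effs["late_vs_early"] = late - early
    host_weights = rng.lognormal(0.0, cfg.weight_sigma, cfg.n_host_genes)

    # ---- planted ncRNAs
    planted_ncrnas: list[tuple[str, int, int, str, str]] = []
    candidates = [
        i
        for i, f in enumerate(features[: cfg.n_phage_genes])
        if f.length >= 320 and phage_class[f.gene_id] != "excluded"
    ]
    if cfg.n_asrna > len(candidates):
        raise ValueError("not enough long phage genes to host planted asRNAs")
    targets_idx = (
        rng.choice(candidates, size=cfg.n_asrna, replace=False)
        if cfg.n_asrna
        else np.array([], dtype=int)
    )
    ncrna_intervals: list[tuple[int, int, str]] = []
    for idx in targets_idx:
        g = features[idx]
        third = str(rng.choice(np.array(["5prime", "middle", "3prime"])))
        max_len = min(400, (2 * g.length) // 3 - 62)
        L = int(rng.integers(150, max_len + 1)) if max_len > 150 else 150
        zlo, zhi = _oriented_third_zone(g.start, g.end, g.strand, third)
        # keep the midpoint >=30 bp inside the targeted third so the planted
        # relation label stays well-defined under detection boundary jitter;
        # the interval itself always stays >=31 bp inside the gene, else its
        # coverage could merge with an adjacent same-strand gene's
        in_lo = g.start + 31 + L // 2
        in_hi = g.end - 31 - (L - L // 2)
        lo = max(zlo + 30, in_lo)
        hi = min(zhi - 30, in_hi)
        if lo > hi:
            # the end third is too tight on a short gene: plant in the middle
            # third instead, which is always feasible for these lengths
            third = "middle"
            zlo, zhi = _oriented_third_zone(g.start, g.end, g.strand, third)
            lo = max(zlo + 30, in_lo)
            hi = min(zhi - 30, in_hi)
        m = int(rng.integers(lo, hi + 1)) if lo <= hi else int(
            np.clip((zlo + zhi) // 2, in_lo, in_hi)
        )
        start = m - L // 2
        end = start + L - 1
        strand = "-" if g.strand == "+" else "+"
        # truth label follows the placed midpoint (clamping may shift thirds)
        placed_third = _third_label(g, start, end)
        planted_ncrnas.append(("phage", start, end, strand,
                               f"antisense_{placed_third}"))
        ncrna_intervals.append((start, end, strand))
    # intergenic transcripts centred in the reserved gaps
    for L in intergenic_lengths:
        placed = False
        for i in range(1, cfg.n_phage_genes):
            gap_lo = phage_layout[i - 1][1] + 1
            gap_hi = phage_layout[i][0] - 1
            if gap_hi - gap_lo + 1 >= L + 2 * 31 and not any(
                s <= gap_hi and e >= gap_lo for s, e, _ in ncrna_intervals
            ):
                mid = (gap_lo + gap_hi) // 2
                start = mid - L // 2
                end = start + L - 1
                strand = str(rng.choice(np.array(["+", "-"])))
                planted_ncrnas.append(("phage", start, end, strand, "intergenic"))
                ncrna_intervals.append((start, end, strand))
                placed = True
                break
        if not placed:
            raise ValueError("no intergenic gap large enough for a planted sRNA")

    # ---- per-sample read counts
    fractions = [cfg.phage_fraction_curve[t] for t in times]
    budget0 = round(cfg.assigned_fraction * cfg.library_size)
    rl = cfg.read_length
    ncrna_rates = np.array(
        [
            cfg.ncrna_target_depth * (e - s + 1 - rl + 1) / rl
            for _, s, e, _, _ in planted_ncrnas
        ]
    )
    n_genes = cfg.n_phage_genes + cfg.n_host_genes
    count_mat = np.zeros((n_genes, len(times)), dtype=np.int64)
    ncrna_counts = np.zeros((len(planted_ncrnas), len(times)), dtype=np.int64)
    unassigned = np.zeros(len(times), dtype=np.int64)
    infected_j = 0
    for j, t in enumerate(times):
        if t > 0 and len(planted_ncrnas):
            ncrna_counts[:, j] = rng.poisson(ncrna_rates)
        gene_budget = budget0 - int(ncrna_counts[:, j].sum())
        t_phage = int(rng.binomial(gene_budget, fractions[j])) if fractions[j] else 0
        t_host = gene_budget - t_phage
        if t > 0:
            lam_p = weights * profile[:, infected_j]
            infected_j += 1
        else:
            lam_p = weights.copy()
        lam_h = host_weights * host_mult[:, j]
        if cfg.dispersion is not None and np.isfinite(cfg.dispersion):
            r = cfg.dispersion
            lam_p = lam_p * rng.gamma(r, 1.0 / r, size=lam_p.shape)
            lam_h = lam_h * rng.gamma(r, 1.0 / r, size=lam_h.shape)
        if t_phage:
            count_mat[: cfg.n_phage_genes, j] = rng.multinomial(
                t_phage, lam_p / lam_p.sum()
            )
        count_mat[cfg.n_phage_genes :, j] = rng.multinomial(
            t_host, lam_h / lam_h.sum()
        )
        unassigned[j] = cfg.library_size - gene_budget - int(ncrna_counts[:, j].sum())

    values = pd.DataFrame(
        count_mat, index=phage_ids + host_ids, columns=sample_ids
    )
    counts = TimeCourseCounts(
        values=values,
        samples=samples,
        features={f.gene_id: f for f in features},
        normalized=False,
    )
    counts.unassigned = pd.Series(unassigned, index=sample_ids)

    # ---- read intervals on the phage contig
    if cfg.emit_coverage:
        intervals = _emit_intervals(
            rng, cfg, features, count_mat, planted_ncrnas, ncrna_counts, sample_ids
        )
    else:
        intervals = pd.DataFrame(
            columns=["contig", "start", "end", "strand", "sample_id"]
        )

    truth = SimTruth(
        phage_gene_class=phage_class,
        host_gene_effect=host_effect,
        planted_ncrnas=planted_ncrnas,
    )
    return features, counts, intervals, truth


def _emit_intervals(
    rng, cfg, features, count_mat, planted_ncrnas, ncrna_counts, sample_ids
) -> pd.DataFrame:
    rl = cfg.read_length
    chunks = []
    for j, sid in enumerate(sample_ids):
        starts_all = []
        strands_all = []
        for i in range(cfg.n_phage_genes):
            n = int(count_mat[i, j])
            if not n:
                continue
            g = features[i]
            hi = max(g.start, g.end - rl + 1)
            s = rng.integers(g.start, hi + 1, size=n)
            starts_all.append(s)
            strands_all.append(np.full(n, g.strand))
        for k, (contig, s0, e0, strand, _) in enumerate(planted_ncrnas):
            n = int(ncrna_counts[k, j])
            if not n:
                continue
            s = rng.integers(s0, e0 - rl + 2, size=n)
            starts_all.append(s)
            strands_all.append(np.full(n, strand))
        if not starts_all:
            continue
        starts = np.concatenate(starts_all)
        ends = np.minimum(starts + rl - 1, cfg.phage_genome_len)
        chunks.append(
            pd.DataFrame(
                {
                    "contig": "phage",
                    "start": starts,
                    "end": ends,
                    "strand": np.concatenate(strands_all),
                    "sample_id": sid,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=["contig", "start", "end", "strand", "sample_id"])
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------


def _depth_to_bedgraph(depth: np.ndarray, contig: str) -> pd.DataFrame:
    """Run-length compress a per-base depth vector into 1-based intervals."""
    change = np.flatnonzero(np.diff(depth)) + 1
    bounds = np.concatenate(([0], change, [len(depth)]))
    rows = [
        (contig, int(a) + 1, int(b), float(depth[a]))
        for a, b in zip(bounds[:-1], bounds[1:])
        if depth[a] > 0
    ]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


def write_fixture(
    dir_path: str | Path,
    features,
    counts: TimeCourseCounts,
    intervals: pd.DataFrame,
    truth: SimTruth,
    contig_length: int | None = None,
    force: bool = False,
) -> None:
    """Write the simulated dataset to disk: GFF3 annotation, counts + sample
    metadata TSVs, per-strand per-sample depth bedGraphs, the read-interval
    table, and ground-truth TSVs.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    from phagetime.coverage import per_base_depth

    out = Path(dir_path)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(out / "annotation.gff3", features)
    write_counts(out / "counts.tsv", counts, meta_path=out / "samples.tsv")
    write_intervals(out / "reads.tsv", intervals)
    if contig_length is None and len(intervals):
        contig_length = int(intervals["end"].max())
    if len(intervals):
        for sid in counts.sample_ids:
            sub = intervals[intervals["sample_id"] == sid]
            for strand, tag in (("+", "fwd"), ("-", "rev")):
                depth = per_base_depth(sub, contig_length, strand)
                write_coverage_bedgraph(
                    out / f"coverage_{sid}_{tag}.bedgraph",
                    _depth_to_bedgraph(depth, "phage"),
                )
    pd.DataFrame(
        sorted(truth.phage_gene_class.items()), columns=["gene_id", "temporal_class"]
    ).to_csv(out / "truth_phage_classes.tsv", sep="\t", index=False)
    rows = [
        {"gene_id": g, "comparison": c, "effect_log2fc": e}
        for g, effs in sorted(truth.host_gene_effect.items())
        for c, e in sorted(effs.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "comparison", "effect_log2fc"]).to_csv(
        out / "truth_host_effects.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        truth.planted_ncrnas,
        columns=["contig", "start", "end", "strand", "relation"],
    ).to_csv(out / "truth_ncrnas.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Recovery metrics (simulation-aware evaluation helpers)
# ---------------------------------------------------------------------------


def evaluate_temporal_recovery(call_table: pd.DataFrame, truth: SimTruth) -> float:
    """Fraction of phage genes whose called temporal class equals the planted one."""
    calls = dict(zip(call_table["gene_id"], call_table["temporal_class"]))
    hits = sum(
        1 for g, cls in truth.phage_gene_class.items() if calls.get(g) == cls
    )
    return hits / len(truth.phage_gene_class)


def evaluate_de_recovery(
    calls: pd.DataFrame, truth: SimTruth, comparison: str
) -> dict[str, float]:
    """Sensitivity / specificity of DE calls against the planted host effects."""
    status = dict(zip(calls["gene_id"], calls["status"]))
    tp = fn = tn = fp = 0
    for gid, st in status.items():
        eff = truth.host_gene_effect.get(gid, {}).get(comparison, 0.0)
        if eff > 0:
            tp += st == "up"
            fn += st != "up"
        elif eff < 0:
            tp += st == "down"
            fn += st != "down"
        else:
            tn += st == "ns"
            fp += st != "ns"
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_planted": tp + fn,
        "n_null": tn + fp,
    }
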