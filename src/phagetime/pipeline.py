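"""End-to-end orchestration: simulate/ingest -> normalize -> classify -> DE ->
coverage & ncRNA -> report bundle, with fixed stage order and explicit
intermediate files so each stage is independently re-runnable.

All randomness lives in the synthetic-data generator; every analysis stage is
deterministic, so a fixed config+seed gives a byte-identical summary JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phagetime import __version__
from phagetime.coverage import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_LENGTH,
    binned_count_table,
    candidates_to_frame,
    classify_relation,
    detect_transcribed_regions,
    per_base_depth,
    write_candidates_bed,
)
from phagetime.de import (
    CONTROL_CAVEAT,
    DEThresholds,
    de_call_late_vs_early,
    de_call_vs_control,
    format_tally,
    tally_de,
)
from phagetime.io import (
    DEFAULT_PHASE_GROUPING,
    TimeCourseCounts,
    read_counts,
    read_gff3,
    read_intervals,
    write_table,
)
from phagetime.normalize import phage_read_fraction, total_count_normalize
from phagetime.simulate import SimConfig, simulate_infection, write_fixture
from phagetime.temporal import DEFAULT_MARGIN, DEFAULT_MIN_TGR, classify_all


@dataclass
class PipelineConfig:
    """One config for the whole pipeline.

    Either ``sim`` is given (synthetic run) or the three input paths are.
    Normalization scopes per stage follow the package defaults: the temporal
    classifier normalizes phage genes against each other (``phage_only`` over
    infected samples), DE uses the whole-library context (``all_reads``),
    coverage bins are reported raw with ``phage_only`` scale factors
    available.
    """

    outdir: str | Path
    sim: SimConfig | None = None
    gff_path: str | Path | None = None
    counts_path: str | Path | None = None
    meta_path: str | Path | None = None
    reads_path: str | Path | None = None
    phage_contig_length: int | None = None
    grouping: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_GROUPING))
    min_tgr: float = DEFAULT_MIN_TGR
    margin_threshold: float = DEFAULT_MARGIN
    de_thresholds: DEThresholds = field(default_factory=DEThresholds)
    bin_width: int = DEFAULT_BIN_WIDTH
    min_depth: float = DEFAULT_MIN_DEPTH
    min_length: int = DEFAULT_MIN_LENGTH
    merge_gap: int = DEFAULT_MERGE_GAP
    make_figures: bool = False

    def validate(self) -> None:
        if self.sim is None and not (
            self.gff_path and self.counts_path and self.meta_path
        ):
            raise ValueError(
                "config needs either a simulation block or input paths "
                "(annotation, counts, sample metadata)"
            )
        for name in ("min_tgr", "margin_threshold", "min_depth", "min_length",
                     "merge_gap", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


def _phase_samples(counts: TimeCourseCounts, grouping, phase: str) -> list[str]:
    return [s.sample_id for s in counts.samples if s.time_min in grouping[phase]]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all outputs under ``config.outdir``, and return
    the machine-readable summary (also written as ``summary.json``)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None

    # ---- stage 0: simulate or ingest
    if config.sim is not None:
        features, counts, intervals, truth = simulate_infection(config.sim)
        write_fixture(
            out / "input",
            features,
            counts,
            intervals,
            truth,
            contig_length=config.sim.phage_genome_len,
            force=True,
        )
        contig_length = config.sim.phage_genome_len
    else:
        features = read_gff3(config.gff_path)
        counts = read_counts(
            config.counts_path,
            config.meta_path,
            features={f.gene_id: f for f in features},
        )
        intervals = (
            read_intervals(config.reads_path)
            if config.reads_path
            else pd.DataFrame(
                columns=["contig", "start", "end", "strand", "sample_id"]
            )
        )
        contig_length = config.phage_contig_length or (
            int(intervals["end"].max()) if len(intervals) else None
        )

    grouping = config.grouping
    control = _phase_samples(counts, grouping, "control")
    early = _phase_samples(counts, grouping, "early")
    middle = _phase_samples(counts, grouping, "middle")
    late = _phase_samples(counts, grouping, "late")
    infected = early + middle + late
    if not control:
        raise ValueError("stage normalize: no control (0 min) sample in metadata")

    version_line = f"phagetime {__version__}"

    # ---- stage 1: phage read fraction (raw counts)
    fraction = phage_read_fraction(counts)
    write_table(out / "phage_fraction.tsv", fraction, f"{version_line}; raw TGR")

    # ---- stage 2: temporal classification (phage genes, phage_only scope)
    phage_ids = [g for g in counts.gene_ids if counts.organism_of(g) == "phage"]
    phage_counts = counts.subset_genes(phage_ids).subset_samples(infected)
    norm_phage = total_count_normalize(phage_counts, scope="phage_only")
    calls, class_summary = classify_all(
        norm_phage, grouping, config.min_tgr, config.margin_threshold
    )
    write_table(
        out / "temporal_calls.tsv",
        calls,
        f"{version_line}; scope=phage_only; min_tgr={config.min_tgr}; "
        f"margin={config.margin_threshold}",
    )

    # ---- stage 3: host differential expression (host_only scope: host genes
    # normalized against each other, so phage take-over of the library does
    # not masquerade as host down-regulation)
    norm_all = total_count_normalize(counts, scope="host_only")
    thr = config.de_thresholds
    de_tables = {}
    host_ids = [g for g in counts.gene_ids if counts.organism_of(g) == "host"]
    for comparison, group in (
        ("early_vs_control", early),
        ("late_vs_control", late),
    ):
        table = de_call_vs_control(
            norm_all, group, control[0], thr, comparison=comparison
        )
        de_tables[comparison] = table
        write_table(
            out / f"de_{comparison}.tsv",
            table,
            f"{version_line}; {CONTROL_CAVEAT}; log2fc_threshold="
            f"{thr.log2fc_threshold}; sd_multiplier={thr.sd_multiplier}",
        )
    table = de_call_late_vs_early(norm_all, early, late, thr)
    de_tables["late_vs_early"] = table
    write_table(
        out / "de_late_vs_early.tsv",
        table,
        f"{version_line}; pooled Student t-test; alpha={thr.alpha}; "
        f"log2fc_threshold={thr.log2fc_threshold}",
    )
    tallies = {
        name: tally_de(tbl, n_total_genes=len(host_ids))
        for name, tbl in de_tables.items()
    }

    # ---- stage 4: coverage binning + ncRNA detection (phage contig)
    candidates = []
    if len(intervals) and contig_length:
        bins = binned_count_table(
            intervals, contig_length, counts.sample_ids, config.bin_width
        )
        write_table(
            out / "coverage_bins.tsv",
            bins,
            f"{version_line}; bin_width={config.bin_width}; reads assigned to "
            "the bin containing their 5' end",
        )
        phage_features = [f for f in features if f.contig == "phage"]
        late_iv = intervals[intervals["sample_id"].isin(late)]
        misc_n = 0
        for strand in ("+", "-"):
            depth = per_base_depth(late_iv, contig_length, strand) / max(len(late), 1)
            regions = detect_transcribed_regions(
                depth,
                strand,
                phage_features,
                "phage",
                config.min_depth,
                config.min_length,
                config.merge_gap,
            )
            for start, end, mean_depth in regions:
                misc_n += 1
                candidates.append(
                    classify_relation(
                        (start, end, strand),
                        phage_features,
                        "phage",
                        name=f"misc_{misc_n}",
                        mean_expression=mean_depth,
                        contig_length=contig_length,
                    )
                )
        candidates.sort(key=lambda c: c.start)
        candidates = [
            type(c)(**{**c.__dict__, "name": f"misc_{i + 1}"})
            for i, c in enumerate(candidates)
        ]
        write_table(
            out / "ncrna_candidates.tsv",
            candidates_to_frame(candidates),
            f"{version_line}; min_depth={config.min_depth}; min_length="
            f"{config.min_length}; merge_gap={config.merge_gap}; detected on "
            "mean late-phase depth",
        )
        write_candidates_bed(out / "ncrna_candidates.bed", candidates)

    # ---- summary
    n_antisense = sum(c.relation.startswith("antisense") for c in candidates)
    summary = {
        "version": __version__,
        "seed": config.sim.seed if config.sim is not None else None,
        "thresholds": {
            "min_tgr": config.min_tgr,
            "margin_threshold": config.margin_threshold,
            "log2fc_threshold": thr.log2fc_threshold,
            "sd_multiplier": thr.sd_multiplier,
            "alpha": thr.alpha,
            "pseudocount": thr.pseudocount,
            "bin_width": config.bin_width,
            "min_depth": config.min_depth,
            "min_length": config.min_length,
            "merge_gap": config.merge_gap,
        },
        "phage_class_sizes": class_summary["class_sizes"],
        "n_phage_genes": class_summary["n_genes"],
        "zero_read_phage_genes": class_summary["zero_read_genes"],
        "de_tallies": {name: format_tally(t) for name, t in tallies.items()},
        "de_tallies_full": tallies,
        "phage_fraction_pct": {
            row.sample_id: row.phage_fraction_pct for row in fraction.itertuples()
        },
        "ncrna": {
            "n_candidates": len(candidates),
            "n_antisense": n_antisense,
            "n_intergenic": len(candidates) - n_antisense,
        },
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.make_figures:
        make_figures(out)
    return summary


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def make_figures(bundle_dir: str | Path) -> list[Path]:
    """Plot the report bundle: per-strand binned coverage curves shaded by
    time point, per-class average percent profiles, and log2FC panels
    (genome-ordered scatter with +/-1.5 guides, plus rank-ordered curves).

    Missing stage outputs skip the corresponding figure with a warning.
    The class-profile plot's data are also written as ``class_profiles.tsv``
    so the plotted curves can be checked programmatically.
    """
    import warnings

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(bundle_dir)
    made: list[Path] = []

    bins_path = out / "coverage_bins.tsv"
    if bins_path.exists():
        bins = pd.read_csv(bins_path, sep="\t", comment="#")
        fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
        samples = sorted(
            {c.rsplit("_", 1)[0] for c in bins.columns if c.endswith(("_fwd", "_rev"))}
        )
        shades = np.linspace(0.8, 0.0, len(samples))
        for ax, tag, label in zip(axes, ("fwd", "rev"), ("+ strand", "- strand")):
            for shade, sid in zip(shades, samples):
                ax.plot(
                    bins["bin_start"],
                    bins[f"{sid}_{tag}"],
                    color=str(shade),
                    lw=0.8,
                    label=sid,
                )
            ax.set_ylabel(f"reads / bin ({label})")
        axes[1].set_xlabel("genome position (bp)")
        axes[0].legend(fontsize=6, ncol=5)
        fig.tight_layout()
        p = out / "fig_coverage.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    else:
        warnings.warn("coverage_bins.tsv missing; skipping coverage figure")

    calls_path = out / "temporal_calls.tsv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t", comment="#")
        kept = calls[calls["temporal_class"].isin(("early", "middle", "late",
                                                   "constitutive"))]
        prof = (
            kept.groupby("temporal_class")[["pct_early", "pct_middle", "pct_late"]]
            .mean()
            .reset_index()
        )
        prof.to_csv(out / "class_profiles.tsv", sep="\t", index=False)
        fig, ax = plt.subplots(figsize=(5, 4))
        for row in prof.itertuples():
            ax.plot(
                [1, 2, 3],
                [row.pct_early, row.pct_middle, row.pct_late],
                marker="o",
                label=f"{row.temporal_class}",
            )
        ax.set_xticks([1, 2, 3], ["early", "middle", "late"])
        ax.set_ylabel("mean % of peak phase TGR")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_class_profiles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    else:
        warnings.warn("temporal_calls.tsv missing; skipping class-profile figure")

    de_paths = sorted(out.glob("de_*.tsv"))
    de_frames = []
    for p in de_paths:
        df = pd.read_csv(p, sep="\t", comment="#")
        if len(df):
            de_frames.append((p.stem.removeprefix("de_"), df))
    if de_frames:
        fig, axes = plt.subplots(
            2, len(de_frames), figsize=(4 * len(de_frames), 6), squeeze=False
        )
        for k, (name, df) in enumerate(de_frames):
            ax = axes[0][k]
            ax.scatter(np.arange(len(df)), df["log2fc"], s=4, c="k")
            for y in (1.5, -1.5):
                ax.axhline(y, color="grey", lw=0.8)
            ax.set_title(name, fontsize=9)
            ax.set_xlabel("gene order along genome")
            ax = axes[1][k]
            ax.plot(np.sort(df["log2fc"].to_numpy())[::-1], c="k", lw=1)
            for y in (1.5, -1.5):
                ax.axhline(y, color="grey", lw=0.8)
            ax.set_xlabel("rank by log2FC")
        axes[0][0].set_ylabel("log2FC")
        axes[1][0].set_ylabel("log2FC")
        fig.tight_layout()
        p = out / "fig_de.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    else:
        warnings.warn("no non-empty DE tables; skipping DE figure")
    return made
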