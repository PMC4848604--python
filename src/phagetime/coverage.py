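"""Strand-specific coverage binning and unannotated-transcript detection.

Binning follows the "count table" construction of the source analysis: the
genome is divided into fixed-width bins (default 250 bp, bin 1 = bases
1..250, bin 2 = 251..500, ...) and every stranded read is assigned to exactly
one bin — the bin containing its 5' end (+ strand reads: the interval start;
- strand reads: the interval end).  This conserves totals: the bin counts on
a strand always sum to the number of reads on that strand.

Candidate non-coding transcripts are maximal runs of per-base depth above a
floor (``min_depth``), merged across short gaps, filtered by length, and
pruned of runs explained by same-strand annotation (ordinary gene
transcription).  Each surviving region is labelled by its relation to the
annotation: antisense to the 5' end / middle / 3' end of an opposite-strand
gene (by thirds of that gene's oriented length), antisense to several genes,
or intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from phagetime.io import GeneFeature

DEFAULT_BIN_WIDTH = 250
DEFAULT_MIN_DEPTH = 10.0
DEFAULT_MIN_LENGTH = 100
DEFAULT_MERGE_GAP = 50
DEFAULT_EXPLAINED_FRACTION = 0.9

ANTISENSE_RELATIONS = ("antisense_5prime", "antisense_middle", "antisense_3prime")


@dataclass(frozen=True)
class NcRNACandidate:
    """An unannotated transcribed region with its relation to the annotation."""

    name: str
    contig: str
    start: int
    end: int
    strand: str
    relation: str
    related_genes: tuple[str, ...]
    per_gene_labels: tuple[str, ...] = ()
    mean_expression: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def five_prime_ends(intervals: pd.DataFrame) -> np.ndarray:
    """5' end position of each stranded read interval (1-based)."""
    plus = intervals["strand"].to_numpy() == "+"
    return np.where(plus, intervals["start"].to_numpy(), intervals["end"].to_numpy())


def bin_coverage(
    read_intervals: pd.DataFrame,
    contig_length: int,
    bin_width: int = DEFAULT_BIN_WIDTH,
    strand: str | None = None,
) -> np.ndarray:
    """Count reads per fixed-width genome bin, assigning each read to the bin
    containing its 5' end.

    ``read_intervals`` columns: ``contig, start, end, strand`` (1-based
    inclusive); rows may be pre-filtered to one sample.  If ``strand`` is
    given, only reads on that strand are counted.  Returns an integer array
    of length ``ceil(contig_length / bin_width)``.

    Raises
    ------
    ValueError
        if any interval lies outside the contig bounds.
    """
    iv = read_intervals
    if strand is not None:
        iv = iv[iv["strand"] == strand]
    n_bins = -(-contig_length // bin_width)
    if len(iv) == 0:
        return np.zeros(n_bins, dtype=np.int64)
    starts = iv["start"].to_numpy()
    ends = iv["end"].to_numpy()
    if (starts < 1).any() or (ends > contig_length).any():
        raise ValueError("read interval outside contig bounds")
    pos5 = np.where(iv["strand"].to_numpy() == "+", starts, ends)
    return np.bincount((pos5 - 1) // bin_width, minlength=n_bins).astype(np.int64)


def binned_count_table(
    read_intervals: pd.DataFrame,
    contig_length: int,
    sample_ids: Sequence[str],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Per-250-bp (by default) count table: one row per bin, one column per
    (sample, strand) pair, plus bin coordinates."""
    n_bins = -(-contig_length // bin_width)
    starts = np.arange(n_bins) * bin_width + 1
    ends = np.minimum(starts + bin_width - 1, contig_length)
    out = pd.DataFrame({"bin_start": starts, "bin_end": ends})
    for sample in sample_ids:
        sub = read_intervals[read_intervals["sample_id"] == sample]
        for strand, tag in (("+", "fwd"), ("-", "rev")):
            out[f"{sample}_{tag}"] = bin_coverage(
                sub, contig_length, bin_width, strand
            )
    return out


def track_to_bedgraph_intervals(
    bins: np.ndarray, contig: str, contig_length: int, bin_width: int
) -> pd.DataFrame:
    """Binned counts as 1-based inclusive intervals ready for bedGraph output."""
    starts = np.arange(len(bins)) * bin_width + 1
    ends = np.minimum(starts + bin_width - 1, contig_length)
    return pd.DataFrame(
        {"contig": contig, "start": starts, "end": ends, "value": bins}
    )


# ---------------------------------------------------------------------------
# Per-base depth and region detection
# ---------------------------------------------------------------------------


def per_base_depth(
    read_intervals: pd.DataFrame, contig_length: int, strand: str
) -> np.ndarray:
    """Read depth at every base (index 0 = base 1) for one strand."""
    iv = read_intervals[read_intervals["strand"] == strand]
    depth = np.zeros(contig_length + 1, dtype=np.float64)
    if len(iv):
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        if (starts < 1).any() or (ends > contig_length).any():
            raise ValueError("read interval outside contig bounds")
        np.add.at(depth, starts - 1, 1.0)
        np.add.at(depth, ends, -1.0)
    return np.cumsum(depth[:-1])


def detect_transcribed_regions(
    depth: np.ndarray,
    strand: str,
    annotation: Sequence[GeneFeature],
    contig: str,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_length: int = DEFAULT_MIN_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
    explained_fraction: float = DEFAULT_EXPLAINED_FRACTION,
) -> list[tuple[int, int, float]]:
    """Find unannotated transcribed regions on one strand.

    Maximal runs of bases with ``depth >= min_depth`` are merged when
    separated by at most ``merge_gap`` bases, runs shorter than
    ``min_length`` are dropped, and runs mostly explained by same-strand
    annotation (>= ``explained_fraction`` of their bases inside the union of
    same-strand genes) are removed — those are ordinary gene transcription,
    including operon-style read-through across short intergenic gaps.

    Returns ``(start, end, mean_depth)`` tuples, 1-based inclusive,
    left-to-right.
    """
    above = depth >= min_depth
    if not above.any():
        return []
    # run-length extraction on the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    runs = list(zip(edges[::2] + 1, edges[1::2]))  # 1-based inclusive
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    same = [
        g for g in annotation if g.strand == strand and g.contig == contig
    ]
    covered = np.zeros(len(depth), dtype=bool)
    for g in same:
        covered[g.start - 1 : g.end] = True
    out = []
    for s, e in merged:
        if e - s + 1 < min_length:
            continue
        if covered[s - 1 : e].mean() >= explained_fraction:
            continue
        out.append((int(s), int(e), float(depth[s - 1 : e].mean())))
    return out


# ---------------------------------------------------------------------------
# Relation labelling
# ---------------------------------------------------------------------------


def _third_label(gene: GeneFeature, seg_start: int, seg_end: int) -> str:
    """Label the overlapped segment of a gene by thirds of the gene's oriented
    length, using the segment midpoint: <=1/3 -> 5', >=2/3 -> 3', else middle."""
    mid = (seg_start + seg_end) / 2.0
    if gene.strand == "+":
        rel = (mid - gene.start + 0.5) / gene.length
    else:
        rel = (gene.end - mid + 0.5) / gene.length
    if rel <= 1.0 / 3.0:
        return "5prime"
    if rel >= 2.0 / 3.0:
        return "3prime"
    return "middle"


def classify_relation(
    region: tuple[int, int, str],
    annotation: Sequence[GeneFeature],
    contig: str,
    name: str = "misc",
    mean_expression: float = 0.0,
    contig_length: int | None = None,
) -> NcRNACandidate:
    """Label a detected region by its relation to the annotated genes.

    For each opposite-strand gene the region overlaps, the overlapped portion
    of THAT gene is labelled 5'-end / middle / 3'-end by thirds of the gene's
    length in the gene's own orientation.  One overlap gives
    ``antisense_{label}``; several give ``antisense_multi`` with per-gene
    labels.  A region overlapping no gene on either strand is ``intergenic``
    and reports its flanking gene pair.
    """
    start, end, strand = region
    if start > end or start < 1 or (contig_length is not None and end > contig_length):
        raise ValueError(f"region ({start},{end}) outside contig bounds")
    genes = [g for g in annotation if g.contig == contig]
    opp = [
        g
        for g in genes
        if g.strand != strand and g.start <= end and g.end >= start
    ]
    if opp:
        opp.sort(key=lambda g: g.start)
        labels = tuple(
            _third_label(g, max(start, g.start), min(end, g.end)) for g in opp
        )
        if len(opp) == 1:
            relation = f"antisense_{labels[0]}"
        else:
            relation = "antisense_multi"
        return NcRNACandidate(
            name=name,
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            relation=relation,
            related_genes=tuple(g.gene_id for g in opp),
            per_gene_labels=labels,
            mean_expression=mean_expression,
        )
    same = [g for g in genes if g.start <= end and g.end >= start]
    if same:
        # partial same-strand read-through not removed upstream: treat as
        # intergenic extension of the overlapped gene(s)
        related = tuple(g.gene_id for g in sorted(same, key=lambda g: g.start))
    else:
        left = max(
            (g for g in genes if g.end < start), key=lambda g: g.end, default=None
        )
        right = min(
            (g for g in genes if g.start > end), key=lambda g: g.start, default=None
        )
        related = tuple(g.gene_id for g in (left, right) if g is not None)
    return NcRNACandidate(
        name=name,
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        relation="intergenic",
        related_genes=related,
        mean_expression=mean_expression,
    )


def candidates_to_frame(candidates: Sequence[NcRNACandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": c.name,
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "relation": c.relation,
                "related_genes": ",".join(c.related_genes),
                "per_gene_labels": ",".join(c.per_gene_labels),
                "mean_expression": c.mean_expression,
            }
            for c in candidates
        ],
        columns=[
            "name", "contig", "start", "end", "strand", "relation",
            "related_genes", "per_gene_labels", "mean_expression",
        ],
    )


def write_candidates_bed(path, candidates: Sequence[NcRNACandidate]) -> None:
    """BED6: 0-based half-open, score = mean per-base depth."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in candidates:
            fh.write(
                f"{c.contig}\t{c.start - 1}\t{c.end}\t{c.name}\t"
                f"{c.mean_expression:.1f}\t{c.strand}\n"
            )


# ---------------------------------------------------------------------------
# Published candidate table (fixture)
# ---------------------------------------------------------------------------


def load_published_ncrna_table() -> pd.DataFrame:
    """The ten novel ncRNA species reported from the phage phiR1-37 genome.

    Columns: ``name, start, end, strand, relation_text``; coordinates
    1-based inclusive on the phage genome.  The free-text relation column is
    normalized into the package's relation vocabulary in
    :func:`parse_relation_text`.
    """
    with resources.files("phagetime.data").joinpath("phiR1-37_ncrna.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["relation"] = df["relation_text"].map(parse_relation_text)
    return df


def parse_relation_text(text: str) -> str:
    """Map a free-text relation ('antisense to 3' end of g048', 'intragenic
    region between g099 and g100', ...) onto the relation vocabulary."""
    t = text.lower()
    if "antisense" not in t:
        return "intergenic"
    if " and " in t:
        return "antisense_multi"
    if "5" in t and "end" in t:
        return "antisense_5prime"
    if "3" in t and "end" in t:
        return "antisense_3prime"
    if "middle" in t:
        return "antisense_middle"
    return "antisense_middle"
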