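"""Readers/writers for annotations, count matrices, coverage and result tables.

Coordinate conventions
----------------------
Internal coordinates are 1-based inclusive (the GFF3 convention): a feature
on bases 100..400 has ``start=100, end=400``. bedGraph files are 0-based
half-open on disk and converted on read/write: ``[a, b)`` on disk maps to
``[a + 1, b]`` internally, an exact bijection.

All tables are TSV (UTF-8); result tables carry a ``#`` header comment line
recording the pipeline version and parameters.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default assignment of post-infection time points (minutes) to phase groups.
#: The grouping is configuration, not inference: it is what the downstream
#: phase-average arithmetic consumes.
DEFAULT_PHASE_GROUPING: dict[str, tuple[int, ...]] = {
    "control": (0,),
    "early": (2, 5),
    "middle": (10, 15, 21),
    "late": (28, 35, 42, 49),
}

PHASES = ("early", "middle", "late")


class FormatError(ValueError):
    """A file violated its declared format; message names the offending line."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: 1-based inclusive interval on a stranded contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    organism: str = "phage"
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: time post-infection and its phase-group label."""

    sample_id: str
    time_min: float
    phase_group: str

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"sample {self.sample_id}: negative time")


def phase_of(time_min: float, grouping: Mapping[str, Sequence[float]]) -> str:
    for phase, times in grouping.items():
        if time_min in times:
            return phase
    raise ValueError(f"time point {time_min} min not covered by phase grouping")


@dataclass
class TimeCourseCounts:
    """A genes x samples matrix of Total Gene Reads (TGR) with metadata.

    ``values`` is a pandas DataFrame indexed by gene_id with one column per
    sample_id, column order equal to the metadata order.  Raw matrices hold
    non-negative integers; normalization produces a separate matrix flagged
    ``normalized=True`` (never in place).
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    features: dict[str, GeneFeature] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            raise ValueError("count matrix columns must equal metadata sample order")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative count in matrix")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene_id {dup!r} in count matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def organism_of(self, gene_id: str) -> str:
        return self.features[gene_id].organism

    def gene_mask(self, organism: str) -> np.ndarray:
        if not self.features:
            raise ValueError("no gene features attached; organism unknown")
        return np.array(
            [self.features[g].organism == organism for g in self.values.index]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "TimeCourseCounts":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        return TimeCourseCounts(
            values=self.values[[s.sample_id for s in keep]].copy(),
            samples=keep,
            features=self.features,
            normalized=self.normalized,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "TimeCourseCounts":
        return TimeCourseCounts(
            values=self.values.loc[list(gene_ids)].copy(),
            samples=list(self.samples),
            features=self.features,
            normalized=self.normalized,
        )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene"}


def read_gff3(path: str | Path, *, skip_rrna: bool = True) -> list[GeneFeature]:
    """Parse gene-type records of a GFF3 file into :class:`GeneFeature` s.

    rRNA genes (attribute ``biotype=rRNA``) are skipped by default so that
    downstream counts are over non-rRNA gene features only.
    """
    features: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype not in _GENE_TYPES:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            attr_map = _parse_attributes(attrs, path, lineno)
            if "ID" not in attr_map:
                raise FormatError(f"{path}: line {lineno}: missing ID attribute")
            if skip_rrna and attr_map.get("biotype") == "rRNA":
                continue
            gene_id = attr_map["ID"]
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate ID {gene_id!r}")
            seen.add(gene_id)
            try:
                feat = GeneFeature(
                    gene_id=gene_id,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    organism=attr_map.get("organism", "phage"),
                    product=attr_map.get("product"),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            features.append(feat)
    return features


def _parse_attributes(attrs: str, path: str | Path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"{path}: line {lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out


def write_gff3(path: str | Path, features: Iterable[GeneFeature]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id};organism={f.organism}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.contig}\tphagetime\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Count matrix + sample metadata
# ---------------------------------------------------------------------------


def read_counts(
    counts_path: str | Path,
    meta_path: str | Path,
    features: Mapping[str, GeneFeature] | None = None,
) -> TimeCourseCounts:
    """Read a TGR matrix (genes x samples TSV) with its sample-metadata sidecar.

    The sidecar TSV has columns ``sample_id``, ``time_min``, ``phase_group``.
    Sample order follows the metadata file; every column of the count matrix
    must be present in the metadata and vice versa.
    """
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str})
    samples = [
        SampleMeta(row.sample_id, float(row.time_min), str(row.phase_group))
        for row in meta.itertuples()
    ]
    raw = pd.read_csv(
        counts_path, sep="\t", comment="#", index_col=0, dtype=str
    )
    missing = set(raw.columns) - {s.sample_id for s in samples}
    if missing:
        raise ValueError(f"samples in counts absent from metadata: {sorted(missing)}")
    missing = {s.sample_id for s in samples} - set(raw.columns)
    if missing:
        raise ValueError(f"samples in metadata absent from counts: {sorted(missing)}")
    values = pd.DataFrame(index=raw.index)
    for col in (s.sample_id for s in samples):
        try:
            values[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()][0]
            raise FormatError(
                f"{counts_path}: non-numeric cell at gene {bad!r}, sample {col!r}"
            ) from None
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{counts_path}: negative count")
    return TimeCourseCounts(
        values=values,
        samples=samples,
        features=dict(features) if features else {},
        normalized=False,
    )


def write_counts(
    dir_or_counts_path: str | Path,
    counts: TimeCourseCounts,
    meta_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a count matrix TSV (and, if ``meta_path`` given, the sidecar)."""
    with open(dir_or_counts_path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = counts.values.copy()
        if not counts.normalized:
            out = out.astype(np.int64)
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t")
    if meta_path is not None:
        with open(meta_path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\ttime_min\tphase_group\n")
            for s in counts.samples:
                t = int(s.time_min) if float(s.time_min).is_integer() else s.time_min
                fh.write(f"{s.sample_id}\t{t}\t{s.phase_group}\n")


# ---------------------------------------------------------------------------
# bedGraph / read intervals
# ---------------------------------------------------------------------------


def read_coverage_bedgraph(
    path: str | Path, contig_length: int | None = None
) -> pd.DataFrame:
    """Read a 4-column bedGraph into 1-based inclusive intervals.

    Returns a DataFrame with columns ``contig, start, end, value`` where
    ``start``/``end`` are 1-based inclusive.  Overlapping intervals or
    negative values are rejected.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            contig, a, b, v = cols
            a, b = int(a), int(b)
            value = float(v)
            if value < 0:
                raise FormatError(f"{path}: line {lineno}: negative value")
            if b <= a:
                raise FormatError(f"{path}: line {lineno}: empty/inverted interval")
            if contig_length is not None and b > contig_length:
                raise FormatError(
                    f"{path}: line {lineno}: interval end {b} beyond contig "
                    f"length {contig_length}"
                )
            rows.append((contig, a + 1, b, value))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "value"])
    for contig, grp in df.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
            raise FormatError(f"{path}: overlapping intervals on contig {contig}")
    return df


def write_coverage_bedgraph(path: str | Path, track: pd.DataFrame) -> None:
    """Write 1-based inclusive intervals (``contig,start,end,value``) as bedGraph."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in track.itertuples(index=False):
            value = int(row.value) if float(row.value).is_integer() else row.value
            fh.write(f"{row.contig}\t{row.start - 1}\t{row.end}\t{value}\n")


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a stranded read-interval table (contig, start, end, strand, sample_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"contig": str, "start": np.int64, "end": np.int64,
               "strand": str, "sample_id": str},
    )
    expected = ["contig", "start", "end", "strand", "sample_id"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_intervals(path: str | Path, intervals: pd.DataFrame) -> None:
    intervals.to_csv(path, sep="\t", index=False)


def write_table(path: str | Path, table: pd.DataFrame, header_comment: str) -> None:
    """Write a result table as TSV with a ``#`` comment recording provenance."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False)
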