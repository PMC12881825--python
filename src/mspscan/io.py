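"""Reading, merging, and sorting of per-sample bedmethyl files.

A bedmethyl file (BED9+2 dialect, as written by per-read modification
aggregators such as modbam2bed) carries one row per cytosine per strand:
the first nine columns are standard BED9, column 10 is the read coverage
and column 11 the percent of reads calling the base methylated.

All coordinates are 0-based half-open internally and in every file this
package writes.  Chromosomes are ordered by natural sort (chr2 before
chr10), positions numerically, strands '+' before '-'.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError

logger = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"

#: column order of the merged-table TSV
MERGED_COLUMNS = ["chrom", "start", "end", "strand", "coverage", "meth_pct", "sample"]

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10 and chrX/chrY after numbers."""
    parts = _NAT_SPLIT.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def chrom_order(chroms: Iterable[str]) -> list[str]:
    return sorted(set(chroms), key=natural_key)


@dataclass(frozen=True)
class BedmethylDialect:
    """0-based column indices of the fields this pipeline consumes.

    The default matches the 11+-column BED9+2 layout; other dialects can be
    accommodated by remapping indices.
    """

    chrom: int = 0
    start: int = 1
    end: int = 2
    strand: int = 5
    coverage: int = 9
    meth_pct: int = 10

    @property
    def min_columns(self) -> int:
        return max(self.chrom, self.start, self.end, self.strand,
                   self.coverage, self.meth_pct) + 1


@dataclass
class SampleManifest:
    """Assignment of each sample to the control or disease group."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.groups.items() if g not in (CONTROL, DISEASE)}
        if bad:
            raise ConfigError(f"unknown group labels in manifest: {bad}")
        if not self.controls:
            raise ConfigError("manifest must contain at least one control sample")
        if not self.diseases:
            raise ConfigError("manifest must contain at least one disease sample")

    @property
    def controls(self) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == CONTROL)

    @property
    def diseases(self) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == DISEASE)

    def group_of(self, sample: str) -> str:
        return self.groups[sample]


@dataclass
class MergedTable:
    """All samples' methylation calls in one sorted table.

    ``df`` holds columns chrom, start, end, strand, coverage, meth_pct,
    sample, sorted by (chrom natural, start, strand, sample).  Rows with
    zero coverage are retained; their methylation is treated as a missing
    observation downstream.
    """

    df: pd.DataFrame
    manifest: SampleManifest = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)


def parse_bedmethyl(path: str | Path, sample_id: str,
                    dialect: BedmethylDialect = BedmethylDialect()) -> pd.DataFrame:
    """Parse one sample's bedmethyl file into a calls DataFrame.

    Raises :class:`ParseError` naming the first offending line for rows
    with too few columns, non-integer coordinates/coverage, a span other
    than one base, or a strand outside {+, -}.  Strand '.' is rejected:
    every downstream step is strand-aware.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < dialect.min_columns:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {dialect.min_columns} "
                    f"tab-separated columns, got {len(fields)}")
            try:
                chrom = fields[dialect.chrom]
                start = int(fields[dialect.start])
                end = int(fields[dialect.end])
                coverage = int(fields[dialect.coverage])
                meth_raw = fields[dialect.meth_pct]
                meth = float(meth_raw) if meth_raw not in ("", ".") else float("nan")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            strand = fields[dialect.strand]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if end != start + 1:
                raise ParseError(
                    f"{path}:{lineno}: interval [{start},{end}) does not span "
                    f"exactly one base")
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if coverage < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage {coverage}")
            if not np.isnan(meth) and not (0.0 <= meth <= 100.0):
                raise ParseError(
                    f"{path}:{lineno}: methylation {meth} outside [0,100]")
            if coverage == 0:
                meth = float("nan")
            rows.append((chrom, start, end, strand, coverage, meth))
    df = pd.DataFrame(rows, columns=MERGED_COLUMNS[:-1])
    df["sample"] = sample_id
    return df


def merge_and_sort(inputs: Sequence[tuple[str | Path, str]],
                   manifest: SampleManifest,
                   dialect: BedmethylDialect = BedmethylDialect()) -> MergedTable:
    """Merge per-sample bedmethyl files into one table sorted by position.

    The output order is total and deterministic: chromosome (natural
    sort), start, strand, sample — so any permutation of the input files
    yields an identical table.
    """
    seen_ids = [sid for _, sid in inputs]
    if len(set(seen_ids)) != len(seen_ids):
        raise ConfigError(f"duplicate sample ids in inputs: {seen_ids}")
    missing = [sid for sid in seen_ids if sid not in manifest.groups]
    if missing:
        raise ConfigError(f"samples missing from manifest: {missing}")
    frames = [parse_bedmethyl(path, sid, dialect) for path, sid in inputs]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=MERGED_COLUMNS)
    dup = df.duplicated(subset=["sample", "chrom", "start", "strand"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise DataError(
            "duplicate observation for key (sample={sample}, chrom={chrom}, "
            "pos={start}, strand={strand})".format(**first.to_dict()))
    return _sorted_table(df, manifest)


def _sorted_table(df: pd.DataFrame, manifest: SampleManifest) -> MergedTable:
    order = {c: i for i, c in enumerate(chrom_order(df["chrom"]))}
    df = (df.assign(_c=df["chrom"].map(order))
            .sort_values(["_c", "start", "strand", "sample"], kind="mergesort")
            .drop(columns="_c")
            .reset_index(drop=True))
    return MergedTable(df=df, manifest=manifest)


def collapse_strands(table: MergedTable) -> MergedTable:
    """Optionally fold '-' strand calls onto the '+' strand C of the CpG.

    The C on the minus strand sits one base right of the plus-strand C;
    calls are combined per sample by summing coverage and averaging
    methylation weighted by coverage.
    """
    df = table.df.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "start"] = df.loc[minus, "start"] - 1
    df.loc[minus, "end"] = df.loc[minus, "end"] - 1
    df["strand"] = "+"
    df["_mc"] = df["meth_pct"] * df["coverage"]
    grouped = df.groupby(["chrom", "start", "end", "strand", "sample"],
                         as_index=False).agg(
        coverage=("coverage", "sum"), _mc=("_mc", "sum"))
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["meth_pct"] = grouped["_mc"] / grouped["coverage"]
    grouped = grouped.drop(columns="_mc")[MERGED_COLUMNS]
    return _sorted_table(grouped, table.manifest)


def write_merged(table: MergedTable, path: str | Path) -> None:
    """Write the merged table as a headered TSV (LF endings, UTF-8)."""
    df = table.df.copy()
    df["meth_pct"] = df["meth_pct"].map(
        lambda v: "nan" if pd.isna(v) else format(v, ".2f"))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_merged(path: str | Path, manifest: SampleManifest) -> MergedTable:
    """Re-read a TSV written by :func:`write_merged`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(df["sample"]) - set(manifest.groups)
    if missing:
        raise ConfigError(f"samples missing from manifest: {sorted(missing)}")
    return _sorted_table(df[MERGED_COLUMNS], manifest)


def read_manifest(path: str | Path) -> tuple[list[tuple[str, str]], SampleManifest]:
    """Read a manifest TSV with columns path, sample, group (no header).

    Relative bedmethyl paths are resolved against the manifest's directory.
    """
    base = Path(path).parent
    inputs, groups = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: manifest rows need 3 columns "
                    "(path, sample, group)")
            p, sample, group = fields
            p = Path(p)
            inputs.append((str(p if p.is_absolute() else base / p), sample))
            groups[sample] = group
    return inputs, SampleManifest(groups)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene in 0-based half-open coordinates."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene records from an Ensembl-style GTF or GFF3.

    Only feature-type ``gene`` rows are used; 1-based inclusive
    coordinates are converted to 0-based half-open.  Rows whose attribute
    column cannot be parsed are skipped with a warning; if no gene row
    parses, a warning is emitted and an empty list returned (annotation
    effectively disabled).
    """
    from gffutils.feature import feature_from_line

    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8 or fields[2] != "gene":
                continue
            try:
                feat = feature_from_line(line)
                attrs = feat.attributes
                gene_id = (attrs.get("gene_id") or attrs.get("ID") or [""])[0]
                gene_id = re.sub(r"^gene:", "", gene_id)
                gene_name = (attrs.get("gene_name") or attrs.get("Name")
                             or [gene_id])[0]
                strand = feat.strand if feat.strand in ("+", "-") else "+"
                genes.append(GeneModel(gene_id=gene_id, gene_name=gene_name,
                                       chrom=feat.seqid, start=feat.start - 1,
                                       end=feat.end, strand=strand))
            except Exception as exc:  # malformed attribute column
                warnings.warn(f"{path}:{lineno}: skipping unparseable gene row "
                              f"({exc})")
    if not genes:
        warnings.warn(f"{path}: no gene features parsed; annotation disabled")
    genes.sort(key=lambda g: (natural_key(g.chrom), g.start, g.end))
    return genes


def open_reference(path: str | Path):
    """Open an indexed FASTA reference (index built on demand)."""
    from pyfaidx import Fasta

    return Fasta(str(path))
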