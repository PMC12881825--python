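"""End-to-end pipeline and deterministic output writers.

The pipeline runs merge -> Filter 1 -> boxplot statistics -> Filter 2 ->
primer enumeration/scoring -> amplicon pairing -> context attachment, and
writes four TSVs (boxplotData, interestingCpGs, primerData, pcrProduct)
plus, when a reference is given, mspRegions.fa.  All writers are
deterministic: identical inputs yield byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .amplicons import (MspRegion, attach_context, attach_primer_sequences,
                        flag_best, form_primer_pairs)
from .filtering import Params, SiteStats, differentiating_sites
from .io import GeneModel, MergedTable, collapse_strands
from .primers import PrimerCandidate, build_candidates

logger = logging.getLogger(__name__)

BOXPLOT_TSV = "boxplotData.tsv"
CPGS_TSV = "interestingCpGs.tsv"
PRIMER_TSV = "primerData.tsv"
PCR_TSV = "pcrProduct.tsv"
REGIONS_FA = "mspRegions.fa"

_NA = "NA"


@dataclass
class PipelineResult:
    stats: list[SiteStats]
    observations: pd.DataFrame
    candidates: list[PrimerCandidate]
    regions: list[MspRegion]
    annotated: bool = False
    with_sequence: bool = False


def run_pipeline(table: MergedTable, params: Params, *,
                 norm_mode: str = "mean", reference=None,
                 genes: list[GeneModel] | None = None,
                 collapse: bool = False) -> PipelineResult:
    """Run the full MSP-region detection workflow on a merged table."""
    if collapse:
        table = collapse_strands(table)
    n_positions = len(table.df[["chrom", "start", "strand"]].drop_duplicates())
    logger.info("positions in: %d", n_positions)
    stats, obs = differentiating_sites(table, params)
    logger.info("differentiating CpGs (Filters 1+2): %d", len(stats))
    candidates = build_candidates(stats, obs, table, params, norm_mode)
    logger.info("candidate primers: %d", len(candidates))
    if reference is not None:
        attach_primer_sequences(candidates, reference)
    regions = form_primer_pairs(candidates, params)
    logger.info("MSP regions: %d", len(regions))
    if not regions:
        logger.warning("no MSP regions found with the current parameters")
    attach_context(regions, obs, table, reference=reference, genes=genes)
    flag_best(regions)
    return PipelineResult(stats=stats, observations=obs, candidates=candidates,
                          regions=regions, annotated=genes is not None,
                          with_sequence=reference is not None)


def _f2(value) -> str:
    if value is None or (isinstance(value, float) and value != value):
        return _NA
    return format(float(value), ".2f")


def write_outputs(result: PipelineResult, table: MergedTable,
                  outdir: str | Path) -> list[Path]:
    """Write all artifacts into ``outdir`` (created if absent,
    existing files overwritten).  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = [
        _write_boxplot(result.stats, outdir / BOXPLOT_TSV),
        _write_cpgs(result.observations, table, outdir / CPGS_TSV),
        _write_primers(result.candidates, outdir / PRIMER_TSV),
        _write_regions(result.regions, outdir / PCR_TSV),
    ]
    if result.with_sequence:
        written.append(_write_fasta(result.regions, outdir / REGIONS_FA))
    return written


def _write_boxplot(stats: list[SiteStats], path: Path) -> Path:
    cols = ["chrom", "start", "end", "strand", "group",
            "p0", "p25", "p50", "p75", "p100", "n"]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in stats:
            for group, box in (("control", s.control), ("disease", s.disease)):
                fh.write("\t".join([
                    s.chrom, str(s.pos), str(s.pos + 1), s.strand, group,
                    _f2(box.p0), _f2(box.p25), _f2(box.p50), _f2(box.p75),
                    _f2(box.p100), str(box.n)]) + "\n")
    return path


def _write_cpgs(obs: pd.DataFrame, table: MergedTable, path: Path) -> Path:
    cols = ["chrom", "start", "end", "strand", "sample", "group",
            "coverage", "meth_pct"]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in obs.itertuples(index=False):
            fh.write("\t".join([
                row.chrom, str(row.start), str(row.end), row.strand,
                row.sample, table.manifest.group_of(row.sample),
                str(row.coverage), _f2(row.meth_pct)]) + "\n")
    return path


def _write_primers(candidates: list[PrimerCandidate], path: Path) -> Path:
    cols = ["chrom", "start", "end", "strand", "length", "n_cpgs",
            "cpg_positions", "score", "gc_pct", "sequence"]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            fh.write("\t".join([
                c.chrom, str(c.start), str(c.end), c.strand, str(c.length),
                str(len(c.sites)), ",".join(map(str, c.sites)),
                _f2(c.score), _f2(c.gc_pct),
                c.sequence if c.sequence else _NA]) + "\n")
    return path


def _write_regions(regions: list[MspRegion], path: Path) -> Path:
    cols = ["chrom", "start", "end", "length", "left_start", "left_end",
            "right_start", "right_end", "score", "mean_coverage", "gc_pct",
            "genes", "locus_class", "is_best"]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in regions:
            genes = _NA if r.locus_class is None else (
                ",".join(r.genes) if r.genes else ".")
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), str(r.length),
                str(r.left.start), str(r.left.end),
                str(r.right.start), str(r.right.end),
                _f2(r.score), _f2(r.mean_coverage), _f2(r.gc_pct),
                genes, r.locus_class or _NA,
                "1" if r.is_best else "0"]) + "\n")
    return path


def _write_fasta(regions: list[MspRegion], path: Path) -> Path:
    with open(path, "w", newline="\n") as fh:
        for r in regions:
            if r.sequence is None:
                continue
            fh.write(f">{r.chrom}:{r.start}-{r.end}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i:i + 70] + "\n")
    return path
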