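"""Pairing primer candidates into MSP regions (amplicons).

An MSP region is an ordered pair of non-overlapping primer windows on the
same chromosome whose span — left primer start to right primer end,
primers included — lies within the amplicon length bounds.  Its score is
exactly the sum of the two primer scores.  Distinct pairs may overlap one
another; that redundancy is deliberate, leaving the choice of annealing
properties to the primer designer.

When a reference is supplied the plus-strand sequence and GC content are
attached; with an annotation each region is classified as overlapping a
gene body, the 500 nt upstream of a transcription start, or intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, MspScanError
from .filtering import KEY, Params
from .io import DISEASE, GeneModel, MergedTable, natural_key
from .primers import PrimerCandidate

UPSTREAM_NT = 500

LOCUS_GENE = "gene"
LOCUS_UPSTREAM = "upstream500"
LOCUS_INTERGENIC = "intergenic"


@dataclass
class MspRegion:
    """Left primer start .. right primer end, with summed score."""

    chrom: str
    left: PrimerCandidate
    right: PrimerCandidate
    score: float
    mean_coverage: float = float("nan")
    mean_meth_diff: float = float("nan")
    gc_pct: float | None = None
    sequence: str | None = None
    genes: list[str] = field(default_factory=list)
    locus_class: str | None = None
    is_best: bool = False

    @property
    def start(self) -> int:
        return self.left.start

    @property
    def end(self) -> int:
        return self.right.end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sites(self) -> list[tuple[int, str]]:
        """Union of both primers' differentiating sites as (pos, strand)."""
        return sorted({(p, self.left.strand) for p in self.left.sites}
                      | {(p, self.right.strand) for p in self.right.sites})


def form_primer_pairs(candidates: list[PrimerCandidate], params: Params
                      ) -> list[MspRegion]:
    """All ordered primer pairs forming a valid amplicon.

    Pairs require the same chromosome, non-overlapping primers
    (left.end <= right.start) and an amplicon length within bounds.
    Output is sorted by (chrom, start, end), ties broken by descending
    score.
    """
    by_chrom: dict[str, list[PrimerCandidate]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    regions: list[MspRegion] = []
    for chrom in sorted(by_chrom, key=natural_key):
        cands = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        starts = np.array([c.start for c in cands])
        for a in cands:
            # right primer must start at or after a.end and end within reach
            lo = np.searchsorted(starts, a.end, side="left")
            for b in cands[lo:]:
                length = b.end - a.start
                if length > params.max_amplicon_len:
                    # b sorted by (start, end): later b never shortens span
                    # below bound once start alone exceeds it
                    if b.start + params.min_primer_len - a.start > params.max_amplicon_len:
                        break
                    continue
                if length < params.min_amplicon_len:
                    continue
                regions.append(MspRegion(chrom=chrom, left=a, right=b,
                                         score=a.score + b.score))
    regions.sort(key=lambda r: (natural_key(r.chrom), r.start, r.end, -r.score))
    return regions


def best_region(regions: list[MspRegion]) -> MspRegion:
    """Highest-scoring region; ties go to the smallest start, then length."""
    if not regions:
        raise MspScanError("no MSP regions to select a best from")
    return min(regions, key=lambda r: (-r.score, r.start, r.length))


def flag_best(regions: list[MspRegion]) -> None:
    if regions:
        best_region(regions).is_best = True


def gc_content(sequence: str) -> float:
    """Percent G+C, case-insensitive; ambiguity codes count only in the
    denominator."""
    if not sequence:
        raise MspScanError("cannot compute GC content of an empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def extract_sequence(reference, chrom: str, start: int, end: int) -> str:
    """Uppercase plus-strand reference sequence of [start, end)."""
    if chrom not in reference:
        raise DataError(f"chromosome {chrom!r} absent from reference "
                        f"(region {chrom}:{start}-{end})")
    length = len(reference[chrom])
    if not (0 <= start < end <= length):
        raise DataError(f"region {chrom}:{start}-{end} outside contig "
                        f"bounds [0,{length})")
    return str(reference[chrom][start:end]).upper()


def classify_and_annotate(region: MspRegion, genes: list[GeneModel]
                          ) -> tuple[list[str], str]:
    """Overlapping gene names and the locus class of an MSP region.

    Class ``gene`` if any gene body overlaps the region by >= 1 nt; else
    ``upstream500`` if the region overlaps the 500 nt upstream of any
    gene's transcription start (upstream of ``start`` for + genes, of
    ``end`` for - genes, clipped at position 0); else ``intergenic``.
    """
    hits = [g for g in genes
            if g.chrom == region.chrom
            and g.start < region.end and region.start < g.end]
    if hits:
        return sorted({g.gene_name for g in hits}), LOCUS_GENE
    for g in genes:
        if g.chrom != region.chrom:
            continue
        if g.strand == "+":
            up_start, up_end = max(0, g.start - UPSTREAM_NT), g.start
        else:
            up_start, up_end = g.end, g.end + UPSTREAM_NT
        if up_start < region.end and region.start < up_end:
            return [], LOCUS_UPSTREAM
    return [], LOCUS_INTERGENIC


def attach_context(regions: list[MspRegion], obs: pd.DataFrame,
                   table: MergedTable, reference=None,
                   genes: list[GeneModel] | None = None) -> None:
    """Fill coverage, methylation difference, sequence/GC and gene context.

    ``mean_coverage`` averages disease coverage over both primers'
    differentiating sites; ``mean_meth_diff`` is disease mean minus
    control mean methylation over those sites (positive by construction
    of Filter 2 at each site).
    """
    rows = obs[(obs["coverage"] >= 1) & obs["meth_pct"].notna()].copy()
    rows["_dz"] = rows["sample"].map(table.manifest.group_of) == DISEASE
    agg = rows.groupby(KEY + ["_dz"]).agg(
        cov_sum=("coverage", "sum"), meth_sum=("meth_pct", "sum"),
        n=("sample", "size"))
    per_site = {k: v for k, v in agg.iterrows()}

    def _sums(region: MspRegion, dz_flag: bool) -> tuple[float, float, int]:
        cov = meth = 0.0
        n = 0
        for p, strand in region.sites:
            row = per_site.get((region.chrom, p, strand, dz_flag))
            if row is not None:
                cov += row["cov_sum"]
                meth += row["meth_sum"]
                n += int(row["n"])
        return cov, meth, n

    for region in regions:
        dcov, dmeth, dn = _sums(region, True)
        _, cmeth, cn = _sums(region, False)
        region.mean_coverage = dcov / dn if dn else float("nan")
        dmean = dmeth / dn if dn else float("nan")
        cmean = cmeth / cn if cn else 0.0
        region.mean_meth_diff = dmean - cmean
        if reference is not None:
            region.sequence = extract_sequence(
                reference, region.chrom, region.start, region.end)
            region.gc_pct = gc_content(region.sequence)
        if genes is not None:
            region.genes, region.locus_class = classify_and_annotate(region, genes)


def attach_primer_sequences(candidates: list[PrimerCandidate], reference) -> None:
    for c in candidates:
        c.sequence = extract_sequence(reference, c.chrom, c.start, c.end)
        c.gc_pct = gc_content(c.sequence)
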