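"""Primer-window enumeration and coverage-normalized scoring.

A candidate MSP primer is a window of ``min_primer_len``..``max_primer_len``
nt that fully spans at least ``min_cpgs`` differentiating CpG dinucleotides
(the C and its following G must both lie inside the window).  Windows are
left-anchored at differentiating sites, which bounds the enumeration while
still producing the overlapping alternatives a primer designer wants.

Each candidate is scored against the disease samples only — control
methylation was already constrained by Filters 1 and 2:

    score = sum_i sum_j (Cov_ij / Norm_i) * Meth_ij

over disease samples i and the candidate's CpGs j, with Meth in percent.
Norm_i normalizes coverage so samples sequenced to different depths
contribute comparably; by default it is sample i's mean coverage over all
differentiating sites it has data for (so Cov/Norm is a relative
coverage), with the plain sum available as an alternative mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import KEY, Params, SiteStats
from .io import DISEASE, MergedTable

logger = logging.getLogger(__name__)

NORM_MODES = ("mean", "sum")


@dataclass(frozen=True)
class SampleNorm:
    """Per-disease-sample coverage normalizer over differentiating sites."""

    sample_id: str
    norm: float  # NaN when the sample has no data at any site
    k_sites: int


@dataclass
class PrimerCandidate:
    """A fixed-length window holding >= min_cpgs differentiating CpGs."""

    chrom: str
    start: int
    end: int
    strand: str
    sites: tuple[int, ...]
    score: float = 0.0
    gc_pct: float | None = None
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def enumerate_candidate_primers(sites: list[int], chrom: str, strand: str,
                                params: Params) -> list[PrimerCandidate]:
    """All primer windows over one chromosome/strand's sorted site list.

    For every differentiating site p and every length L in
    [min_primer_len, max_primer_len], the window [p, p+L) is a candidate
    iff it contains >= min_cpgs sites whose CpG dinucleotide fits inside
    (site + 2 <= p + L).  Output is deduplicated and sorted by
    (start, end).
    """
    pos = np.asarray(sorted(sites), dtype=np.int64)
    out: list[PrimerCandidate] = []
    seen: set[tuple[int, int]] = set()
    for p in pos:
        lo = np.searchsorted(pos, p, side="left")
        for length in range(params.min_primer_len, params.max_primer_len + 1):
            end = p + length
            # dinucleotide must fit: site <= end - 2
            hi = np.searchsorted(pos, end - 2, side="right")
            inside = pos[lo:hi]
            if inside.size >= params.min_cpgs and (int(p), int(end)) not in seen:
                seen.add((int(p), int(end)))
                out.append(PrimerCandidate(
                    chrom=chrom, start=int(p), end=int(end), strand=strand,
                    sites=tuple(int(x) for x in inside)))
    out.sort(key=lambda c: (c.start, c.end))
    return out


@dataclass
class DiseaseObservations:
    """Disease coverage/methylation at differentiating sites, for scoring.

    Wide matrices indexed by (chrom, pos, strand) rows and disease-sample
    columns; missing observations (no row, or zero coverage) are NaN.
    """

    coverage: pd.DataFrame
    meth: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    @classmethod
    def from_observations(cls, obs: pd.DataFrame, table: MergedTable
                          ) -> "DiseaseObservations":
        samples = table.manifest.diseases
        dz = obs[obs["sample"].isin(samples)
                 & (obs["coverage"] >= 1) & obs["meth_pct"].notna()]
        cov = dz.pivot_table(index=KEY, columns="sample", values="coverage",
                             aggfunc="first")
        meth = dz.pivot_table(index=KEY, columns="sample", values="meth_pct",
                              aggfunc="first")
        cov = cov.reindex(columns=samples)
        meth = meth.reindex(columns=samples)
        return cls(coverage=cov, meth=meth, samples=samples)


def compute_sample_norms(dz: DiseaseObservations, mode: str = "mean"
                         ) -> dict[str, SampleNorm]:
    """Coverage normalizer per disease sample over all differentiating sites.

    mode "mean": Norm_i = (sum_k Cov_k) / K — mean coverage of the K
    sites sample i has data for.  mode "sum": Norm_i = sum_k Cov_k, the
    genome-wide total.  A sample with no data at any site gets a missing
    norm and contributes zero to every primer score (warned).
    """
    if mode not in NORM_MODES:
        raise ValueError(f"norm mode must be one of {NORM_MODES}, got {mode!r}")
    norms: dict[str, SampleNorm] = {}
    for sample in dz.samples:
        col = dz.coverage[sample] if sample in dz.coverage else pd.Series(dtype=float)
        col = col.dropna()
        k = int(col.size)
        if k == 0:
            logger.warning(
                "disease sample %s has no data at any differentiating site; "
                "it contributes 0 to all primer scores", sample)
            norms[sample] = SampleNorm(sample, float("nan"), 0)
            continue
        total = float(col.sum())
        norm = total / k if mode == "mean" else total
        norms[sample] = SampleNorm(sample, norm, k)
    return norms


def score_primer(candidate: PrimerCandidate, dz: DiseaseObservations,
                 norms: dict[str, SampleNorm]) -> float:
    """Coverage-weighted disease methylation summed over the window's CpGs.

    Terms with a missing coverage or methylation observation contribute
    zero; the score is therefore non-negative and additive over both
    samples and sites.
    """
    idx = [(candidate.chrom, p, candidate.strand) for p in candidate.sites]
    cov = candidate_matrix(dz.coverage, idx)
    meth = candidate_matrix(dz.meth, idx)
    total = 0.0
    for sample in dz.samples:
        sn = norms[sample]
        if not np.isfinite(sn.norm) or sn.norm <= 0:
            continue
        term = (cov[sample] / sn.norm) * meth[sample]
        total += float(term.sum(skipna=True))
    return total


def candidate_matrix(wide: pd.DataFrame, idx: list[tuple]) -> pd.DataFrame:
    present = [i for i in idx if i in wide.index]
    return wide.loc[present]


def score_all(candidates: list[PrimerCandidate], dz: DiseaseObservations,
              norms: dict[str, SampleNorm]) -> None:
    for cand in candidates:
        cand.score = score_primer(cand, dz, norms)


def build_candidates(stats: list[SiteStats], obs: pd.DataFrame,
                     table: MergedTable, params: Params,
                     norm_mode: str = "mean") -> list[PrimerCandidate]:
    """Enumerate and score primer candidates over all chromosomes/strands."""
    dz = DiseaseObservations.from_observations(obs, table)
    norms = compute_sample_norms(dz, norm_mode)
    by_cs: dict[tuple[str, str], list[int]] = {}
    for s in stats:
        by_cs.setdefault((s.chrom, s.strand), []).append(s.pos)
    candidates: list[PrimerCandidate] = []
    from .io import natural_key
    for (chrom, strand) in sorted(by_cs, key=lambda k: (natural_key(k[0]), k[1])):
        candidates.extend(enumerate_candidate_primers(
            by_cs[(chrom, strand)], chrom, strand, params))
    score_all(candidates, dz, norms)
    return candidates
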