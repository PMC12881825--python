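"""Site-level filters selecting differentiating CpGs.

Filter 1 keeps positions that are essentially unmethylated in the control
group: enough controls must reach the coverage gate, and none of those
assessable controls may exceed the methylation ceiling.  Filter 2 then
keeps positions whose disease median methylation lies strictly above the
control group's upper whisker (the "100th percentile" of a boxplot with
1.5*IQR fences).

Both comparisons are strict: a control at exactly the ceiling passes
Filter 1, and a disease median equal to the control whisker fails
Filter 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CONTROL, DISEASE, MergedTable

KEY = ["chrom", "start", "strand"]


@dataclass(frozen=True)
class Params:
    """Pipeline thresholds.

    max_ctrl_meth
        Highest tolerated control methylation (percent); strictly above
        this in any assessable control removes the position (Filter 1).
    min_ctrl_cov
        Reads a control needs at a position to be assessable.
    min_ctrls_frac
        Fraction of controls that must be assessable; the required count
        is ``ceil(frac * n_controls)``.
    min_primer_len, max_primer_len
        Primer window length bounds in nt.
    min_cpgs
        Minimum differentiating CpGs a primer window must span.
    min_amplicon_len, max_amplicon_len
        MSP amplicon (left primer start to right primer end) bounds in nt.
    """

    max_ctrl_meth: float = 10.0
    min_ctrl_cov: int = 3
    min_ctrls_frac: float = 0.5
    min_primer_len: int = 18
    max_primer_len: int = 24
    min_cpgs: int = 3
    min_amplicon_len: int = 60
    max_amplicon_len: int = 400

    def __post_init__(self) -> None:
        if self.min_primer_len > self.max_primer_len:
            raise ConfigError("min_primer_len > max_primer_len")
        if self.min_amplicon_len > self.max_amplicon_len:
            raise ConfigError("min_amplicon_len > max_amplicon_len")
        if 2 * self.min_primer_len > self.max_amplicon_len:
            raise ConfigError("two primers cannot fit in max_amplicon_len")
        if self.min_cpgs < 1:
            raise ConfigError("min_cpgs must be >= 1")
        if not (0.0 < self.min_ctrls_frac <= 1.0):
            raise ConfigError("min_ctrls_frac must be in (0, 1]")
        if self.min_primer_len < 2:
            raise ConfigError("a primer must span at least a CpG dinucleotide")


@dataclass(frozen=True)
class BoxStats:
    """Five-number boxplot summary with whisker-bounded extremes.

    p25/p75 are linear-interpolation (type-7) quartiles of the non-missing
    values, p50 their median.  p0 is the smallest value at or above
    ``p25 - 1.5*iqr`` and p100 the largest value at or below
    ``p75 + 1.5*iqr``; values beyond the fences are outliers and never
    reported as extremes.
    """

    p0: float
    p25: float
    p50: float
    p75: float
    p100: float
    n: int

    @property
    def iqr(self) -> float:
        return self.p75 - self.p25


_EMPTY = BoxStats(*([float("nan")] * 5), n=0)


def group_percentiles(values: Iterable[float]) -> BoxStats:
    """Boxplot summary of one group's methylation values at a position.

    Missing values (NaN) carry no information and are dropped; with no
    observations every field is NaN, with one observation all five
    percentiles equal it.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return _EMPTY
    p25, p50, p75 = np.percentile(arr, [25, 50, 75])
    iqr = p75 - p25
    lo_fence = p25 - 1.5 * iqr
    hi_fence = p75 + 1.5 * iqr
    p0 = float(arr[arr >= lo_fence].min())
    p100 = float(arr[arr <= hi_fence].max())
    return BoxStats(p0=p0, p25=float(p25), p50=float(p50), p75=float(p75),
                    p100=p100, n=int(arr.size))


@dataclass(frozen=True)
class SiteStats:
    """Per-position boxplot summaries of both groups (Filter-1 survivors)."""

    chrom: str
    pos: int
    strand: str
    control: BoxStats
    disease: BoxStats


def required_controls(n_controls: int, frac: float) -> int:
    return math.ceil(frac * n_controls)


def filter1_control_sites(table: MergedTable, params: Params) -> pd.DataFrame:
    """Positions whose control samples are unmethylated and covered.

    A position is kept iff (a) at least ``ceil(min_ctrls_frac *
    n_controls)`` controls reach the coverage gate there and (b) no
    control at the gate shows methylation strictly above
    ``max_ctrl_meth``.  Controls below the gate are unassessable: they
    neither veto the position nor count toward the quorum.

    Returns the kept (chrom, start, strand) keys as a DataFrame.
    """
    controls = table.manifest.controls
    if not controls:
        raise ConfigError("no control samples in manifest")
    df = table.df
    ctrl = df[df["sample"].isin(controls)]
    assessable = ctrl[(ctrl["coverage"] >= params.min_ctrl_cov)
                      & ctrl["meth_pct"].notna()]
    need = required_controls(len(controls), params.min_ctrls_frac)
    if assessable.empty:
        return pd.DataFrame(columns=KEY)
    per_site = assessable.groupby(KEY).agg(
        n_assessable=("sample", "size"),
        max_meth=("meth_pct", "max"))
    keep = per_site[(per_site["n_assessable"] >= need)
                    & ~(per_site["max_meth"] > params.max_ctrl_meth)]
    return keep.reset_index()[KEY]


def filter2_differentiating(stats: SiteStats) -> bool:
    """True iff the disease median is strictly above the control whisker."""
    if stats.disease.n < 1 or stats.control.n < 1:
        return False
    return stats.disease.p50 > stats.control.p100


def compute_site_stats(table: MergedTable, kept_sites: pd.DataFrame,
                       params: Params) -> list[SiteStats]:
    """Boxplot statistics per Filter-1-surviving position and group.

    Control values enter only from controls at the coverage gate (the
    same evidence Filter 1 used); disease values from disease samples
    with at least one read.
    """
    df = table.df.merge(kept_sites, on=KEY)
    group = df["sample"].map(table.manifest.group_of)
    is_ctrl = group == CONTROL
    usable = np.where(
        is_ctrl,
        (df["coverage"] >= params.min_ctrl_cov) & df["meth_pct"].notna(),
        (df["coverage"] >= 1) & df["meth_pct"].notna())
    df = df[usable]
    out: list[SiteStats] = []
    for (chrom, pos, strand), site in df.groupby(KEY, sort=False):
        grp = site["sample"].map(table.manifest.group_of)
        out.append(SiteStats(
            chrom=chrom, pos=int(pos), strand=strand,
            control=group_percentiles(site.loc[grp == CONTROL, "meth_pct"]),
            disease=group_percentiles(site.loc[grp == DISEASE, "meth_pct"])))
    return out


def differentiating_sites(table: MergedTable, params: Params
                          ) -> tuple[list[SiteStats], pd.DataFrame]:
    """Run Filters 1 and 2; return surviving stats and their observations.

    The returned DataFrame holds the per-sample rows (both groups) at the
    surviving positions, for reporting and downstream scoring.
    """
    kept = filter1_control_sites(table, params)
    stats = compute_site_stats(table, kept, params)
    surviving = [s for s in stats if filter2_differentiating(s)]
    if surviving:
        keys = pd.DataFrame(
            [(s.chrom, s.pos, s.strand) for s in surviving], columns=KEY)
        obs = table.df.merge(keys, on=KEY)
    else:
        obs = table.df.iloc[0:0]
    return surviving, obs
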