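"""Synthetic multi-sample methylomes with planted hypermethylated clusters.

The generator emulates the data regime this pipeline targets: per-strand
CpG positions along one synthetic contig, per-sample integer read
coverage (Poisson — clinical nanopore panels sit near 7x per sample),
near-zero control methylation with bounded uniform noise, and planted
clusters of CpGs that are hypermethylated in the disease group.  Clusters
are planted in pairs spaced so that two primer windows form an amplicon
within the default 60-400 nt bounds, giving ground-truth intervals the
pipeline should recover.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (CONTROL, DISEASE, MERGED_COLUMNS, MergedTable, SampleManifest,
                 _sorted_table)

TRUTH_CLUSTER = "primer_cluster"
TRUTH_AMPLICON = "amplicon"


@dataclass(frozen=True)
class ClusterSpec:
    """A planted run of CpGs: ``n_cpgs`` sites every ``spacing`` nt from
    ``anchor``, methylated at ``disease_meth`` in disease and
    ``control_meth`` in control samples."""

    anchor: int
    n_cpgs: int = 5
    spacing: int = 5
    disease_meth: float = 90.0
    control_meth: float = 0.0

    @property
    def start(self) -> int:
        return self.anchor

    @property
    def end(self) -> int:
        # last C plus its G
        return self.anchor + (self.n_cpgs - 1) * self.spacing + 2

    @property
    def positions(self) -> list[int]:
        return [self.anchor + i * self.spacing for i in range(self.n_cpgs)]


@dataclass(frozen=True)
class TruthRegion:
    chrom: str
    start: int
    end: int
    kind: str  # primer_cluster | amplicon


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic methylome."""

    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int = 30_000
    n_control: int = 4
    n_disease: int = 4
    cpg_spacing: float = 100.0  # mean background inter-CpG gap, min 2 nt
    coverage_lambda: float = 7.0  # clinical nanopore depth
    control_meth_noise: float = 5.0  # background meth ~ U[0, noise]
    disease_background_meth: float = 5.0
    cluster_pairs: tuple[tuple[ClusterSpec, ClusterSpec], ...] = ()

    @property
    def clusters(self) -> list[ClusterSpec]:
        return [c for pair in self.cluster_pairs for c in pair]

    def validate(self) -> None:
        spans = sorted((c.start, c.end) for c in self.clusters)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ConfigError(
                    f"planted clusters overlap: [{s1},{e1}) and [{s2},{e2})")
        for c in self.clusters:
            if c.end > self.chrom_length:
                raise ConfigError(f"cluster [{c.start},{c.end}) exceeds "
                                  f"chrom_length {self.chrom_length}")


def default_config(seed: int = 0, n_pairs: int = 3, *,
                   coverage_lambda: float = 7.0, disease_meth: float = 90.0,
                   control_meth: float = 0.0, noise: float = 5.0,
                   pair_gap: int = 150, inter_pair: int = 2000) -> SimConfig:
    """Standard planted layout: ``n_pairs`` amplicons of two 5-CpG
    clusters ``pair_gap`` nt apart, pairs separated by ``inter_pair`` nt
    (beyond the default amplicon bound, so pairs cannot cross-talk)."""
    pairs = []
    for i in range(n_pairs):
        a = ClusterSpec(anchor=1000 + i * inter_pair,
                        disease_meth=disease_meth, control_meth=control_meth)
        b = replace(a, anchor=a.anchor + pair_gap)
        pairs.append((a, b))
    return SimConfig(seed=seed, chrom_length=1000 + n_pairs * inter_pair,
                     coverage_lambda=coverage_lambda,
                     control_meth_noise=noise,
                     disease_background_meth=noise,
                     cluster_pairs=tuple(pairs))


@dataclass
class SimResult:
    config: SimConfig
    calls: pd.DataFrame  # merged-table layout incl. sample column
    manifest: SampleManifest
    truth: list[TruthRegion]

    def to_merged_table(self) -> MergedTable:
        return _sorted_table(self.calls.copy(), self.manifest)

    @property
    def truth_amplicons(self) -> list[TruthRegion]:
        return [t for t in self.truth if t.kind == TRUTH_AMPLICON]


def generate_methylome(config: SimConfig) -> SimResult:
    """Draw one synthetic methylome (all samples) from ``config``.

    CpGs sit on the + strand.  Per sample and site, coverage is
    Poisson(coverage_lambda); methylation is the planted value plus
    uniform noise in [-noise, +noise] at cluster sites, or background
    uniform [0, noise] elsewhere, clipped to [0, 100].  Zero-coverage
    sites are emitted with missing methylation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cluster_pos = {p: c for c in config.clusters for p in c.positions}

    # background CpG lattice avoiding planted footprints
    positions = sorted(cluster_pos)
    footprint = set()
    for c in config.clusters:
        footprint.update(range(c.start - 2, c.end + 2))
    pos = 10
    mean_gap = max(config.cpg_spacing, 3.0)
    while pos < config.chrom_length - 2:
        if pos not in footprint:
            positions.append(pos)
        pos += 2 + int(rng.geometric(1.0 / (mean_gap - 2.0)))
    positions = sorted(set(positions))

    samples = ([f"ctrl{i + 1}" for i in range(config.n_control)]
               + [f"dis{i + 1}" for i in range(config.n_disease)])
    groups = {s: (CONTROL if s.startswith("ctrl") else DISEASE)
              for s in samples}
    noise = config.control_meth_noise
    rows = []
    for sample in samples:
        is_dis = groups[sample] == DISEASE
        cov = rng.poisson(config.coverage_lambda, size=len(positions))
        jitter = rng.uniform(-noise, noise, size=len(positions)) if noise else \
            np.zeros(len(positions))
        background = rng.uniform(0.0, noise, size=len(positions)) if noise else \
            np.zeros(len(positions))
        for j, p in enumerate(positions):
            spec = cluster_pos.get(p)
            if spec is None:
                base = background[j]
            else:
                planted = spec.disease_meth if is_dis else spec.control_meth
                base = planted + jitter[j]
            meth = float(np.clip(base, 0.0, 100.0))
            c = int(cov[j])
            rows.append((config.chrom, p, p + 1, "+", c,
                         meth if c > 0 else float("nan"), sample))
    calls = pd.DataFrame(rows, columns=MERGED_COLUMNS)

    truth = [TruthRegion(config.chrom, c.start, c.end, TRUTH_CLUSTER)
             for c in config.clusters]
    truth += [TruthRegion(config.chrom, a.start, b.end, TRUTH_AMPLICON)
              for a, b in config.cluster_pairs]
    return SimResult(config=config, calls=calls,
                     manifest=SampleManifest(groups), truth=truth)


def write_fixture(result: SimResult, outdir: str | Path) -> tuple[list, Path, Path]:
    """Write per-sample bedmethyl files, a manifest TSV, and truth BED6.

    Returns ([(bedmethyl path, sample)], manifest path, truth path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = []
    for sample in sorted(result.manifest.groups):
        sub = result.calls[result.calls["sample"] == sample]
        path = outdir / f"{sample}.bedmethyl"
        with open(path, "w", newline="\n") as fh:
            for row in sub.itertuples(index=False):
                meth = "nan" if pd.isna(row.meth_pct) else format(row.meth_pct, ".2f")
                score = min(int(row.coverage), 1000)
                fh.write("\t".join([
                    row.chrom, str(row.start), str(row.end), "m", str(score),
                    row.strand, str(row.start), str(row.end), "0,0,0",
                    str(row.coverage), meth]) + "\n")
        inputs.append((str(path), sample))
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w", newline="\n") as fh:
        for path, sample in inputs:
            fh.write(f"{Path(path).name}\t{sample}\t"
                     f"{result.manifest.group_of(sample)}\n")
    truth_path = outdir / "truth.bed"
    with open(truth_path, "w", newline="\n") as fh:
        for t in result.truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.kind}\t0\t+\n")
    return inputs, manifest_path, truth_path


@dataclass(frozen=True)
class RecoveryReport:
    n_truth: int
    n_recovered: int
    false_positives: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")


def _reciprocal50(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    overlap = min(a_end, b_end) - max(a_start, b_start)
    if overlap <= 0:
        return False
    return (overlap >= 0.5 * (a_end - a_start)
            and overlap >= 0.5 * (b_end - b_start))


def evaluate_recovery(truth: list[TruthRegion], predicted) -> RecoveryReport:
    """Score predictions against planted amplicons.

    A truth amplicon is recovered when some prediction overlaps it by at
    least 50% reciprocally; a prediction matching no truth amplicon at
    that stringency counts as a false positive.
    """
    amplicons = [t for t in truth if t.kind == TRUTH_AMPLICON]
    preds = [(p.chrom, p.start, p.end) for p in predicted]
    recovered = 0
    for t in amplicons:
        if any(c == t.chrom and _reciprocal50(t.start, t.end, s, e)
               for c, s, e in preds):
            recovered += 1
    fp = sum(1 for c, s, e in preds
             if not any(t.chrom == c and _reciprocal50(t.start, t.end, s, e)
                        for t in amplicons))
    return RecoveryReport(n_truth=len(amplicons), n_recovered=recovered,
                          false_positives=fp)
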