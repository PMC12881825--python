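# Methods

## Problem setting and model

`mspscan` screens per-cytosine, per-strand methylation calls from a
control group and a disease group for loci suitable for
methylation-specific PCR: regions essentially unmethylated in every
control sample, hypermethylated in disease samples, and dense enough in
differentiating CpGs that an MSP primer placed there interrogates
several of them at once. The pipeline is deliberately filter-based, not
test-based: no p-values are computed anywhere. The working assumption is
that for a clinical MSP assay the interesting loci are the extreme,
unambiguous ones, and that coverage-weighted effect size is a better
ranking criterion at low sequencing depth than significance against a
noise model one would have to invent.

Observations are `(coverage, percent methylation)` per sample at each
cytosine. A call with zero coverage is retained in the merged table but
treated as a missing observation everywhere downstream: absence of reads
is evidence of nothing. Strands are processed independently — a CpG's
plus-strand and minus-strand cytosines are separate sites — because
hemimethylation is real and MSP primers anneal to one converted strand.
An opt-in `--collapse-strands` mode folds minus-strand calls onto the
plus-strand C (coverage summed, methylation coverage-weighted) for
callers that report symmetric CpG measurements on both strands.

## Filters

**Filter 1 (control methylation ceiling).** A position survives iff
(a) at least `ceil(min_ctrls_frac · n_controls)` controls have coverage
≥ `min_ctrl_cov` there, and (b) no control at that gate has methylation
strictly above `max_ctrl_meth`. Both comparisons are strict because the
thresholds are phrased as "above": a control at exactly 10% passes.
Controls below the coverage gate are *unassessable*: they neither veto
the site nor count toward the quorum. A consequence worth knowing:
raising `min_ctrl_cov` is not monotone in the survivor set — it can
rescue a site by pushing its only methylated control below the gate.
That is intended; a 2-read methylation estimate should not veto anything.

**Boxplot statistics.** Per surviving position and group, quartiles are
computed by linear interpolation between order statistics (the numpy
`nanpercentile`/`nanmedian` default) over non-missing values. The
reported 0th/100th percentiles are whisker-bounded: with
`iqr = p75 − p25`, the 0th percentile is the smallest observed value
≥ `p25 − 1.5·iqr` and the 100th the largest observed value
≤ `p75 + 1.5·iqr`. These are always observed values, so a single outlier
sample cannot set the group extreme. Control statistics use the same
evidence base as Filter 1 (controls at the coverage gate); disease
statistics use disease samples with ≥ 1 read. With one observation all
five percentiles equal it; with none the site is dropped.

**Filter 2 (differentiating CpGs).** Kept iff `disease.p50 >
control.p100`, strictly, with ≥ 1 disease observation. Using the
whiskered maximum rather than the raw maximum means one outlier control
does not mask a locus — but that outlier already failed Filter 1 unless
it was below the coverage gate, so in practice Filter 2 separates the
disease median from the *trustworthy* control ceiling.

## Primer enumeration and scoring

Candidate windows are left-anchored at differentiating sites: for every
site `p` and every length `L ∈ [min_primer_len, max_primer_len]`
(defaults 18–24 nt), the window `[p, p+L)` is a candidate iff it fully
contains at least `min_cpgs` (default 3) differentiating CpG
dinucleotides — a CpG counts only if both its C and the following G lie
inside (`pos + 2 ≤ end`), since a primer must physically span the
dinucleotide it discriminates on. Anchoring at sites keeps the
enumeration finite and deterministic while still producing the
overlapping alternative windows a primer designer wants; windows shifted
off-site to the left would contain the same site subsets or fewer.

Scores sum, over disease samples `i` and window CpGs `j`,
`(Cov_ij / Norm_i) · Meth_ij` with methylation in percent. `Norm_i` is
computed once per sample over all `K` differentiating sites with data in
that sample. The default is the **mean** coverage, making `Cov/Norm` a
relative coverage with expectation 1 and the score scale approximately
`N_samples · M_cpgs · mean_methylation` — a few hundred to a few
thousand for real loci. The literal sum (`norm_mode="sum"`) divides by
the genome-wide total instead and is kept as a mode; it rescales every
sample's contribution by `1/K` and is useful only for comparing runs
with identical site sets. Missing observations contribute zero — no
imputation. A disease sample with no data at any differentiating site
gets a missing norm, contributes zero everywhere, and is warned about.

## Amplicon pairing and context

Every ordered pair of candidates on one chromosome with
`left.end ≤ right.start` (PCR primers cannot overlap on the amplicon)
and span `right.end − left.start` within `[min_amplicon_len,
max_amplicon_len]` (defaults 60–400 nt, primers included) becomes an MSP
region scored as the exact sum of its two primer scores. All pairs are
reported — distinct overlapping pairs give the bench scientist freedom
over annealing properties — and the single globally best region (maximal
score, ties to the smallest start, then smallest length) is flagged.
Pairing ignores the strand of the underlying evidence: both windows are
genomic intervals, and converting them into strand- and
bisulfite-aware primer sequences is downstream of this tool.

Reported per region: mean disease coverage over both primers'
differentiating sites, mean disease-minus-control methylation over those
sites (strictly positive by construction — each site individually passed
Filter 2), GC content and plus-strand sequence when a reference FASTA is
given, and overlapping gene names plus a locus class when a GTF/GFF3 is
given. The class is `gene` on ≥ 1 nt overlap with any gene body, else
`upstream500` if the region overlaps the 500 nt upstream of any gene's
transcription start (upstream of `start` for + genes, of `end` for −
genes, clipped at position 0), else `intergenic` — an exhaustive,
mutually exclusive partition.

## Synthetic methylomes

The generator emulates the data regime the pipeline targets, on one
synthetic contig with plus-strand CpGs:

- background CpG lattice with geometric inter-site gaps
  (mean `cpg_spacing` = 100 nt, minimum 2 nt);
- per sample per site coverage ~ Poisson(λ); the default λ = 7
  reflects clinical nanopore panels near 7× per sample, and λ ≥ 20–25 a
  high-coverage research run;
- control and background methylation uniform on [0, noise]
  (default noise = 5%); planted sites get their cluster's value plus
  uniform ±noise, clipped to [0, 100]; zero-coverage sites are emitted
  with missing methylation;
- planted signal as pairs of 5-CpG clusters (intra-cluster spacing 5 nt,
  span 22 nt ≤ the 24 nt window), cluster starts 150 nt apart within a
  pair, pairs 2000 nt apart — so each pair yields amplicons inside the
  60–400 nt bounds and pairs cannot cross-talk.

Everything derives from one integer seed (`numpy.random.default_rng`)
and is byte-reproducible. Recovery is scored per planted amplicon by
≥ 50% reciprocal overlap with any predicted region; a prediction
reaching that stringency with no planted amplicon counts as a false
positive.

What the simulator does **not** model: read-level error, bisulfite
conversion failure, minus-strand or hemimethylated sites, coverage
autocorrelation along the genome, biological between-sample
heterogeneity beyond uniform noise, and CpG-island-like clustering of
background sites. Passing the recovery tests therefore demonstrates the
pipeline's arithmetic and geometry, not its false-positive rate on real
methylomes — notably, with 5% uniform noise in both groups an isolated
background site occasionally passes Filter 2 by chance, and in rare
seeds three such sites fall within one 24 nt window and seed spurious
regions, which is exactly the behavior low-coverage real data would
show.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere (BED convention);
  chromosome order is natural sort. Output TSVs are UTF-8, LF,
  tab-separated, floats at 2 decimals; writers are byte-deterministic.
- Quartile convention is type-7 (linear interpolation), matching the
  numpy default; the whisker scan runs over observed values only.
- The Filter-1 quorum rounds up (`ceil`): "at least half of 3 controls"
  means 2.
- Duplicate (sample, chrom, pos, strand) rows are a hard error rather
  than silently aggregated.
- GC content counts G+C over the full window length, ambiguity codes in
  the denominator only.
- Problem sizes in the test suite and acceptance script (30 kb contigs,
  ~300 background CpGs, 8 samples, 20 replicates per regime) were chosen
  as the smallest instances that exercise every stage with comfortable
  statistical margin.

## Known limitations

- No primer thermodynamics (melting temperature, hairpins, dimers) and
  no bisulfite-converted primer sequence generation; outputs are regions
  and plus-strand genomic sequence, to be fed into a primer-design tool.
- No allele-specific or read-level methylation handling.
- `best_region` is a single global flag; per-locus best selection is a
  trivial post-filter on the full pair table but is not built in.
- The pairing step is quadratic per chromosome in the number of
  candidates within a 400 nt reach; dense pathological inputs (every
  position a candidate) will be slow before they are wrong.
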