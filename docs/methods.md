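# Methods

## Enrichment model

The array model treats each probe as a paired observation of ChIP and
input intensity at a genomic midpoint (0-based). Enrichment is the M
value, `log2(chip/input)`; intensities must be strictly positive and
are never pseudocount-imputed — non-positive values raise an error
identifying the probe, on the view that silent imputation hides
upstream QC problems. Probes carry a uniqueness (mappability) flag
supplied with the data; only unique probes inform normalization and
binning by default, since multi-mapping probes cannot be attributed to
a single locus. Consequently all TE-family statistics describe the
uniquely mappable portion of each family, which for high-copy families
is a biased (typically diverged-copy) subset — a limitation inherent to
the assay, not the software.

Bins are half-open `[k·w, (k+1)·w)` windows aligned to coordinate 0
(default w = 500 bp). A bin's value is the arithmetic mean of its
member probes' M; empty bins are omitted rather than zero-filled, so
downstream means are never diluted by uncovered territory.

### Normalization

Each sample is median-centered over unique probes, the convention that
typical background probes sit at M = 0. The global median is only an
unbiased estimate of the background level when background dominates
heavily; when heterochromatic probes are, say, a third of the track,
the mixture median sits 0.1–0.2 log2 units above the euchromatic peak,
and because both condition tracks are shifted almost identically, the
wild-type-vs-mutant difference Δm survives intact while every
percent-decrease denominator is deflated — inflating recovered
decreases by ~5–25% relative, as measured against planted truth. The
pipeline therefore applies a second centering step after class
assignment: the probe-weighted mean M of euchromatin-labeled bins is
subtracted from all bins (`normalization: euchromatin`, the default;
`median` gives the plain per-sample scale). A robust mode estimator
(half-sample mode) was evaluated for one-step background centering and
rejected: its sampling jitter (~0.05 in M at these track sizes) enters
the differential numerator directly and multiplies the variance of the
percent-decrease estimate several-fold.

### Class assignment

Feature classes are overlapping label sets, not a partition: a bin can
be simultaneously `TE:<family>`, `pericentric`, and
`subtelomere:<arm>`. A bin belongs to an interval feature iff its
midpoint lies inside the interval — unambiguous, symmetric, and
appropriate for 500-bp bins against kb-scale features; a
fractional-overlap rule would need an arbitrary threshold. Pericentric
territory is the centromere-proximal side of a supplied border
coordinate (borders are inputs, e.g. from H3K9me2 domain calls; this
package does not call them). Arms flagged chromosome-4-like are
entirely heterochromatic as class `chromosome4` and carry no
pericentric label. `euchromatin` means "no heterochromatic label";
subtelomere labels are positional, not heterochromatic, so a bin can be
subtelomeric euchromatin. Subtelomeric windows are the terminal 50 kb
of each arm's assembly on the telomere side (whole arm if shorter),
with series orientation normalized telomere → centromere.

### Differential summaries

Per label, profiles report the arithmetic mean over member bins, the
bin count, and SE = sd(bin means)/√n. The SE deliberately includes
between-feature geometric variance (families at different baselines
within the `te` aggregate), making recovery tests conservative.
Differentials report Δm always, and the percent decrease of the class
mean only when the wild-type mean exceeds `m_floor` (default 0.1):
ratios against near-zero reference means produce absurd percentages
for roo-like families, which are reported as Δm-only and flagged.
Exact equality of the two means reports 0% even below the floor.
"Decreased" means Δm < 0 strictly; ties count as unchanged. Families
and clusters enter the direction counts only with ≥ `min_bins` (5)
bins in both conditions. Percent-decrease SEs use first-order (delta
method) propagation of the two class-mean SEs.

## Synthetic data

The generator emulates a two-channel tiling array over a small genome
whose layout mirrors the profiled system: two major arms with
pericentric blocks (~0.75 Mb of 5.5 Mb), a 1.2-Mb chromosome-4-like
arm (the real chromosome 4 assembly is ~1.2 Mb), 30 TE families × 6
instances (0.8–2 kb), and 20 piRNA clusters (10–30 kb). Probes tile
every 300 bp (so a 500-bp bin holds 1–2 probes), input intensities are
lognormal, ChIP = input · 2^(true M + N(0, 0.3)), and 15% of probes
are flagged non-unique. Feature placement is length-weighted across
arms and uniform within them, rejection-sampled to keep placed
intervals disjoint; telomere-associated families (HeT-A- and
TART-like) place into the 50-kb terminal windows. True M at a position
is the baseline of the most specific containing feature (TE family >
piRNA cluster > pericentric/chr4 background > euchromatin at 0); the
mutant condition applies that feature's shift (relative by default,
additive available, plus an optional additive subtelomere term).

Family baselines span the observed range: eight low-enrichment
families near M ≈ 0.05–0.25 that do not respond to the depletion
(roo-like), seventeen mid families at M 0.85–1.7, three at M > 2
(gypsy5-like), and two telomeric families. Five clusters are inert and
one (42AB-like) gains 5%. The planted *class-mean* decreases are the
study targets — 13.4% (TE), 6.7% (pericentric), 5.7% (chr4), 8.7%
(clusters) — and because insensitive members and embedded
steeper-falling TE/cluster territory are part of each class mean, the
per-territory shifts are solved from the weighted-mean equation at the
expected feature occupancies (TE 4.6%, clusters 7.4% of any
territory), giving −0.139 (sensitive TEs), −0.063 (pericentric
background), −0.051 (chr4 background), −0.128 (sensitive clusters).
The insensitive-minority sizes are set so the expected decreased
fractions match the ~5/6 of families and clusters that lose enrichment
in the profiled data, counting near-zero-shift members as coin flips
and the gaining cluster as a near-certain increase. Exact truth per
realization (SimTruth) is computed by pushing the noiseless true-M
field through the same binning and labeling path, so recovery is
judged against what a noise-free assay would measure, edge bins
included.

What the generator does **not** emulate: probe sequences and
cross-hybridization, dye bias and spatial array artifacts, copy-number
differences between conditions, correlated (domain-level) noise, and
biological replicate structure (each condition is one track). Passing
recovery tests therefore demonstrate estimator correctness under
independent probe noise, not robustness to array artifacts — real data
should arrive already replicate-merged and QC'd.

qPCR plates follow the standard-curve model: input-dilution wells at
fractions (1, 0.1, 0.01, 0.001) with Ct = ct_full + slope·log10(f),
slope = −1/log10(1+E); IP wells sit at the curve's value for the
locus's true pulldown efficacy (control-locus efficacy 1%, times the
planted fold enrichment), all with Gaussian Ct noise (sd 0.15).
Reporter assays draw a lognormal activity per replicate (sd 0.2, n = 6,
matching 4–8 extract samples per genotype) and emit an exact OD574 line
over 0–120 min (within-series read noise is negligible next to
between-extract variability) or an OD480 endpoint; planted
genotype-class folds are (C, M, Z, M+Z) = (1, 2, 4, 6).

## Assay computations

Pulldown efficacy inverts the fitted dilution line at an IP Ct,
yielding the input-fraction equivalent; relative enrichment is the
ratio of mean efficacies (linear scale — efficacy, not Ct, is the
normalized quantity) of target over control locus. The enrichment SEM
combines replicate scatter with the curve-fit uncertainty evaluated by
the delta method with the OLS slope–intercept covariance
(cov(a,b) = −x̄·var(b)); the curve error is shared by all IP wells
inverted through one curve, so it does not average out with replicates
and omitting it understates the SEM several-fold at high replicate
counts. IP Cts outside the fitted dilution span set an out-of-range
flag rather than failing. ΔΔCT uses ideal doubling (base 2) by
default, with the fitted amplification base available as an
efficiency-corrected option; the reference sample's fold is 1 by
construction and fold SEMs propagate the replicate ΔCt spread of
sample and reference. β-gal activity is the least-squares OD574/min
slope over the full 2-hour window (an OD ceiling for linear-range
restriction is available, default off); negative slopes clamp to 0
with a flag. Genotype-class folds are ratios of class means with
delta-method SEMs; per-fly pigment normalization is optional since the
extract protocol fixes flies per sample.

## Determinism and problem sizes

All randomness flows from one integer seed through named
`numpy.random.default_rng([seed, stream])` streams, one per sampling
purpose; probe uniqueness flags draw from a condition-independent
stream because mappability is a property of the probe. Identical
config and seed reproduce byte-identical outputs, and the run manifest
records the config snapshot, input checksums, versions, and seed.

The validation suite runs the reference genome at 10 seeds
(~18,500 probes per condition each) for class-shift recovery, single
10⁴-element random instances for the brute-force kernel checks, 100 IP
replicates for qPCR recovery, and 200 seeds for reporter-fold
recovery; the whole suite and the acceptance script each complete in
well under a minute on one CPU.

## Known limitations

Peak calling, significance testing of per-family changes, replicate
merging, dye-bias/quantile normalization, border calling from
H3K9me2, and coordinate lift-over are out of scope. The percent
decreases are computed on bin means of the log2 scale; computing them
over probes or per-instance means would give slightly different
values. Direction counts are sensitive to the `min_bins` coverage
threshold when families are sparsely covered by unique probes.
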