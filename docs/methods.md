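# Methods

## The assay being modeled

A drop-off dPCR assay interrogates one amplicon with up to four hydrolysis
probes read on separate dye channels. One *reference* probe (HEX/SUN) binds
a stretch of the amplicon where no breaks map, so it detects every template;
the remaining *drop-off* probes sit directly on mutation-prone CpG sites,
and an indel under a probe abolishes its binding. A mutant template
therefore produces a reference-positive, drop-off-negative partition. The
per-site instability readout is the drop-off fraction
f = C_mut / C_ref.

## Partition statistics

With n partitions analyzing volume V·a (reaction volume V, analyzed
fraction a), each template species lands in a given partition with Poisson
count of mean λ_s = C_s · V·a/n. The negative fraction of a channel
estimates e^{−λ}, giving the standard Poisson correction
λ̂ = −ln(N_neg/N_total) and Ĉ = λ̂·n/(V·a). Confidence intervals map
Clopper–Pearson bounds on the negative fraction through −ln(·); a channel
with no negative partitions is *saturated* and reports only a lower bound.
Sanity anchor: 10 ng of human gDNA (3.3 pg per haploid genome; constant
exposed as `PG_PER_HAPLOID_GENOME`) in 9 μL gives 336.7 copies/μL, i.e.
λ ≈ 0.148 on the default 20,480-partition chip.

### Co-encapsulation correction

The naive mutant estimate — count (ref+, probe−) partitions over ref+
partitions — is biased low as loading grows, because a partition holding
both a mutant and a wild-type template lights every probe. Two corrected
estimators are implemented:

* **difference** (default): λ̂_mut = λ̂_ref − λ̂_probe. Each channel is
  Poisson-corrected independently; since the mutant species still binds the
  reference probe, the difference of the two channel rates is exactly the
  mutant rate under the model. Negative raw differences (sampling noise at
  f ≈ 0) are floored at zero and flagged, since concentration is physical.
* **joint**: solve e^{−λ̂_intact} from the probe-negative fraction, then
  λ̂_mut from P(ref+, probe−) = (1 − e^{−λ_mut})·e^{−λ_intact}.

Both are consistent; the test suite uses the joint estimator as the
cross-check of the default and demonstrates the naive estimator's bias at
λ_ref = 1.5 (naive ≈ 0.32 for a true f = 0.5).

Interval estimates for f̂ and for CNV ratios use a partition-resampling
bootstrap, implemented as a multinomial resample of the joint probe-pattern
counts — equivalent to resampling partitions with replacement, and the same
mechanism serves both quantities. Replicate chips are pooled by summing
pattern counts before quantification (used when the expected mutant count
per chip is a handful of molecules), and replicate-level aggregation
reports mean ± SEM across chips.

### CNV from probe ratios

r̂ = Ĉ_ref/Ĉ_probe per drop-off probe, with bootstrap CI. The call is
`hemizygous-reference` only when every probe's CI excludes 1 and contains
0.5; `euploid` when every CI contains 1; otherwise `other`. The package
deliberately stops at the ratio call — it cannot resolve which homolog
lost the site.

## Gating

Auto-thresholding does an exact two-center 1-D partition of each channel's
intensities (the split of the sorted values minimizing within-cluster sum
of squares, found by prefix sums). This is deterministic and cannot
mis-converge when the positive cluster is a fraction of a percent of
partitions — the regime of a drop-off assay near baseline. The threshold is
the midpoint of the two centers; calls are strict (`intensity > threshold`),
so exact ties gate negative, conservative for drop-off detection. A channel
whose two candidate centers are closer than 3 pooled within-cluster SDs is
degenerate (single cluster) and is called all-negative when its median sits
near the chip-wide 1st-percentile baseline, all-positive otherwise. The
all-positive branch relies on at least one other channel anchoring the
baseline; a chip whose every channel is saturated positive gates wrong, a
documented limit of data-driven thresholding without a fluorescence
calibration. "Rain" partitions get no third class; the threshold rule
decides them.

## The chip simulator

Per partition, species counts are independent Poissons; a dye is truly
positive iff ≥ 1 template of a species whose site for that dye is intact.
Intensities are conditional two-component Gaussians, defaults baseline
N(1000, 50) and positive N(5000, 200) arbitrary units, separable by
construction (the model refuses positive_mean ≤ baseline_mean + 4·max sd).
A `rain_fraction` (default 1%) of truly positive partitions draws from an
intermediate cluster at `rain_position` (default 0.7) of the
baseline→positive separation with the positive cluster's SD. Rain sits
between the clusters but overwhelmingly above a midpoint threshold: that
placement is forced by the assay this emulates, whose measured baseline
drop-off is ~10³-fold below a 10% editing signal — rain centered exactly
midway would flip ~half of itself negative under any midpoint threshold
and impose a false-drop-off floor orders of magnitude above that. Defaults
give end-to-end state recovery error below 10⁻³.

What the simulator does *not* model: PCR amplification kinetics (partitions
are endpoint-binary in truth), inter-chip fluorescence scale drift,
pipetting/dead-volume variation (analyzed_fraction defaults to 1.0 and the
exact instrument partition volume is not public — concentrations use the
ratio form λ·n/(V·a)), and probe cross-talk. Passing tests therefore show
the statistical machinery is correct under Poisson loading and separable
clusters, not that vendor-instrument artifacts are handled.

Default chip geometry is 20,480 partitions ("over 20,000 microchambers"
rounded to a power-of-two plate layout) in a 9 μL reaction; both are
configurable.

## The read simulator and indel profiling

Each amplicon-spanning read is independently edited with probability
`p_edit` (one indel per read — a single NHEJ scar per allele). The edit
position is a weighted hotspot (CpG) center plus a discretized
Gaussian(0, kernel_sd) offset; kernel_sd ≈ 3 bp reproduces focal
(Nalm6-like) peaks, larger values the spread (Reh-like) pattern. Type is a
deletion with probability 0.8 (deletions dominate insertions; the exact
ratio is a fixture choice, no published value), lengths are 1 + geometric
(defaults: mean ≈ 2.5 bp deletions, ≈ 1.7 bp insertions — small NHEJ
scars). Placements that would leave no aligned flank are resampled with a
bounded retry budget, then skipped with a warning. Reads carry exact CIGARs;
no substitution/sequencing-error model is layered on top, so the profiler's
exact truth-recovery tests are meaningful.

The profiler counts, per reference position: read depth (deletions included
in the footprint), deletion coverage, deletion starts, and insertions
(assigned to the reference position immediately following the insertion
point; a terminal insertion clips to the last position). Substitutions are
ignored — the profile is an indel readout. Frequencies are reported as
events/depth; per-read normalization would differ only by multi-event
reads, which the simulator does not produce.

CpG-proximity enrichment counts one event per deletion *start* plus one per
insertion (coverage-weighting would over-weight long deletions), and asks
what fraction lies within ±8 bp (default) of a CpG. The null re-places that
many events over covered positions with depth-proportional probability;
since proximity is a binary property of position, the null fraction is
Binomial(n_events, p_near), sampled `n_perm` times with the add-one p-value
convention. The null is depth-weighted uniform, not
sequence-composition-matched: it answers "are indels near CpGs given where
reads land", without assuming a mutational model.

`probe_window_dropoff` is the sequence-level analog of the dPCR readout:
among reads fully spanning a probe interval (full-span requirement avoids
edge-read denominator bias), the fraction carrying an indel overlapping the
interval (insertion at p overlaps [p−1, p+1)). On matched simulations it
tracks the dPCR f̂ up to kernel mass falling outside the probe window.

## Dose–response trend

The Jonckheere–Terpstra statistic, JT = Σ_{i<j} [#{x_i < x_j} + ½#{x_i = x_j}],
tests a monotone increasing alternative over ordered dose groups. It is
implemented from scratch (the statistic is part of the package's test
surface): exact enumeration of all value-to-slot assignments when total
n ≤ 8, label permutation with the add-one convention otherwise. Rank-based,
hence invariant to monotone transforms; ties use the ½ convention.
Long-format input supports both pooling modes for "biological replicates in
triplicate" designs: every measurement as a replicate, or technical means
per biological replicate.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; hg38-style anchors on the
  bundled fixtures are placeholders (the real probe/primer sequences are
  not public), and the fixture amplicons are synthetic: generated from a
  fixed seed with CpGs placed only at the designed sites. The CRLF2-like
  design keeps the published geometry — two proximal CpGs 23 bp apart, a
  distal CpG ~150 bp away, three drop-off probes (FAM/TAMRA/Cy5) plus the
  HEX reference; the BCL2-like panel has FAM/Cy5 drop-off probes.
* Dye "HEX" is canonical for the reference channel; "SUN" is accepted as an
  alias in panels and CSV headers.
* Units standardize on copies/μL (figure captions elsewhere mix in
  copies/mL; the Methods-style unit is used throughout).
* All randomness flows from explicit seeds (numpy Generator); pipeline
  reports embed the seeds used, and identical configs reproduce
  byte-identical JSON.
* Study-scale experiment drivers (`abcquant.experiments`) use 24 replicate
  chips for editing-recovery runs and 100 pooled chips per condition for
  the baseline comparison; at 10 ng load the baseline condition holds only
  ~0.3 mutant templates per chip, which is why partitions are pooled before
  Poisson correction there. The pooled baseline fraction estimate retains
  ~19% relative sampling SD at these sizes, the dominant uncertainty in the
  edited-over-baseline fold.

## Known limitations

* No multi-chip fluorescence normalization; chips gate independently.
* No joint multi-probe haplotype model — drop-off probes are quantified
  independently, matching how multi-site panels are read in practice.
* The enrichment null and the profiler assume amplicon-local alignments;
  no genome-wide realignment or translocation analysis.
* No EC50/functional dose–response fit; the trend test claims monotonicity
  only.
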