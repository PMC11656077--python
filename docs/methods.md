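# Methods

This note records the models, conventions and numerical choices behind
`epiretscore`, and what the synthetic cohorts do and do not establish
about real data.

## Data model and conventions

A methylation matrix holds per-CpG beta values (methylated read
fraction, in [0, 1]) for a set of samples, indexed by (chromosome,
1-based position), with optional per-cell read coverage.  BED intervals
are 0-based half-open; a CpG at 1-based position `p` lies in `[s, e)`
iff `s ≤ p − 1 < e`.  Missing cells (token `"."`, or coverage 0) are
excluded from every mean and test, never imputed: RRBS coverage is
sparse by design and imputation would manufacture signal.  Strand is
ignored — inputs are assumed strand-collapsed methylation-caller
output.

## DMR calling

Candidate segmentation is deliberately simple and fully documented
rather than a re-implementation of any published segmentation engine.
Per comparison, a CpG is retained when both groups have at least
`min_samples_per_group` (default 2) samples passing `min_coverage`.
Retained CpGs are split into runs broken at gaps > `max_gap` (300 bp);
within a run, maximal stretches of CpGs whose per-CpG group-mean
difference shares one sign become candidates when they span at least
`min_cpgs` (10) CpGs and reach mean |Δβ| ≥ `min_abs_delta` (0.1).  A
stretch whose overall mean falls below the threshold is discarded
whole; no sub-window search is attempted, trading a little power at
region edges for determinism and auditability.  Setting
`min_abs_delta = 0` disables the sign/effect filter entirely, making
candidate selection depend only on CpG positions — the configuration
under which the significance gate can be calibration-tested, since
sign-filtered candidates are preconditioned on the observed group
difference and no uniform-p claim can hold for them.

Significance is a two-sided Mann–Whitney U test comparing the vector of
per-CpG group-A means against the group-B means over the candidate's
CpGs, emitted at p < `alpha` (0.05), with direction labelled by the
sign of the mean difference (hyper = B above A).  No multiple-testing
correction is applied by default, matching the raw-p gate the score was
designed around; Benjamini–Hochberg adjustment is available behind
`fdr=True`.  Per-CpG group means are unweighted over passing samples —
the simplest defensible estimator; coverage weighting was considered
and rejected as a default because it couples the test statistic to
library depth.

### Exact vs approximate branch

For combined n ≤ 12 the p-value is computed by exhaustive enumeration
of all C(n1+n2, n1) group assignments on midranks (ties kept as-is),
with the two-sided p defined as P(|U − n1·n2/2| ≥ observed); the U
null distribution is symmetric, so this coincides with the doubled
one-tail for tie-free data.  Above n = 12 the tie- and
continuity-corrected normal approximation is used.  Sweeping every
achievable U at 6 vs 6 (tie-free), the approximation tracks the exact
enumeration to within |Δp| ≤ 0.0155; without the continuity correction
the worst-case gap is 0.069, which is why the correction is kept.  At
candidate sizes typical for this package (tens of CpGs) the
approximation's null exceedance rate at the 0.05 gate is 0.047–0.05.

## Signature and score

The signature is the set of degeneration DMRs (untreated P21 vs P60)
overlapping at least one treatment DMR by ≥ `min_overlap_bp` (1 bp),
keeping the degeneration DMR's coordinates and direction.  Anchors are
the untreated P21 and P60 group means over region CpGs — the
natural-progression arm defines the scale, not sham-treated animals,
because the score is meant to measure position along the degeneration
trajectory.  Regions are dropped (and logged) when their computed
anchors contradict the direction label or the anchor span falls below
`min_anchor_span` (0.01, guarding the normalization against
near-degenerate denominators).

The primary score normalizes each region separately and averages:
`r_i = (b_i − a21_i)/(a60_i − a21_i)`, score = mean `r_i` over
computable regions.  The sentence "min/max from P21/P60, reversed for
hypomethylated regions" also admits an aggregate reading — average the
betas within each direction stratum first, then normalize the
aggregates — and that variant is provided (`normalization="stratum"`,
strata combined weighted by region count).  Both are exactly 0/1 at the
anchor profiles; neither is claimed to be "the" published computation.
Per-region-first is the default because it is invariant to
between-region baseline differences.  Scores are not clipped to [0, 1]:
sub-zero scores (healthier than P21) and scores above 1 are
diagnostically meaningful, and clipping would destroy monotonicity
checks.  Signatures are sex-specific; cross-sex scoring is refused
unless forced.

cfDNA scoring restricts the signature to regions overlapping a
caller-supplied detectable set, then per sample to regions with ≥ 1
covered CpG, reporting the per-sample subset size.

## Synthetic cohorts

The generator encodes the study design: untreated animals at P21, P35,
P42, P49, P60 and sham/low/high arms at P60 only, both sexes, default
4 animals per cell.  Planted regions (default 30, 12 CpGs at 50-bp
spacing, isolated by 2-kb flanks) are hyper- or hypomethylated
(60/40, matching the observed excess of hypermethylated DMRs) and
assigned to both sexes or one sex via `sex_overlap`.  Group-mean beta
follows

    baseline + direction · drift_max · (t − 21)/(t_max − 21) · (1 − effect[group])

with `drift_max = 0.3` and treatment effects {sham 0, low 0.2,
high 0.6} by default — effect magnitudes are artifact choices (the
source observations are only graphical), chosen so the low arm is a
modest and the high arm a strong reversal.  Drift is linear in
postnatal day; real degeneration is progressive but not established to
be linear — linearity is chosen so the untreated score has the closed
form (t − 21)/39, giving exact oracles for every downstream stage.
Background CpGs share a single baseline of 0.5 across all groups;
region baselines are drawn uniformly from direction-feasible ranges
(hyper 0.2–0.6, hypo 0.4–0.8) so baseline + drift stays inside [0, 1],
enforced at config validation.

Observations are beta-distributed around the expected value with
precision κ (shape `mκ`, `(1−m)κ`); κ = 50 gives per-CpG s.d. ≈ 0.07
at m = 0.5, a realistic RRBS-like dispersion, and `noise_kappa=None`
yields exact expected values.  Coverage is Poisson with mean 30;
zero-coverage cells are missing.  cfDNA pools mix the pooled tissue
mean with a background beta (`f·tissue + (1−f)·background`), add
optional beta noise, and drop a fraction of the signal: whole regions
when a region set is supplied — plasma libraries lose loci coherently,
which is what limits the tissue-detectable subset — or independent
sites otherwise.

What passing tests on these cohorts show: the pipeline's arithmetic,
calibration and invariances are correct under the assumed structure.
What they do not show: robustness to cell-composition drift within the
degenerating retina, non-linear or region-heterogeneous trajectories,
batch and conversion-efficiency artifacts, read-level sampling, or
genome-scale CpG spatial structure — none of which the generator
emulates.

## Clustering and annotation

Sample clustering uses Ward linkage on pairwise-complete Manhattan
distances: for each pair, the mean absolute difference over jointly
observed sites rescaled to the full site count (so sparse samples are
comparable), fed to the standard Lance–Williams update.  A pair with no
jointly observed site raises, naming the pair.  CpG context uses the
conventional 2-kb shores and 2-kb shelves with precedence
island > shore > shelf > open sea; a flag collapses flanks into open
sea for two-bucket summaries.  Interval overlap is counted region-wise
(distinct query regions with ≥ 1 partner), matching "% of DMRs also
found in ..." reporting; the overlap summary keeps both directional
counts, since they differ for region sets, plus a symmetrized Jaccard.
Set-overlap percentages are kept at full precision and rounded to one
decimal only for reporting.

## Problem sizes and determinism

Default test-suite cohorts use 1–10 chromosomes with a few hundred to a
thousand CpGs each and 4 samples per arm — large enough for the
calibration checks (≥ 2000 null candidates, 80 planted regions) while
keeping the whole suite and the acceptance script in the seconds-to-
minutes range on a single core.  All randomness flows from explicit
integer seeds via `numpy.random.default_rng`; identical configs produce
byte-identical outputs, which the pipeline test verifies end to end.

## Known limitations

* Candidate segmentation is greedy and sign-based; diffuse or
  direction-mixed differential regions are fragmented or missed.
* The MWU is applied to per-CpG group means, so within-group variance
  enters only through those means; very unbalanced coverage between
  samples is not modelled in the test statistic.
* Treatment-effect magnitudes, noise precision and cfDNA parameters are
  simulation choices, not estimates from data.
* Gene/pathway assignment is input, not computation: pathway lists are
  compared by exact name intersection only.
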