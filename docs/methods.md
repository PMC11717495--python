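# Methods

## Mixture model and purity adjustment

A bulk sample is modelled as a two-component mixture: a fraction `p` (tumour
purity) of tumour cells carrying `cn_tumour` copies of a locus, and `1−p`
normal diploid cells. The observed absolute copy number is

    cn_obs = p · cn_tumour + 2(1 − p),

and segmented input carries it as a log2 ratio relative to diploid,
`cn_obs = 2·2^log2`. Adjustment inverts the mixture,

    cn_tumour = max(0, (cn_obs − 2(1 − p)) / p),

clipped at zero because copy numbers cannot be negative. The model is linear
in copy number space; it assumes a single tumour clone, diploid normal
contamination, and no allele-specific information. Equivalence with the
log-space rescaling some segmentation tools apply internally is not claimed:
the linear inversion is the documented model here.

Substituting an estimate `p̂` for the true `p` gives the exact identity

    cn_adj = 2 + (p / p̂) · (cn_tumour − 2),

which drives everything downstream: `p̂ > p` shrinks deviations from diploid
(CNAs are lost once the deviation falls inside the rounding band — for a
single-copy event exactly when `p̂ > 2p`), while `p̂ < p` amplifies them and
amplifies measurement noise on neutral arms by `1/p̂`, creating spurious
calls at low estimated purity. Undercalling by purity over-estimators and
overcalling by under-estimators is therefore a structural property of the
correction, not an empirical accident.

**Purity floor.** Purity is clamped to ≥ 5% before division (warning
emitted). Below that the inversion is numerically explosive and a sample
would normally fail molecular QC anyway. The floor is configurable
(`--purity-floor`).

**Classification.** Tumour copy number is rounded half-away-from-zero and
thresholded: ≥ 3 gain, 2 neutral, ≤ 1 loss. The rule is stated on integers;
rounding first makes it total on the real line and is equivalent to
cut-points at 1.5 and 2.5. This was a genuinely open choice (thresholds
could instead apply to the real-valued estimate); the integer reading was
chosen because the rule enumerates integer states.

## Coordinate frame and arm aggregation

All intervals are 0-based half-open internally (BED convention); SEG-dialect
files are 1-based inclusive on disk and converted at the boundary. The
default karyotype is the 39 autosomal arms — 22 autosomes with the p-arms of
the acrocentric chromosomes 13, 14, 15, 21, 22 omitted — with hg19 cytoband
p/q boundaries (the frame tiles each chromosome at the centromere junction;
total 2,798,633,286 bp). The assembly is a fixture choice, not an inference:
any BED4 arm table can be substituted (`--arm-table`). Sex chromosomes are
excluded throughout, which keeps the samples × 39 arithmetic of the
published cross-tabulations intact.

Arm calls are the length-weighted plurality of overlapping segment calls,
ties broken toward neutral (an aberration without a length plurality is not
asserted). Arms without segment coverage are called neutral and *counted*,
so every sample contributes exactly 39 calls. The aggregation rule was open;
plurality-with-neutral-ties is the conservative choice and is cross-checked
in tests against a basepair-resolution majority vote.

## WGII

WGII is the length fraction of the genome with a non-neutral call. Default
resolution is the arm (numerator: summed lengths of aberrant arms;
denominator: the arm frame's total autosomal length), consistent with the
arm being the unit of the concordance analysis; a segment-level variant
normalises by segment-covered length instead. Whether sex chromosomes enter
the denominator is a frame choice; the default frame is autosomal.

## Concordance statistics

Arm calls of a reference and a comparator run are cross-tabulated 3×3
(loss/neutral/gain). Off-diagonal cells are differing calls; *undercalling*
is the off-diagonal part of the neutral column (reference CNA missed by the
comparator) and *overcalling* is everything else, including loss↔gain sign
switches — the comparator asserts an alteration the reference did not make.
Assigning sign switches to overcalling reproduces the published counts
exactly (e.g. a single loss→gain cell accounting for the one overcall in an
11,232-call comparison). Percentages are displayed to one decimal, halves
rounded away from zero; internal values keep full precision.

The published FOCUS (288 samples) and GRAMPIAN (74 samples) cross-tabulation
matrices ship as package data and serve as deterministic worked examples.
Three of their printed numerators (51/192, 103/973, 906/973) are mutually
inconsistent with their own printed percentages and matrices; the
implementation follows the matrices and percentages (which imply 45, 924 and
49 respectively).

## Statistical comparisons

Pearson correlations use the product-moment estimate with a 95% Fisher-z
confidence interval (SE `1/√(n−3)`, via scipy). Paired comparisons use the
classical two-sided paired t-test. Bland–Altman agreement reports
bias = mean(a−b) and limits of agreement bias ± 1.96·SD(a−b). The difference
convention is first argument minus second throughout. No multiple-testing
correction is applied (comparisons are reported pairwise and descriptively).

## Synthetic cohort generator

The generator produces the joint structure the analysis assumes, with every
component on its own named RNG stream derived from one seed (streams:
profile, segments, slides, bias, points), so runs are bit-reproducible and
adding a component cannot perturb the others.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| n_samples | 300 | of the order of the larger published cohort arm-call analysis (288) |
| cna_rate | 0.30 | per-arm aberration probability giving CRC-like genome instability (mean WGII ≈ 0.3) |
| aberrant CN weights | {0: 0.05, 1: 0.45, 3: 0.40, 4: 0.10} | single-copy events predominate; deep deletions and double gains are minority states |
| truth purity | N(58.9, 16.3) truncated to [5, 95] | matches the cell-count method's published marginal, treated as closest to truth; truncation keeps samples within plausible QC bounds |
| replicate_sd | 5 points | gives serial-section purity r ≈ 0.91, the published reproducibility magnitude |
| noise_sd | 0.15 | per-bin log2 noise typical of sparse targeted panels |
| bin_spacing | 3 Mb | the probe backbone density of the emulated panel design |

Observed profiles are simulated per bin: each 3 Mb bin of an arm carries
`log2((p·cn + 2(1−p))/2)` plus independent N(0, noise_sd), and bins average
into one segment per arm. The effective arm-level noise is therefore
`noise_sd/√n_bins` (≈ 0.02–0.05 depending on arm size), which is what makes
true-purity call recovery ≥ 99% attainable and mirrors how segment means
behave over many probes in real data.

Biased purity observers are affine-plus-noise models:
`value = m + a·(true − μ)·(s/σ) + ε`, `ε ~ N(0, s·√(1−a²))`, clamped to
[1, 100] and optionally rounded to a reporting granularity. Over a Gaussian
truth this realises marginal mean `m`, SD `s` and correlation `a` with the
truth exactly. Calibration targets are the published cohort marginals —
ESTIMATE 79.2 ± 10.5, InfiniumPurify 62.7 ± 11.8, conventional pathology
35.9 ± 13.1 (granularity 5, floor 5% after rounding) — with attenuation 0.6,
which lands the cross-method correlations in the published 0.3–0.6 range.
The true per-sample purity is unobservable in real cohorts, so any joint
distribution matching those marginals is a modelling choice among many; this
is the simplest one.

Paired slides observe the truth plus independent N(0, replicate_sd) per
slide, clamped to [0, 100]. The closed-form attenuation of the paired
correlation is `σ²/(σ² + replicate_sd²)` ≈ 0.914 at σ = 16.3; checks against
this closed form draw *untruncated* truths, because truncation shrinks the
realised truth SD (~15.5) and with it the expected correlation. Cell point
patterns are homogeneous Poisson in a rectangular ROI (defaults 19,000
cells/mm² for resection-like and 26,000 for biopsy-like tissue), labelled
tumour independently with probability purity/100.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial tumour heterogeneity and subclonality
(one clone, one purity per sample), segmentation error (segments coincide
with arms by construction), GC/wave artefacts, allele-specific signal,
ploidy shifts (near-tetraploid genomes can mimic near-diploid ones after
mixing), non-Gaussian observer errors, and any real dependence between a
method's bias and tumour biology. The published real-data correlations and
cohort means are simulator *calibration constants*, not quantities the
package claims to reproduce.

## Numerical choices and degenerate inputs

* Purity 0 or an empty slide (TC+BC = 0) raise — undefined purity is flagged,
  never silently 0.
* Boundary points count as inside an ROI (inclusive containment; matches
  raster-mask semantics). Overlapping ROI polygons are unioned so points are
  counted once. Detection confidence is not thresholded by default
  (`--min-confidence 0`), as detector post-processing normally already has.
* Pearson on fewer than 4 pairs or zero-variance input raises; paired lists
  with perfect |r| = 1 short-circuit to a degenerate CI.
* Display rounding (1 decimal for percentages, 3 for correlations) happens
  only at serialisation; all internal arithmetic is full precision.

## Problem sizes

Simulated analyses run at 300 samples × 39 arms (11,700 arm calls) with the
serial-section check at n = 334, chosen to match the scale of the emulated
study designs; the whole chain completes in seconds on one CPU, and the
scale is comfortably past the point where the binomial error of the
reported rates is small relative to the effects being demonstrated.
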