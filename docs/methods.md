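# Methods

## The quantification model

`itraqdiff` analyses 4-plex isobaric-label (iTRAQ) reporter-ion data in
which each of the channels 114–117 carries one pooled sample. The atomic
measurement is a peptide's reporter-ion peak area per channel; relative
abundance between two conditions is the ratio of two channel areas for the
same peptide, analysed throughout on the natural-log scale.

The central statistical object is a **Gaussian null model of technical
ratio variation**. For one contrast (numerator channel / denominator
channel) in one experiment:

1. every retained peptide with both areas strictly positive contributes
   `ln(area_num / area_den)`; rows with a non-positive area are excluded
   and logged, never silently converted to NaN;
2. the ln-ratios are histogrammed on `[−1, +1]` in 200 equal bins
   (half-open bins, final bin closed; values outside the range are counted
   separately and do not enter the fit);
3. the counts are smoothed with a Savitzky–Golay filter (window 11,
   polynomial order 3 by default);
4. a Gaussian `A·exp(−(x−μ)²/(2σ²))` is least-squares fitted to the
   smoothed counts; the fitted σ is the estimate of random ln-ratio
   variation.

A peptide is **discriminatory** when `|ln_ratio − center| ≥ k·σ` with
k = 2.5 by default; for a Gaussian null this corresponds to two-sided
confidence 2Φ(2.5)−1 = 98.76%, conventionally quoted as 98.8%. The
boundary is inclusive. Each peptide also receives a two-sided tail
p-value `2(1 − Φ(|ln_ratio − center|/σ))`; the k = 2.5 call and the
p-value threshold `2(1 − Φ(2.5))` are exactly equivalent. Observations
outside the histogram range do not inform the fit but are still scored —
a 12σ outlier must remain callable.

Protein rollup: a protein's reported ratio per contrast is the median of
its discriminatory peptides' ratios, computed on the ln scale and
exponentiated (for an even count this is the geometric mean of the two
central ratios; for odd counts it is simply the median ratio). Proteins
with no discriminatory peptide get no ratio and call `none`; a
single-peptide result is flagged rather than dropped. The direction call
is the majority direction among discriminatory peptides; an exact tie
yields `none` with a conflict note.

Candidate selection across the technical duplicate requires
(1) significance with the same direction in both experiments and
(2) at least `min_discriminatory_peptides` (default 2) peptides with
p < `max_peptide_p` (default 0.02, strict) in each experiment. Any
biological-plausibility judgement is left to the analyst as a free-text
annotation; it is never applied automatically.

## Identification filtering

Peptides are accepted at a confidence threshold (default 95%, the
equivalent of a ProteinPilot ProtScore of 1.3 via
`score = −log10(1 − confidence/100)`); proteins then need at least 2
distinct retained peptide sequences (uppercased; modifications are not
modelled). The confidence rule is applied before the uniqueness count, so
a protein whose second peptide fails the confidence cut loses both rows.
Upstream identification FDR control is treated as a property of the input
table and is not recomputed (doing so would require the decoy search).

## Validation-arm statistics

Per-subject analyte concentrations (e.g. ELISA of epithelial lining
fluid) are summarised as median (range) per group × timepoint × analyte.
Within-group before/after changes use the Wilcoxon signed-rank test;
between-group comparisons (baseline levels, and per-subject after−before
changes) use the Mann–Whitney U test.

The **exact** methods literally enumerate the permutation distribution:
all 2^n sign assignments of the (mid-)ranked absolute differences
(signed-rank, n ≤ 20) or all C(n1+n2, n1) group assignments of the pooled
mid-ranks (rank-sum, n1+n2 ≤ 14). Ties are therefore handled exactly,
conditional on the observed tie pattern, with a warning noting that
caveat; above the enumeration limits the implementation falls back to the
normal approximation with a warning. Two-sided exact p is the standard
atom-inclusive `min(1, 2·min(P(T ≤ t), P(T ≥ t)))`.

The **normal approximation** uses the tie-corrected variance and no
continuity correction — the convention under which small all-same-sign
configurations give the familiar two-sided values 0.043 (n = 5) and
0.028 (n = 6). Note that the atom-inclusive exact p exceeds the
uncorrected normal p near p ≈ 1 by up to ~0.03 at n = 15; in the
decision-relevant region (exact p ≤ 0.1) the two agree to < 0.01 there,
and the discrepancy shrinks as n grows. Zero differences are dropped and
counted. No multiple-testing adjustment is applied by default, matching
the single-comparison convention of small validation panels.

## Synthetic data generator

The generator emulates a pooled 4-plex experiment run in duplicate, with
ground truth:

- **Peptides per protein**: shifted Poisson, `1 + Poisson(mean − 1)` —
  one parameter, long right tail, minimum 1.
- **Areas**: each peptide draws a log-normal baseline abundance
  (`base_area_ln_mean = 7`, `base_area_ln_sd = 1`) shared by the four
  channels; each channel multiplies it by `exp(N(0, null_sigma/√2))`, so
  every pairwise channel ln-ratio has SD exactly `null_sigma` — the
  Gaussian structure the null model assumes.
- **Effects**: a fraction `de_fraction` (default 0.05) of proteins is
  truly changed, with ln fold-change `±effect_ln_fc` (default 1.0, sign
  Rademacher(½) — both directions occur). The effect multiplies the
  numerator channel of the designated contrast (default 116/117), which
  is the physically faithful consequence of one changed sample.
- **Noise SD**: `null_sigma = 0.15` by default. The magnitude of
  technical ln-ratio variation in real pooled runs is instrument- and
  run-dependent; 0.15 is a plausible mid-range value and is fully
  configurable.
- **Seeding**: one master seed; truth (protein effects, peptide counts,
  sequences) derives from a seed-only stream, so duplicate experiments
  quantify the same peptides with the same true effects; technical noise
  derives from a per-experiment stream (seed + CRC32 of the experiment
  id). Identical configurations are bit-identical after serialisation.
- **Dropout** (zero areas) is off by default and only used to exercise
  degenerate-input handling.

What the generator does *not* emulate: isotope-impurity cross-talk
between channels, intensity-dependent variance (variance is homoscedastic
in ln-space here, whereas real low-intensity reporter ions are noisier),
shared/razor peptides, missed cleavages, chromatographic fraction
effects, and any protein-level correlation structure. Tests passing on
this generator therefore demonstrate the correctness and calibration of
the statistical procedure under its own assumptions, not robustness to
those real-data violations.

## Numerical choices

- **Savitzky–Golay edges**: interior points are the standard least-squares
  convolution; at each of the `window//2` edge points the polynomial is
  re-fitted on the window truncated to the signal (degree capped at
  points − 1) and evaluated in place. Polynomials of degree ≤ order are
  reproduced exactly everywhere provided order ≤ window//2.
- **Gaussian fit**: initialised from the weighted mean/SD of the
  non-negative smoothed counts (σ floored at one bin width); on
  non-convergence a zero-centered two-parameter fit is retried; σ is
  reported as its absolute value; residual sum of squares is recorded.
  Fewer than 5 positive bins, or a flat histogram, is a fit error.
- **Center policy**: the significance center defaults to the fitted μ
  (a free-center fit also absorbs global channel bias); a zero-center
  policy is available for sensitivity analysis.
- **Boundary ties**: exactly k·σ is significant ("at least"); the p < 0.02
  selection threshold is strict.
- **Histogram**: numpy half-open bins with the final bin closed; a value
  exactly at +1 is counted in the last bin.

## Problem sizes

Default simulations use 300 proteins × ~4 peptides (≈1,200 peptides per
experiment); calibration checks use up to 13,000 proteins (≈52,000
peptides) so that the ±2.5σ coverage of the fitted null can be measured
to a fraction of a percentage point. At these sizes the full test suite
runs in well under a minute of numerical work.

## Known limitations

- One null is fitted per contrast per experiment; there is no pooling or
  shrinkage across contrasts, and no variance-stabilising transform.
- No isotope-impurity correction or channel normalisation beyond the
  fitted center.
- Exact rank tests are limited to enumerable sizes (n ≤ 20 paired,
  n1+n2 ≤ 14 two-group), which covers the intended small validation
  panels; larger samples use the normal approximation.
- The candidate-selection false-discovery behaviour is controlled only
  implicitly (duplicate concordance + per-peptide thresholds); no formal
  FDR guarantee is computed.
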