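# Methods

## Model and assumptions

The detector treats a census of \(n\) positive sizes as a realisation of
either (H0) a single continuous unimodal distribution of \(\log_{10}\)
size — the "neutral null", encoding one optimal scale and no hierarchical
structure — or (H1) a multimodal distribution whose antimodes show up as
oversized gaps between adjacent rank-ordered values. It is designed for
*census* data: the inference is about the small, nearly fully observed
population itself, not about a superpopulation, which is why a resampling
comparison against an explicit null stands in for classical sampling
theory. Species with indeterminate growth (e.g. fishes), where a single
mean mass is a poor size proxy, are outside the intended domain.

The null is the Gaussian KDE of the log10 data with the smallest
bandwidth that is unimodal. Two classical facts make this well defined:
the Gaussian-KDE mode count is non-increasing in bandwidth, and every
Gaussian KDE is unimodal for large enough bandwidth. The unimodal-KDE
null is deliberately data-adaptive: it has no fixed internal constants,
which is the point of this method relative to its predecessor, the Gap
Rarity Index.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `bandwidth_increment` | 0.001 | log10 grams | scan step; h = j·increment, j ≥ 1 (h = 0 excluded) |
| `h_max_fraction_of_range` | 0.5 | — | scan cap; exceeded automatically (and recorded) if no unimodal h exists below it |
| `grid_points` | 2048 | — | density grid spanning centers ± 4h |
| `resamples` (B) | 5000 | — | null resamples; the percentile resolution is 1/(2B) |
| `threshold` | 0.90 | percentile | flag rule is strict: percentile > threshold |
| `sampling_mode` | `centers` | — | each kernel center used once per replicate, perturbed by N(0, h*²); `iid` is the standard KDE draw |
| `support_lower_bound` | none | log10 grams | optional truncation of the density support; off because masses below 1 g make negative log10 values legitimate |
| `seed` | 0 | — | master seed; replicate b uses a counter-derived stream, so growing B preserves earlier replicates |

Classic indices: `gamma` (1.3 birds, 1.1 mammals by convention) with both
readings of the transform — exponent on the index or pre-transform of the
masses — selectable, since the original usage is ambiguous; the indices
are descriptive only and carry no significance criterion.

## Numerical choices

- **Mode counting** is discrete: positive-to-negative sign changes of the
  first difference of the gridded density, with plateaus of equal values
  collapsed to one candidate and a negative discrete second difference
  confirming each maximum. A 2048-point grid over centers ± 4h keeps
  >99.99% of every kernel's mass on-grid, so edge modes are not clipped
  and the trapezoid integral is within 1% of 1.
- **Bandwidth search** defaults to bisection over the increments,
  justified by mode-count monotonicity; a literal linear scan is
  available (`method="linear"`) and agrees with bisection in tests. The
  boundary is verified explicitly: unimodal at h*, at least two modes at
  h* − increment (when that is positive).
- **"Without replacement" resampling** of a continuous density is
  realised at the kernel-component level: with resample size equal to the
  census size, every center is used exactly once per replicate and
  perturbed by N(0, h*²), an exact KDE draw with stratified components.
  The i.i.d. alternative is one flag away; oversized draws are only legal
  in `iid` mode.
- **Percentiles** use mid-rank tie handling,
  (#below + 0.5·#tied)/B — symmetric under ties, which arise at
  zero-width gaps (tied masses). A tied-mass rank can never be flagged
  (its percentile is ≤ 0.5 under any continuous null).
- **Multiple testing**: none, matching the method's alpha-level framing;
  reports carry the advisory expected-false-positive count
  (n−1)(1−threshold) instead.
- **Degenerate inputs**: fewer than 3 records, non-positive or
  non-finite masses, and zero-range censuses are rejected with named
  diagnostics.

## Synthetic data generator

`default_mixture()` is a k=10 equal-weight Gaussian mixture on the log10
axis with means evenly spaced over 0.5–5.0 (≈3 g shrew to ≈100 kg moose)
and standard deviations rising linearly 0.05→0.12, giving a
separation-to-sd ratio ≥ 4 so the analytic density has exactly 10 modes.
The structure (even spacing, increasing variances, equal weights, 100
point censuses) is the study condition; the specific range and sd values
are this package's choice, made once, and config-exposed. Census success
is modelled as uniform random deletion down to round(success·n) members —
every species equally likely to be missed, which ignores the realistic
tendency for rare or small species to be missed more often. The mixture
draws i.i.d. species masses, with no phylogenetic correlation and no
measurement error on the masses. Passing tests therefore demonstrate
detection of clean, well-separated multimodality under unbiased thinning,
not robustness to biased censuses or noisy mass estimates.

The sensitivity harness runs the full factorial (sample size × census
success × replicate) with per-run seeds derived from the master seed, so
replicate allocation is explicit (the full configuration ships as
`data/sensitivity_full.yaml`: 1,000 replicates per cell, B = 5,000; tests
and examples use desk-scale reductions of 10–50 replicates at B = 200–1,000).
Detected discontinuity locations are taken as the log10 midpoint of each
flagged rank gap — a gap is an interval, and its midpoint is the natural
scalar to cluster.

## Clustering of pooled detections

Pooled detection locations are clustered with 1-D Gaussian mixtures
(equal-variance and free-variance families, 1…k_max components) selected
by BIC, each location assigned to its maximum-responsibility component —
the mclust model family restricted to one dimension, implemented with
scikit-learn. Degenerate input (all locations identical) returns one
cluster with zero spread; the component count never exceeds the number of
distinct locations.

For the sample-size/census-success *trend*, location spread is measured
against the known truth: each detection is assigned to the true gap
midpoint within half a mode spacing and the per-gap standard deviations
are averaged (`location_spread_by_true_gap`). With simulated truth
available this is a more stable precision measure than the spread of
free-k BIC clusters, whose count varies between conditions; the BIC
clustering is still computed and reported for the pooled population,
where no truth anchoring is possible in real use.

## Design choices that were genuinely open

- The half-range scan cap is a convenience, not a hard bound: if no
  unimodal bandwidth exists below it the search continues (doubling) and
  records `cap_exceeded`, rather than failing.
- Support truncation on the log axis is off by default (see the
  parameter table); the truncating reading is available as
  `support_lower_bound=0.0`.
- Detection calls are strict inequalities (percentile > threshold), so a
  threshold above 1 − 1/(2B) can never flag anything.
- The replicate-allocation question for the sensitivity experiment
  (per-cell vs total) is resolved by making it explicit configuration.

## Known limitations

- The test is calibrated slightly conservatively: refitting the null to
  each census smooths the data, so the realised flag rate at threshold
  0.9 sits near 5–10% rather than exactly 10% (measured by the
  calibration test and the acceptance script).
- Power falls quickly with census size and success; below ~20 members the
  per-rank null distributions are wide and few true gaps are detectable.
  Conversely the method will flag ~(n−1)(1−threshold) spurious gaps per
  census, so individual flags in small censuses warrant type-2-aware
  interpretation.
- The weak ordering of location spread across sensitivity corners is a
  trend in expectation; at 50 replicates per cell individual seeds can
  reverse it, which is visible in the acceptance script's reported
  corner values.
- Only the standard normal kernel and fixed (non-adaptive) bandwidths are
  implemented; no boundary-corrected KDE, no confidence intervals on gap
  locations.
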