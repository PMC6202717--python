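# Full-scale sensitivity experiment configuration.
#
# 1,000 replicate censuses per (sample size, census success) cell, each
# simulated from the default 10-mode log-scale Gaussian mixture, thinned
# to the cell's census success, and tested at the 0.90 acceptance
# percentile with 5,000 null resamples.  The replicate allocation
# (per-cell, not total) is explicit here because it materially changes
# the experiment's cost and power.
mixture:
  k: 10
  log_range: [0.5, 5.0]
  sd_range: [0.05, 0.12]
sample_sizes: [20, 30, 40, 50, 60, 70, 80, 90, 100]
successes: [0.75, 0.8, 0.85, 0.9, 0.95, 1.0]
# Figure-style preset: successes [0.8, 0.85, 0.9, 0.95, 1.0] with
# sample_sizes [40, 60, 80, 100] is the other grid in circulation.
replicates: 1000
threshold: 0.9
resamples: 5000
bandwidth_increment: 0.001
sampling_mode: centers
seed: 0
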