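"""Simulate a multimodal census and recover its known gaps.

A 10-mode Gaussian mixture on the log10 mass axis (means even from 0.5
to 5.0, i.e. ~3 g to ~100 kg) stands in for a community structured into
ten body-mass aggregations.  A 100-species census is drawn, the detector
is run, and detections are matched to the 9 true between-mode midpoints.
"""

from ddetect import default_mixture, detect_discontinuities, gap_recovery, simulate_census

spec = default_mixture(k=10)
census = simulate_census(spec, n=100, seed=7)
report = detect_discontinuities(census, threshold=0.9, B=1000, seed=7)

flagged = report.flagged
locations = 0.5 * (flagged["lower_logmass"].to_numpy()
                   + flagged["upper_logmass"].to_numpy())
recovery = gap_recovery(locations, spec)
print(f"true between-mode gap midpoints: {spec.true_gap_midpoints.round(2)}")
print(f"detected gap midpoints:          {locations.round(2)}")
print(f"recovery: {recovery:.0%} of the {spec.k - 1} true gaps found "
      "within half a mode spacing")
# Recovery near 100% at n=100 / full census success is the expected
# behaviour; smaller or thinner censuses recover fewer gaps.
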