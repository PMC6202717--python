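# ddetect — discontinuity detection in rank-ordered census data

Ecological communities are often structured into *body-mass aggregations*:
clusters of similarly sized species separated by gaps ("discontinuities")
that are interpreted as boundaries between the scales at which resources
are available. `ddetect` provides an objective, resampling-based test for
locating such discontinuities in census data — a complete enumeration of a
community's members with a strictly positive size proxy per member (body
mass in grams, firm size, city size, ...). No abundance data are needed.
It is aimed at ecologists and complex-systems researchers who want
probability-scaled gap calls rather than subjective difference-index
thresholds or variance-partitioning clusters.

## The method

Given masses \(M_1,\dots,M_n\), let \(m_i = \log_{10} M_i\) sorted
ascending.

1. **Neutral null.** Fit Gaussian kernel density estimates
   \[\hat f_h(x) = \frac{1}{nh}\sum_{i=1}^n K\!\Big(\frac{x-m_i}{h}\Big),
   \qquad K(x)=\tfrac{1}{\sqrt{2\pi}}e^{-x^2/2},\]
   for bandwidths \(h = 0.001, 0.002, \dots\) up to half the data range.
   The null is the estimate with the **smallest unimodal bandwidth**
   \(h^\*\) (the critical bandwidth of Silverman's multimodality test):
   the hypothesis of a single "optimal" body size.
2. **Rank-gap bootstrap.** Resample the null \(B\) times (default 5,000)
   at sample size \(n\): each kernel center is used once per replicate and
   perturbed by \(N(0, h^{*2})\). Each resample is rank-ordered and
   differenced, giving a null distribution of gap sizes *per rank*.
3. **Percentile test.** Each observed gap
   \(g_r = m_{(r+1)} - m_{(r)}\) is scored by its mid-rank percentile in
   the same-rank null distribution; gaps with percentile \(> 0.90\)
   (configurable, akin to choosing an alpha level) are flagged as
   discontinuities.

The package also ships the classic descriptive baselines
(Holling's \(HI = ((M_{n+1}-M_{n-1})/M_n)^\gamma\) and Siemann–Brown's
\(SB = \log_{10}(M_{n+1}/M_n)\)), a synthetic-census generator
(Gaussian mixtures on the log scale with known gap locations), and a
sensitivity harness that measures detection performance as a function of
sample size and census success, with BIC-selected 1-D Gaussian-mixture
clustering of the pooled detections.

## Worked example

```sh
python examples/01_detect_discontinuities.py
```

prints, for the packaged 30-species toy census (two clusters at ~16 g and
~2.5 kg):

```
census: n = 30, log10 mass range = 2.592
null bandwidth h* = 1.053 (log10 grams)
flagged 1 of 29 gaps (expected under the null: 2.9)
 rank lower_label upper_label  gap_log10  percentile
   15   smallsp11   largesp07   1.653687         1.0
```

The null needed a bandwidth of 1.053 log10 grams to smooth the two
clusters into one mode; exactly one gap — the 1.65-decade jump between
the largest small-bodied species and the smallest large-bodied one — is
larger than every same-rank gap in 2,000 null resamples (percentile 1.0)
and is called a discontinuity. Under a truly unimodal community roughly
2.9 of the 29 gaps would be flagged by chance at the 0.90 threshold; the
expected-false-positive line is printed as a reminder that no multiplicity
correction is applied.

The same analysis from the shell:

```sh
dd detect census.csv --threshold 0.9 --resamples 5000 --seed 1 --out report.tsv
dd indices census.csv --gamma 1.3 --out indices.tsv
dd simulate --modes 10 --n 100 --seed 1 --out sim.csv
dd sensitivity --config src/ddetect/data/sensitivity_full.yaml --out results/
```

The other example scripts cover the classic indices, mixture simulation
with known-gap recovery, and a desk-scale sensitivity experiment.

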