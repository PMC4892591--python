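# dendrosync

Analysis pipeline for **synchronized alpine tree growth**: from raw
tree-ring widths to a quantitative picture of how strongly a network of
high-elevation forest sites grows in unison, which climate variable drives
that coherence, and whether the climate–growth relationship is stable and
linear. The package was built around a 17-chronology conifer network from
the southeast Tibetan Plateau (four species, reliable spans reaching back
to the 16th century, CRU-style monthly climate from 1951), but every stage
works on any Tucson-format ring-width collection plus a monthly climate
table.

Who it is for: dendroclimatologists and climate-ecology researchers who
want the standard chronology → synchrony → response-function workflow as
tested, scriptable Python instead of a chain of GUI tools.

## What it computes

1. **Chronologies** (`dendrosync.chronology`). Each core is detrended with
   a conservative growth curve — negative exponential `a·e^(−b·t)+k`
   (a>0, b>0, k≥0), falling back to a non-positive-slope line, falling back
   to a stiff smoothing spline with a 50% frequency-response cutoff at 67%
   of the site's mean segment length. Ring-width indices are ratios
   `x_t/G_t`; the site chronology is their Tukey biweight robust mean. Site
   reliability is tracked with the mean inter-series correlation r̄, the
   expressed population signal `EPS = N·r̄/(N·r̄+1−r̄)` and the subsample
   signal strength

   `SSS(t) = n(t)·(1+(N−1)·r̄) / (N·(1+(n(t)−1)·r̄))`,

   truncating each chronology where SSS < 0.85.
2. **Network synchrony** (`dendrosync.synchrony`). PCA on the correlation
   matrix of the chronologies over their common period; the PC1 variance
   share in 50-year windows advanced by 10 years (final window anchored to
   the period end) tracks how shared growth variability evolves; extreme
   wide/narrow rings are flagged per chronology at mean ± 1.5 SD and
   counted across the network per year.
3. **Climate response** (`dendrosync.climate`). Pearson correlation
   functions between regional growth (PC1 scores) and monthly climate over
   the 17-month dendroclimatic year (previous May … current September),
   with t-based 95%/99% critical values; seasonal composites; 30-year
   moving correlations plotted at the window center with a Fisher-z band;
   and a seeded Monte Carlo stability test (bivariate AR(1) surrogates
   matched to each series' persistence and the full-period correlation;
   statistic = variance of the moving correlation).
4. **Fuzzy partitioning** (`dendrosync.fcm`). Fuzzy C-means (`FuzzyCMeans`,
   a scikit-learn-style estimator) on the site × year index matrices of
   fixed cold (1965–1980) and warm (1990–2005) winter intervals, with fuzzy
   cardinalities, centroid distance, a fuzzy pseudo-F and the count of
   years with significant between-cluster Welch-t differences.
5. **Nonlinearity diagnostics** (`dendrosync.emd`, `dendrosync.ann`).
   In-house EMD/EEMD for nonlinear climate trends, and a small
   feed-forward backpropagation network (`GrowthANN`, 2 → 4 sigmoid → 1)
   mapping winter temperatures to growth; its response surface is scanned
   for the temperature below which growth stops responding (two-segment
   piecewise-linear breakpoint fit).
6. **Synthetic data** (`dendrosync.simulate`). A seeded generator for
   ring-width networks (one-factor common signal whose strength may shift
   through time, optional two-group site structure, staggered core starts,
   negative-exponential age trends) and monthly climate (seasonal cycle,
   AR(1) anomalies, trend segments, coupling of one month to the network
   signal) — every downstream stage has a parameter-recovery test with
   known ground truth.

## Worked example

```bash
dendrosync simulate --out-dir demo --seed 0    # synthetic 17-site bundle
dendrosync run-all --config demo/config.yaml   # full pipeline
```

```
fixture bundle written to demo (17 sites); pipeline config: demo/config.yaml
report written to demo/report
```

The demo emulates the study conditions: a network whose common-signal
fraction steps from 0.3 to 0.6 in 1955, a two-group site contrast that
strengthens after 1990, and a January minimum temperature series coupled to
the growth signal at r = 0.6. `demo/report/` then holds plain TSV/JSON
tables, e.g. (numbers from the run above, seed 0):

- `running_pc1.tsv` — the PC1 share rises from 28.1% in "1825–1874" to
  63.4% in the anchored final window "1955–2005": the simulated
  late-century synchronization is recovered.
- `correlation_function.tsv` — the strongest correlate of regional growth
  is January minimum temperature (r = 0.544 at n = 55, above the 99%
  critical value 0.3445), exactly the injected coupling month.
- `fcm_summary.tsv` — fuzzy cardinalities of the two clusters sum to 17.000
  in both intervals (9.331 + 7.669 in the warm one); the warm-interval
  pseudo-F (27.8) exceeds the cold one (0.0), recovering the stronger
  warm-era partition built into the fixture.
- `threshold.json` — the two-segment breakpoint fit of the ANN response
  surface. The demo's temperature coupling is linear, so the reported knot
  (−13.6 °C, slope ratio 0.69) is the weak bend of a noisy fit of linear
  truth, not a real saturation; the acceptance script's threshold study
  injects a true −7 °C saturation and recovers it within ±1 °C.

The same verbs (`chronology`, `synchrony`, `climate`, `fcm`, `nonlinear`)
run single stages; stages exchange data through the report directory and
are skipped when their outputs already exist.

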