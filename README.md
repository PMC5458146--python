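# paleospread

Spatially standardized species-richness estimation for fossil occurrence
data.

## The problem

Apparent diversity in the fossil record tracks how much of the world was
sampled. Because species richness grows with area (the species–area effect),
a time interval whose fossil localities span half a continent will yield
more species than an equally diverse interval known from a single basin —
even after classical sampling-standardization. Long-term diversification
studies built on raw or merely coverage-standardized counts therefore risk
mistaking the history of *collecting* for the history of *life*.

`paleospread` implements a workflow that controls for this bias before
richness is estimated:

1. **Clean and time-bin** PaleoDB-style occurrence tables (drop
   indeterminate, wastebasket, marine, flying, ichno-, oo- and soft-tissue
   taxa; keep only occurrences dated entirely within one ~9-myr bin).
2. **Measure palaeogeographic spread** as summed minimum-spanning-tree (MST)
   length over occupied 1° grid cells (1° ≈ 111 km of arc), along with
   convex-hull area, maximum great-circle distance, standard distance and
   grid-cell occupancy.
3. **Standardize spread**: split each bin's global MST into continental
   regions by iteratively removing the longest branch until every subtree is
   below a 13,000 km ceiling, then grow 20 replicate subsamples of
   localities per region, each to a target summed MST length (3,200 km
   ± 10% at continental scale) from a random seed locality.
4. **Estimate richness** per pool three ways: raw counts; shareholder
   quorum subsampling (SQS, quorum 0.4, coverage measured against Good's
   *u*); and TRiPS, which models per-species sampling as a Poisson process
   with intensity λ, so detection probability is p = 1 − e^(−λ) and
   estimated richness is N̂ = n_obs / p̂ with profile-likelihood confidence
   intervals.
5. **Fit trend models**: log-link GLMs of richness against bin midpoint
   (negative-binomial errors for counts, Gaussian for SQS/TRiPS series).
   With time t in Ma counting down, E[S] = exp(a + bt) and −b estimates the
   net diversification rate per myr; |b| × span gives the cumulative ln
   increase and 100(e^x − 1) its percentage. Bonferroni corrections are
   provided for families of series.

A synthetic-data module generates occurrence worlds with known truth
(species ranges, abundances, clustered localities, per-bin richness
trajectories), so the whole pipeline is testable end to end without any
external download.

## Worked example

`examples/06_species_area_demo.py` builds a world whose **true richness is
constant** while the sampled spread doubles across eight 9-myr bins, then
runs the full pipeline:

```
                series     slope       se        p  percent_increase  n_points
  unstandardized (raw) -0.009121 0.001985 0.000004         77.649883         8
  unstandardized (sqs) -0.003879 0.002062 0.059926         27.682820         8
unstandardized (trips) -0.008216 0.001697 0.000001         67.804345         8
    standardized (raw)  0.001134 0.003241 0.726408          7.405009         8
    standardized (sqs)  0.003227 0.002653 0.223934         22.541225         8
  standardized (trips)  0.002665 0.002319 0.250506         18.284031         8

unstandardized raw trend P : 4.32e-06  (spurious)
equal-spread SQS trend P   : 0.224
spread CV: regional pools 45% -> equal-spread samples 4.4%
```

The unstandardized raw series shows a highly significant diversification
trend (P ≈ 4 × 10⁻⁶, a ~78% apparent increase) that is pure sampling
artefact; after equal-spread subsampling the trend is gone (P ≈ 0.2−0.7),
and the spread of the sampled pools is an order of magnitude more uniform.
The other examples (`examples/01…05`) each demonstrate one layer: cleaning
and binning, spread metrics, equal-spread subsampling, the three richness
estimators, and trend fitting.

A thin CLI wraps the same pipeline for shell use:

```bash
paleospread simulate --out sim/ --seed 2
paleospread clean sim/synthetic_occurrences.csv --out cleaned/
paleospread all config.yaml    # full pipeline from a YAML config
```

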