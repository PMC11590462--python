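# movestrat

Movement-strategy analysis for GPS-tracked waterbirds: distance metrics with
permutation comparisons, variogram-based monthly residency classification,
autocorrelation-aware kernel (AKDE) residency areas merged into blocks by
Bhattacharyya overlap, residency odds with delta-method intervals, and site
revisitation statistics — exercised end-to-end on synthetic tracks with known
ground truth.

## Modules

| module | purpose |
| --- | --- |
| `movestrat.synthetic` | exact simulation of resident (position–velocity Gaussian process), nomadic (correlated-heading walk), mixed-schedule and diel (roost/forage) tracks, with per-month truth labels |
| `movestrat.track_io` | fix CSV reading (default and Movebank dialects), 30-day / exclusion-window filtering, 6-hourly grid regularization (nearest within tolerance, no interpolation), calendar-month splitting in local time |
| `movestrat.metrics` | daily cumulative / max-from-roost / roost-shift distances, cumulative rates, monthly percentile summaries, percentile permutation tests with Holm adjustment |
| `movestrat.variogram` | per-axis empirical semivariance, three-parameter model semivariance fit (weighted least squares, multi-start), derivative-based asymptote residency check |
| `movestrat.akde` | effective sample size, reference-bandwidth kernel UDs, 95% highest-density contour areas, Bhattacharyya overlap (grid-sum and Gaussian closed form), parametric-bootstrap overlap CI, block merging and summaries |
| `movestrat.odds` | monthly residency odds with delta-method CIs, residency percentages, seasonal two-proportion permutation tests |
| `movestrat.revisit` | visit detection against polygons, revisitation summaries, wetland-layer classification |

## CLI

```sh
movestrat simulate ouf --sigma2 100 --tau-p 24 --tau-v 1 --duration 60 --out track.csv
movestrat metrics compute --fixes track.csv --out daily.csv
movestrat metrics test --daily daily.csv --groupby species --statistic median --n-perm 1000 --seed 1
movestrat residency classify --fixes track.csv --out calls.csv
movestrat residency odds --calls calls.csv --out odds.csv --plot odds.png
```

## Conventions worth knowing

- Semivariance is per axis (`E|dr|^2 / (2 d)`, d = 2), so the asymptote of a
  range-resident process equals its per-axis stationary variance.
- Percentiles use linear interpolation between order statistics (NumPy
  default, R type 7) — p80 values depend on this choice.
- Permutation p-values carry the +1 finite-sample correction.
- The residency check lag defaults to half the month window with both
  derivative tolerances at 0.05; all three are configurable and echoed in
  every call's diagnostics.
- Grid regularization anchors at UTC midnight; month membership and diel
  logic use local clock time via the per-bird UTC offset.
- Unusable months (fewer than 20 grid fixes) are excluded from odds
  denominators rather than counted as non-resident.
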