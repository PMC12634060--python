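# firegraze

A tested, reusable pipeline for quantitative palaeoecology of disturbance
regimes: from stratigraphic pollen and coprophilous fungal-spore counts to
pollen influx, a habitat-combustibility index, diversity metrics, assemblage
turnover, stratigraphic zonation, and herbivory–diversity correlation tests.

It is written for palaeoecologists who hold a counted sediment sequence (a
taxon × sample count table, an exotic-marker spike record and a pre-computed
age–depth chronology) and want to ask how fire-proneness of the surrounding
vegetation and herbivore pressure covaried with plant diversity through
time. A synthetic-data generator with exact ground truth makes every stage
of the analysis verifiable without any deposited dataset.

## What it computes

**Influx.** Counts become concentrations through the exotic-marker
(*Lycopodium* tablet) ratio and influx through the deposition time:

```
concentration_i = n_i · (spike_added / spike_counted) / volume        [grains cm⁻³]
influx_i        = concentration_i / deposition_time                  [grains cm⁻² yr⁻¹]
```

**Habitat combustibility.** Terrestrial taxa are mapped to six
Mediterranean habitat types carrying ordinal combustibility classes
(beech forest, white oak coppice → 1; green oak coppice → 2; pine forest
→ 3; garrigue/heathland → 4; dry grassland → 5; unassignable taxa → an
"other" category excluded from the index). The per-sample index is the
influx-weighted mean class:

```
C̄ = Σ_h influx_h · class_h / Σ_h influx_h        over classed habitats h
```

Periods (default boundaries 6500, 4000, 1000 cal BP) are compared with
pairwise two-sided Mann–Whitney *U* tests and a compact letter display.

**Diversity.** Rarefied palynological richness `PRI = Σ_i [1 − C(N−Nᵢ,n)/C(N,n)]`
at a common base count n (default: the minimum terrestrial pollen sum);
Hurlbert's evenness `PIE = N/(N−1)·(1 − Σ(Nᵢ/N)²)`; evenness-detrended
richness DPRI (OLS residuals of PRI on PIE); coprophilous-spore richness
and influx as herbivore-density proxies.

**Turnover.** A rate-of-change analysis on moving-window time bins
(200-yr bins, 5 shifts, standardization to the minimum count, age-weighted
smoothing, 100 randomizations): the chi-squared dissimilarity
`d(p,q) = √Σ (pₖ−qₖ)²/(pₖ+qₖ)` between adjacent working units, rescaled to
dissimilarity per 200 years, with peaks flagged against a nonlinear
(LOESS) trend.

**Zonation.** Stratigraphically constrained incremental sum-of-squares
clustering (CONISS) with broken-stick significance of the zone count.

**Associations.** Spearman rank correlations between the herbivory proxies
and influx/richness, plus linear fits retained only when Shapiro–Wilk
accepts residual normality.

## Worked example

```python
import firegraze as fg

counts, meta, chron, truth = fg.generate_dataset(fg.SyntheticConfig(seed=1))
influx = fg.influx_table(counts, chron)

comb = fg.combustibility_series(influx, meta, chron)
labels = fg.assign_periods(comb["age_calBP"])
res = fg.compare_periods(comb["mean_combustibility"], labels)
for period in reversed(res.means.index):
    print(f"{period}: mean combustibility {res.means[period]:.2f} "
          f"[{res.letters[period]}] (truth {truth.period_means[period]:.2f})")

roc = fg.roc_series(counts, meta, chron, fg.RoCConfig(seed=0))
print("turnover peaks (cal BP):", roc.loc[roc["peak"], "age_calBP"].tolist())

div = fg.diversity_series(counts, meta, influx, chron)
rho, p = fg.spearman(div["spore_influx"], div["PRI"])
print(f"rho(spore influx, richness) = {rho:.2f} (p = {p:.3f})")
```

prints

```
Period 1: mean combustibility 3.11 [c] (truth 3.10)
Period 2: mean combustibility 2.69 [b] (truth 2.68)
Period 3: mean combustibility 2.71 [b] (truth 2.69)
Period 4: mean combustibility 3.34 [a] (truth 3.33)
turnover peaks (cal BP): [900.0, 6500.0]
rho(spore influx, richness) = 0.36 (p = 0.001)
```

The default synthetic sequence alternates open (high-combustibility) and
closed (forested) phases with transitions at 6500 and 1000 cal BP. The
pipeline recovers the generator's closed-form period means (3.10 / 2.68 /
2.69 / 3.33), the letter display separates open from closed periods while
grouping the two statistically indistinguishable forested periods, the
turnover peaks land on the two configured transitions, and spore influx
correlates positively with rarefied richness, as built into the generator's
openness coupling.

The same analysis runs from the shell on a YAML config naming either input
CSVs or a simulate block:

```sh
firegraze run --config cfg.yaml --out results/
firegraze simulate|combust|diversity|roc|zones|associations --config cfg.yaml
```

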