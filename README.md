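# thermopair

Tools for estimating insect thermal requirements and asking whether
invasive species differ from their non-invasive relatives in them.

Ectotherm development speeds up roughly linearly with temperature over the
ecologically relevant range. Writing the developmental rate (the reciprocal
of development time in days) as

    rate(T) = a + b·T = (T − LDT) / SET,

two constants summarize a species' thermal biology: the **lower
developmental threshold** LDT = −a/b (°C), the temperature at which
development ceases, and the **sum of effective temperatures** SET = 1/b
(day-degrees D° above the LDT needed to complete a stage). `thermopair`
estimates these constants from laboratory rearing tables, and then supports
a paired comparative design: each non-invasive species is matched to its
closest invasive relative (genus → tribe → subfamily → family) from the
same continent of origin, and the per-pair differences d_LDT and d_SET are
analysed with

* pooled and paired-difference t-tests of the status effect,
* REML linear mixed models — a random intercept per pair (the model-based
  paired t, yielding the intraclass correlation
  ICC = σ²_pair / (σ²_pair + σ²_res)), and random intercepts on the nested
  taxonomy (order, family-within-order) with likelihood-ratio tests between
  the structures; fixed-effect t-tests use Satterthwaite denominator df,
* a Pearson correlation of (d_LDT, d_SET), testing whether pairs trade a
  higher threshold for a lower thermal sum,
* degree-day phenology: single-sine accumulation above the LDT and the
  crossing temperature T_c above which a higher-LDT/lower-SET species
  develops faster.

A synthetic-data module generates rearing tables and pair-structured trait
tables with known effect sizes, variance components and difference
correlation, so the whole pipeline is testable without any external data.

Intended users: insect ecologists and risk-assessment modellers working
with degree-day phenology and comparative trait analyses.

## Worked example

```python
from thermopair import (SimulationConfig, generate_pair_dataset, paired_lmm,
                        difference_correlation, status_t_test)
from thermopair.pairs import long_from_pairs_frame

traits, pairs = generate_pair_dataset(SimulationConfig(seed=42, n_pairs=100))
long = long_from_pairs_frame(pairs, "ldt")
t = status_t_test(long["value"].to_numpy(), long["status"].to_numpy(),
                  long["pair_id"].to_numpy(), variant="paired_differences")
lmm = paired_lmm(long)
corr = difference_correlation(pairs)
print(f"paired t (LDT): t = {t.statistic_t:.2f}, df = {t.df:.0f}, "
      f"mean difference = {t.mean_difference:.2f} °C")
print(f"paired LMM:     beta = {lmm.fixed_effect_status:.2f} °C, "
      f"t = {lmm.statistic_t:.2f}, df = {lmm.satterthwaite_df:.1f}, ICC = {lmm.icc:.3f}")
print(f"d_LDT vs d_SET: r = {corr.r:.3f}, p = {corr.p_value:.4f}, n = {corr.n}")
```

prints

```
paired t (LDT): t = 3.51, df = 99, mean difference = 1.13 °C
paired LMM:     beta = 1.13 °C, t = 3.51, df = 99.0, ICC = 0.155
d_LDT vs d_SET: r = -0.359, p = 0.0006, n = 88
```

One simulated study of 100 pairs: invasive species average 1.13 °C higher
thresholds than their non-invasive relatives (significant by both the
paired t and its mixed-model analogue), trait values within a pair are
mildly correlated (ICC 0.155), and pairs where the invasive member has the
higher threshold tend to have the lower thermal sum (r < 0, on the 88 pairs
with SET data).

The same stages are available from the shell:

```sh
thermopair simulate pairs --n 100 --seed 42 --out-traits traits.csv --out-pairs pairs.csv
thermopair pair --traits traits.csv --out pairs.csv
thermopair compare --traits traits.csv --trait both --out results.json
thermopair simulate devdata --ldt 10 --set 100 --seed 7 --out obs.csv
thermopair estimate --in obs.csv --out tr.csv
thermopair phenology --weather weather.csv --ldt 10 --set 300 --out dd.csv
thermopair run --config pipeline.yaml
```

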