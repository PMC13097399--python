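# periwalk

Smartphone-derived walk-test maxima and perioperative activity analysis
from phone health exports.

## The problem

Supervised walk tests such as the 6-minute walk test (6MWT) measure what a
patient *can* do, but only at scattered clinic visits. Phones passively
record time-stamped walking/running distances and step counts for months,
before and after surgery, free of the Hawthorne effect. `periwalk` turns
one Apple-Health-style `export.xml` per patient into **digital mobility
outcomes**: for every civil day it derives the maximum distance walked in
any contiguous 1-minute and 6-minute window (a simulated 1MWT/6MWT), the
total step count, and the active time, then analyzes their trajectory
across four perioperative intervals. It is aimed at clinical researchers
studying functional recovery — the built-in cohort model targets lumbar
decompression/discectomy patients, but nothing is spine-specific.

## Method

For each patient-day:

1. **Parsing** — walking/running-distance and step-count `Record` elements
   are read from the export XML and canonicalized (meters, counts).
2. **Normalization** — each distance record is spread uniformly over its
   `[start, end)` span and credited to the day's 1440 minute bins in
   proportion to temporal overlap, giving a per-minute distance vector
   `x₁ … x₁₄₄₀` (1380/1500 bins on daylight-saving days).
3. **Sliding window** — the simulated walk tests are
   `wMWT = max_i Σ_{j=i}^{i+w−1} x_j` for `w ∈ {1, 6}`, computed in O(n)
   via prefix sums; windows never cross midnight.

Daily steps are date-aggregated (records spanning midnight are split by
overlap), and active time is the union of the day's recorded activity
spans, in hours.

Patient-days are assigned to four half-open intervals relative to the
surgery date `S`: baseline `[S−183 d, S−14 d)`, final two preoperative
weeks `[S−14 d, S)`, early postoperative `[S, S+14 d)` and late
postoperative `[S+14 d, S+42 d)`. Per patient × interval × metric the
daily values give mean, median, sample SD and the day-to-day stability
measure `CV% = 100·SD_daily/mean_daily`. For each metric, all six
interval pairs are compared on per-patient interval means: the paired
differences are Shapiro–Wilk tested (α = 0.05) and routed to a paired
*t*-test or the Wilcoxon signed-rank test, and the family of six raw
p-values is adjusted with the Simes–Hochberg step-up procedure
(significance: adjusted p < 0.05). Pooled Pearson correlations across all
patient-days are reported descriptively.

A synthetic-cohort generator (`periwalk.synthetic_cohort`) emits
export-dialect XML for a simulated 41-patient perioperative cohort built
from non-overlapping constant-speed walking bouts, for which every daily
metric is known in closed form — so the whole pipeline can be validated
end to end without patient data.

## Worked example

```sh
periwalk simulate --out cohort --n-patients 41 --seed 1
periwalk run --manifest cohort/manifest.csv --out results
```

prints

```
wrote 41 exports and 9225 ground-truth rows to cohort
pipeline complete: 11 artifacts under results
```

and `results/comparisons.csv` contains, for the 1-minute walk maximum:

```
    metric   interval_a   interval_b  n_pairs  shapiro_p test_used  statistic  p_raw  p_adjusted  significant
max_1min_m     baseline preop_last2w       41     0.1188  paired_t    -9.1149 0.0000      0.0000         True
max_1min_m preop_last2w   early_post       41     0.0897  paired_t    -0.0383 0.9696      0.9696        False
max_1min_m preop_last2w    late_post       41     0.5937  paired_t    12.2819 0.0000      0.0000         True
```

(three of six rows shown): the cohort declines significantly from
baseline into the final two preoperative weeks (median per-patient mean
91.3 → 78.9 m), stays flat through the early postoperative weeks
(79.0 m, adjusted p = 0.97), and recovers past baseline by weeks 2–6
(98.1 m, adjusted p < 0.05) — the decline-dip-recovery pattern the
generator plants. `results/` also holds the daily-metrics,
interval-summary, correlation and CV tables, boxplot/heatmap figures,
and a JSON run log with parse-rejection counts and the effective
configuration.

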