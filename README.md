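# quadarray

Feature-level processing and subtype-specificity classification for
one-color expression microarrays whose non-control probes are printed
**four times per array** (on-chip quadruplicate features), as used for
transcriptome comparisons of murine iNKT1 / iNKT2 / iNKT17 thymocyte
subsets across mouse strains. The package consumes the tab-delimited
per-feature tables emitted by feature-extraction software (the processed
green-channel signal `gProcessedSignal`, QC flags and per-feature pixel
CVs), and produces normalized expression matrices, pairwise "Venn"
classifications of subset-specific genes, and small-sample group
comparisons — plus a synthetic-data generator with planted ground truth so
every stage can be validated without any array data.

## Method

For each array *i* with raw signals *g*, normalization is **global linear
scaling** to a series-wide reference 75th percentile:

```
g'  =  g · f_i ,     f_i = P75_ref / P75(g_i)      (P75_ref = 1500 RU)
```

so every array's non-control 75th percentile equals 1500 "RNA units" after
scaling. Within each probe's quadruplicate, features are then excluded —
in order, one recorded reason each — if they (i) carry a manual flag,
(ii) were flagged as outliers by the extraction software, (iii) fall
outside the quartile fences `[Q1 − k·IQR, Q3 + k·IQR]` of the
quadruplicate's normalized signals with `k = 1.42`, or (iv) have a pixel
coefficient of variation above 0.5. Surviving replicates are collapsed by
the **geometric mean**, and collapsed values below the surrogate floor of
**20 RU** (derived from negative-control intensities) are substituted by
the floor; probes losing all four replicates are reported missing, not
imputed.

For a pair of subsets (A, B) each probe is then classified as

* `negligible` — below **500 RU** in both subsets,
* `shared` — ≥ 500 RU in at least one subset, fold difference ≤ 2,
* `unique_A` / `unique_B` — ≥ 500 RU in at least one subset and a
  greater-than-twofold difference, named for the higher subset,

per experiment, and summarised across independent experiments as
mean ± s.d. per category. Group-level (animal) data use a fixed decision
tree: Mann–Whitney *U* (exact for small groups) whenever either group has
n ≤ 4; otherwise a Lilliefors-corrected Kolmogorov–Smirnov normality gate
decides between the unpaired two-tailed *t*-test and Mann–Whitney.

## Worked example

```python
import numpy as np, pandas as pd
from quadarray import (GeneratorParams, generate_dataset, ArrayPreprocessor,
                       venn_summary, summarize_across_experiments, run_comparison)

params = GeneratorParams(n_probes=2000, strains=("BALBC",), seed=42)
tables, truth = generate_dataset(params)          # 6 arrays: 3 subsets x 2 experiments

pre = ArrayPreprocessor()                          # sklearn-style transformer
matrix = pre.fit_transform(tables)                 # probes x samples, RU
print(matrix.shape)                                # (2000, 6)
print(round(pre.normalization_[0].scaling_factor, 4))   # 1.473
print(float(np.nanmin(matrix.to_numpy())))         # 20.0  (surrogate floor)

meta = pd.DataFrame([(t.sample_id, t.strain, t.subset, t.experiment_id)
                     for t in tables],
                    columns=["SampleID", "Strain", "Subset", "ExperimentID"])
summaries = [venn_summary(matrix, meta, ("iNKT1", "iNKT2"), e)
             for e in ("Exp1", "Exp2")]
print(summarize_across_experiments(summaries).to_string(index=False))
```

```
       pair   category   mean       sd  n_experiments
iNKT1|iNKT2 negligible 1240.0 0.000000              2
iNKT1|iNKT2     shared  679.0 1.414214              2
iNKT1|iNKT2   unique_A   40.5 0.707107              2
iNKT1|iNKT2   unique_B   40.5 0.707107              2
```

The scaling factor 1.473 is this array's 1500/P75 correction; 20.0 is the
intensity floor. The Venn rows say that, averaged over the two
experiments, 1240 probes were negligible in both subsets, 679 expressed
but within twofold, and ~40 specific to each subset — with the generator
having planted 40 unique probes per subset (`frac_unique_per_pair=0.02`),
recovered here through the full normalize/exclude/collapse/floor/classify
chain.

```python
res = run_comparison([12.1, 9.8, 11.4], [18.9, 17.2, 21.5, 19.0])
print(res.test_used, round(res.p_value, 4), res.stars)   # mann_whitney 0.0571 NS
```

With n = 3 and 4, the size gate forces the exact Mann–Whitney test; the
two-sided p for this near-separation is 0.0571, i.e. not significant.

The same pipeline is scriptable from the shell:

```sh
quadarray simulate --out-dir sim --seed 42 --strains BALBC
quadarray run --metadata sim/metadata.tsv --out-dir results_run
quadarray stats --input groups.tsv
```

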