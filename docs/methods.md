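# Methods notes

## Scope and model

`quadarray` implements the downstream half of a one-color microarray
workflow: it starts from the per-feature tabular output of image
extraction (one row per physical feature with its processed signal,
flags and pixel CV) and ends at per-probe expression values in RNA units
(RU), pairwise subset-specificity calls, and group-level statistics. The
arrays it models print every non-control probe four times ("on-chip
quadruplicates"), which is what makes within-array replicate QC and
collapse possible. Image processing itself (background subtraction,
spotfinding, the computation of `gProcessedSignal`) is upstream and out
of scope; so is any between-array statistic on the chip data beyond the
descriptive mean ± s.d. across independent experiments, since two
experiments per condition cannot support inferential comparisons.

Processing of one array is strictly sequential and deterministic:

1. **Scaling**: all signals are multiplied by
   `f = reference_percentile_value / P75(non-control signals)`.
   The population for P75 is every non-control feature (all four
   replicates, before any exclusion); control features are excluded
   because their intensity design is unrelated to the sample. Scaling
   before exclusion keeps the factor independent of QC decisions.
2. **Exclusion** within each quadruplicate, rules in order, first match
   recorded: (i) manual flag, (ii) software outlier flag, (iii) value
   outside `[Q1 − k·IQR, Q3 + k·IQR]` of the quadruplicate's normalized
   values, (iv) pixel CV > cutoff. The fence population is the members
   that survived (i)–(ii) — a wildly wrong flagged value must not widen
   the fences — and includes the candidate member itself.
3. **Collapse**: geometric mean of survivors (equivalently
   `exp(mean(log v))`); a probe with no survivors becomes missing.
4. **Floor**: collapsed values below the surrogate floor are replaced by
   it. Missing stays missing: the floor is an intensity threshold, not
   an imputation rule.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `reference_percentile_value` | 1500 | RU | series-wide scaling anchor |
| `percentile` | 75 | — | the anchored quantile |
| `surrogate_floor` | 20 | RU | from negative-control intensity levels |
| `iqr_multiplier` | 1.42 | — | replicate fence width |
| `pixel_cv_max` | 0.5 | — | within-feature pixel heterogeneity cutoff |
| `expression_floor` | 500 | RU | "negligible" boundary of the pair rule |
| `fold_threshold` | 2 | — | subtype-specificity boundary |
| `alpha_normality` | 0.05 | — | normality gate of the decision tree |

## Numerical and convention choices

* **Quantile convention.** All quantiles (the scaling P75 and the fence
  quartiles) use linear interpolation between order statistics (type 7,
  the numpy/pandas default), set once in `PipelineConfig` so every stage
  agrees. No authoritative convention exists for this assay; anchoring
  one convention everywhere is what matters for reproducibility.
* **Fence convention.** "Outside 1.42 × IQR" is ambiguous between Tukey
  quartile fences and a median-centered band; quartile fences are the
  default, `fence_convention="median_centered"` selects the alternative.
  Note that with three identical members and one distinct member, the
  quartile fences always exclude the distinct one; realistic replicate
  spread behaves sensibly.
* **Rule order.** The four exclusion rules are alternatives with no
  inherent order; they are applied (i)→(iv) with single-reason
  attribution so audit counts are well defined.
* **Floor placement.** The floor applies to the collapsed per-probe
  value (`floor_stage="post_collapse"`); flooring replicate values before
  collapse is selectable for sensitivity analysis. The final values are
  clipped at the floor in both modes (in pre-collapse mode this only
  irons out last-bit float error of `exp(mean(log ·))`).
* **Degenerate inputs.** An array whose non-control P75 is not strictly
  positive cannot be scaled (`DegenerateArrayError`). Quadruplicates with
  1–2 survivors still collapse (no minimum-survivor rule). A normalized
  signal of exactly 0 among survivors is an error under post-collapse
  flooring, since the geometric mean is undefined there.
* **Classification edges.** Exactly 500 RU counts as expressed; a fold of
  exactly 2 is `shared` (both boundaries follow the strict inequalities
  of the scheme). Folds are max/min ratios of floored values, hence
  always finite. Classification is per experiment, then averaged across
  experiments (sample s.d., ddof = 1); probes missing in either sample
  are counted separately as `unclassifiable`.
* **Statistics.** The normality gate uses the Lilliefors-corrected KS
  test (estimated mean and s.d.); plain KS is selectable. The gate
  requires both groups to pass. Mann–Whitney p-values are exact (full
  permutation distribution) for group sizes up to 8 without ties, and
  use the tie-corrected normal approximation otherwise. The t-test is
  the classic equal-variance unpaired test, with Welch selectable. The
  source material also mentions an unnamed "variance test" with no
  described consequence; it is deliberately not implemented — a
  documented gap rather than a guessed behaviour.
* **Heat-map export.** Row standardisation uses log2 values and the
  sample s.d. (ddof = 1); zero-variance rows are emitted as zeros. This
  replaces interactive heat-map software with a plain matrix export.

## Synthetic data

The generator emulates the *structure* the pipeline depends on, not the
intensity distribution of any real series: quadruplicate printing,
strains × subsets × experiments layout, log-normal expressed signal,
planted subset-specific probes (baseline × `planted_fold` in their
subset), planted negligible probes (30–350 RU), planted sub-floor probes
(1–15 RU), arbitrary per-array scale factors (log-uniform in [0.5, 2]) to
exercise normalization, multiplicative log-normal replicate noise, and
planted QC events (value outliers at ×/÷ `outlier_magnitude`, manual and
software flags — whose signals are corrupted the same way, so that
exclusion is observable — and high-CV members).

The planted truth table is stored on the post-normalization scale: each
subset column is renormalized so its feature-level P75 equals the 1500 RU
reference, which makes the pipeline's output directly comparable to the
truth (exactly so at zero noise). Planted categories are derived by
applying the pairwise rule to the truth table, so they are correct by
construction whatever the parameter mix. Defaults (62 % negligible, 2 %
unique per subset, 3 % sub-floor) mirror the proportions such arrays
show: roughly two-thirds of probes unexpressed, a third shared, a small
percentage subset-specific.

Randomness uses per-array substreams keyed by (seed, sample id), so
arrays are reproducible and independent of generation order; adding
probes does, however, shift draws within an array. What passing tests on
these data show is that the *pipeline logic* is correct under its own
assumptions; they cannot show robustness to spatial artifacts, probe
sequence effects, saturation, or non-log-normal noise, none of which are
simulated.

## Problem sizes

Desk-scale defaults keep every check fast: 2,000 probes (the real design
carries ~32,000 transcripts; the generator scales up via `n_probes`),
six arrays per recovery run, 1,000 random quadruplicates for the
exclusion oracle, exhaustive Mann–Whitney enumeration up to n = 5 per
group, and 10,000 null replicates (normal and exponential) for the
decision-tree calibration. The planted-category recovery criterion
(≥ 99 %) is evaluated in a clean regime — fold 4, replicate log-noise
0.05, no planted QC events — matching the margins the classifier is
expected to separate; pushing noise toward the fold threshold will
degrade recovery smoothly.

## Known limitations

* The parser reads the package's canonical dialect (plus a column map);
  it does not ingest full vendor exports column-for-column, nor series
  matrices from public repositories.
* No probe→gene collapsing: classification counts are probe-level.
* No multiple-testing correction in `stats` (none is defined for the
  modelled workflow), and no paired designs.
* The spike-in controls of real series are treated as ordinary controls
  and excluded from every computation.
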