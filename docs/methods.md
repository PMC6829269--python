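# Methods

## Scope and model

`tcelsig` treats the bulk expression of a non-lymphoid tissue as a cell
mixture: the measured linear-scale signal of a T-cell-restricted gene in a
tissue with T-cell fraction f is approximately
`f · 2^meanT(g) + (1 − f) · 2^bg(g)`, where `meanT(g)` is the gene's mean
log2 level in purified T cells and `bg(g)` its parenchymal background. When
`bg` is negligible — the defining property of a T-cell-restricted gene — the
log2 tissue level is `meanT(g) + log2 f`, so the per-gene offset from the
T-cell reference measures the T-cell fraction directly. Everything in the
package follows from this premise:

- the **six-round selection** keeps only genes for which the premise holds
  (large margins versus immune subsets, tissues and cell lines; coherent
  per-tissue behavior across the cohort of surviving genes);
- **Ts%** inverts the premise: averaging `x(g) − meanT(g)` over the
  signature in log2 space and exponentiating gives `100·f` when the
  background is negligible. Log-space (geometric) averaging is the only
  choice for which a cohort sitting uniformly d log2 below T cells scores
  `100·2^(−d)`; with arithmetic averaging of linear ratios a single
  high-background gene would dominate the score;
- **Tav** drops the T-cell reference (needed when a platform carries no
  purified T-cell data) at the cost of platform-specific units;
- **Ts-l2** replaces the T-cell reference with a matched healthy-tissue
  reference, making tumor-versus-healthy comparisons platform-portable.

## Selection procedure: conventions

- All six rounds consume group means, computed per group from only that
  group's samples. The T-cell reference pools all T-cell samples by default;
  `mean_of_subgroup_means` weighting is available because the corpus
  composition (which T subsets, how many arrays each) is a study property,
  not a property of the method.
- Thresholds are strict as worded: a margin exactly equal to 3.32 log2
  survives rounds 1/2/6, a range exactly at 2.5 or 8.5 survives round 3,
  and a deviation exactly at 3.32 survives rounds 4/5.
- Round 1 defaults to per-subset margins (a gene must clear every non-T
  immune subset); round 2 defaults to the margin against the average
  tissue. The asymmetry is deliberate: a per-tissue round-2 test would make
  round 3's range window largely redundant, whereas immune subsets are the
  direct confusers a T-cell signature must clear individually.
- Rounds 4/5 are one-sided (deviations above the cohort mean): constitutive
  parenchymal expression can only raise `nl/Tc`, never lower it. Exclusions
  within a pass are simultaneous — the cohort statistic `M_nl/Tc(t)` is
  frozen at pass entry — and exactly two passes are run by default, because
  removing outliers moves `M_nl/Tc` and can expose genes that the first
  pass's outliers masked. Per-gene diagnostics include the SD across tissues
  of the deviations, a useful homogeneity summary of the surviving cohort.
- Round 6 evaluates each cell line individually (not lineage aggregates) and
  counts distinct parenchymal sources among the violating lines; a single
  violating immune-derived line suffices for exclusion. Per-line evaluation
  is the stricter and more faithful reading; lineage averaging would let one
  permissive line hide behind a strict one.
- Degenerate inputs degrade softly: candidates absent from the matrix are
  dropped with a warning, a round whose sample class is missing is skipped
  with a warning, an outlier pass entered by fewer than two genes is skipped
  (the cohort mean needs a cohort), and an empty survivor set is a reported
  outcome, not an error.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `log2_min_overexpr` | 3.32 | log2 | ten-fold margin, log2(10) |
| `range_min`, `range_max` | 2.5, 8.5 | log2 | plausible spread of tissue-resident T-cell density across organs (5.6- to 363-fold) |
| `deviation_threshold` | 3.32 | log2 | ten-fold departure from the cohort profile |
| `outlier_passes` | 2 | — | one recomputation exposes masked outliers; further passes change little on realistic corpora |
| `cellline_min_parenchymal_sources` | 2 | sources | one aberrant line is tolerated; two independent sources indicate inducibility |
| `BandConfig.reference_ts` | 3.0 | Ts% | mean healthy-tissue Ts% under the 15-gene signature |
| similar band | 0.80–1.25 × reference | — | ±0.32 log2, i.e. 80–125% of the healthy-tissue signal |
| moderate/high cut | 2.5 × reference | — | package choice; no published value, configurable |
| very-low/extremely-low cut | 0.4 × reference | — | package choice; consistent with an extremely-low call at Ts% ≈ 1.1 against reference 3.0 |
| Tav bin edges | 0.125, 0.5, 2 | log2 | outer edges published; middle edge is a package default, configurable |
| response rules | 0.5/10, 1, 0.5 | — | fixed published thresholds; all strict |

## Survival statistics

The Kaplan–Meier estimator and the Mantel–Cox log-rank test are implemented
in-package because the downstream hazard ratio needs the per-group observed
and expected event counts the test produces; both are verified against
lifelines to 1e-6 on shared fixtures. The k-group statistic uses the full
hypergeometric covariance of O − E (df = k − 1). The hazard ratio follows
the log-rank (O/E) method, `HR = (O_A/E_A)/(O_B/E_B)`, with
`CI95 = exp(log HR ± 1.96·√(1/E_A + 1/E_B))`.

A property of this estimator worth knowing: it is consistent only near the
null. At a design hazard ratio of 3 with several hundred events it
underestimates the true ratio by roughly 13% on the log scale (simulation:
median estimate ≈ 2.6), and because that bias is comparable to the CI
half-width, the 95% CI covers the true value in only ~80–86% of replicates.
The Mantel–Haenszel variant `exp((O−E)/V)` errs in the opposite direction
(median ≈ 3.4) with similar under-coverage. At the null the estimator is
unbiased and coverage is nominal (~95% empirically). The O/E form is kept
because it is the documented "log-rank method" of the statistical software
this methodology standardizes on; users needing unbiased effect estimates
at large effect sizes should fit a Cox model instead (out of scope here).

Simulation sizes used throughout the package's own checks: 50 replicates of
n = 300 per group with 20% censoring for hazard-ratio recovery (runs in
about a second), 60-gene corpora for selection, and 200-patient checkpoint
cohorts. These sizes give stable estimates while keeping every check fast.

## The synthetic corpus

`generate_corpus` emulates exactly the structure the method assumes: linear
mixing of a T-cell profile into tissue backgrounds at per-tissue fractions
(defaults 0.002–0.03, brain lowest and colon highest, mirroring the rank
order of tissue-resident T-cell density), lognormal measurement noise
(log2-additive Gaussian, SD 0.3 — typical inter-array spread after
normalization), a T-cell level of 10 log2 and a margin of 7 log2 to
non-T backgrounds (safely above threshold + 6σ, the feasibility bound the
generator enforces). Six confounder classes are planted, each designed to
pass every round before the one it violates, so exclusion attribution is
testable per round. The default background for planted genes sits 4 log2
below the smallest T-cell tissue contribution — negligible but non-zero;
an effectively zero background (e.g. `background_log2=-30`) is used when
validating Ts% fraction recovery, where even a small background inflates
Ts% at f = 0.01 by several percent.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, RNA-seq count noise (negative binomial), correlated genes,
or T-cell subset heterogeneity. Passing tests therefore demonstrate that
the thresholds, scores and statistics behave as specified under the
method's own model — not that the signature generalizes to any particular
real platform or cohort.

`generate_survival_cohort` draws exponential event times with per-bin
hazards and censors each record with the stated probability at a uniform
fraction of its event time. `generate_melanoma_cohort` constructs half of
its profiles to satisfy all three response criteria and half to violate
exactly one (uniformly chosen), with Bernoulli responses per group and
response-linked survival.

## Numerical conventions

- Round-trip TSV I/O is value-preserving to 1e-9 (`%.10g` formatting).
- Trimmed-mean normalization discards `floor(trim_fraction · N)` cells at
  each tail of the pooled value distribution and applies one additive log2
  shift (a multiplicative rescale of linear intensities), so within-matrix
  differences — and hence every downstream margin, range and score — are
  invariant. The operation is idempotent at a fixed target. Whether the
  original between-dataset adjustment operated in linear or log space is
  not documented; the log2-additive form is the default because it
  preserves downstream statistics exactly.
- Band classification guards its edges with a 1e-9 relative epsilon so that
  e.g. a Ts% of exactly 2.4 against reference 3.0 lands in the similar band
  despite binary-float rounding of 0.8 × 3.0.
- Quartile concordance ranks descending with stable specimen-id tie-breaks
  and uses ⌈n/4⌉ specimens per quartile.
- The infiltrated call uses the sample SD (n − 1) of the healthy-tissue
  Tavs and a strict inequality.
- Tav binning: lowest bin strictly below the first edge, highest strictly
  above the last; a value exactly at the last edge falls below it.
- PD-1 = 0 classifies as "bad" with a warning rather than erroring: the
  PD-1-dependent criteria are unsatisfiable, which is a prediction, not a
  data defect. Likewise Tav-RNAseq ≤ 0 for the third criterion.

## Known limitations

- The selection procedure assumes margins computed on group means; very
  unbalanced group sizes shift the pooled T-cell reference (use
  `mean_of_subgroup_means` to weight subsets equally).
- Ts% is a relative mRNA-signal measure, not a cell-count estimate: it
  inherits activation-state and cell-size effects on mRNA content, and a
  signature gene expressed by another infiltrating population (e.g. NK
  cells for granzyme-family genes) inflates it.
- Strict set-monotonicity of the survivor set in the margin threshold can
  in principle be violated through the rounds-4/5 cohort statistic (removing
  genes moves `M_nl/Tc`); on corpora with well-separated planted structure
  the property holds and is tested there.
- The log-rank O/E hazard ratio is biased toward the null away from HR = 1
  (see above).
- The response rules are fixed thresholds evaluated as published; no
  fitting, calibration or cross-validation is performed.
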