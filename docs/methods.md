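# Methods

## Model and assumptions

The package scores decision units (countries) on a multidimensional
phenomenon — the propensity of children and adolescents to experience
anxiety- and depression-related difficulties — by aggregating 37
country-level adversity factors with the Ordered Weighted Averaging
(OWA) operator in two stages. The underlying assumptions are:

* each factor is monotonically related to adversity once oriented
  (protective factors reflected after min-max normalization; reflection
  after normalization is equivalent to reversing the raw scale first,
  because min-max scaling is affine);
* factors within a dimension are exchangeable once normalized — OWA
  weights attach to *ordered positions*, not to named factors, so the
  aggregation is symmetric in its inputs;
* the external validation variable (percentage of children/adolescents
  with difficulty in the anxiety-and-depression field) is a noisy
  monotone proxy of the same latent construct, which is what makes rank
  correlation the appropriate validation statistic.

Stage 2 consumes the stage-1 dimension scores **as-is**. Renormalizing
them would force the composite minimum to 0 and destroy the
interpretation of the final score as a weighted mean of dimension
scores; it would also make the composite's extreme values disagree with
the extreme dimension values, which published summaries of this kind of
pipeline preserve.

## Factor orientation

Published factor lists of this type rarely state which factors were
reversed. Orientation here is *data, not code*: the default registry
assigns `protective` to factors where a larger raw value plausibly
reduces adversity (GDP per inhabitant, education levels, parental ages,
household assets, health insurance, biological-parent co-residence and
survival, "feel safe" percentages) and `adversity_increasing` to the
rest (violent discipline, alcohol days, pessimism and unhappiness,
child labour, punishment beliefs, victimisation, discrimination). Every
assignment can be overridden per factor in a YAML/JSON registry, and the
orientation is part of the provenance of every score.

## Emphasis weights

The drop-k weight scheme resolves an ambiguity: zeroing k ordered
positions while keeping the weights summing to one forces the remaining
positions to 1/(ρ−k), not 1/ρ. The sum-to-one condition is a hard
constraint of the OWA definition, so 1/(ρ−k) is used. The intensity t
maps to k = max(1, ⌊tρ⌋) zeroed positions whenever an emphasis is
requested, so "25 % negative emphasis" always discounts at least the
single best-performing oriented value even for small ρ (ρ = 3 at stage
2, ρ = 4 would give k = 1). An emphasis that would zero every position
is rejected as infeasible.

## Missing data

Default policy `exclude_reweight`: a missing cell simply drops out of
that unit's OWA, with the position weights rebuilt for the reduced ρ.
This is the natural choice when some questionnaires (e.g. father
modules) are absent in whole countries; it requires every unit to keep
at least two non-missing factors per dimension. `median_impute` (column
median, every imputation logged) is offered when strict comparability
of ρ across units matters more than respecting the observed support.
Both policies are idempotent.

## Quality tests

* **Explanatory power** is the Spearman coefficient computed as Pearson
  on midrank vectors (scipy's implementation). It is invariant under
  strictly monotone relabelings of either series; a series with zero
  rank variance has no defined coefficient and is rejected.
* **Discriminant power** is computed in two variants, reported side by
  side. The *raw-score* variant, −(1/ln δ)·Σ s ln s with 0·ln 0 := 0,
  treats the scores themselves as masses; it is kept verbatim for
  comparability but is not an entropy of a distribution (it depends on
  the score scale). The *frequency-entropy* variant is the base-2
  Shannon entropy of the empirical distribution of score values; it
  equals log₂ δ exactly when all δ scores are pairwise distinct (5.755
  bits at δ = 54) and 0 when all coincide, which matches how the
  statistic behaves in published applications of this pipeline. Score
  bounds are checked with a 1e-9 tolerance because OWA scores are convex
  combinations and can land an ulp outside [0, 1].
* **Atypical measurements**: the external variable is min-max rescaled
  to [0, 1] so the (score, external) pair is commensurate; each pair's
  squared Mahalanobis distance from the bivariate sample mean (classical
  δ−1 covariance) is compared with the χ² quantile at 2 degrees of
  freedom — the dimensionality of the pair, which is what the ellipse in
  a bivariate outlier plot encodes. The quantile defaults to 0.975 and
  is configurable. A raw scalar difference of score minus external
  admits no 2×2 covariance and is not used for flagging. The classical
  estimator is intentionally not robustified (no MCD): the test
  describes compatibility of the bulk, and contaminating points are
  expected to self-identify against the χ² ellipse.

## Synthetic data generator

The generator emulates the structure the analysis assumes: per-country
latent adversity A ~ Uniform(0, 1); per-dimension latents mixing A with
independent uniform noise (weight `latent_mix`, default 0.7); each
factor a bounded monotone transform of its dimension latent plus
Gaussian noise (`noise_sd`, default 0.15 on the unit scale), clipped to
its value-kind range and reflected for protective factors; continents
assigned round-robin. The external variable is a monotone map of a
latent that mixes the adversity ranks with Gaussian noise, with the
mixing weight bisected until the realized Spearman correlation is within
±0.05 of the target `signal` (default 0.53, a typical validation-grade
correlation for an index of this kind).

Defaults: 54 units and 15/9/13 factors per dimension — the scale of a
multi-country survey round — so tests exercise the pipeline at its
intended problem size. All Monte-Carlo tests use 100–200 replicates of
this 54 × 37 table (a few milliseconds per replicate), which puts the
standard error of a recovered correlation near 0.01.

The external variable lands in a *prevalence band* (default 5–40 %)
rather than spanning the full percentage axis, as survey prevalences do.
This matters for outlier injection: an injected outlier must lie outside
the support of the clean distribution, otherwise it is merely the sample
minimum and "injected-outlier recall" measures nothing. Injected
outliers are the `n_outliers` units with the *highest realized composite
score*, whose external value is replaced by 0 — strictly below the clean
band and maximally discordant with their indicator position. Ground
truth records the latents, the injected ids and the realized
correlation.

What the generator does **not** emulate: spatial/continental structure
in the factors (continents are labels only, so continent summaries are
exercised but their values carry no signal), heavy-tailed or skewed
factor distributions beyond the currency transform, correlated
missingness, and survey measurement error that varies by country.
Passing recovery tests therefore show the pipeline recovers a monotone
latent signal at realistic noise — not that any particular real-world
table satisfies these assumptions.

## Reproduction sweeps

For published tables whose exact configuration is under-documented
(orientation choices, stage-2 emphasis, missing-data handling — and
where published composite and dimension means can even be mutually
inconsistent at face value), `owaci.reproduction.sweep_configurations`
runs the study under every combination of the documented knobs and ranks
configurations by mean absolute deviation from the published numbers at
2-decimal rounding, reporting the best match and the full grid. On
synthetic data with a known generating configuration the sweep recovers
that configuration exactly, which is the testable contract; matching a
specific published table additionally requires that table as input.

## Numerical choices and degenerate inputs

* Min-max normalization requires ≥ 2 distinct values; constant columns
  raise a degenerate-column error naming the factor (the remedy is
  dropping the factor, not silently emitting 0/0).
* Descending sort is stable; ties at the zero/nonzero weight boundary
  cannot affect the score because tied values contribute equal α.
* Weight vectors are validated to sum to 1 within 1e-12.
* The bivariate covariance is rejected as singular when its determinant
  falls below 1e-15 (perfect collinearity of score and external).
* Dimension-proportion shares (score_d / Σ score_d, the contribution
  under uniform weights) are undefined for a unit whose three dimension
  scores are all zero; such a unit raises rather than yielding NaN.
  Continent-level shares are the shares of continent-mean scores, not
  the mean of unit shares, so they are consistent with aggregating the
  dimension scores first.
* CSV output uses '.' decimals, comma delimiters and 10-significant-
  digit floats, making repeated runs byte-identical.

## Known limitations

* The classical Mahalanobis test is subject to masking when many
  outliers cluster; it is kept classical by design (see above), so
  recall guarantees hold for a small number of extreme discordant
  points, not for heavy contamination.
* Orientation defaults encode domain judgement; results on real tables
  can depend on assignments for ambiguous factors (e.g. parental age),
  which is why orientation is overridable data.
* The raw-score discriminant-power variant depends on the score scale
  and should be compared only across models on the same data.
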