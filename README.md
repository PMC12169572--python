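# owaci — an OWA composite indicator of childhood adversity

`owaci` builds a per-country **composite indicator of the propensity of
children and adolescents to experience anxiety- and depression-related
difficulties**, from 37 country-level adversity factors grouped into three
dimensions — socioeconomic conditions, vulnerability, and risk/insecurity —
and validates the result with three quality tests. It is aimed at
epidemiologists and public-health analysts who work with country-level
survey aggregates (e.g. UNICEF MICS indicators) and need a transparent,
reproducible aggregation pipeline rather than a black-box index.

## The method

Scores are built in two stages with the **Ordered Weighted Averaging (OWA)**
operator. For one decision unit (country) with sub-indicator values
Ω₁,…,Ω_ρ:

1. **Normalize** each sub-indicator across countries:
   Ω = (ω − min ω) / (max ω − min ω).
2. **Orient** so higher always means more adversity: protective factors
   (GDP, education, asset ownership, "feel safe" percentages, …) are
   reflected to 1 − Ω.
3. **Sort** the unit's values in descending order (α₁ ≥ α₂ ≥ … ≥ α_ρ).
4. **Weight** the ordered positions with β (β_λ ∈ [0,1], Σβ_λ = 1). With no
   emphasis β is uniform and the OWA is the arithmetic mean; a *negative
   emphasis* of intensity t zeroes the k = max(1, ⌊tρ⌋) highest positions
   (a positive emphasis mirrors this), spreading 1/(ρ−k) over the rest.
5. **Aggregate**: OWA(Ω₁,…,Ω_ρ) = Σ_λ β_λ α_λ.

Stage 1 applies this within each dimension (15, 9, and 13 factors); stage 2
treats the three dimension scores as sub-indicators and aggregates them,
without renormalizing, into the final indicator.

Three **quality tests** validate a score vector against an external
variable ϵ (the percentage of children/adolescents with difficulty in the
anxiety-and-depression field):

* **Explanatory power** — Spearman rank correlation ρ(score, ϵ) with
  midranks for ties;
* **Discriminant power** — entropy of the score distribution, in two
  variants: the raw-score form −(1/ln δ)·Σ s ln s, and the base-2
  frequency entropy of the score values, which equals log₂ δ (≈ 5.755 bits
  for δ = 54) when all country scores are distinct;
* **Proportion of atypical measurements** — each (score, rescaled-ϵ) pair
  is tested against the χ²₂ Mahalanobis ellipse (default 0.975 quantile);
  the proportion B is the flagged fraction.

A synthetic-data module generates country tables with a known latent
adversity structure (and optional injected outliers) so every pipeline
property can be tested against ground truth.

## Worked example

```python
from owaci import SyntheticConfig, generate_synthetic_dataset, run_full_study

dataset, truth = generate_synthetic_dataset(SyntheticConfig(seed=1))
result = run_full_study(dataset)
q = result.quality["final"]
print("final mean %.3f" % result.final_scores.mean())
print("rho %.3f  discriminant %.3f bits  atypical %.3f"
      % (q.explanatory_power, q.discriminant_power_reported,
         q.outlier_proportion))
```

prints

```
final mean 0.528
rho 0.494  discriminant 5.755 bits  atypical 0.019
```

i.e. the 54 synthetic countries average 0.528 on the [0, 1] propensity
scale; the indicator rank-correlates 0.49 with the external variable
(the generator's target signal is 0.53); all 54 scores are distinct, so
the indicator carries the maximal log₂ 54 ≈ 5.755 bits of
distinguishability; and 1 of 54 countries (1.9 %) falls outside the
0.975 χ² ellipse.

The same pipeline runs from the shell:

```bash
owaci simulate --seed 1 --out sim/
owaci run --factors sim/factors.csv --external sim/external.csv --out reports/
owaci compare --factors sim/factors.csv --external sim/external.csv \
      --emphasis none,negative:0.25 --out comparison.csv
```

`reports/` then holds `scores.csv` (per-country dimension and final
scores), `quality.csv`, `continents.csv` and `proportions.csv`. Real data
goes in the same way: a CSV with `country_id,name,continent` plus the 37
factor columns (see `owaci.default_registry()` for ids and orientations,
all overridable via `--registry registry.yaml`), and a
`country_id,value` CSV for the external variable.

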