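# starrpairs

Analysis toolkit for **paired-enhancer STARR-seq screens**: reporter assays in
which every ordered pair of ~1000 candidate sequences (enhancers spanning a
wide activity range plus random negative controls) is fused around a
transcriptionally inert spacer, cloned downstream of a core promoter, and
quantified by UMI-collapsed RNA/input sequencing. The package is written for
regulatory-genomics groups who want to measure how two enhancers combine —
additively, multiplicatively, or with saturation — and what transcription-factor
motif content does to that cooperativity.

## What it computes

For a pair with 5′ and 3′ individual log2 activities *A* and *B* (fold changes
over the basal promoter, inferred from pairings with robust negative controls),
the combined activity is predicted under

* an **additive** model: P = log2(2^A + 2^B − 1) — RNA outputs add;
* a **multiplicative** model: P = A + B — fold changes multiply;
* a fitted **interaction** model: P = β₀ + β₁A + β₂B + β₃·A·B + ε (OLS),
  whose negative β₃ captures promoter saturation at high combined activity.

Model performance is R² = 1 − SS_res/SS_tot (adjusted for the fitted model),
and the fraction of pairs for which the multiplicative prediction beats the
additive one summarises the dominant regime. Around that core sit the full
pipeline stages:

* `pool` / `variants` — candidate pools, all-|pool|² ordered pair designs,
  construct references, and motif paste/mutate sequence variants;
* `simulate` — synthetic screens with known ground truth (negative-binomial
  UMI counts, four cooperativity regimes, optional paired FASTQ);
* `quantify` — read-pair assignment against the construct reference with a
  Hamming budget, exact UMI collapsing, and the heterotypic ≥5-input-UMI filter;
* `activity` — median-of-ratios + pseudocount log2 fold changes centred on
  control/control pairs, robust-control selection (|z| ≤ 1), individual
  activities (≥10 control partners), and active calls (log2 > 1, Fisher/BH
  FDR < 0.05);
* `coopmodel` — the model/results classes described above plus promoter
  saturation curves (weak- vs strong-anchor analysis);
* `motifs` — PWM scanning with exact p-value-calibrated thresholds (dynamic
  programming over the null score distribution), Fisher/FDR motif enrichment,
  pairwise motif-combination grids, and a nested cross-validated LASSO
  predicting activity or residuals from motif counts.

## Worked example

Simulate a screen at realistic conditions (150 enhancers + 60 controls, two
input and two RNA replicates, ~100 input UMIs per pair, interaction-regime
truth β = 0.1/1.1/1.0/−0.1, 0.1 log2 biological noise), run the pipeline and
fit the cooperativity model:

```python
import starrpairs as sp
from starrpairs.quantify import filter_pairs

config = sp.SimulationConfig(n_enhancers=150, n_controls=60,
                             mean_input_depth=100.0, seed=7)
model = sp.TrueActivityModel(regime="interaction", beta0=0.1, beta1=1.1,
                             beta2=1.0, beta3=-0.1, noise_sd=0.1)
dataset = sp.simulate_dataset(config, model)

counts = filter_pairs(dataset.counts, dataset.design, min_input=5)
pair_acts, indiv, controls = sp.run_activity_pipeline(counts, dataset.design,
                                                      dataset.pool)
results = sp.PairCooperativityModel.from_tables(pair_acts, indiv,
                                                dataset.pool).fit()
print(results.summary())
comparison = results.compare_models(both_active_only=True)
print(f"multiplicative prediction wins for "
      f"{comparison.frac_multiplicative_better:.1%} of both-active pairs")
```

Output:

```
Pair cooperativity model (OLS with interaction)
  pairs:                 22350 (both active: 51.7%)
  adj. R^2 (fitted):     0.894
  R^2 additive:          0.447
  R^2 multiplicative:    0.852
  coefficients (log2 activity units):
    beta0  +0.1305  (se 0.0124)
    beta1  +1.0895  (se 0.0054)
    beta2  +0.9927  (se 0.0054)
    beta3  -0.0972  (se 0.0023)

multiplicative prediction wins for 84.1% of both-active pairs
```

The fitted coefficients recover the generating values within a few hundredths
of a log2 unit: both enhancers contribute near-unit weights (multiplicative
behaviour), and the small negative interaction term reflects the built-in
saturation. The multiplicative R² far exceeds the additive one on
multiplicative-regime data, and the best-model fraction points the same way.

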