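# pairscreen

Prediction and synergy analysis of high-order drug cocktails from
**single-dose** single-drug and drug-pair viability measurements.

Testing every cocktail drawn from a drug panel is impossible — the number of
combinations explodes with panel size. When each pair can be measured at
several doses, response-surface models interpolate the rest; but on scarce
material (patient-derived tumor samples, large screens) only a *single dose*
per drug is affordable. `pairscreen` implements the model family for exactly
that setting, for viability screens where each measurement is the surviving
cell fraction g ∈ [0, ~1] relative to untreated control.

## The models

For an M-drug cocktail with single-drug viabilities g₁…g_M and pair
viabilities g_ij, all measured at the same fixed doses:

| model | formula | noise factor (×σ) |
|---|---|---|
| Bliss independence | g = ∏ gᵢ | √M |
| **pairs model** | g = (∏ g_ij)^(1/(M−1)) | √(M / 2(M−1)) |
| regression | g = ∏ g_ij / (∏ gᵢ)^(M−2) | √(M(M−1)/2 + M(M−2)²) |
| Isserlis (M = 3, 4) | g₁g₂₃ + g₂g₁₃ + g₃g₁₂ − 2g₁g₂g₃ | — |
| log-linear family | g = (∏ g_ij)^α (∏ gᵢ)^β, β = 1 − (M−1)α | √(α²M(M−1)/2 + β²M) |

The log-linear family interpolates Bliss (α = 0), the pairs model
(α = 1/(M−1), β = 0) and regression (α = 1); the β constraint makes every
member *Bliss-conserving* (if all pairs satisfy g_ij = gᵢg_j, the prediction
collapses to ∏ gᵢ). The last column is the standard deviation of the log
prediction under independent multiplicative measurement noise of log-scale
σ per input — the pairs model is the quietest member, which is why it wins
on noisy data.

Synergy/antagonism of a measured cocktail is scored as the log deviation
from Bliss, **I = ln(1 + g_observed − ∏ gᵢ)** (I < 0 synergy, I > 0
antagonism), with significance from a percentile bootstrap over biological
repeats (5th/95th percentiles of resample means).

The package ships, as an embedded fixture, a complete published reference
screen: all 63 combinations of six chemotherapy drugs (CPT, CisPt, CbPt,
NCZ, MG132, Etopo) at LD20 doses on H1299 cells, plus the 46 combinations
retained for HeLa, with printed interaction scores and bootstrap CIs. A
synthetic-data module generates fully factorial screens with known pairwise
ground truth for benchmarking and parameter recovery.

## Worked example

```sh
pairscreen fixture --out t2.csv
pairscreen evaluate --data t2.csv --models pairs,bliss,regression
```

```
# pairscreen 0.1.0 evaluate data=t2.csv models=pairs,bliss,regression min_order=3
model,cell_lines,n_points,r2,n_skipped
pairs,H1299;HeLa,68,0.546759,15
bliss,H1299;HeLa,68,0.290241,0
regression,H1299;HeLa,68,-12.1682,15
```

Across the 68 measured cocktails of 3–6 drugs (both cell lines pooled), the
pairs model explains R² ≈ 0.55 of the variance, Bliss independence 0.29, and
the regression formula is far worse than predicting the mean (R² ≈ −12) —
its (M−2)-th-power division by singles amplifies measurement noise. The 15
skipped entries are HeLa cocktails containing the CbPt+NCZ pair, which has
no measured HeLa value.

Scanning the log-linear exponent on the triplets shows the fit peaking at
the pairs-model point α = 1/(M−1) = 0.5:

```sh
pairscreen scan-alpha --data t2.csv --order 3
# pairscreen 0.1.0 scan-alpha data=t2.csv grid=0:0.05:1 order=3 best_alpha=0.45
```

And the synergy sign of a high-order cocktail is almost always echoed by at
least one of its pairs:

```sh
pairscreen consistency --data t2.csv --cell-line HeLa
cell_line: HeLa
antagonistic (order>=3): 16 (16 with an antagonistic pair)
synergistic (order>=3): 10 (10 with a synergistic pair)
exceptions: none
```

The same analyses are available as library calls
(`pairscreen.evaluate_models`, `alpha_scan`, `pair_consistency_summary`,
`bootstrap_interaction`, `generate_screen`, …); see the module docstrings
and `docs/methods.md`.

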