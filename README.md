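# mirprofile

Chemometric calibration and ICH Q2(R1)-style method validation for
quantifying a minor analyte — linoleic acid spiked into skimmed milk — from
Fourier-transform mid-infrared (FT-MIR) absorbance spectra.

The package is aimed at analytical chemists and chemometricians who want a
reproducible, fully scriptable version of the standard workflow:

1. **Spectra** — a synthetic generator produces milk-like absorbance spectra
   on a uniform grid over 926–5012 cm⁻¹ (Beer–Lambert superposition of
   Gaussian bands, per-sample nuisance interferents, per-day offsets,
   instrument noise), with the study design baked in: a calibration set of
   7 spiking levels × 15 replicates (105 samples, each the average of two
   acquisitions) and a 3-replicate × 5-level × 3-day validation set
   (45 samples), plus blanks.
2. **Preprocessing** — removal of the O–H water regions (retaining
   [926, 1618] ∪ [1705, 3025] cm⁻¹, ≈524 points) and the usual transforms:
   standard normal variate (SNV), 11-point Savitzky–Golay smoothing and
   first/second derivatives, and their compositions.
3. **Calibration** — PLSR (NIPALS), PCR and a single-hidden-layer ANN,
   compared by an 80/20 split with 10-fold cross-validation over a
   (preprocessing × algorithm × hyperparameter) grid ranked by RMSE_CV;
   the winner is scored on the held-out test set (RMSE_P, R²_P).
4. **Band selection** — random-forest response-permutation testing: the
   forest's out-of-bag permutation importance per spectral point is
   compared with its null distribution over B refits with permuted
   response; points with p ≤ 0.05 are kept and models are rebuilt on them.
5. **Validation** — per-level trueness (bias%, recovery%), repeatability /
   intermediate precision from the one-way (day) ANOVA mean squares, LOD
   from blanks (3·S₀), and an **accuracy profile**: two-sided β-content,
   γ-confidence tolerance intervals (β = 0.667, γ = 0.9, Mee /
   Hoffman–Kringle construction) compared against ±20% acceptance limits,
   with LLOQ/ULOQ located by piecewise-linear interpolation.

The tolerance interval at a level with bias `b%` and intermediate-precision
RSD `s%` is `b ± χ_k·s`, where

```
χ_k = sqrt( k · χ²_{1,β}(λ²) / χ²_{k,1−γ} ),
k   = (R′+1)² / [ (R′+1/n)²/(m−1) + (1−1/n)/(mn) ]      (Satterthwaite df)
λ²  = (nR′+1) / (mn(R′+1))                               (SE of the mean)
R′  = max(0, (MSB/(MSE·F_{0.15; m−1, m(n−1)}) − 1)/n)     (upper bound on σ²_B/σ²_e)
```

with m days, n replicates/day, MSB/MSE the between/within-day mean squares,
χ²_{1,β}(λ²) the β-quantile of a noncentral chi-square and χ²_{k,1−γ} the
lower (1−γ) central chi-square quantile.

## Worked example

The CLI exposes every stage (`mirprofile simulate|preprocess|train|
select-bands|validate|run-all`); a full reduced-size run from Python:

```python
from mirprofile.pipeline import RunConfig, run_all

cfg = RunConfig(seed=7, methods=("RAW", "SG", "SG1"), algorithms=("PLSR", "PCR"),
                max_components=12, n_permutations=30, n_trees=100)
bundle = run_all(cfg, "runs/demo")
```

That run prints (see `runs/demo/report.md`):

```
winner: PLSR(SG, nLV=2)   R2_P = 0.998
LOD = 3.05 mg/100 mL (S0 = 1.02)
linear profile: y = 0.992 x - 1.22, R2 = 0.9986
LLOQ = 35.11, ULOQ = 100.0 mg/100 mL

level  mean   bias%   repeat.%  IP%    tolerance limits (%)
5      3.52   -29.7   20.1      37.0   [-149.1,  89.8]
10     8.80   -12.0    9.6       9.6   [ -27.8,   3.9]
20     18.70   -6.5    6.0       8.8   [ -33.3,  20.2]
50     48.49   -3.0    2.5       2.5   [  -6.9,   0.9]
100    97.91   -2.1    1.3       1.3   [  -5.1,   0.9]
```

Reading: a smoothed-spectrum PLSR with 2 latent variables wins the grid;
blank predictions put the detection limit near 3 mg/100 mL; predictions
track the spiked truth almost 1:1; and the β-content tolerance intervals
stay inside ±20% only from somewhere between 20 and 50 mg/100 mL upward at
this seed — low levels fail on both bias and precision, exactly the pattern
an accuracy profile is designed to expose.

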