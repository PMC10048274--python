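# Methods

## Scope and model

`mirprofile` implements a complete quantitative-spectroscopy workflow for a
single analyte in a complex matrix: calibration of predicted concentration
against FT-MIR absorbance spectra, data-driven selection of informative
spectral bands, and formal method validation with an accuracy profile.
The concrete system emulated is linoleic acid spiked into skimmed milk
(standard-addition design), but every stage is generic.

## Synthetic spectra

Real milk spectra for this assay are not publicly deposited, so the package
ships a generator whose output has the statistical features the downstream
methods rely on, with known ground truth.

Each spectrum on the uniform grid w (926–5012 cm⁻¹, 1060 points, step
≈3.86 cm⁻¹) is

    a(w) = baseline(w) + c · Σᵢ Aᵢ(w) + z · Σⱼ Iⱼ(w) + d + ε(w)

* `baseline` — six broad Gaussians, including strong water bands inside the
  omitted O–H bending (1600–1710 cm⁻¹) and stretching (3020–5012 cm⁻¹)
  windows, which is why those windows are masked.
* `Aᵢ` — six analyte Gaussians with responses in AU per (mg/100 mL),
  placed inside the regions that carry fatty-acid information in real milk
  spectra: C–O–C ester stretch (940–1215), CH bending / ester Fermi
  resonance (1342–1489), carbonyl stretch (1720–1766) and C–H stretch
  (2823–2935 cm⁻¹). Band shape is Gaussian — the simplest smooth unimodal
  choice; nothing downstream depends on the exact line shape.
* `Iⱼ` — five interferent Gaussians scaled by a per-sample lognormal
  nuisance covariate z (σ = 0.4), a proxy for residual fat/protein
  variation. Two interferents overlap analyte regions so that band
  selection is non-trivial.
* `d` — an additive baseline offset shared by all spectra of one day
  (σ_day = 0.003 AU), the simplest random-effects structure matching the
  between/within-day ANOVA of the validation stage. A multiplicative
  per-day gain is available but off by default.
* `ε` — iid Gaussian instrument noise, σ_noise = 0.025 AU per acquisition;
  each sample averages two acquisitions.

Magnitudes are free parameters, not literature values. They were fixed once
so that the default pipeline behaves like a realistic mid-IR assay of a
minor component: hold-out RMSE_P ≈ 2–3 mg/100 mL over the 1–100 mg/100 mL
range (R²_P ≈ 0.99), a detection limit of a few mg/100 mL, every planted
analyte band recoverable by permutation selection, and day-to-day effects
of 1–2 mg/100 mL in prediction space so intermediate precision visibly
exceeds repeatability at some levels.

What the generator does **not** emulate: instrument physics (interferogram,
FFT, apodisation), scattering artifacts, wavelength calibration drift,
correlated (pink) noise, and real covariance between milk constituents.
Passing tests therefore demonstrate correctness of the statistical
machinery under a plausible data-generating model, not performance on real
milk spectra.

Study design defaults follow the emulated assay: calibration 7 levels
{1, 5, 10, 20, 50, 70, 100} × 15 replicates = 105 samples; validation
3 replicates × 5 levels {5, 10, 20, 50, 100} × 3 days = 45 samples;
10 blanks for the LOD.

## Preprocessing

Masking drops grid points strictly inside the omit windows
(1618–1705 and >3025 cm⁻¹ by default); interval ends are kept, so the
retained regions are the closed intervals [926, 1618] ∪ [1705, 3025],
≈524 points on the default grid.

SNV divides by the sample SD (ddof = 1, configurable). The Savitzky–Golay
filter uses an 11-point window and polynomial order 2 by default (order
exposed in the method object); derivatives are analytic derivatives of the
local fit scaled by the grid step, so they are per cm⁻¹. At the spectrum
ends the window is truncated to the available points and the polynomial
refit — no padding, no fabricated data; polynomials up to the fit order are
reproduced exactly along the whole spectrum, edges included. Compositions
apply SNV first, then the SG smoothing/derivative.

## Calibration models

* **PLSR** — NIPALS with y-deflation, single response. The implementation
  keeps the regression-coefficient vector after every extracted component,
  so cross-validating component counts 1..A costs one decomposition per
  fold. Requests beyond the effective rank truncate with a warning. At full
  rank PLSR equals OLS on the centred data (tested to 1e−8).
* **PCR** — SVD of the mean-centred spectra (no variance scaling), OLS on
  the leading scores; score orthogonality again yields the whole component
  path from one decomposition. The minimum number of components explaining
  95% of spectral variance is reported informationally; the grid search is
  the primary component-choice mechanism.
* **ANN** — one hidden layer of logistic units, linear output, L2 penalty
  (`decay`), trained full-batch with L-BFGS (deterministic for a fixed
  seed). Inputs standardised, response min-max scaled internally. The decay
  grid is {0, 1e-4, 1e-3, 1e-2, 0.1, 0.2, 0.3, 0.4, 0.5}; hidden sizes
  1–6.

Model selection: random 80/20 split (test size = round(0.2·n); 105 → 21),
10-fold CV on the training part, candidates ranked by RMSE_CV = mean of
per-fold RMSEs (SD across folds reported alongside). R² is defined as
1 − SS_res/SS_tot pooled over held-out predictions, for CV and for the test
set alike. Negative predicted concentrations are reported, not clipped.

## Band selection

A regression random forest (500 trees by default; mtry = p/3 and node size
5, the conventional regression defaults) supplies per-point importance as
the mean increase in out-of-bag MSE when that point is permuted among each
tree's OOB samples. Features a tree never splits on contribute exactly zero
for that tree, which the implementation exploits for speed. Node-impurity
importance is available as an option.

Significance comes from refitting the forest B times (1000 by default)
with the response permuted: p = (1 + #{null ≥ observed})/(B + 1), the
add-one estimator that avoids zero p-values. Selection keeps p ≤ 0.05 (the
inclusive convention) with no multiple-testing correction — the selector is
a screening step, and its type-I behaviour is tested directly. Adjacent
selected points merge into reported regions; a wavenumber gap wider than
1.5× the median grid step (e.g. across the masked water window) splits
regions.

Practical note on the permutation null: p-values can only be approximately
uniform when every feature is split on at least once per forest, since
never-used features tie at exactly zero importance. With ~200 candidate
points this needs of the order of 150+ trees.

## Validation statistics

Per level, the m×n day-by-replicate matrix of predicted concentrations
yields bias% = 100(Ȳ−Yr)/Yr and recovery% = bias% + 100 (identities tested
to machine precision), the one-way ANOVA mean squares MSB/MSE, repeatability
σ_Re² = MSE and total intermediate precision σ_IP² = MSE + (MSB−MSE)/n when
MSB > MSE, else the pooled variance (divisor mn−1) for both. Defining
intermediate precision as the *total* SD — not the between-day component
alone — keeps σ_IP ≥ σ_Re by construction, as a precision hierarchy must.

LOD = 3·S₀ with S₀ the sample SD of blank predicted concentrations.

### Tolerance intervals

The two-sided β-content, γ-confidence interval on the relative scale is
bias% ± χ_k·RSD_IP%, with the Mee / Hoffman–Kringle factor

    χ_k = sqrt( k · Qncχ²(β; df=1, nc=λ²) / Qχ²(1−γ; df=k) ).

`k` is the Satterthwaite effective df of σ̂_IP² = MSB/n + (1−1/n)·MSE and
λ² = (nR′+1)/(mn(R′+1)) is the squared standardised SE of the grand mean;
both are evaluated at R′, a truncated **upper** confidence bound on the
variance ratio σ_B²/σ_e²:

    R′ = max(0, (MSB/(MSE·F_{0.15; m−1, m(n−1)}) − 1)/n).

Two conventions here are deliberate and were checked by simulation:

* the denominator of χ_k is the **lower** (1−γ) chi-square quantile — an
  upper quantile would shrink intervals as confidence rises, inverting the
  meaning of γ;
* R′ divides MSB/MSE by a **lower** F quantile (equivalently multiplies by
  F_{0.85; m(n−1), m−1}), giving an upper bound on the ratio. Dividing by
  the upper 0.85 quantile instead — a reading sometimes seen in print —
  gives a lower bound and, at m = n = 3 with σ_B = σ_e, an empirical
  confidence of only ≈0.76 against the nominal γ = 0.9; the upper-bound
  convention achieves ≈0.92 (2000 simulated datasets,
  `coverage_simulation`). A consequence of the upper bound is that R′ > 0
  can occur even when MSB ≤ MSE; truncation applies below
  MSB/MSE = F_{0.15; m−1, m(n−1)} < 1.

The construction is approximate and conservative: empirical confidence sits
slightly above γ and approaches it from above as the number of series m
grows. Negative variance estimates are truncated at zero throughout.

### Accuracy profile and quantification limits

A level passes when its tolerance interval lies inside the acceptance band
(±20% by default; the intermediate-precision CV > 20% is flagged
separately). LLOQ/ULOQ are found on the longest contiguous run of passing
levels, refining the edges by piecewise-linear interpolation of each limit
against concentration; where both limits cross, the later (higher-
concentration) crossing is the LLOQ. Applied to the published per-level
limits of the emulated assay (upper limits 28.21% at 10 and 13.41% at
20 mg/100 mL), the interpolation returns LLOQ ≈ 15.55 mg/100 mL, which
`scripts/acceptance.py` recomputes.

The per-level tolerance limits printed in the source validation table are
not internally reconcilable with its own bias/precision columns (the
implied χ_k varies by an order of magnitude across levels), so those limit
values are used only as interpolation inputs, never as oracles for the
interval construction itself.

## Problem sizes in tests

The test suite runs everything at desk scale, chosen once: band-selection
tests use 40–200 permutations and 60–150 trees (the library defaults
remain B = 1000, 500 trees); the 10-seed calibration/parity study uses a
PLSR component grid of 1..15 with Savitzky–Golay preprocessing; the
confidence simulation uses 2000 datasets at m = n = 3. These sizes are
statements about what the tests demonstrate, and all thresholds
(R²_P ≥ 0.95, parity within 0.03, confidence ≥ 0.85, type-I within two
binomial SEs of α) were fixed before the sizes were tightened.

## Known limitations

* The synthetic generator's realism gaps listed above; in particular the
  day effect is a flat offset, which derivative/SNV preprocessing removes
  almost entirely — a real day effect would be messier.
* The ANN is a small dense network; no early stopping or architecture
  search beyond the size/decay grid.
* Only balanced validation designs (equal replicates per day) are
  supported, matching the factorial protocol.
* β-expectation (Student-t) intervals, uncertainty profiles and Bayesian
  tolerance methods are out of scope.
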