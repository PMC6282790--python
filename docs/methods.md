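# Methods

## The measurement model

Micellar liquid chromatography (MLC) runs a reversed-phase column with a
surfactant solution above its critical micellar concentration (CMC) as
mobile phase. A solute that partitions into the micelles elutes faster
as the micellar concentration rises. For a binding solute the retention
factor

    k' = (t_R - t0) / t0

follows the partitioning law

    k' = k'0 / (1 + K_AM * C_M),

so 1/k' is linear in the micellar concentration C_M with intercept 1/k'0
and slope K_AM/k'0. Ordinary least squares on the (C_M, mean 1/k')
points gives the micelle–water association constant K_AM =
slope/intercept and the partition coefficient log P_mw = log10(K_AM).
Replicate retention factors are averaged per concentration level before
the reciprocal line is fitted. An antibinding solute (retention rising
with C_M) produces a negative reciprocal slope; classification uses a
two-sided t test on the slope (default alpha = 0.05), since slopes
indistinguishable from zero support neither class.

The ratio convention deserves a note: the published formula prints
"log intercept/slope", but for binding solutes with log P_mw in the
observed 0.93–2.96 range only slope/intercept (the standard
Armstrong–Nome relation) produces association constants of the right
magnitude over the C_M range used. The package therefore defaults to
slope/intercept; the literal intercept/slope ratio is available through
`convention="intercept_over_slope"` and every fit records which
convention produced it.

## The micellar mobile phase

The reference mobile phase is a mixture of six bile salts (NaTC, NaTDC,
NaDC, NaC, NaGC, NaGDC at 2.71, 2.00, 2.08, 2.08, 4.70, 3.43 mM; total
17.00 mM) with 0.75 mM egg phosphatidylcholine, in 10 mM HEPES pH 6.5
and 0.15 M NaCl — the composition and ratios of human intestinal fluid.
Design choices:

* the "total surfactant concentration" is the bile-salt total; lecithin
  is tracked but excluded (the printed six concentrations sum to exactly
  17.00 mM with lecithin listed separately);
* the mixture CMC is the **unweighted** arithmetic mean of the component
  CMCs in 0.15 M NaCl (0.004, 0.0024, 0.0024, 0.0075, 0.009, 0.0022 M →
  0.004583 M, i.e. 0.0046 M to two significant figures); a mole-fraction
  weighted mean does not reproduce the working value;
* C_M = total − mixture CMC by default. The 2 mM diluting mixture is the
  constant monomer background of the dilution design, and an optional
  `monomer_background` argument subtracts that instead for users who
  prefer the constant-monomer reading;
* preparation bookkeeping is in mM, all C_M values exposed to the
  retention model are in M.

Dilution targets must lie in (diluent, stock]: pure diluent sits at the
monomer background, below the mixture CMC, and is not a usable level.

## The absorption model

Percentage human intestinal absorption is bounded, so the response is
the base-10 logit

    logit(%HIA) = log10( %HIA / (100 − %HIA) ),

undefined at 0 and 100% — such compounds are excluded from training.
The model is OLS with intercept:

    logit(%HIA) = b0 + b1 * logP_mw + b2 * PSA.

Diagnostics follow standard definitions: R² and adjusted R² on the
0–100 scale; S = sqrt(SSE/(n−p−1)) in logit units; overall F with its
F-distribution p-value; per-coefficient t statistics and 95% confidence
intervals from the t distribution with n−p−1 df; standardized
coefficient b_j·sd(x_j)/sd(y); VIF_j = 1/(1−R²_j) from regressing x_j
on the other predictors (1 when only one predictor remains).
Predictive ability uses PRESS through the hat-matrix identity
PRESS = Σ(e_i/(1−h_ii))², with R²_PRED = 100·(1 − PRESS/SS_total);
a leverage of 1 makes PRESS undefined and raises. Back-transformed
predictions use 100·10^L/(1+10^L); rounded values use
nearest-integer, half away from zero.

Backward elimination runs in two phases: first the predictor with the
highest VIF is dropped while any VIF exceeds `vif_limit` (default 10,
an accepted rule-of-thumb; VIFs here are computed directly from the
design matrix so an exactly collinear pair resolves to an infinite VIF
instead of a singular fit), then the predictor with the largest p-value
is dropped while it exceeds `alpha_remove` (default 0.05, matching the
significance level reported for the retained terms), refitting at every
step. If everything is eliminated an intercept-only fit is returned
with a warning. The published elimination started from nine candidate
descriptors whose values are not tabulated, so that exact path cannot
be replayed; the procedure is validated on synthetic data with a known
generating model instead.

The bundled 18-compound table carries the published log P_mw and PSA
values with experimental %HIA; the three footnoted validation compounds
(acetaminophen, ibuprofen, salicylic acid) are flagged
`role=validation`, leaving 15 training compounds. Acetaminophen has
%HIA = 100, so the exclusion rule and the validation designation
coincide for it. Refitting reproduces every printed statistic to within
the tolerances expected from 2-decimal rounding of the tabulated
predictors, and 16 of the 18 rounded %HIA predictions match the printed
column (fenoprofen and naproxen differ by one unit). The printed
overall-model p-value (0.007) is inconsistent with F = 38.12 at (2, 12)
df; the reproduction report shows the F-distribution value (≈7·10⁻⁶)
with a note rather than echoing 0.007.

## Synthetic data

The generators exist so every stage is testable without instruments.

* **Retention tables**: t_R = t0·(1 + k'(C_M))·(1 + ε) with
  multiplicative noise ε ~ N(0, cv²) — chromatographic retention
  variability is proportional to retention time. Defaults mirror the
  reference experiment: six levels evenly spanning 5–17 mM total
  surfactant (C_M after subtracting the 0.0046 M CMC), three replicate
  injections, t0 = 1.5 min, 1% retention-time CV. Antibinding is
  simulated with negative K_AM restricted to K_AM·C_M > −1.
* **Chromatograms**: Gaussian analyte peak at the simulated retention
  time, optional solvent-front Gaussian at t0, linear baseline drift,
  additive detector noise. No tailing, pump pulsation or column aging —
  passing peak-picking tests shows apex localisation on symmetric
  peaks, not robustness to asymmetric real traces.
* **Compound tables**: predictors uniform over ranges covering the
  studied drugs (log P_mw 0.9–3.0, PSA 37–89 Å²), response from the
  published coefficients (4.103, −0.939, −0.02218) with logit noise
  SD 0.247 — the fitted residual standard error. Records whose %HIA
  rounds to 0 or 100 at double precision are redrawn so every record
  has a defined logit; this truncates the extreme noise tail very
  slightly, which is irrelevant at the default noise scale.

All generators are deterministic given a seed (numpy `default_rng`).

## Numerical choices and degenerate inputs

* Peak picking: centred moving-average smoothing (default 5 samples),
  global maximum; multi-peak mode uses prominence above 5× the baseline
  noise SD estimated by the median absolute deviation of the first 5%
  of samples. Flat traces (range below that floor) raise rather than
  return a spurious apex.
* Dead time below 10 replicates warns (protocol calls for ≥10) but
  still returns the mean; non-positive times raise.
* A retention time before the solvent front raises — it cannot yield a
  physical k'.
* Reciprocal fits require ≥3 distinct levels and all k' > 0; a
  non-positive fitted intercept (non-physical k'0) raises.
* Fits are unweighted OLS throughout.

## Problem sizes

Tests run the refit on the 15-compound table, property checks on
50-replicate batches of small random datasets, 200-seed recovery
simulations for the noisy retention round trip, and n = 100–200
synthetic compounds for elimination and coverage checks; the whole
suite completes in a few seconds.

## Known limitations

* Table 1 log P_mw values are inputs, not recomputed: the raw retention
  times behind them are not published. The retention stage is validated
  by round trips against its own generating law.
* Only the linear 1/k' treatment is implemented; the Foley and
  Arunyanart–Cline-Love variants are out of scope.
* Descriptor calculation from structure (PSA etc.) is out of scope;
  descriptors are taken as given.
* The model is a 15-compound regression over a narrow chemical space;
  nothing here estimates an applicability domain.
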