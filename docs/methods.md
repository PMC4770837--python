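# Methods

This note documents the quantitative model behind `vnaflow`: the
quantitation chain, the rule engines, the validation estimators, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Quantitation chain

**Calibration.** For each analyte the response ratio
R = quant-ion area / ISTD area is regressed on the known amount ratio
x = native mass / ISTD mass by weighted least squares (statsmodels WLS),
with weights `none`, `1/x` or `1/x²` (default `1/x²`). The default curve
has 8 levels log-spaced from 0.5 % to 100 % of the 400 ng/mL top standard.
Acceptance requires ≥ 3 distinct levels and a positive slope; r² is
reported on the weighted fit, and per-level back-calculation residuals are
carried as diagnostics. The weighting default matters: the noise on
response ratios is dominated by a proportional component, for which `1/x²`
is the inverse-variance choice; with `1/x` the extrapolated intercept picks
up error from the mid- and high-level calibrants and the resulting run-level
offset at pg/mL concentrations (~2.4 pg/mL) would exceed the method's
characterized near-zero imprecision. Both alternatives remain configurable.

**Units.** All calibration is done in dimensionless amount-ratio space. The
bridge between the solution-phase calibrants (ng/mL) and the urine scale
(pg/mL) is the nominal 20× extract concentration factor (2 mL urine worked
down to ~100 µL of extract), so the top standard corresponds to an amount
ratio of 80 and 1 unit of amount ratio to 250 pg/mL of urine (500 pg ISTD /
2 mL). Unknowns at tens of pg/mL therefore back-calculate below the lowest
calibrant; the linear curve extrapolates, which is why the intercept
stability discussed above is the binding constraint.

**Blank subtraction.** Each batch carries two DCM blanks (first and last
plate wells). Per analyte, the mean of their calculated concentrations is
subtracted from every other result of the batch. The blanks keep their raw
values so run rejection sees the uncorrected background. Negative corrected
concentrations are reported as-is and flagged `below_lod` (never clamped),
keeping batch statistics unbiased. Subtraction also removes any run-common
additive offset, including calibration-intercept error — this is what makes
the scheme robust near the detection limits.

## QA rules

Per (sample, analyte) the engine emits exactly one flag per rule:
quant-peak RT and ISTD RT within ±0.1 min of expectation; confirmation/
quant ion-area ratio within ±20 % (relative, closed interval) of the
expected ratio; ISTD area ≥ 50 000 counts; batch blank status; the
carryover-follow rule; and a quantifiability guard (ISTD area zero marks
the injection unquantifiable instead of raising). RT tolerance, ratio
tolerance and the ISTD floor are method-configuration values, not printed
constants; the defaults are documented working values.

Run rejection is strict: a DCM blank (and, if enabled, the batch-opening
ACN blank — the three purge blanks after the top standard are exempt)
*exceeding* its per-analyte blank limit rejects the run; a blank exactly at
the limit passes. Shipped blank limits default to 2× the characterized LODs
and are placeholders pending a local multi-run blank characterization.

Carryover: an unknown whose immediately preceding injection carried any
analyte above 200 pg/mL (strict, on blank-subtracted values) is flagged for
reinjection; all its analytes are flagged because the vial is reinjected
whole, and the trigger uses the predecessor's maximum across analytes
(conservative — the rule names no analyte). Reinjections are accepted by the
tiered repeatability criterion |a−b|/mean ≤ 20 % below 50 pg/mL and ≤ 10 %
at or above (the denominator is the pair mean; two exact zeros pass); a
passing pair reports the reinjection value, a failing pair sends the sample
to re-preparation.

## Westgard batch QC

QC pools at 50 and 200 pg/mL are converted to z-scores against a *frozen*
characterization (mean, SD per pool; in-flight batches never update it, so
drift cannot mask itself). The engine implements 1₂ₛ, 1₃ₛ, 2₂ₛ, R₄ₛ, 4₁ₛ
and 10ₓ with per-rule enable/disable, warn/reject action, and within-pool /
across-pool / both scoping, so any plausible "modified" multirule scheme is
expressible in configuration. Defaults: 1₃ₛ, 2₂ₛ, R₄ₛ reject; 1₂ₛ warns.
All excursions are strict inequalities; streak rules (2₂ₛ within-pool, 4₁ₛ,
10ₓ) consume a supplied window of recent historical values. Note that 10ₓ
is magnitude-blind by definition, so "everything within ±1 SD" only
guarantees acceptance for rule sets without mean-side streak rules — the
default set has that property. Enabling additional rules can only add
rejections (monotonicity), which the tests assert.

The shipped characterization (SD 4.1 pg/mL at the low pool, 14.3 pg/mL at
the high pool, n = 60) equals the pools' total imprecision — intra-run,
between-run, integration floor and blank-subtraction noise — at the
generator's default operating conditions, i.e. what a real ≥ 20-run
characterization would converge to; it is a placeholder for a lab's own
history.

## Validation estimators

**3·S₀ detection limit.** Per-pool SDs from the 0/2.5/5/7.5 pg/mL study are
regressed on nominal concentration by unweighted OLS; S₀ is the intercept
and LOD = 3·S₀. Sample SDs are divided by the normal-theory constant c₄(n)
first (≈ 0.4 % at n = 60): without this the extrapolated intercept is
biased low by more than the Monte-Carlo error of a 500-study parameter-
recovery check, and the estimator should be unbiased by construction. The
SD-input path (`lod_3s0_from_sds`) takes SDs as given, so an exactly linear
profile (2.0, 2.1, 2.2, 2.3) returns 6.0 exactly. A non-positive intercept
aborts with advice to use the CLSI route.

**CLSI LoB/LoD.** Parametric, EP17-style with z = 1.645:
LoB = mean(blanks) + 1.645·SD(blanks), LoD = LoB + 1.645·SD(low pools),
low-pool SDs pooled by degrees of freedom. Used for NPYR, whose blanks are
clean.

**Precision.** Intra-run CV per run (100·SD/mean, ddof = 1), inter-run CV
as the CV of the run means with n = the number of runs — a deliberate
choice over an ANOVA variance decomposition, matching how such tables are
conventionally labeled. CVs are exactly scale-invariant.

**Accuracy.** Matrix spike recovery per value is
(measured − mean unspiked baseline)/nominal × 100, summarized as mean and
CV per level over the 9 values of the triplicate × 3-day design. The
second-source solution check back-calculates fresh calibrators at 0.5/25/
50 % of the top standard through the working curve and compares the mean
per-level accuracy against a configurable 90 % floor.

## Synthetic-data generator

The generator emulates integrated peak tables, not chromatograms. Per
injection and analyte:

    quant_area = g · x · istd_area · (1 + ε_prop) + ε_add,  truncated at 0

with ISTD areas ~ N(2×10⁵, 5 %), ε_prop ~ N(0, 5 %) for prep-processed
samples and N(0, 1 %) for solution calibrants (isotope dilution cancels
most instrument noise; the 5 % is dominated by preparation, which
calibrants skip), and ε_add ~ N(0, 1000 counts) — an integration floor of
≈ 1.25 pg/mL that, combined with calibration-transfer error, reproduces the
method's ≈ 2.2 pg/mL total near-zero imprecision. Confirmation-ion areas
track the expected ratio with 2 % noise; retention times jitter by 0.01 min.
One multiplicative run factor ~ N(1, 5 %) per batch applies to everything
that passes through sample preparation (not the calibrants), which is what
makes between-run CVs exceed within-run CVs on average. Blanks carry only
process contamination — NDMA at 9.81 pg/mL (~1.5× LOD), the other
positive-blank analytes at ~0.5× LOD, NPYR clean. Carryover adds 0.2 % of
the previous same-analyte injection's area for NDMA/NMEA/NDEA only; the
three ACN purge blanks after the top standard absorb it, exactly as the
sequence layout intends. A single RNG keyed by (seed, batch id) makes every
batch independently and exactly reproducible.

The validation-study designs are generated directly on the concentration
scale: the 60-run LOD design draws pool values with the linear SD profile
S₀ + 0.02·conc that the 3·S₀ extrapolation assumes, with per-analyte S₀
defaults equal to the method's characterized detection limits divided by 3
(NPYR: divided by 2×1.645, inverting the CLSI formula); the precision and
accuracy designs use the proportional + run-factor + floor model above.
Unknowns default to plausible mixed-population urine levels
(8–30 pg/mL), endogenous baselines to small positive values for
NDMA/NPYR/NMOR and zero otherwise, and spike recovery to unbiased (1.0).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: chromatographic peak-shape pathology (tailing,
co-elution, integration-baseline artifacts), heavy-tailed or correlated
noise, matrix effects that vary by donor, ISTD degradation, drift within a
run, and truly out-of-control QC excursions. The noise model is Gaussian
and truncation at zero is its only non-linearity; one visible artifact is
that analytes with (near-)zero blank contamination acquire a small
rectified-noise background (~+0.8 pg/mL for NPYR), which blank subtraction
then removes from — i.e. subtracts out of — every sample.

## Numerical choices and degenerate inputs

Zero ISTD area → unquantifiable flag, never an exception; a batch without
exactly two quantifiable DCM blanks per analyte is unreportable; constant
QC history (SD 0) is a characterization error; a zero mean makes a CV
undefined (error); repeatability at mean 0 passes only for an exact (0, 0)
pair. LIMS concentrations are exported at 3 decimal places, which is why
the export/re-import round trip is bit-exact. With every noise term zero
the full simulate → quantify → subtract chain is the identity to machine
precision, and the tests pin that at ≤ 10⁻⁹ relative.

## Scales used by the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen as the package's own study sizes: 60-run detection-limit
studies (averaged over 5 replicate studies in the acceptance script),
6 × 5 precision and 3 × 3 × 3 accuracy designs, 100-batch conservation
sweeps, 500-study parameter-recovery checks, and 10⁵ QC draws for the
false-rejection rate of 1₃ₛ (expected 0.27 % per QC for in-control
Gaussian controls).

## Known limitations

Reinjection resolution is bookkeeping only (no scheduler); calibration is
strictly linear (no quadratic mode, no standard addition); QC
characterization must be refreshed explicitly; the Westgard 4₁ₛ/10ₓ
across-pool scopes assume exactly two pools; and the LIMS file is a
documented generic CSV dialect, not any vendor's native format.
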