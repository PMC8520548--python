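# Methods

## The measurement model

A same-day VP SPECT study pair yields four raw observables per patient:
the summed projection counts of the ventilation scan in the photopeak
(primary) and adjacent Compton-scatter energy windows, the summed
photopeak counts of the perfusion scan, and the photopeak counts of a
60 s planar static of the MAA injection site. Together with the
radiopharmacy dispense record (activity and time) these determine the
derived measures:

| measure | definition | units |
|---|---|---|
| E_ratio | ventilation primary / scatter window counts | — |
| VCR | ventilation primary counts / t1 | cps |
| PVCR | perfusion primary counts / t2 | cps |
| PCR | PVCR − DF(Δt_VP) · VCR | cps |
| P/V | PCR / VCR | — |
| A_inj | ICR / DF(Δt_PS) / S | MBq |
| A_sys | DF(Δt_DP) · A_disp − A_inj | MBq |
| PCR_norm | PCR / A_sys / S | — |

with t1, t2 the scan durations (frames × frame duration), S the
camera–collimator sensitivity (cps/MBq), ICR the injection-site count
rate, and DF(Δt) = 2^(−Δt/T½) the Tc-99m decay factor over the interval
Δt (T½ = 6.0067 h = 21 624.12 s, configurable).

**Decay-correction convention.** `decay_factor` takes a non-negative
elapsed time and returns a fraction ≤ 1. A quantity measured *later*
than the reference time is corrected back by *division*; a quantity
fixed *earlier* is carried forward by *multiplication*. The convention
matters for A_inj: the static image is acquired after the perfusion
SPECT, so its count rate is divided by the decay factor, which
guarantees A_inj ≥ ICR/S as physics requires. The residual ventilation
term in PCR is the opposite case (ventilation precedes perfusion) and
is multiplied. All intervals are differences of acquisition-start
timestamps; decay *during* an acquisition is neglected, consistent with
using whole-scan count sums.

Known, uncorrected simplifications: residual syringe activity is not
measured (A_sys slightly overestimates the systemic activity),
radiochemical purity is taken as 100%, and right–left shunting of MAA
is not modelled.

## The regression and prediction intervals

PCR_norm is regressed on E_ratio by ordinary least squares (delegated
to statsmodels; tests cross-check against closed-form normal
equations). The shipped clinical constants are slope 0.28, intercept
−0.198, n = 342, MSE = 0.001089, x̄ = 1.83. The predictor sum of
squares Σ(x_i − x̄)², needed for prediction intervals but not part of
the published constants, is reconstructed from the predictor SD as
341 × 0.21² = 15.0381; the 1/n and (x_h − x̄)²/Sxx terms it enters are
small corrections, so the reconstruction error is negligible. Student-t
quantiles on n − 2 degrees of freedom are evaluated at run time.

A new observation's interval is ŷ ± t(α/2, n−2) ·
sqrt(MSE (1 + 1/n + (x_h − x̄)²/Sxx)); 0.90 and 0.95 are the levels
offered in routine use. The interval is narrowest at x_h = x̄ and its
empirical coverage under the generative model is within Monte-Carlo
error of nominal (the t-based width is marginally conservative because
it also accounts for estimation error the generator does not have).

**P/V under a planned delay.** The predicted perfusion count rate for a
dose A is A · S · ŷ. The ratio denominator is the *residual* ventilation
rate at perfusion start, VCR · DF(delay): with zero delay this is
exactly the measured-VCR definition above, and with a positive delay it
is the quantity a deferred perfusion scan actually competes against.
Interval bounds for P/V are the PCR_norm bounds pushed through the same
strictly increasing linear map; VCR is treated as measured without
error. The predictor range x̄ ± 3 SD flags extrapolation.

## Planning

Inverting the prediction gives the two planning primitives:

- required immediate dose: A = target_PV · VCR / (S · ŷ);
- required delay at a fixed dose:
  delay = max(0, T½ · log2(target_PV · VCR / (A · S · ŷ))).

The two are exact inverses of the forward prediction (unit-tested to
1e-9). The built-in recommendation policy is dose-sparing: hold the
dose at the target (default 120 MBq, the same-day protocol
recommendation, with 185 MBq as the package-insert maximum) and defer
the perfusion scan by the required delay when the immediate prediction
falls short of P/V = 3. Prediction-interval bounds accompany each
recommendation, but the point estimate drives the decision. Delay is
stored in seconds and reported in minutes.

The impact simulation replays this policy over a cohort whose true
PCR_norm is known (synthetic ground truth standing in for the
retrospectively computable perfusion rate per MBq), after normalising
each VCR to the recommended 2-million-count ventilation total. Per
study it reports the blind dose immediate injection would truly have
required, dose spared by deferral, and unnecessary/insufficient delay
(tool-recommended minus truly required, clipped at zero in each
direction). Validation accuracy is the mean absolute percentage error
(MAPE) of predicted versus actual P/V ratios; dose, sensitivity and VCR
scale both ratios of a study identically, so this equals the MAPE on
PCR_norm itself.

## The synthetic-data generator

`synthetic_data.generate_cohort` emulates a clinical cohort study by
study: E_ratio ~ Normal(1.83, 0.21) (training profile; validation
profile Normal(1.80, 0.23)) truncated to > 0.8; true PCR_norm =
0.28 · E_ratio − 0.198 + Normal(0, √0.001089), resampled if ≤ 0.05 (both
floors are generator artefacts guarding against the unphysical
negatives a linear-Gaussian model can produce; essentially never active
at the defaults); systemic activity ~ Normal(114.8, 8) MBq (validation:
118.4, 9.9); injection-site residual ~ Uniform(0.2, 2.0) MBq, a
package choice for a quantity reported only via excluded misinjections.
Raw observables are then constructed *backwards* so the full pipeline
reproduces the ground truth: ventilation photopeak counts fixed at
2 × 10⁶ (optional Poisson jitter, off by default so identity tests are
exact), scatter counts = primary/E_ratio rounded, perfusion counts =
(PCR_norm·S·A_sys + DF·VCR)·t2 rounded, static counts and dispense
activity back-computed through the decay chain. Default clinic timings:
dispense 30 min before ventilation; perfusion immediately after
ventilation; static 5 min after the perfusion scan ends. E_ratio and
VCR are generated independently — their true joint distribution in the
clinic is unknown.

The DICOM fixture writer emits minimal but structurally valid NM
multi-frame objects (two energy windows at the protocol thresholds, 120
frames per window mapped by the EnergyWindowVector, protocol timing,
rotation and collimator tags) whose per-window pixel sums equal the
cohort totals exactly, plus injection-site statics and a dispense CSV.
Images are uniform count fields: only count sums matter downstream, so
no anatomical realism is attempted.

**What passing tests show — and don't.** The generator reproduces the
first two moments of the reported cohorts and the generative regression
structure, so tests demonstrate that the pipeline arithmetic, model
fitting, interval construction and planning inversions are correct and
that the fit statistics and validation MAPE are what that model implies
at the reported sample sizes. It does not emulate attenuation physics,
scatter spatial structure, camera dead time, or the clinic's joint
distribution of count rates and body habitus; real-cohort impact counts
(numbers of deferred patients, median sparing) are data-dependent and
are checked for order of magnitude only. With ventilation totals fixed
at 2 × 10⁶ counts, the generator's mean P/V (≈ 2.9) is lower than the
reported clinical mean (≈ 4.0), which reflects the clinic's variable
ventilation count totals that neither profile parameterises.

## Numerical and QC choices

- Energy-window QC tolerance ±0.5 keV, absorbing the GE/Siemens upper
  threshold difference (151 vs 150.5 keV); frame duration distinguishes
  the two profiles for ventilation scans.
- Count-anomaly flag: ventilation E_ratio outside the training mean
  ± 3 SD (1.83 ± 0.63, configurable) warns of extracorporeal
  contamination or extrapolation; the flag is advisory, mirroring
  outlier handling by inspection rather than hard exclusion.
- Misinjection flag at A_inj > 20 MBq (configurable; chosen between
  typical sub-2 MBq portal residuals and the 36/83 MBq excluded cases).
- Zero scatter counts, non-positive predicted count rates, negative
  intervals, and dispense-after-scan records raise typed errors rather
  than propagating NaNs.
- Problem sizes in the standard checks: 200 simulated cohorts for fit
  statistics and MAPE, 10 000 points for interval coverage, four-study
  cohorts for DICOM round-trip tests — all chosen to keep Monte-Carlo
  error well inside the assertion tolerances.
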