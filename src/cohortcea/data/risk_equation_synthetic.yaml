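# SYNTHETIC stand-in risk equation (not a published tool).
#
# Logistic model for 10-year risk of a first acute cardiovascular event
# (myocardial infarction or cerebrovascular disease) from age, sex,
# systolic blood pressure and current smoking.  The coefficients below
# were chosen once for epidemiological plausibility (roughly 8% 10-year
# risk for a 50-year-old male hypertensive non-smoker with SBP 154 mmHg)
# and are NOT estimates from any cohort.  Substitute a manifest for a
# validated risk tool to reproduce real-world results.
name: synthetic-logistic-cvd
form: logistic
horizon_years: 10
coefficients:
  intercept: -2.7        # log-odds at age 60, female, SBP 140, non-smoker
  age_per_year: 0.07     # centred at age 60
  male: 0.55
  sbp_per_mmhg: 0.03     # centred at 140 mmHg
  smoker: 0.60
centering:
  age: 60.0
  sbp: 140.0
validity:
  age: [30, 100]
  sbp: [90, 220]
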