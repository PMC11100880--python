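# SYNTHETIC life-table manifest (not national statistics).
#
# Gompertz-Makeham hazards h(x) = makeham + baseline * exp(slope * x)
# per sex, ages 0-100, terminal qx forced to 1.  Baselines were tuned
# once with cohortcea.synthetic.tune_gompertz_baseline so that the
# undiscounted (curtate) life expectancy at age 50 is 30.0 y for men
# and 32.6 y for women, a plausible band for a middle-income country.
male:
  baseline: 1.937826357118828e-05
  slope: 0.1
  makeham: 0.0015
  target_le50: 30.0
female:
  baseline: 1.4808142242506246e-05
  slope: 0.1
  makeham: 0.0010
  target_le50: 32.6
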