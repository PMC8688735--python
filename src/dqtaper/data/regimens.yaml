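# Default TNFi regimen registry: standard (full) dose and dosing interval.
# Doses in mg (infliximab in mg per kg body weight); intervals in days.
# Override with your own file via `load_registry(path)` or the CLI
# --registry option.
etanercept:
  standard_dose: 25.0
  standard_interval: 3.5
adalimumab:
  standard_dose: 40.0
  standard_interval: 14.0
golimumab:
  standard_dose: 50.0
  standard_interval: 28.0
infliximab:
  standard_dose: 5.0
  standard_interval: 56.0
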