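# Desk-scale pipeline configuration: three outcomes, five imputations,
# shortened Gibbs chain. Generator overrides mirror GeneratorParams fields.
p: 3
M: 5
burn_in: 100
between: 50
n_quad: 9
scale: desk
generator:
  n_hospitals: 6
  clinicians_per_hospital: [10.0, 8.0]
  patients_per_clinician: [6.0, 2.0, 3, 46]
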