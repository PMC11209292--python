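# Generic adult rat physiology (0.25 kg) for translating in vivo BMDL doses
# to plasma concentrations.
species: rat
body_weight: 0.25
volumes:                 # L
  gut: 0.011
  liver: 0.0103
  kidney: 0.0025
  lung: 0.0021
  rest: 0.197
  arterial: 0.0045
  venous: 0.0113
flows:                   # L/h
  gut: 0.81
  hepatic_artery: 0.11
  kidney: 0.76
  rest: 3.72
cardiac_output: 5.4
gfr: 0.08
hepatocellularity: 110.0
liver_mass: 10.3         # g
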