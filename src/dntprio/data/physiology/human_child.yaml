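# Generic human toddler physiology (nominal 15 kg, within the 10.75-20.25 kg
# body weights used by the oral-dose equations).  Volumes scale linearly and
# flows allometrically (bw^0.75) from the adult table.
species: human_child
body_weight: 15.0
volumes:                 # L
  gut: 0.257
  liver: 0.386
  kidney: 0.066
  lung: 0.107
  rest: 10.29
  arterial: 0.364
  venous: 0.836
flows:                   # L/h
  gut: 17.0
  hepatic_artery: 6.0
  kidney: 20.7
  rest: 50.5
cardiac_output: 94.2
gfr: 2.36
hepatocellularity: 110.0
liver_mass: 386.0
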