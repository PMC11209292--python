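# Generic human adult physiology for the flow-limited PBTK model.
# Values are rounded literature-scale defaults (editable); tissue blood
# flows must sum exactly to cardiac_output.
species: human_adult
body_weight: 70.0        # kg
volumes:                 # L
  gut: 1.2
  liver: 1.8
  kidney: 0.31
  lung: 0.5
  rest: 48.0
  arterial: 1.7
  venous: 3.9
flows:                   # L/h
  gut: 54.0
  hepatic_artery: 19.0
  kidney: 66.0
  rest: 161.0
cardiac_output: 300.0    # L/h
gfr: 7.5                 # L/h (~125 mL/min)
hepatocellularity: 110.0 # 1e6 cells per g liver
liver_mass: 1800.0       # g
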