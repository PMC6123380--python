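# Ionic-model variants: multiplicative conductance scalings relative to the
# published baseline human atrial model.  Values follow the chronic-AF and
# fibrotic remodeling conventions of the patient-specific atrial modeling
# literature: AF remodeling reduces I_CaL, I_to and I_Kur and doubles I_K1;
# fibrosis-affected myocytes additionally lose I_Na, I_CaL and I_K1.
baseline:
  model: detailed
  scalings: {gNa: 1.0, gK1: 1.0, gto: 1.0, gKur: 1.0, gCaL: 1.0}
  Cm: 100.0
chronic_af:
  model: detailed
  scalings: {gNa: 1.0, gK1: 2.0, gto: 0.5, gKur: 0.5, gCaL: 0.3}
  Cm: 100.0
chronic_af_fibrotic:
  model: detailed
  # relative to chronic_af: I_Na x0.6, I_CaL x0.5, I_K1 x0.5
  scalings: {gNa: 0.6, gK1: 1.0, gto: 0.5, gKur: 0.5, gCaL: 0.15}
  Cm: 100.0
reduced_test:
  model: reduced
  scalings: {exc: 1.0, rep: 1.0}
  Cm: 100.0
reduced_test_fibrotic:
  model: reduced
  # lowered excitability and prolonged repolarization in
  # fibrosis-affected tissue
  scalings: {exc: 0.8, rep: 0.7}
  Cm: 100.0
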