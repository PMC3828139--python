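{
  "alpha": 2.1,
  "beta": 0.067,
  "gamma": 0.57,
  "tau_r": 50.0,
  "n_y": 3.0,
  "tau_y": 20.0,
  "n_z": 7.0,
  "tau_z": 20.0,
  "label": "B",
  "units": "ms, photons/um^2/ms, mV",
  "notes": "Fit to turtle-cone step families of Burkhardt; kernel shape values and tau_r were set to typical values rather than fitted."
}
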