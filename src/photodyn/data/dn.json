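{
  "alpha": 1.4,
  "beta": 0.074,
  "gamma": 0.22,
  "tau_r": 66.0,
  "n_y": 3.7,
  "tau_y": 18.0,
  "n_z": 7.8,
  "tau_z": 13.0,
  "label": "DN",
  "units": "ms, photons/um^2/ms, mV",
  "notes": "Fit to turtle-cone flash-on-background traces of Daly and Normann."
}
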