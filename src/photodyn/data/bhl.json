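{
  "alpha": 1.1,
  "beta": 0.044,
  "gamma": 0.93,
  "tau_r": 39.0,
  "n_y": 1.5,
  "tau_y": 38.0,
  "n_z": 7.0,
  "tau_z": 20.0,
  "label": "BHL",
  "units": "ms, photons/um^2/ms, mV",
  "notes": "Fit to turtle-cone flash data of Baylor, Hodgkin and Lamb."
}
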