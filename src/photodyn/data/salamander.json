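{
  "alpha": 2.0,
  "beta": 0.16,
  "gamma": 0.23,
  "tau_r": 28.0,
  "n_y": 4.0,
  "tau_y": 33.0,
  "n_z": 10.0,
  "tau_z": 19.0,
  "label": "Salamander Fit",
  "units": "ms, photons/um^2/ms, mV",
  "notes": "Fit to salamander cone flicker recordings; alpha was reported in arbitrary units and is stored here at the typical magnitude of 2 mV um^2 ms/photon."
}
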