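{
  "seed": 1,
  "out_dir": "demo_out",
  "stages": ["traces", "indent", "ephys"],
  "traces": {"n_cells": 60, "responder_frac": 0.6},
  "indent": {"E_true_kPa": 15.0, "side_um": 2.0, "spacing_um": 0.5},
  "ephys": {"basal_mean": 50.13, "inhibited_mean": 13.8, "sd": 5.0, "n_per_group": 27}
}
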