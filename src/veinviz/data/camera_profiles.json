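{
  "Low light": {"gain": 2.0, "exposure": 1.0, "contrast": 1.0},
  "Medium light": {"gain": 1.3, "exposure": 1.0, "contrast": 1.0},
  "Very bright": {"gain": 0.7, "exposure": 1.0, "contrast": 1.2},
  "LED profile": {"gain": 1.0, "exposure": 1.0, "contrast": 1.4}
}
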