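bmi_class,failures,attempts
1,23,80
2,119,360
3,34,60
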