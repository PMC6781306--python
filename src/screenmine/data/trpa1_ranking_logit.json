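{
 "b_class": 2.725,
 "b_pic50": 3.967,
 "b_dg": -0.404,
 "intercept": -29.986
}
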