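# SYNTHETIC EXAMPLE impurity values (not a manufacturer certificate).
# Plausible magnitudes for demonstrating and testing the correction only.
channel,minus2,minus1,plus1,plus2
114,0.0,1.0,5.9,0.2
115,0.0,2.0,5.6,0.1
116,0.0,3.0,4.5,0.1
117,0.1,4.0,3.5,0.1
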