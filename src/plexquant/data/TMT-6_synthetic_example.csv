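# SYNTHETIC EXAMPLE impurity values (not a manufacturer certificate).
channel,minus2,minus1,plus1,plus2
126,0.0,0.0,6.1,0.0
127,0.0,0.5,6.7,0.0
128,0.0,1.1,4.2,0.0
129,0.0,1.7,4.1,0.0
130,0.0,1.6,3.2,0.0
131,0.2,3.1,2.8,0.0
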