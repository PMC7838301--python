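# SYNTHETIC EXAMPLE impurity values (not a manufacturer certificate).
channel,minus2,minus1,plus1,plus2
126,0.0,0.0,5.0,0.0
127N,0.0,0.2,5.8,0.0
127C,0.0,0.3,4.8,0.1
128N,0.0,0.6,4.1,0.1
128C,0.0,0.9,3.7,0.1
129N,0.0,1.2,3.3,0.1
129C,0.0,1.4,2.9,0.1
130N,0.1,1.7,2.8,0.0
130C,0.1,1.9,2.2,0.0
131,0.1,2.4,1.8,0.0
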