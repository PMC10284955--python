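method_a,method_b,wins_a,wins_b
linear,supervised,13,107
linear,unsupervised,10,110
supervised,unsupervised,57,63
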