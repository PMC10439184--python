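pattern	spectral_class	note
Karlodinium micrum	BPR	experimentally blue-shifted; database annotation is green-type
Ceratium fusus	BPR	experimentally blue-shifted; database annotation is green-type
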