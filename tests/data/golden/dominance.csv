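category,dominance,n_evaluated,n_significant
Structural,0.144914,15,2
Signaling,0.267056,17,4
Energy,0.563014,10,5
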