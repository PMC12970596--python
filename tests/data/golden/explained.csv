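component,explained_fraction
PC1,0.675196
PC2,0.218205
PC3,0.105408
PC4,0.000951783
PC5,0.000239194
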