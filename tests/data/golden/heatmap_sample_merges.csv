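left,right,height,count
0,1,4.869792337,2
3,4,5.002221516,2
2,6,6.633540554,3
5,7,6.77757064,3
8,9,11.93788381,6
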