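sample,LV1,LV2
EXP_1,4.73882,3.07083
EXP_2,4.88365,0.60303
EXP_3,4.95822,-3.5378
CTRL_1,-4.92835,3.04938
CTRL_2,-4.89762,0.513461
CTRL_3,-4.75472,-3.69891
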