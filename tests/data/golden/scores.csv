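sample,PC1,PC2,PC3,PC4,PC5
EXP_1,-4.69718,-2.91284,-1.81439,-0.213105,0.0765418
EXP_2,-4.87473,-0.909082,2.61168,-0.0246198,-0.130017
EXP_3,-5.0074,3.62206,-0.814461,0.236807,0.0547437
CTRL_1,4.97003,-2.84816,-1.85507,0.208189,-0.074259
CTRL_2,4.90564,-0.781997,2.6919,0.0247267,0.126752
CTRL_3,4.70364,3.83003,-0.81965,-0.231997,-0.0537617
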