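index,PC1,PC2,PC3,PC4,PC5
cardiolipin_fraction,0.18614,0.0348141,0.0377143,-0.00228578,0.0581324
ce_total,0.177875,0.0897097,0.0803486,-0.0832777,0.118291
chol_plmem,0.0294479,-0.323297,0.062803,-0.0360324,-0.0074418
chol_sm,0.00454145,-0.321539,-0.108153,-0.0544074,0.030403
double_bond_index,-0.18759,-0.0111775,0.0125778,-0.0667354,0.0713822
mono_poly,0.187722,0.00405139,0.000760257,0.0983929,-0.112421
odd_even_chain,-0.184327,0.0459427,0.057701,0.222608,-0.205062
oxpl_pl,-0.18768,-0.00980249,0.00701215,-0.0147334,-0.0249363
pc_unsat_sat,-0.0204589,0.313504,0.140327,0.0682381,-0.0476811
pe_pc,0.026894,-0.312995,0.135794,-0.0267936,-0.0186561
membrane_fluidity,-0.0393381,0.285942,-0.216049,0.0478054,0.0721081
pl_sm,-0.0424252,-0.192934,-0.370458,-0.052983,0.114565
saturation_index,0.187384,-0.0143665,-0.0193194,0.119606,-0.122528
sm_pc,0.0668969,0.0862965,0.426351,0.030868,-0.0760945
structural_energetic,0.187075,0.0270095,-0.0068651,-0.103095,-0.149369
lysopl_pl,-0.186476,0.0176308,0.0457061,0.160305,-0.276318
aa_dha,-0.172361,0.12024,-0.0727811,0.176441,0.181807
bmp_fraction,0.158073,-0.0871676,-0.222793,0.158298,-0.319513
cer_sm,-0.186079,-0.0419079,0.00826446,-0.201166,-0.0801534
ceramide_fraction,-0.186302,-0.0378554,0.0199342,-0.133293,-0.112745
dg_pl,0.0108599,-0.305271,0.179443,-0.032001,-0.0338996
ether_fraction,-0.143502,-0.122787,-0.247599,0.370512,-0.308424
ferroptosis_index,-0.121761,-0.206303,0.19928,0.543413,0.434685
gm3_gm2,-0.186936,0.0269427,-0.011788,0.189117,0.178719
lpc_pc,-0.186696,0.0139463,0.043001,0.140885,-0.281343
lpe_pe,-0.00455392,0.32976,0.024789,0.0534816,-0.00777415
lyso_o_pl_o,0.00130434,-0.133218,0.434855,-0.00963815,-0.117756
lyso_p_pl_p,0.187411,0.0179405,0.0143071,-0.051946,0.0367187
lyso_pl_matched,-0.186311,0.0285031,0.0369687,0.206743,-0.206108
pa_pl,0.0115774,-0.198458,-0.378766,-0.032147,0.0854052
pi_pl,0.0104322,0.307024,-0.173306,0.0326716,0.0337715
omega6_omega3,-0.186997,0.0248678,-0.0217609,0.0716411,0.200335
acylcarnitine_fraction,0.176981,-0.0952046,-0.0789635,0.158943,-0.0864749
dg_tg,0.185815,-0.0392203,0.0289167,0.252527,0.226801
energy_load,-0.187419,-0.0177979,0.0137187,-0.0624755,-0.00382769
long_medium_chain,-0.187144,-0.0262989,-0.00805472,-0.0658866,0.0344213
neutral_polar,-0.187434,-0.0182173,0.00920621,-0.0887394,-0.00522772
short_long_chain,0.184792,-0.0451264,-0.0519722,0.140348,-0.146164
storage_index,-0.187504,-0.0175007,0.00270077,-0.0616003,0.00808214
tg_ce,-0.186404,-0.0357029,-0.0183135,-0.178771,0.14447
tg_fa,-0.18605,-0.0411766,0.0162097,-0.192804,-0.143689
tg_pl,-0.187393,-0.0203167,0.00575825,-0.076157,-0.0285665
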