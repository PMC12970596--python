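sample,cardiolipin_fraction,ce_total,chol_plmem,chol_sm,double_bond_index,mono_poly,odd_even_chain,oxpl_pl,pc_unsat_sat,pe_pc,membrane_fluidity,pl_sm,saturation_index,sm_pc,structural_energetic,lysopl_pl,aa_dha,bmp_fraction,cer_sm,ceramide_fraction,dg_pl,ether_fraction,ferroptosis_index,gm3_gm2,lpc_pc,lpe_pe,lyso_o_pl_o,lyso_p_pl_p,lyso_pl_matched,pa_pl,pi_pl,omega6_omega3,acylcarnitine_fraction,dg_tg,energy_load,long_medium_chain,neutral_polar,short_long_chain,storage_index,tg_ce,tg_fa,tg_pl
EXP_1,0.00929367,0.044733,0.267039,3.46429,1.74307,1.80835,0.0112351,0.0098085,4.8644,0.174604,3.53649,12.1337,0.821913,0.108162,1.58162,0.0414599,1.65833,0.00118372,0.343469,0.0125534,0.0356572,0.0319897,0.0356824,2.11373,0.0461343,0.0474083,0.123832,0.115028,0.059812,0.0089984,0.0509059,14.0186,0.000759323,0.0612319,0.456622,894.389,0.605133,0.000438714,0.342364,5.95656,28.3211,0.582331
EXP_2,0.00949016,0.0472974,0.264993,3.36,1.74723,1.81323,0.0124487,0.00994711,5.21759,0.17443,3.50915,11.8386,0.815584,0.110539,1.58341,0.0454868,1.64498,0.00102963,0.3399,0.0126899,0.0361529,0.030182,0.0362151,2.13592,0.0510689,0.0484791,0.143817,0.118788,0.0652759,0.00785566,0.050583,13.8796,0.000715721,0.0619079,0.461596,884.821,0.60839,0.000413686,0.342059,5.64367,28.4506,0.58398
EXP_3,0.00950452,0.047893,0.255874,3.2598,1.73949,1.8122,0.012593,0.00979405,5.48104,0.164154,3.65701,11.8973,0.814624,0.109293,1.64494,0.0447994,1.86306,0.00107612,0.313824,0.0118425,0.0306546,0.0307182,0.0347543,2.3134,0.0499748,0.0504243,0.118622,0.118835,0.0659793,0.00807568,0.0547578,14.784,0.000702508,0.0542828,0.44901,874.874,0.59151,0.000410206,0.334344,5.4824,26.0076,0.564721
CTRL_1,0.0111337,0.0539646,0.268369,3.46429,1.54682,2.26661,0.00690688,0.00445841,4.82362,0.175827,3.5119,12.0694,0.941247,0.108919,3.2366,0.0224045,1.26716,0.00141582,0.156122,0.0067845,0.0358471,0.0301826,0.0345858,0.960784,0.021117,0.0474083,0.123832,0.253061,0.0323981,0.00904633,0.0511909,7.92157,0.000908137,0.13471,0.263433,658.103,0.329687,0.00059623,0.160941,2.70753,12.8732,0.266106
CTRL_2,0.011384,0.057163,0.266328,3.36,1.55453,2.2566,0.00765699,0.00452141,5.17388,0.175665,3.48448,11.775,0.930066,0.111321,3.23792,0.0243312,1.25081,0.00123304,0.1545,0.00686653,0.0363482,0.0278899,0.0350894,0.970874,0.0233775,0.0484791,0.143817,0.261333,0.0349988,0.00789809,0.0508701,7.8932,0.000857059,0.136197,0.268513,650.425,0.33438,0.000562767,0.161051,2.56531,12.9321,0.266879
CTRL_3,0.011364,0.0576922,0.257144,3.2598,1.54886,2.25003,0.00772589,0.00445184,5.43646,0.165291,3.63186,11.8343,0.927219,0.11005,3.38988,0.0239624,1.43729,0.00128456,0.142647,0.00638965,0.0308177,0.0283372,0.0331354,1.05155,0.0228732,0.0504243,0.118622,0.261438,0.0353801,0.00811863,0.0550651,8.48196,0.000838519,0.119422,0.260565,644.721,0.326227,0.000556642,0.15731,2.492,11.8216,0.258056
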