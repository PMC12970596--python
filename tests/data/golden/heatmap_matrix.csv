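sample,pc_unsat_sat,lpe_pe,membrane_fluidity,pi_pl,ether_fraction,aa_dha,double_bond_index,oxpl_pl,energy_load,storage_index,neutral_polar,tg_pl,cer_sm,ceramide_fraction,tg_fa,long_medium_chain,tg_ce,gm3_gm2,omega6_omega3,odd_even_chain,lyso_pl_matched,lysopl_pl,lpc_pc,pl_sm,pa_pl,ferroptosis_index,chol_sm,chol_plmem,pe_pc,dg_pl,sm_pc,lyso_o_pl_o,bmp_fraction,acylcarnitine_fraction,short_long_chain,ce_total,cardiolipin_fraction,structural_energetic,lyso_p_pl_p,dg_tg,mono_poly,saturation_index
EXP_3,1.13723,1.20926,1.42391,1.21056,0.546346,1.40961,0.876712,0.893719,0.847839,0.859172,0.843774,0.840474,0.721224,0.741801,0.715754,0.834691,0.78457,1.09782,1.0721,1.0839,1.04374,0.983227,0.968316,-0.190929,-0.471245,-0.147359,-1.11051,-1.37855,-1.38632,-1.31567,-0.366511,-0.851954,-0.905809,-1.13383,-1.02121,-0.644446,-0.834055,-0.865929,-0.895403,-1.02384,-0.908798,-0.95299
EXP_1,-1.08989,-0.996118,-0.260797,-0.633247,1.37839,0.567738,0.910565,0.898628,0.920312,0.94056,0.935282,0.942992,1.01786,0.968967,0.994527,0.986944,1.06195,0.794358,0.845472,0.564166,0.665202,0.686314,0.706744,1.45348,1.22431,0.728755,1.12541,0.696551,0.543279,0.516838,-1.35157,-0.414042,-0.142548,-0.451214,-0.683352,-1.21581,-1.03923,-0.934406,-0.944638,-0.847486,-0.924517,-0.838141
EXP_2,0.18574,-0.213145,-0.642985,-0.787779,0.195489,0.512843,0.949823,0.945721,0.967662,0.937459,0.95716,0.952588,0.982143,1.01259,1.01014,0.912296,0.878914,0.828092,0.804311,1.02866,1.00056,1.04434,1.04283,-0.598903,-0.875549,1.23166,-0.0149061,0.316229,0.511172,0.69842,0.718071,1.266,-1.23554,-0.975083,-0.979973,-0.752134,-0.848037,-0.932466,-0.896018,-0.83033,-0.904599,-0.937856
CTRL_3,0.976212,1.20926,1.07225,1.35764,-1.01169,-0.341254,-0.92383,-0.921312,-0.946262,-0.937334,-0.938072,-0.944757,-0.991553,-1.00064,-0.993649,-0.960947,-0.964801,-0.819909,-0.793876,-0.77896,-0.834358,-0.869387,-0.877543,-0.628716,-0.392321,-1.67564,-1.11051,-1.14244,-1.17637,-1.25595,0.292648,-0.851954,0.572729,0.500315,0.714255,1.12736,0.975367,1.02096,0.948576,0.629313,0.881088,0.821035
CTRL_1,-1.23716,-0.996118,-0.604538,-0.496817,0.195861,-1.04085,-0.943019,-0.919081,-0.918958,-0.900489,-0.914832,-0.897898,-0.85672,-0.874465,-0.866934,-0.856539,-0.838718,-0.957847,-0.959802,-1.09243,-1.01739,-1.0079,-0.997155,1.00634,1.31238,-0.306398,1.12541,0.943707,0.769025,0.586409,-0.692143,-0.414042,1.50388,1.33675,1.18343,0.453364,0.75121,0.855205,0.840258,1.0173,0.948868,1.04206
CTRL_2,0.0278676,-0.213145,-0.987845,-0.650349,-1.30439,-1.10808,-0.870252,-0.897675,-0.870593,-0.899369,-0.883313,-0.893398,-0.872954,-0.848253,-0.859838,-0.916445,-0.921917,-0.942513,-0.9682,-0.805332,-0.857762,-0.836595,-0.843194,-1.04127,-0.797581,0.168988,-0.0149061,0.564504,0.73921,0.76995,1.3995,1.266,0.207293,0.723062,0.78685,1.03167,0.994747,0.85664,0.947224,1.05505,0.907959,0.865893
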