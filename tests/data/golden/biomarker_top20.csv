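rank,index_id,name,category,n_exp,n_ctrl,mean_exp,mean_ctrl,log2fc,se_log2fc,t,df,p_value,cohens_d,auc,power,comparable
1,double_bond_index,Double Bond Index,Structural,3,3,1.74327,1.55007,0.16946,0.00283371,60.1481,3.99634,4.62651e-07,49.1107,1,1,True
2,oxpl_pl,OxPL/PL Index,Structural,3,3,0.00984989,0.00447722,1.1375,0.0101061,100.249,2.79261,4.73354e-06,81.8529,1,1,True
3,energy_load,Energy Load Index,Energy,3,3,0.455743,0.264171,0.786749,0.0171835,44.1904,3.38725,8.48358e-06,36.0813,1,1,True
4,long_medium_chain,Long/Medium Chain,Energy,3,3,884.694,651.083,0.442338,0.0125782,34.1589,3.54736,1.34991e-05,27.8906,1,1,True
5,storage_index,Storage Index,Energy,3,3,0.339589,0.159767,1.08782,0.0157307,62.0593,2.83735,1.56057e-05,50.6712,1,1,True
6,mono_poly,Mono/Poly Ratio,Structural,3,3,1.81126,2.25775,-0.317892,0.00329888,-88.5319,2.37519,3.09641e-05,-72.286,1,1,True
7,neutral_polar,Neutral/Polar,Energy,3,3,0.601678,0.330098,0.866097,0.0161337,47.7757,2.8002,3.66183e-05,39.0087,1,1,True
8,tg_pl,TG/PL Index,Energy,3,3,0.577011,0.26368,1.12981,0.0218098,46.2269,2.80268,3.98612e-05,37.7441,1,1,True
9,lyso_p_pl_p,Lyso-P/PL-P (matched),Signaling,3,3,0.11755,0.258611,-1.1375,0.0218927,-46.2769,2.79261,4.09465e-05,-37.7849,1,1,True
10,cardiolipin_fraction,Cardiolipin Fraction,Structural,3,3,0.00942945,0.0112939,-0.260297,0.0146134,-17.7152,3.89443,7.2209e-05,-14.4644,1,1,True
11,omega6_omega3,ω6/ω3 Index,Signaling,3,3,14.2274,8.09891,0.812874,0.0444865,18.0087,3.52892,0.000133886,14.704,1,1,True
12,saturation_index,Saturation Index,Structural,3,3,0.817374,0.932844,-0.19064,0.00775412,-23.791,3.05518,0.000143662,-19.4253,1,1,True
13,structural_energetic,Structural/Energetic,Structural,3,3,1.60332,3.28813,-1.0362,0.029139,-30.6507,2.65141,0.000185808,-25.0262,1,1,True
14,ceramide_fraction,Ceramide Fraction,Signaling,3,3,0.0123619,0.00668023,0.887936,0.0441651,18.8683,3.14333,0.000243264,15.4059,1,1,True
15,tg_ce,TG/CE Index,Energy,3,3,5.69421,2.58828,1.1375,0.0498731,20.3141,2.79261,0.000405648,16.5864,1,1,True
16,cer_sm,Cer/SM Index,Signaling,3,3,0.332398,0.15109,1.1375,0.0573543,17.6644,2.79261,0.000597889,14.4229,1,1,True
17,tg_fa,TG/FA Index,Energy,3,3,27.5931,12.5423,1.1375,0.0586824,17.2646,2.79261,0.000637067,14.0965,1,1,True
18,gm3_gm2,GM3/GM2 Ratio,Signaling,3,3,2.18768,0.994401,1.1375,0.0589278,17.1927,2.79261,0.000644476,14.0378,1,1,True
19,lpc_pc,LPC/PC Index,Signaling,3,3,0.0490593,0.0224559,1.12743,0.0622357,16.1662,2.80332,0.000748729,13.1997,1,1,True
20,lysopl_pl,(LPC+LPE)/PL Index,Signaling,3,3,0.0439154,0.023566,0.898018,0.0545516,14.7812,2.85804,0.000868663,12.0688,1,1,True
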