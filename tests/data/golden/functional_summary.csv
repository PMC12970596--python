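index_id,name,category,n_exp,n_ctrl,mean_exp,mean_ctrl,log2fc,se_log2fc,t,df,p_value,cohens_d,auc,power,comparable,significant,interpretation
cardiolipin_fraction,Cardiolipin Fraction,Structural,3,3,0.00942945,0.0112939,-0.260297,0.0146134,-17.7152,3.89443,7.2209e-05,-14.4644,1,1,True,False,
ce_total,CE/Total Index,Structural,3,3,0.0466411,0.0562733,-0.270848,0.0423124,-6.35729,3.87281,0.00349898,-5.1907,1,0.995342,True,False,
chol_plmem,Chol/PLmem Index,Structural,3,3,0.262635,0.263947,-0.00718938,0.0266731,-0.269535,3.99986,0.800852,-0.220074,0.666667,0.0551687,True,False,
chol_sm,Chol/SM Index,Structural,3,3,3.36136,3.36136,0,0.0358317,0,4,1,0,0.5,0.05,True,False,
double_bond_index,Double Bond Index,Structural,3,3,1.74327,1.55007,0.16946,0.00283371,60.1481,3.99634,4.62651e-07,49.1107,1,1,True,False,
mono_poly,Mono/Poly Ratio,Structural,3,3,1.81126,2.25775,-0.317892,0.00329888,-88.5319,2.37519,3.09641e-05,-72.286,1,1,True,False,
odd_even_chain,Odd/Even Chain,Structural,3,3,0.0120923,0.00742992,0.702667,0.0723386,9.2472,3.30441,0.00179246,7.5503,1,0.999996,True,False,
oxpl_pl,OxPL/PL Index,Structural,3,3,0.00984989,0.00447722,1.1375,0.0101061,100.249,2.79261,4.73354e-06,81.8529,1,1,True,True,"Oxidized phospholipids accumulate, indicating lipid peroxidation and oxidative membrane stress."
pc_unsat_sat,PC Unsat/Sat Index,Structural,3,3,5.18768,5.14466,0.0120148,0.0703273,0.17084,3.99984,0.872643,0.139491,0.666667,0.0520744,True,False,
pe_pc,PE/PC Index,Structural,3,3,0.171063,0.172261,-0.01007,0.0412424,-0.244163,3.99969,0.819118,-0.199358,0.777778,0.0542401,True,False,
membrane_fluidity,Membrane Fluidity Index,Structural,3,3,3.56755,3.54275,0.0100663,0.0260185,0.386892,3.99994,0.718539,0.315896,0.666667,0.0606681,True,False,
pl_sm,PL/SM Index,Structural,3,3,11.9565,11.8929,0.00769567,0.0154052,0.49955,3.99996,0.64362,0.407881,0.777778,0.0678233,True,False,
saturation_index,Saturation Index,Structural,3,3,0.817374,0.932844,-0.19064,0.00775412,-23.791,3.05518,0.000143662,-19.4253,1,1,True,False,
sm_pc,SM/PC Index,Structural,3,3,0.109331,0.110097,-0.0100682,0.0128342,-0.78447,3.99954,0.476622,-0.640517,0.666667,0.0942413,True,False,
structural_energetic,Structural/Energetic,Structural,3,3,1.60332,3.28813,-1.0362,0.029139,-30.6507,2.65141,0.000185808,-25.0262,1,1,True,True,"Neutral storage lipids dominate over membrane lipids, indicating lipid storage or membrane loss."
lysopl_pl,(LPC+LPE)/PL Index,Signaling,3,3,0.0439154,0.023566,0.898018,0.0545516,14.7812,2.85804,0.000868663,12.0688,1,1,True,False,
aa_dha,AA/DHA Index,Signaling,3,3,1.72213,1.31842,0.385383,0.0880438,4.36982,3.89142,0.0127201,3.56795,1,0.896822,True,False,
bmp_fraction,BMP Fraction,Signaling,3,3,0.00109649,0.00131114,-0.257929,0.0847924,-3.02257,3.88216,0.0406042,-2.46792,1,0.625395,True,False,
cer_sm,Cer/SM Index,Signaling,3,3,0.332398,0.15109,1.1375,0.0573543,17.6644,2.79261,0.000597889,14.4229,1,1,True,True,"Ceramide rises against sphingomyelin, indicating sphingomyelinase-driven stress and pro-apoptotic signaling."
ceramide_fraction,Ceramide Fraction,Signaling,3,3,0.0123619,0.00668023,0.887936,0.0441651,18.8683,3.14333,0.000243264,15.4059,1,1,True,False,
dg_pl,DG/PL Index,Signaling,3,3,0.0341549,0.0343377,-0.00769848,0.104912,-0.0733798,3.99987,0.945027,-0.0599143,0.666667,0.0503825,True,False,
ether_fraction,Ether Lipid Fraction,Signaling,3,3,0.0309633,0.0288032,0.10433,0.0431159,2.44633,3.74137,0.0751068,1.99742,0.888889,0.461728,True,False,
ferroptosis_index,Ferroptosis Susceptibility Index,Signaling,3,3,0.0355506,0.0342702,0.0529174,0.0301329,1.76666,3.65678,0.158722,1.44247,0.888889,0.27546,True,False,
gm3_gm2,GM3/GM2 Ratio,Signaling,3,3,2.18768,0.994401,1.1375,0.0589278,17.1927,2.79261,0.000644476,14.0378,1,1,True,True,"GM3 rises against GM2, consistent with hexosaminidase-driven GM2 catabolism or ST3GAL5 activity."
lpc_pc,LPC/PC Index,Signaling,3,3,0.0490593,0.0224559,1.12743,0.0622357,16.1662,2.80332,0.000748729,13.1997,1,1,True,True,"LPC accumulates relative to PC, indicating phospholipase-A or LCAT-driven PC deacylation."
lpe_pe,LPE/PE Index,Signaling,3,3,0.0487706,0.0487706,0,0.0369288,0,4,1,0,0.5,0.05,True,False,
lyso_o_pl_o,Lyso-O/PL-O (matched),Signaling,3,3,0.128757,0.128757,0,0.121677,0,4,1,0,0.5,0.05,True,False,
lyso_p_pl_p,Lyso-P/PL-P (matched),Signaling,3,3,0.11755,0.258611,-1.1375,0.0218927,-46.2769,2.79261,4.09465e-05,-37.7849,1,1,True,True,"Intact plasmalogens dominate their matched lyso forms, indicating plasmalogen reacylation."
lyso_pl_matched,Lyso/PL (matched),Signaling,3,3,0.0636891,0.034259,0.894563,0.0592136,13.6083,2.87741,0.00106089,11.1111,1,1,True,False,
pa_pl,PA/PL Index,Signaling,3,3,0.00830991,0.00835435,-0.00769415,0.085931,-0.0895382,3.9999,0.932958,-0.0731077,0.666667,0.0505695,True,False,
pi_pl,PI/PL Index,Signaling,3,3,0.0520823,0.0523754,-0.00809714,0.0525236,-0.154161,3.99989,0.884948,-0.125872,0.666667,0.0516889,True,False,
omega6_omega3,ω6/ω3 Index,Signaling,3,3,14.2274,8.09891,0.812874,0.0444865,18.0087,3.52892,0.000133886,14.704,1,1,True,False,
acylcarnitine_fraction,Acylcarnitine Fraction,Energy,3,3,0.00072585,0.000867905,-0.257865,0.0485929,-5.26511,3.85997,0.00687733,-4.29894,1,0.969447,True,False,
dg_tg,DG/TG Index,Energy,3,3,0.0591408,0.13011,-1.1375,0.0840679,-12.0513,2.79261,0.00171991,-9.83985,1,1,True,True,"Triacylglycerol dominates its DG precursor, indicating net TG synthesis (DGAT flux)."
energy_load,Energy Load Index,Energy,3,3,0.455743,0.264171,0.786749,0.0171835,44.1904,3.38725,8.48358e-06,36.0813,1,1,True,False,
long_medium_chain,Long/Medium Chain,Energy,3,3,884.694,651.083,0.442338,0.0125782,34.1589,3.54736,1.34991e-05,27.8906,1,1,True,False,
neutral_polar,Neutral/Polar,Energy,3,3,0.601678,0.330098,0.866097,0.0161337,47.7757,2.8002,3.66183e-05,39.0087,1,1,True,False,
short_long_chain,Short/Long Chain,Energy,3,3,0.000420869,0.00057188,-0.442342,0.0437113,-9.91463,3.65973,0.000895136,-8.09526,1,0.999999,True,False,
storage_index,Storage Index,Energy,3,3,0.339589,0.159767,1.08782,0.0157307,62.0593,2.83735,1.56057e-05,50.6712,1,1,True,True,"Triacylglycerol storage is expanded relative to the rest of the lipidome, indicating net energy storage."
tg_ce,TG/CE Index,Energy,3,3,5.69421,2.58828,1.1375,0.0498731,20.3141,2.79261,0.000405648,16.5864,1,1,True,True,Neutral-lipid storage shifts from cholesteryl esters toward triacylglycerols.
tg_fa,TG/FA Index,Energy,3,3,27.5931,12.5423,1.1375,0.0586824,17.2646,2.79261,0.000637067,14.0965,1,1,True,True,Fatty acids are sequestered into TG (net esterification) rather than circulating free.
tg_pl,TG/PL Index,Energy,3,3,0.577011,0.26368,1.12981,0.0218098,46.2269,2.80268,3.98612e-05,37.7441,1,1,True,True,"Triacylglycerols expand against membrane phospholipids, indicating energy storage over membrane synthesis."
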