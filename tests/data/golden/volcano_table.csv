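index_id,name,category,log2fc,se_log2fc,p_value,significant,interpretation
cardiolipin_fraction,Cardiolipin Fraction,Structural,-0.260297,0.0146134,7.2209e-05,False,
ce_total,CE/Total Index,Structural,-0.270848,0.0423124,0.00349898,False,
chol_plmem,Chol/PLmem Index,Structural,-0.00718938,0.0266731,0.800852,False,
chol_sm,Chol/SM Index,Structural,0,0.0358317,1,False,
double_bond_index,Double Bond Index,Structural,0.16946,0.00283371,4.62651e-07,False,
mono_poly,Mono/Poly Ratio,Structural,-0.317892,0.00329888,3.09641e-05,False,
odd_even_chain,Odd/Even Chain,Structural,0.702667,0.0723386,0.00179246,False,
oxpl_pl,OxPL/PL Index,Structural,1.1375,0.0101061,4.73354e-06,True,"Oxidized phospholipids accumulate, indicating lipid peroxidation and oxidative membrane stress."
pc_unsat_sat,PC Unsat/Sat Index,Structural,0.0120148,0.0703273,0.872643,False,
pe_pc,PE/PC Index,Structural,-0.01007,0.0412424,0.819118,False,
membrane_fluidity,Membrane Fluidity Index,Structural,0.0100663,0.0260185,0.718539,False,
pl_sm,PL/SM Index,Structural,0.00769567,0.0154052,0.64362,False,
saturation_index,Saturation Index,Structural,-0.19064,0.00775412,0.000143662,False,
sm_pc,SM/PC Index,Structural,-0.0100682,0.0128342,0.476622,False,
structural_energetic,Structural/Energetic,Structural,-1.0362,0.029139,0.000185808,True,"Neutral storage lipids dominate over membrane lipids, indicating lipid storage or membrane loss."
lysopl_pl,(LPC+LPE)/PL Index,Signaling,0.898018,0.0545516,0.000868663,False,
aa_dha,AA/DHA Index,Signaling,0.385383,0.0880438,0.0127201,False,
bmp_fraction,BMP Fraction,Signaling,-0.257929,0.0847924,0.0406042,False,
cer_sm,Cer/SM Index,Signaling,1.1375,0.0573543,0.000597889,True,"Ceramide rises against sphingomyelin, indicating sphingomyelinase-driven stress and pro-apoptotic signaling."
ceramide_fraction,Ceramide Fraction,Signaling,0.887936,0.0441651,0.000243264,False,
dg_pl,DG/PL Index,Signaling,-0.00769848,0.104912,0.945027,False,
ether_fraction,Ether Lipid Fraction,Signaling,0.10433,0.0431159,0.0751068,False,
ferroptosis_index,Ferroptosis Susceptibility Index,Signaling,0.0529174,0.0301329,0.158722,False,
gm3_gm2,GM3/GM2 Ratio,Signaling,1.1375,0.0589278,0.000644476,True,"GM3 rises against GM2, consistent with hexosaminidase-driven GM2 catabolism or ST3GAL5 activity."
lpc_pc,LPC/PC Index,Signaling,1.12743,0.0622357,0.000748729,True,"LPC accumulates relative to PC, indicating phospholipase-A or LCAT-driven PC deacylation."
lpe_pe,LPE/PE Index,Signaling,0,0.0369288,1,False,
lyso_o_pl_o,Lyso-O/PL-O (matched),Signaling,0,0.121677,1,False,
lyso_p_pl_p,Lyso-P/PL-P (matched),Signaling,-1.1375,0.0218927,4.09465e-05,True,"Intact plasmalogens dominate their matched lyso forms, indicating plasmalogen reacylation."
lyso_pl_matched,Lyso/PL (matched),Signaling,0.894563,0.0592136,0.00106089,False,
pa_pl,PA/PL Index,Signaling,-0.00769415,0.085931,0.932958,False,
pi_pl,PI/PL Index,Signaling,-0.00809714,0.0525236,0.884948,False,
omega6_omega3,ω6/ω3 Index,Signaling,0.812874,0.0444865,0.000133886,False,
acylcarnitine_fraction,Acylcarnitine Fraction,Energy,-0.257865,0.0485929,0.00687733,False,
dg_tg,DG/TG Index,Energy,-1.1375,0.0840679,0.00171991,True,"Triacylglycerol dominates its DG precursor, indicating net TG synthesis (DGAT flux)."
energy_load,Energy Load Index,Energy,0.786749,0.0171835,8.48358e-06,False,
long_medium_chain,Long/Medium Chain,Energy,0.442338,0.0125782,1.34991e-05,False,
neutral_polar,Neutral/Polar,Energy,0.866097,0.0161337,3.66183e-05,False,
short_long_chain,Short/Long Chain,Energy,-0.442342,0.0437113,0.000895136,False,
storage_index,Storage Index,Energy,1.08782,0.0157307,1.56057e-05,True,"Triacylglycerol storage is expanded relative to the rest of the lipidome, indicating net energy storage."
tg_ce,TG/CE Index,Energy,1.1375,0.0498731,0.000405648,True,Neutral-lipid storage shifts from cholesteryl esters toward triacylglycerols.
tg_fa,TG/FA Index,Energy,1.1375,0.0586824,0.000637067,True,Fatty acids are sequestered into TG (net esterification) rather than circulating free.
tg_pl,TG/PL Index,Energy,1.12981,0.0218098,3.98612e-05,True,"Triacylglycerols expand against membrane phospholipids, indicating energy storage over membrane synthesis."
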