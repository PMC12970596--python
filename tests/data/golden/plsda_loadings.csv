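index,LV1,LV2
cardiolipin_fraction,-0.186308,-0.0342074
ce_total,-0.178294,-0.091429
chol_plmem,-0.0280281,0.320501
chol_sm,-0.00309712,0.32725
double_bond_index,0.187643,0.0079473
mono_poly,-0.187747,-0.00151011
odd_even_chain,0.184119,-0.0514838
oxpl_pl,0.187729,0.0068564
pc_unsat_sat,0.0190448,-0.3211
pe_pc,-0.0255331,0.306383
membrane_fluidity,0.0381123,-0.275343
pl_sm,0.0433496,0.211559
saturation_index,-0.187323,0.0179446
sm_pc,-0.0673599,-0.107461
structural_energetic,-0.1872,-0.0240802
lysopl_pl,0.186396,-0.0225752
aa_dha,0.171847,-0.118867
bmp_fraction,-0.157651,0.100883
cer_sm,0.18627,0.0389287
ceramide_fraction,0.186472,0.0342662
dg_pl,-0.00954076,0.296177
ether_fraction,0.144097,0.133632
ferroptosis_index,0.122642,0.194328
gm3_gm2,0.186825,-0.0289147
lpc_pc,0.186633,-0.0187527
lpe_pe,0.0030885,-0.331157
lyso_o_pl_o,-0.000794145,0.110743
lyso_p_pl_p,-0.187499,-0.0161009
lyso_pl_matched,0.186184,-0.0329952
pa_pl,-0.0106289,0.218256
pi_pl,-0.011761,-0.297955
omega6_omega3,0.186897,-0.0263204
acylcarnitine_fraction,-0.176551,0.101738
dg_tg,-0.185653,0.0402831
energy_load,0.187502,0.014511
long_medium_chain,0.187268,0.0241447
neutral_polar,0.187519,0.0151646
short_long_chain,-0.184589,0.0503629
storage_index,0.187587,0.0147831
tg_ce,0.186572,0.0340958
tg_fa,0.186235,0.0377856
tg_pl,0.187488,0.0174428
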