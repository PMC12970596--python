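index,VIP
cardiolipin_fraction,1.2094
ce_total,1.16102
chol_plmem,0.165996
chol_sm,0.0354045
double_bond_index,1.21641
mono_poly,1.21677
odd_even_chain,1.18959
oxpl_pl,1.21684
pc_unsat_sat,0.109329
pe_pc,0.150854
membrane_fluidity,0.23283
pl_sm,0.295972
saturation_index,1.2128
sm_pc,0.444637
structural_energetic,1.2145
lysopl_pl,1.20609
aa_dha,1.10674
bmp_fraction,1.01506
cer_sm,1.20936
ceramide_fraction,1.2103
dg_pl,0.0539618
ether_fraction,0.942379
ferroptosis_index,0.805982
gm3_gm2,1.20893
lpc_pc,1.20787
lpe_pe,0.0353059
lyso_o_pl_o,0.00907818
lyso_p_pl_p,1.21594
lyso_pl_matched,1.20415
pa_pl,0.0600996
pi_pl,0.098403
omega6_omega3,1.20964
acylcarnitine_fraction,1.13781
dg_tg,1.20066
energy_load,1.21583
long_medium_chain,1.215
neutral_polar,1.21601
short_long_chain,1.19306
storage_index,1.21645
tg_ce,1.21123
tg_fa,1.209
tg_pl,1.21594
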