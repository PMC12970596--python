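enzyme,direction,balance_exp,balance_ctrl,supporting_indices,reaction
SGMS1,indeterminate,0.148542,0.15248,,Cer + PC -> SM + DG
SGMS2,indeterminate,0.148542,0.15248,,Cer + PC -> SM + DG
SMPD1,forward-increased,0.3322,0.151,,SM -> Cer
CERS2,forward-increased,1.32703,0.603196,,sphingoid base + acyl-CoA (proxied by FA) -> Cer
DGAT1,forward-increased,16.9044,7.68382,dg_tg;storage_index;tg_ce;tg_fa;tg_pl,DG + acyl-CoA -> TG
DGAT2,forward-increased,16.9044,7.68382,dg_tg;tg_ce;tg_fa;tg_pl,DG + acyl-CoA -> TG
PNPLA2,forward-decreased,0.0954521,0.209995,tg_fa,TG -> DG + FA
LIPE,indeterminate,0.613562,0.613562,tg_fa,DG -> MG + FA
LPL,forward-decreased,0.036296,0.0798511,dg_tg;storage_index;tg_ce;tg_pl,TG -> glycerol + FA
PLA2G4A,forward-increased,0.0764364,0.0500202,oxpl_pl,PC -> LPC + FA
LPCAT3,forward-decreased,20.3801,44.5245,,LPC + acyl-CoA -> PC (Lands cycle)
PEMT,indeterminate,5.84821,5.80754,,PE -> PC
SCD1,indeterminate,3.72327,3.72327,,saturated FA -> monounsaturated FA
SOAT1,indeterminate,0.360863,0.360863,,cholesterol + acyl-CoA -> CE
CPT1A,indeterminate,0.0788282,0.0788282,structural_energetic,acyl-CoA (proxied by FA) + carnitine -> acylcarnitine
PLD1,indeterminate,0.0108601,0.0109362,lpc_pc,PC -> PA + choline
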