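# Curated minimal table of lipid reactions used for enzyme-direction calls.
# Human gene symbols; selectors use the same vocabulary as the index library.
# Co-substrates that are not lipids measurable in a lipidomics matrix
# (acyl-CoA, carnitine, choline headgroups...) are omitted; completeness is
# not claimed.

- enzyme: SGMS1
  name: sphingomyelin synthase 1
  substrates: [{classes: [Cer]}, {classes: [PC]}]
  products: [{classes: [SM]}, {classes: [DG]}]
  note: Cer + PC -> SM + DG

- enzyme: SGMS2
  name: sphingomyelin synthase 2
  substrates: [{classes: [Cer]}, {classes: [PC]}]
  products: [{classes: [SM]}, {classes: [DG]}]
  note: Cer + PC -> SM + DG

- enzyme: SMPD1
  name: acid sphingomyelinase
  substrates: [{classes: [SM]}]
  products: [{classes: [Cer]}]
  note: SM -> Cer

- enzyme: CERS2
  name: ceramide synthase 2
  substrates: [{classes: [FA]}]
  products: [{classes: [Cer]}]
  note: sphingoid base + acyl-CoA (proxied by FA) -> Cer

- enzyme: DGAT1
  name: diacylglycerol O-acyltransferase 1
  substrates: [{classes: [DG]}]
  products: [{classes: [TG]}]
  note: DG + acyl-CoA -> TG

- enzyme: DGAT2
  name: diacylglycerol O-acyltransferase 2
  substrates: [{classes: [DG]}]
  products: [{classes: [TG]}]
  note: DG + acyl-CoA -> TG

- enzyme: PNPLA2
  name: adipose triglyceride lipase (ATGL)
  substrates: [{classes: [TG]}]
  products: [{classes: [DG]}, {classes: [FA]}]
  note: TG -> DG + FA

- enzyme: LIPE
  name: hormone-sensitive lipase
  substrates: [{classes: [DG]}]
  products: [{classes: [MG]}, {classes: [FA]}]
  note: DG -> MG + FA

- enzyme: LPL
  name: lipoprotein lipase
  substrates: [{classes: [TG]}]
  products: [{classes: [FA]}]
  note: TG -> glycerol + FA

- enzyme: PLA2G4A
  name: cytosolic phospholipase A2
  substrates: [{classes: [PC]}]
  products: [{classes: [LPC]}, {classes: [FA]}]
  note: PC -> LPC + FA

- enzyme: LPCAT3
  name: lysophosphatidylcholine acyltransferase 3
  substrates: [{classes: [LPC]}]
  products: [{classes: [PC]}]
  note: LPC + acyl-CoA -> PC (Lands cycle)

- enzyme: PEMT
  name: phosphatidylethanolamine N-methyltransferase
  substrates: [{classes: [PE]}]
  products: [{classes: [PC]}]
  note: PE -> PC

- enzyme: SCD1
  name: stearoyl-CoA desaturase 1
  substrates: [{classes: [FA], species_db_max: 0}]
  products: [{classes: [FA], species_db_min: 1, species_db_max: 1}]
  note: saturated FA -> monounsaturated FA

- enzyme: SOAT1
  name: sterol O-acyltransferase 1 (ACAT1)
  substrates: [{classes: [Chol]}]
  products: [{classes: [CE]}]
  note: cholesterol + acyl-CoA -> CE

- enzyme: CPT1A
  name: carnitine palmitoyltransferase 1A
  substrates: [{classes: [FA]}]
  products: [{classes: [CAR]}]
  note: acyl-CoA (proxied by FA) + carnitine -> acylcarnitine

- enzyme: PLD1
  name: phospholipase D1
  substrates: [{classes: [PC]}]
  products: [{classes: [PA]}]
  note: PC -> PA + choline
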