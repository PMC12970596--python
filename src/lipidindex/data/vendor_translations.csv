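vendor_name,shorthand_name
CholEster,CE
ChE,CE
CholE,CE
Cholesteryl ester,CE
TAG,TG
DAG,DG
MAG,MG
Cholesterol,Chol
FC,Chol
LysoPC,LPC
LysoPE,LPE
LysoPA,LPA
LysoPI,LPI
LysoPG,LPG
LysoPS,LPS
AcCa,CAR
AcCar,CAR
CerP,Cer
PlsPC,PC P
PlsPE,PE P
GPCho,PC
GPEtn,PE
GPSer,PS
GPIns,PI
GPGro,PG
GPA,PA
FFA,FA
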