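gene	coefficient
ARPC5L	0.5170
CYP19A1	0.7593
ESYT1	-0.3070
FDXR	-0.2311
HSPD1	0.3795
IGLL1	-0.0791
KRBOX4	0.3644
PLPP3	0.2472
RIOK2	-0.4239
STK25	0.4301
TNKS2	-0.3409
TRIM8	0.2820
ULK1	-0.3810
ZMIZ1	0.2613
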