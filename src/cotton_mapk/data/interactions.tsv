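upstream	downstream	tier	source
MEKK4_2	MKK1	KKK-KK	Y2H
MEKK10_1	MKK1	KKK-KK	Y2H
MEKK3_2	MKK2_2	KKK-KK	Y2H
MEKK5_1	MKK3	KKK-KK	Y2H
MEKK17	MKK3	KKK-KK	Y2H
MEKK19	MKK3	KKK-KK	Y2H
RAF31_1	MKK3	KKK-KK	Y2H
RAF38_3	MKK3	KKK-KK	Y2H
MEKK4_2	MKK4	KKK-KK	Y2H
MEKK20	MKK4	KKK-KK	Y2H
MEKK20	MKK5	KKK-KK	Y2H
ZIK1	MKK5	KKK-KK	Y2H
RAF30_1	MKK5	KKK-KK	Y2H
ZIK1	MKK10_1	KKK-KK	Y2H
CTR1_1	MKK10_1	KKK-KK	Y2H
RAF17_2	MKK10_1	KKK-KK	Y2H
RAF30_1	MKK10_1	KKK-KK	Y2H
RAF32	MKK10_1	KKK-KK	Y2H
MKK1	MPK6	KK-K	Y2H
MKK1	MPK12	KK-K	Y2H
MKK2_2	MPK3	KK-K	Y2H
MKK2_2	MPK6	KK-K	Y2H
MKK2_2	MPK18	KK-K	Y2H
MKK2_2	MPK12	KK-K	Y2H
MKK2_2	MPK23	KK-K	Y2H
MKK3	MPK20	KK-K	Y2H
MKK3	MPK25	KK-K	Y2H
MKK3	MPK7	KK-K	Y2H
MKK3	MPK15	KK-K	Y2H
MKK4	MPK8	KK-K	Y2H
MKK4	MPK20	KK-K	Y2H
MKK5	MPK13	KK-K	Y2H
MKK5	MPK3	KK-K	Y2H
MKK5	MPK6	KK-K	Y2H
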