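0	rCRS
1	M	489,10400,14783,15043
2	D	5178A
3	D4	3010,8414,14668
4	D4a	3206,14979
5	D4a1	1438,489!
4	D4b	8020,15440
3	D5	1107,5301,10397
2	G	4833,8200,14569
2	M7	6455,9824
3	M7b	4071,6680,12811
2	M8	4715,7196,8584
3	C	3552,9545,13263
3	Z	6752,9090,15784
1	N	10873,15301
2	A	663,4824,8794
2	N9	5417,16257
3	Y	8392,10398,14178
2	R	12705
3	B4	827,15535,16217
3	B5	709,9950
3	F	6962,10310,13928
4	F1	6392,10609
3	R9	3970,16304
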