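time_h,amount_mg
0,0
1,0.914
2,1.093
3,0.997
4,0.952
5,0.626
6,0.684
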